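"""Tile-level ChIP-seq enrichment on a simulated library with planted domains.

Builds a toy two-chromosome genome, plants enrichment domains of 2x/4x/8x
over a flat background, simulates 100k ChIP and input reads, and runs the
full tile pipeline: genome-unique counting, depth normalization with
pseudocount, and background-median correction.
"""

import numpy as np
import pandas as pd

import rhinotools as rt
from rhinotools import simulate as sim
from rhinotools.tiles import compute_mappability

genome = sim.sim_genome(seed=1)
tiles = rt.make_tiles({c: len(genome.sequences[c]) for c in genome.nuclear_chroms})
compute_mappability(tiles, genome.mappable_blocks())

chip, inp, truth = sim.sim_chip(genome, n_reads=100_000, seed=2)
table = rt.run_chip_pipeline(rt.PipelineConfig(rng_seed=1), chip, inp, tiles)

print(f"tiles: {len(tiles)}  correction factor: {table.correction_factor:.4f}")
mult = pd.Series(truth.tile_multipliers)
for m in (1.0, 2.0, 4.0, 8.0):
    ids = mult[mult == m].index
    est = table.values.loc[ids].mean()
    print(f"planted {m:>3.0f}x over {len(ids):>3} tiles -> estimated {est:6.3f}")

curated = tiles.curated_mask()
print(f"median corrected enrichment over curated tiles: "
      f"{np.median(table.values.to_numpy()[curated]):.6f}")
print("Each planted multiplier is recovered by the corrected enrichment; the "
      "background median is pinned to 1 by construction of the correction factor.")
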
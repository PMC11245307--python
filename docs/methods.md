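# Methods

`rhinotools` implements the computational core of a heterochromatin / piRNA
study design built around the germline HP1-family protein Rhino: tile-based
ChIP-seq enrichment with background-median correction, small-RNA (piRNA)
quantification with explicit multimapper rules, a binary Rhino-dependence
classifier, subfamily-discriminative residue scanning of protein family
alignments, and rigid-body chromodomain superposition with steric-clash
analysis. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not establish.

## Genomic tiles and curation

The genome is partitioned per chromosome into non-overlapping fixed-width
tiles (`tile_size`, default 1000 bp). The terminal tile of each chromosome is
retained at its true (shorter) length, and all per-base quantities
(mappability fraction, per-position coverage) use that true length; dropping
chromosome ends silently seemed worse, and the curation filters remove
pathological short tiles anyway.

Three independent filters mark tiles unusable; a tile may carry several
labels and is *curated* iff it carries none:

* **mappability** — fraction of the tile covered by blocks of continuous
  mappability below `mappability_min` (default 0.25). The mappability track
  is an input, not computed here.
* **input_deviation** — read count in a representative input library more
  than `input_deviation_fold` (default 3) away from the median over tiles.
  The deviation is interpreted two-sided (count > 3x median, or
  count < median/3) with strict inequality: deviation is directionless, and
  the two tails capture collapsed-repeat pileups and dead zones
  respectively. Exactly threefold is retained.
* **ko_residual** — log2 ChIP enrichment in a knockout library above
  `ko_residual_log2_max` (default 1.0). "Strong residual signal" has no
  published numeric definition, so the package exposes a configurable
  log2 ceiling; 1.0 (twofold) is the default because residual signal below
  twofold is within the noise band of background tiles at typical depths.

Curation is idempotent, and lowering the mappability floor can only retain
more tiles (monotonicity); both are asserted by tests.

## ChIP enrichment

Per tile, only genome-unique reads (exactly one best-stratum alignment) are
counted. Each read is assigned to exactly one tile by its **midpoint**; the
5' end is available as a configurable alternative. The assignment rule is a
package choice — either is defensible, and midpoint avoids double counting
across tile boundaries.

Counts are scaled to reads-per-million (`depth_scale` / library depth, where
depth is the library's total genome-unique mapped reads, including reads on
no tile), a pseudocount of 1 is added to both ChIP and input, and the ratio
taken:

    E(t) = (chip_rpm(t) + 1) / (input_rpm(t) + 1)

Because immunoprecipitation efficiency varies between samples, every sample
is rescaled by a correction factor `1 / median(E over background tiles)` so
the background median enrichment is exactly 1. The background unit set
defaults to all curated tiles — the genome is overwhelmingly non-enriched,
so the median over curated tiles estimates the background level without
requiring an explicit background annotation; an explicit mask can be
supplied instead. Enrichment is computed and stored in linear space; log2 is
applied only in the reported column, so the correction stays multiplicative.

For transposon consensus mapping, reads longer than 23 nt
(`te_min_read_length` = 24) are kept; each multimapping read is assigned to
its unique minimal-mismatch hit, with exact ties broken uniformly at random.
The tie-break uses one seeded generator per library and processes reads in
lexicographic read-id order, so results are bit-reproducible regardless of
input ordering. Per element, depth-normalized coverage is averaged over all
consensus positions, the pseudocount ratio is formed, and the sample's
tile-derived correction factor is applied. Replicates are averaged as the
arithmetic mean of log2 enrichments (a geometric mean in linear space).

## Small-RNA processing

Raw reads carry the cloning architecture
`[4 random nt] insert [6 random nt] [5 nt barcode] [3' linker]`. The
published chemistry fixes the component sizes but not every positional
detail, so the layout is configurable; the default places the random
hexamer and barcode 5' of the constant linker. Trimming finds the leftmost
linker occurrence allowing `max_linker_mismatches` (default 1) and a
truncated linker of at least 6 nt at the read end, strips linker + barcode +
random nucleotides, and rejects reads with no linker (`no_adapter`) or an
insert shorter than 18 nt (`too_short`). Barcodes are recorded but reads are
not collapsed by them: whether the random nucleotides were used for
deduplication is unstated upstream, and not collapsing is the conservative
choice.

After genome mapping (0 mismatches, all best hits — consumed from SAM/BAM
or from the package's exact-match aligner), a read is removed if **any** hit
touches an rRNA/tRNA/snRNA/snoRNA locus or the mitochondrial chromosome.
miRNA reads are defined by locus overlap of any hit (not by length, since
normalization is to *sequenced miRNA reads*, a locus-defined quantity).
Remaining reads of 23–29 nt are piRNA candidates. All downstream tables are
scaled by the same factor `1e6 / miRNA reads`; a library with zero miRNA
reads is a hard error because the normalization is undefined.

## piRNA quantification and dependence

* **Per transposon:** only reads assigned antisense to the consensus are
  counted; counts are scaled by the miRNA factor and by 1000/length
  (reads per kb), so elements of different length are comparable.
* **Per cluster (locus-unique multimappers):** a read counts once for
  cluster C iff the strand-aware 5' end (leftmost base on +, rightmost on −)
  of *every* genome hit falls inside C — reads with any hit outside all
  clusters, or hits in two clusters, count nowhere; multiple hits within C
  still count once. A brute-force enumeration oracle checks this rule on
  randomized instances.
* **Per tile:** the same locus-unique rule applied at tile granularity
  (every hit's 5' end inside one cluster tile), used for per-tile log2 fold
  changes across genotypes; tiles with a zero count in any genotype are
  excluded and reported.
* **Dependence:** an element is *dependent* when its normalized antisense
  level in the test condition is at most `control / dependence_fold`
  (default 2). The boundary — exactly twofold — is called dependent
  ("a twofold reduction" read as *at least* twofold; a fixed rule is
  required for testability). Zero-control elements are unclassifiable.

## Subfamily residue and indel scanning

Alignment columns covered by fewer than `msa_min_column_coverage` (default
0.70, inclusive) of sequences are removed first. Each remaining column is
scored by a deterministic frequency contrast: the focal consensus is the
modal non-gap residue among focal rows (ties alphabetical), and

    score = freq(consensus | focal) − freq(consensus | non-focal) ∈ [−1, 1],

with gaps counting in both denominators so sparse columns cannot score
spuriously high. This is a deterministic surrogate for sampling-based
relief-style feature weighting: reproducible, parameter-free, and in exact
agreement on the clear-cut columns (score 1 ⇔ residue fixed in the focal
subfamily and absent outside it) that motivate the analysis. Columns near
threshold may rank differently than a sampling-based weighting would.
Focal-specific insertions are columns ≥90% occupied in the focal subfamily
and ≤10% occupied outside (defaults; the symmetric case is reported as a
deletion).

## Structure comparison

Superposition is the closed-form least-squares rigid fit (Kabsch, via SVD
with a determinant correction enforcing a proper rotation) over paired
atoms — by default the Cα atoms of caller-supplied residue ranges, paired by
order. Pairing by order rather than by sequence alignment is deliberate: the
analysis this reproduces states its residue window explicitly, and embedding
an aligner would hide that choice. Selections of fewer than 3 atoms or of
rank < 2 (collinear) are rejected because the rotation is underdetermined.
Structures are read with gemmi: first model only, waters dropped, alternate
locations resolved to the highest-occupancy conformer.

Steric clashes are inter-group atom pairs with distance <
r(A) + r(B) − tolerance, with van der Waals radii C 1.70, N 1.55, O 1.52,
S 1.80 Å and tolerance 0.4 Å, hydrogens excluded by default (experimental
and predicted structures rarely carry them consistently). Reports are
sorted by overlap depth.

The real-structure worked example (laying the HP1a chromodomain, PDB 6MHA,
onto Rhino chromodomain residues 26–57 of PDB 4U68, expected RMSD ≈ 0.55 Å)
runs whenever the two public PDB files are placed under `tests/data/`; they
are not redistributed with the package.

## Synthetic data: what it emulates, and what it does not

`simulate.sim_genome` builds two 100-kb chromosomes plus a 5-kb
mitochondrial chromosome, three transposon consensi (2/1.5/1 kb) with exact
copies embedded so reads drawn from them are genuine multimappers: TE1 twice
inside cluster *42AB* (locus-unique multimappers), TE2 split between *42AB*
and *38C* (disqualified by the locus-unique rule), TE3 single-copy outside
clusters. It plants two low-mappability blocks, four structural-ncRNA loci,
four miRNA loci, and records everything in a truth object.

`sim_chip` samples input reads uniformly and ChIP reads proportionally to
per-tile multipliers (background 1; planted domains of five tiles each at
2x, 4x and 8x), at 100k reads per library — enough that per-domain
estimates carry a relative sampling error of a few percent. `sim_srna`
emits raw FASTQ with the full adapter architecture; the default composition
(20k/10k miRNA reads; thousands of TE antisense reads) plants
miRNA-normalized antisense fold changes of 8x, 4x and 1x across the two
genotypes, plus cluster-unique reads, ncRNA/mitochondrial contaminants, and
31-nt reads that fall outside the piRNA length range. Expected category
counts, normalization factors, per-TE counts and cluster counts are
computed analytically from the composition, so the pipeline tests assert
exact equality, not approximate recovery.

Deliberately absent from the simulation: sequencing errors and quality
variation, mismatched alignments (the exact-match aligner mirrors the
0-mismatch small-RNA rule but cannot exercise the ≤3-mismatch ChIP regime's
mismatch tie-breaking beyond planted ties), PCR duplicates, chromatin
fragment-length structure, and realistic genome repeat complexity. Passing
tests therefore demonstrate that the counting rules, normalizations and
classifiers implement their definitions and recover planted truth under
clean sampling noise — not that the pipeline is robust to artefacts of real
libraries.

## Numerical and reproducibility notes

* All genomic intervals are 0-based half-open internally; BED is native,
  GFF converted on ingest (1-based inclusive → half-open).
* The background median after correction equals 1 to within one double ulp
  (the worst observed deviation is ~1e-16 for even-sized backgrounds, where
  the median is the mean of two scaled values).
* Every stochastic step (multimapper tie-breaks, all simulators) takes an
  explicit integer seed; pipelines are byte-reproducible for fixed inputs
  and seed, and multimapper assignment is additionally invariant to input
  ordering.
* Degenerate inputs fail loudly and early: zero library depth, empty
  background, zero-length elements, zero miRNA reads, chromosome-name
  mismatches between alignments and tiles, unknown elements in the radii
  table.

## Problem sizes

Default test and acceptance-script workloads: 200 one-kb tiles, 100k reads
per ChIP library, ~35k/~13k reads per small-RNA library, 100 randomized
oracle instances, 1000 random rigid transforms for the optimality check, and
a 32-row × 80-column alignment — sizes chosen so every planted effect is
several standard errors away from its decision boundary while the whole
suite runs in well under a minute.
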
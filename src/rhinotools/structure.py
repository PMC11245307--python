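"""Rigid-body superposition of structure selections and steric-clash detection.

Superposition is the closed-form least-squares (Kabsch) fit over paired
atoms — by default the Cα atoms of caller-supplied residue ranges, matched
by order, mirroring how one chromodomain is laid onto another over a stated
residue window. Clash detection enumerates inter-group atom pairs closer
than the sum of van der Waals radii minus a tolerance (0.4 Å default),
hydrogens excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "SuperpositionResult",
    "ClashPair",
    "ClashReport",
    "DEFAULT_VDW_RADII",
    "load_structure",
    "kabsch",
    "superpose",
    "apply_transform",
    "detect_clashes",
]

# van der Waals radii in Å for clash detection
DEFAULT_VDW_RADII: Dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: Tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    number: int
    name: str
    atoms: Dict[str, Atom] = field(default_factory=dict)


@dataclass
class StructureModel:
    id: str
    chains: Dict[str, List[Residue]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> List[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.id} "
                f"(chains: {sorted(self.chains)})"
            )
        return self.chains[chain_id]

    def select_atoms(
        self,
        chain_id: str,
        first: Optional[int] = None,
        last: Optional[int] = None,
        atom_name: Optional[str] = "CA",
    ) -> List[Tuple[str, Atom]]:
        """Atoms of residues [first, last] (inclusive, by author numbering).

        atom_name=None selects all atoms of each residue. Labels are
        ``chain/resname resnum/atom``.
        """
        out = []
        for res in self.chain(chain_id):
            if first is not None and res.number < first:
                continue
            if last is not None and res.number > last:
                continue
            atoms = (
                [res.atoms[atom_name]] if atom_name is not None and atom_name in res.atoms
                else list(res.atoms.values()) if atom_name is None
                else []
            )
            for atom in atoms:
                out.append((f"{chain_id}/{res.name}{res.number}/{atom.name}", atom))
        return out

    def coords(self, selection: Sequence[Tuple[str, Atom]]) -> np.ndarray:
        return np.array([a.xyz for _, a in selection], dtype=float)


def load_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Read PDB/mmCIF into a light structure model.

    Only one model is kept (the first by default); waters are dropped;
    alternate locations are resolved to the highest-occupancy conformer.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    st.setup_entities()
    model = st[model_index]
    out = StructureModel(id=st.name or Path(path).stem)
    for chain in model:
        residues: List[Residue] = []
        for res in chain:
            if res.name in WATER_NAMES or res.is_water():
                continue
            residue = Residue(number=res.seqid.num, name=res.name)
            for atom in res:
                current = residue.atoms.get(atom.name)
                if current is None or atom.occ > current.occupancy:
                    residue.atoms[atom.name] = Atom(
                        name=atom.name,
                        element=atom.element.name.upper(),
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                    )
            if residue.atoms:
                residues.append(residue)
        if residues:
            out.chains[chain.name] = residues
    if not out.chains:
        raise ValueError(f"structure file {path} contains no non-water atoms")
    return out


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_atoms: int
    selection: Tuple[str, str] = ("", "")  # (mobile, target) selection strings


def kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid transform mapping mobile onto target.

    Returns rotation R (proper, det +1) and translation t such that
    ``mobile @ R.T + t`` best fits target, with the residual RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"paired coordinate sets must both be (N, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired atoms, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinear selections leave a rotation degree of freedom undetermined
    for name, X in (("mobile", P0), ("target", Q0)):
        if np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, np.abs(X).max())) < 2:
            raise ValueError(f"degenerate (collinear) {name} selection")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def superpose(
    mobile: StructureModel,
    mobile_selection: Tuple[str, int, int],
    target: StructureModel,
    target_selection: Tuple[str, int, int],
    atom_name: str = "CA",
) -> SuperpositionResult:
    """Superpose Cα atoms of a mobile residue range onto a target range.

    Selections are (chain, first residue, last residue), inclusive in author
    numbering; atoms are paired by order, so the two ranges must yield
    equally many atoms.
    """
    msel = mobile.select_atoms(*mobile_selection, atom_name=atom_name)
    tsel = target.select_atoms(*target_selection, atom_name=atom_name)
    if len(msel) != len(tsel):
        raise ValueError(
            f"selection size mismatch: mobile {len(msel)} vs target {len(tsel)} "
            f"{atom_name} atoms"
        )
    result = kabsch(mobile.coords(msel), target.coords(tsel))
    result.selection = (
        f"{mobile_selection[0]}:{mobile_selection[1]}-{mobile_selection[2]}/{atom_name}",
        f"{target_selection[0]}:{target_selection[1]}-{target_selection[2]}/{atom_name}",
    )
    return result


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


@dataclass(frozen=True)
class ClashPair:
    atom_a: str
    atom_b: str
    distance: float
    cutoff: float  # radius(A) + radius(B) - tolerance

    @property
    def overlap(self) -> float:
        return self.cutoff - self.distance


@dataclass
class ClashReport:
    pairs: List[ClashPair]
    tolerance: float
    radii: Dict[str, float]

    def __len__(self) -> int:
        return len(self.pairs)


def detect_clashes(
    group_a: Sequence[Tuple[str, Atom]],
    group_b: Sequence[Tuple[str, Atom]],
    radii: Optional[Mapping[str, float]] = None,
    tolerance: float = 0.4,
    include_hydrogens: bool = False,
) -> ClashReport:
    """All inter-group atom pairs closer than rA + rB - tolerance.

    Pairs are sorted by overlap depth (worst first). An element without a
    radius raises, naming the atom.
    """
    radii = dict(radii or DEFAULT_VDW_RADII)

    def prepare(group):
        kept = []
        for label, atom in group:
            if not include_hydrogens and atom.element in {"H", "D"}:
                continue
            if atom.element not in radii:
                raise ValueError(
                    f"no van der Waals radius for element {atom.element!r} (atom {label})"
                )
            kept.append((label, atom))
        return kept

    a, b = prepare(group_a), prepare(group_b)
    pairs: List[ClashPair] = []
    if a and b:
        from scipy.spatial import cKDTree

        xa = np.array([at.xyz for _, at in a])
        xb = np.array([at.xyz for _, at in b])
        max_cut = max(radii[at.element] for _, at in a) + max(
            radii[at.element] for _, at in b
        )
        tree = cKDTree(xb)
        for i, (label_a, atom_a) in enumerate(a):
            for j in tree.query_ball_point(xa[i], max_cut):
                label_b, atom_b = b[j]
                cutoff = radii[atom_a.element] + radii[atom_b.element] - tolerance
                dist = float(np.linalg.norm(xa[i] - xb[j]))
                if dist < cutoff:
                    pairs.append(ClashPair(label_a, label_b, dist, cutoff))
    pairs.sort(key=lambda p: p.overlap, reverse=True)
    return ClashReport(pairs=pairs, tolerance=tolerance, radii=dict(radii))
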
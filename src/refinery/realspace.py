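"""Real-space density-fit scoring and rebuild candidate selection.

The weighted-mean density fit of a group of atoms scores how well the
atoms sit in an electron-density map: each map grid point within an atom's
radius contributes the density there, tapered linearly with distance from
the atom centre, and atoms are weighted by occupancy and (inversely) by
their mean displacement.  On the normalized 2mFo−DFc scale this score
drives water pruning: waters fitting the map worse than 0.37 are removed —
a resolution-independent cutoff chosen to minimize false positives — with
waters involved in LINK records always kept.

The rebuild selectors are conservative filters: by default every residue is
a candidate, with negative selection for residues where unsupervised
rebuilding is risky (linked backbones, secondary-structure middles for
peptide flips; linked or multi-conformer side chains for side-chain
rebuilds).  The validation-driven final pass positively selects only the
enumerated residue types and issues, with the negative selectors still in
force.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Literal, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import InvalidInputError, UndefinedFitError
from .modelprep import AtomRecord

__all__ = [
    "GridMap",
    "FitScore",
    "density_fit",
    "centrifuge",
    "rebuild_candidates",
    "validation_tasks",
    "CENTRIFUGE_CUTOFF",
    "DEFAULT_ATOM_RADII",
]

#: weighted-mean density fit below which a water is removed
CENTRIFUGE_CUTOFF = 0.37

#: fallback per-element atom radii in Å (config-overridable)
DEFAULT_ATOM_RADII: Dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
_FALLBACK_RADIUS = 1.7

_EIGHT_PI_SQ = 8.0 * math.pi * math.pi


@dataclass
class GridMap:
    """A gridded density volume on an axis-aligned orthogonal grid."""

    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidInputError("values must be a 3-D array")
        if min(self.spacing) <= 0:
            raise InvalidInputError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("map values must be finite")


@dataclass(frozen=True)
class FitScore:
    score: float
    n_grid_points: int


def linear_taper(dist: np.ndarray, radius: float) -> np.ndarray:
    """Default taper ``t(x) = max(0, 1 − |x − x_a|/r_atom)``."""
    return np.maximum(0.0, 1.0 - dist / radius)


def density_fit(
    grid: GridMap,
    atoms: Sequence[AtomRecord],
    radius_table: Optional[Dict[str, float]] = None,
    taper: Callable[[np.ndarray, float], np.ndarray] = linear_taper,
) -> FitScore:
    """Weighted mean fit of a group of atoms to the map.

    ``score = Σ_a w_a Σ_g t(x_g)·ρ(x_g) / Σ_a w_a Σ_g t(x_g)`` over grid
    points with non-zero taper, with atom weight ``w_a = occ/(1 + U_a)``
    where ``U = B/8π²`` is the mean displacement.  The taper is pluggable
    so an alternative kernel can be swapped in.  Scores are evaluated at
    grid points only (no interpolation).
    """
    if not atoms:
        raise InvalidInputError("atoms must be non-empty")
    radii = dict(DEFAULT_ATOM_RADII)
    if radius_table:
        radii.update(radius_table)
    origin = np.asarray(grid.origin, dtype=float)
    spacing = np.asarray(grid.spacing, dtype=float)
    shape = grid.values.shape

    num = 0.0
    den = 0.0
    n_points = 0
    for a in atoms:
        r_atom = radii.get(a.element.strip().upper(), _FALLBACK_RADIUS)
        pos = np.asarray(a.position, dtype=float)
        lo_idx = np.floor((pos - r_atom - origin) / spacing).astype(int)
        hi_idx = np.ceil((pos + r_atom - origin) / spacing).astype(int)
        lo_idx = np.maximum(lo_idx, 0)
        hi_idx = np.minimum(hi_idx, np.array(shape) - 1)
        if np.any(lo_idx > hi_idx):
            continue
        ax = [origin[d] + spacing[d] * np.arange(lo_idx[d], hi_idx[d] + 1)
              for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        dist = np.sqrt((gx - pos[0]) ** 2 + (gy - pos[1]) ** 2 + (gz - pos[2]) ** 2)
        t = taper(dist, r_atom)
        mask = t > 0.0
        if not np.any(mask):
            continue
        rho = grid.values[lo_idx[0]:hi_idx[0] + 1,
                          lo_idx[1]:hi_idx[1] + 1,
                          lo_idx[2]:hi_idx[2] + 1]
        u = a.b_factor / _EIGHT_PI_SQ
        w = a.occupancy / (1.0 + u)
        num += w * float(np.sum(t[mask] * rho[mask]))
        den += w * float(np.sum(t[mask]))
        n_points += int(np.count_nonzero(mask))
    if n_points == 0 or den == 0.0:
        raise UndefinedFitError("no grid point within any atom radius")
    return FitScore(score=num / den, n_grid_points=n_points)


def centrifuge(
    waters: Sequence[Tuple[AtomRecord, FitScore]],
    linked_water_ids: Optional[Set] = None,
    cutoff: float = CENTRIFUGE_CUTOFF,
) -> Tuple[List[AtomRecord], List[AtomRecord]]:
    """Split waters into (kept, removed) by density fit.

    A water is removed iff its fit score is strictly below the cutoff and
    it is not involved in any LINK record.
    """
    linked = linked_water_ids or set()
    kept: List[AtomRecord] = []
    removed: List[AtomRecord] = []
    for atom, fit in waters:
        if fit.score < cutoff and atom.atom_id() not in linked:
            removed.append(atom)
        else:
            kept.append(atom)
    return kept, removed


# ---------------------------------------------------------------------------
# rebuild candidate selection

ResidueId = Tuple[str, int]  # (chain, res_seq)
SecondaryStructure = Literal["helix_mid", "strand_mid", "other"]

_BACKBONE_FLIP_ATOMS = {"N", "O"}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class RebuildEligibility:
    peptide_flip: bool
    sidechain: bool


def rebuild_candidates(
    residues: Sequence[ResidueId],
    linked_atoms: Iterable[Tuple[str, int, str]] = (),
    altloc_residues: Iterable[ResidueId] = (),
    ss: Optional[Dict[ResidueId, SecondaryStructure]] = None,
) -> Dict[ResidueId, RebuildEligibility]:
    """Per-residue eligibility flags for the rebuilding stages.

    ``linked_atoms`` are (chain, res_seq, atom_name) triples appearing in
    LINK records.  A residue is excluded from the peptide-flip stage when its
    backbone N or O is linked or it sits in the middle of a helix or
    strand; excluded from side-chain rebuilding when a side-chain atom is
    linked or the side chain has multiple conformations.
    """
    ss = ss or {}
    backbone_linked: Set[ResidueId] = set()
    sidechain_linked: Set[ResidueId] = set()
    for chain, seq, name in linked_atoms:
        rid = (chain, seq)
        if name.strip().upper() in _BACKBONE_FLIP_ATOMS:
            backbone_linked.add(rid)
        if name.strip().upper() not in _BACKBONE_ATOMS:
            sidechain_linked.add(rid)
    altlocs = set(altloc_residues)
    out: Dict[ResidueId, RebuildEligibility] = {}
    for rid in residues:
        pep = rid not in backbone_linked and ss.get(rid, "other") == "other"
        side = rid not in sidechain_linked and rid not in altlocs
        out[rid] = RebuildEligibility(peptide_flip=pep, sidechain=side)
    return out


#: validation issue kind → residue types it applies to
_TASK_RULES: Dict[str, Set[str]] = {
    "hbond_flip": {"HIS", "ASN", "GLN"},
    "chi_standardize": {"ASP", "GLU", "PHE", "TYR"},
    "arg_ne_swap": {"ARG"},
    "chirality_cb": {"THR", "ILE", "VAL"},
    "chirality_cg": {"LEU"},
}


@dataclass(frozen=True)
class ValidationFinding:
    residue_id: ResidueId
    residue_type: str
    issue: str


@dataclass(frozen=True)
class RebuildTask:
    residue_id: ResidueId
    residue_type: str
    action: str


def validation_tasks(
    findings: Sequence[ValidationFinding],
    eligibility: Optional[Dict[ResidueId, RebuildEligibility]] = None,
) -> List[RebuildTask]:
    """Positive-selection task list from validation findings.

    Only the enumerated residue types/issue kinds yield tasks; the
    negative selectors from :func:`rebuild_candidates` still apply (a
    side-chain-ineligible residue yields no task).  Unknown issue kinds
    are skipped with a warning.
    """
    tasks: List[RebuildTask] = []
    for f in findings:
        rule = _TASK_RULES.get(f.issue)
        if rule is None:
            warnings.warn(f"unknown validation issue kind {f.issue!r}; skipped")
            continue
        if f.residue_type.strip().upper() not in rule:
            continue
        if eligibility is not None:
            el = eligibility.get(f.residue_id)
            if el is not None and not el.sidechain:
                continue
        tasks.append(RebuildTask(f.residue_id, f.residue_type.strip().upper(), f.issue))
    return tasks
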
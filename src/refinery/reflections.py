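"""Standardization and sanity checks for structure-factor reflection data.

Deposited reflection files are notoriously inconsistent.  Before anything
else runs, the data set is reduced to a single, sane list of observations:

* only the first data set in the file is used;
* reflections with negative values are rejected if they are marked as
  amplitudes, but kept if they are intensities (a negative measured
  intensity is physically meaningful; a negative amplitude is not);
* if every σ value is identical the σ column carries no information and is
  flagged unusable for scaling;
* individual σ values of 0.0 are reset to the highest σ in the data set.

Completeness is computed against the number of symmetry-unique Miller
indices inside the resolution sphere (Friedel pairs merged), enumerated
with gemmi's reciprocal-space asymmetric unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import gemmi
from pydantic import BaseModel, Field, model_validator

from .errors import EmptyDatasetError, InvalidInputError

__all__ = [
    "ReflectionRecord",
    "SanitationLog",
    "Lattice",
    "sanitize_reflections",
    "completeness",
    "read_reflections",
    "write_reflections",
]


class ReflectionRecord(BaseModel):
    """One Miller-indexed observation."""

    h: int
    k: int
    l: int
    value: float
    sigma: Optional[float] = None
    kind: Literal["amplitude", "intensity"] = "amplitude"
    free_flag: Optional[int] = None
    dataset_id: str = "1"

    @model_validator(mode="after")
    def _check_indices(self) -> "ReflectionRecord":
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("Miller index (0,0,0) is not a reflection")
        return self


class SanitationLog(BaseModel):
    n_rejected_negative_amplitudes: int = Field(default=0, ge=0)
    sigmas_usable: bool = True
    n_sigma_reset: int = Field(default=0, ge=0)
    datasets_dropped: int = Field(default=0, ge=0)


@dataclass(frozen=True)
class Lattice:
    """Unit cell + symmetry + resolution limit for completeness checks."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    spacegroup: str = "P 1"
    d_min: float = 2.0

    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def sanitize_reflections(
    records: Sequence[ReflectionRecord],
) -> Tuple[List[ReflectionRecord], SanitationLog]:
    """Apply the standardization rules; returns the clean set and a log.

    Raises :class:`EmptyDatasetError` if every reflection is rejected.
    """
    if not records:
        raise InvalidInputError("records must be non-empty")

    first_id = records[0].dataset_id
    dataset_ids = {r.dataset_id for r in records}
    kept = [r for r in records if r.dataset_id == first_id]

    n_neg = sum(1 for r in kept if r.kind == "amplitude" and r.value < 0.0)
    kept = [r for r in kept if not (r.kind == "amplitude" and r.value < 0.0)]
    if not kept:
        raise EmptyDatasetError("all reflections rejected during sanitation")

    sigmas = [r.sigma for r in kept if r.sigma is not None]
    n_reset = 0
    if not sigmas:
        usable = False
    elif all(s == sigmas[0] for s in sigmas):
        # a constant sigma column carries no weighting information
        usable = False
    else:
        usable = True
        max_sigma = max(sigmas)
        fixed = []
        for r in kept:
            if r.sigma is not None and r.sigma <= 0.0:
                fixed.append(r.model_copy(update={"sigma": max_sigma}))
                n_reset += 1
            else:
                fixed.append(r)
        kept = fixed

    log = SanitationLog(
        n_rejected_negative_amplitudes=n_neg,
        sigmas_usable=usable,
        n_sigma_reset=n_reset,
        datasets_dropped=len(dataset_ids) - 1,
    )
    return kept, log


def unique_indices(lattice: Lattice) -> List[Tuple[int, int, int]]:
    """All symmetry-unique Miller indices inside the resolution sphere.

    Friedel pairs are merged; systematic absences are not excluded (the
    decision pipeline never needs absence bookkeeping).
    """
    if min(lattice.a, lattice.b, lattice.c) <= 0 or lattice.d_min <= 0:
        raise InvalidInputError("degenerate cell or resolution limit")
    cell = lattice.unit_cell()
    if cell.volume <= 0:
        raise InvalidInputError("degenerate cell")
    sg = gemmi.SpaceGroup(lattice.spacegroup)
    asu = gemmi.ReciprocalAsu(sg)
    ops = sg.operations()
    hmax = int(lattice.a / lattice.d_min) + 1
    kmax = int(lattice.b / lattice.d_min) + 1
    lmax = int(lattice.c / lattice.d_min) + 1
    seen = set()
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if cell.calculate_d([h, k, l]) < lattice.d_min:
                    continue
                canon, _ = asu.to_asu([h, k, l], ops)
                seen.add(tuple(canon))
    return sorted(seen)


def completeness(records: Sequence[ReflectionRecord], lattice: Lattice) -> float:
    """Fraction of the theoretically possible unique reflections observed."""
    theo = set(unique_indices(lattice))
    if not records:
        return 0.0
    sg = gemmi.SpaceGroup(lattice.spacegroup)
    asu = gemmi.ReciprocalAsu(sg)
    ops = sg.operations()
    obs = set()
    for r in records:
        canon, _ = asu.to_asu([r.h, r.k, r.l], ops)
        obs.add(tuple(canon))
    return len(obs & theo) / len(theo)


# ---------------------------------------------------------------------------
# structure-factor mmCIF I/O

_STATUS_FREE = {"f"}
_STATUS_WORK = {"o"}


def _decode_status(values: List[str]) -> List[Optional[int]]:
    """Map a _refln.status column to free flags (1 = free, 0 = work).

    Dialects accepted: {o/f} letters, {1/0} integers, and multi-valued
    integer flags where 0 marks the free set.  For a pure {0,1} column the
    minority class is taken as the free set (a free set larger than the
    work set is handled downstream by validate_free_set's swap rule).
    """
    stripped = [v.strip() for v in values]
    if any(v in _STATUS_FREE or v in _STATUS_WORK for v in stripped):
        return [1 if v in _STATUS_FREE else 0 for v in stripped]
    try:
        ints = [int(v) for v in stripped]
    except ValueError:
        return [None] * len(stripped)
    distinct = set(ints)
    if distinct <= {0, 1}:
        n_one = sum(ints)
        free_val = 1 if n_one * 2 <= len(ints) else 0
        return [1 if v == free_val else 0 for v in ints]
    # multi-valued flag column: 0 is the free set
    return [1 if v == 0 else 0 for v in ints]


def read_reflections(path: str) -> Tuple[List[ReflectionRecord], Optional[Lattice]]:
    """Read a structure-factor mmCIF file (_refln loop)."""
    doc = gemmi.cif.read(str(path))
    records: List[ReflectionRecord] = []
    lattice: Optional[Lattice] = None
    for bi, rb in enumerate(gemmi.as_refln_blocks(doc)):
        block = rb.block
        hs = block.find_loop("_refln.index_h")
        ks = block.find_loop("_refln.index_k")
        ls = block.find_loop("_refln.index_l")
        fs = block.find_loop("_refln.F_meas_au") or block.find_loop("_refln.F_meas")
        kind = "amplitude"
        sig_tag = "_refln.F_meas_sigma_au"
        if not fs:
            fs = block.find_loop("_refln.intensity_meas")
            kind = "intensity"
            sig_tag = "_refln.intensity_sigma"
        sigs = block.find_loop(sig_tag) or block.find_loop("_refln.F_sigma")
        status = block.find_loop("_refln.status") or block.find_loop(
            "_refln.pdbx_r_free_flag"
        )
        flags = _decode_status(list(status)) if status else [None] * len(hs)
        sig_list = list(sigs) if sigs else [None] * len(hs)
        for i, (h, k, l, f) in enumerate(zip(hs, ks, ls, fs)):
            sigma = None
            if sig_list[i] not in (None, "?", "."):
                sigma = float(sig_list[i])
            records.append(
                ReflectionRecord(
                    h=int(h), k=int(k), l=int(l),
                    value=float(f), sigma=sigma, kind=kind,
                    free_flag=flags[i] if flags else None,
                    dataset_id=str(bi + 1),
                )
            )
        if lattice is None and rb.cell and rb.cell.a > 0:
            sg = rb.spacegroup.hm if rb.spacegroup else "P 1"
            lattice = Lattice(
                rb.cell.a, rb.cell.b, rb.cell.c,
                rb.cell.alpha, rb.cell.beta, rb.cell.gamma,
                spacegroup=sg,
            )
    return records, lattice


def write_reflections(
    records: Sequence[ReflectionRecord], path: str, lattice: Optional[Lattice] = None
) -> None:
    """Write reflections in the structure-factor mmCIF dialect read back by
    :func:`read_reflections` (status column in the {o/f} dialect)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("refinery_sf")
    if lattice is not None:
        for tag, val in [
            ("_cell.length_a", lattice.a), ("_cell.length_b", lattice.b),
            ("_cell.length_c", lattice.c), ("_cell.angle_alpha", lattice.alpha),
            ("_cell.angle_beta", lattice.beta), ("_cell.angle_gamma", lattice.gamma),
        ]:
            block.set_pair(tag, f"{val:.4f}")
        block.set_pair("_symmetry.space_group_name_H-M",
                       gemmi.cif.quote(lattice.spacegroup))
    kind = records[0].kind if records else "amplitude"
    value_tag = "F_meas_au" if kind == "amplitude" else "intensity_meas"
    sigma_tag = "F_meas_sigma_au" if kind == "amplitude" else "intensity_sigma"
    loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                       value_tag, sigma_tag, "status"])
    for r in records:
        status = "f" if r.free_flag == 1 else "o"
        sig = "?" if r.sigma is None else f"{r.sigma:.6g}"
        loop.add_row([str(r.h), str(r.k), str(r.l), f"{r.value:.6g}", sig, status])
    doc.write_file(str(path))
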
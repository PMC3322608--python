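"""Selection of the optimal refinement from a set of candidates.

Every strategy search (TLS-model optimization, B-restraint-weight search,
re-refinement, final refinement) produces a set of candidate refinements
from which one model must be chosen without overfitting.  The quality of
the *starting* structure defines the cutoffs: R and R_free cutoffs come
from the baseline (or from the TLS-reset baseline when the candidates come
from TLS optimization), and geometry cutoffs are 1.0 r.m.s. Z unless the
input structure was already worse.

For each candidate a maximum admissible R_free is derived from its own R
(``R_free,max = R·R_ratio + 3.5σ(R_free)``, capped at ``R + 6%``, floored
at the baseline R_free/R ratio times R).  Candidates violating any limit
are rejected; among survivors the lowest free likelihood and lowest R_free
are found, ties between the two broken by the higher Z(R_free).  An empty
selection is a valid outcome — the caller adapts (e.g. drops TLS or falls
back to automatic weighting).
"""

from __future__ import annotations

from typing import Dict, List, Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, Field

from .categorize import Category
from .errors import InvalidInputError, UndefinedZError
from .metrics import BaselineMetrics, ModelStats, sigma_r_free, z_r_free

__all__ = ["Cutoffs", "Selection", "establish_cutoffs", "r_free_max", "pick"]

#: σ(R_free) multiplier in the R_free,max formula
SIGMA_MULTIPLIER = 3.5
#: hard cap on the R_free − R gap (percentage points on the R scale)
GAP_CAP = 0.06
#: vlow/xlow gap-ratio rejection factor
LOW_RES_GAP_FACTOR = 2.0


class Cutoffs(BaseModel):
    r_co: float = Field(gt=0.0)
    r_free_co: float = Field(gt=0.0)
    rmsz_bond_co: float = Field(ge=1.0)
    rmsz_angle_co: float = Field(ge=1.0)
    source: Literal["tls_opt", "general"] = "general"


class Selection(BaseModel):
    chosen: Optional[str] = None
    rejected: List[Tuple[str, List[str]]] = Field(default_factory=list)
    r_free_max_per_candidate: Dict[str, float] = Field(default_factory=dict)


def establish_cutoffs(
    base: BaselineMetrics, source: Literal["tls_opt", "general"] = "general"
) -> Cutoffs:
    """Derive R/R_free and geometry cutoffs from the baseline.

    ``tls_opt`` candidates are judged against the TLS-reset baseline
    (R_TLS / R_free,TLS); everything else against R_calc / R_free,calc —
    with the unbiased expectation substituted when the free set is biased.
    """
    if source == "tls_opt":
        if base.r_tls is None or base.r_free_tls is None:
            raise InvalidInputError("tls_opt cutoffs need r_tls and r_free_tls")
        r_co, r_free_co = base.r_tls, base.r_free_tls
    else:
        r_co = base.r_calc
        r_free_co = base.r_free_unb_calc if base.free_set_biased else base.r_free_calc
    return Cutoffs(
        r_co=r_co,
        r_free_co=r_free_co,
        rmsz_bond_co=max(1.0, base.rmsz_bond_calc),
        rmsz_angle_co=max(1.0, base.rmsz_angle_calc),
        source=source,
    )


def r_free_max(
    r_i: float, r_ratio: Optional[float], sigma_i: Optional[float], cut: Cutoffs
) -> float:
    """Maximum admissible R_free for a candidate with R factor ``r_i``.

    Three stages, in exactly this order: the expectation plus 3.5σ; a cap
    at ``r_i + 0.06`` so the R_free − R gap never grows large; a floor at
    the baseline R_free/R ratio times ``r_i`` for structures that started
    with a high ratio.  When ``r_ratio`` or ``sigma_i`` is unavailable the
    first stage is skipped and only the cap (then the floor) applies.
    """
    if cut.r_co <= 0:
        raise InvalidInputError("r_co must be positive")
    if r_ratio is not None and sigma_i is not None:
        m = r_i * r_ratio + SIGMA_MULTIPLIER * sigma_i
        m = min(m, r_i + GAP_CAP)
    else:
        m = r_i + GAP_CAP
    return max(m, (cut.r_free_co / cut.r_co) * r_i)


def pick(
    candidates: Sequence[ModelStats],
    cut: Cutoffs,
    r_ratio: Optional[float],
    category: Optional[Category] = None,
) -> Selection:
    """Select the best refinement; see the module docstring for the rules."""
    if not candidates:
        raise InvalidInputError("candidates must be non-empty")
    low_res = category is not None and category.name in ("vlow", "xlow")

    survivors: List[Tuple[ModelStats, Optional[float]]] = []  # (stats, Z)
    rejected: List[Tuple[str, List[str]]] = []
    rfmax_map: Dict[str, float] = {}
    for c in candidates:
        sigma_i: Optional[float] = None
        z_i: Optional[float] = None
        if c.n_test_reflections > 0 and c.r_free > 0:
            sigma_i = sigma_r_free(c.r_free, c.n_test_reflections)
        if sigma_i is not None and r_ratio is not None:
            try:
                z_i = z_r_free(c.r_free, c.r * r_ratio, sigma_i)
            except UndefinedZError:
                z_i = None
        rfmax = r_free_max(c.r, r_ratio, sigma_i, cut)
        rfmax_map[c.label] = rfmax

        reasons: List[str] = []
        if c.rmsz_bond > cut.rmsz_bond_co:
            reasons.append("rmsz_bond_above_cutoff")
        if c.rmsz_angle > cut.rmsz_angle_co:
            reasons.append("rmsz_angle_above_cutoff")
        if c.r_free > rfmax:
            reasons.append("r_free_above_max")
        if c.r_free > cut.r_free_co:
            reasons.append("r_free_above_baseline")
        if low_res and (c.r_free - c.r) > LOW_RES_GAP_FACTOR * (cut.r_free_co - cut.r_co):
            reasons.append("gap_above_low_resolution_limit")
        if reasons:
            rejected.append((c.label, reasons))
        else:
            survivors.append((c, z_i))

    if not survivors:
        return Selection(chosen=None, rejected=rejected,
                         r_free_max_per_candidate=rfmax_map)

    best_ll = min(survivors, key=lambda sz: sz[0].ll_free)
    best_rf = min(survivors, key=lambda sz: sz[0].r_free)
    if best_ll[0].label == best_rf[0].label:
        chosen = best_ll[0]
    else:
        chosen = _higher_z(best_ll, best_rf)
    return Selection(chosen=chosen.label, rejected=rejected,
                     r_free_max_per_candidate=rfmax_map)


def _higher_z(
    a: Tuple[ModelStats, Optional[float]], b: Tuple[ModelStats, Optional[float]]
) -> ModelStats:
    """Z comparison with deterministic tie-breaking.

    An undefined Z loses against a defined one.  Exact ties (both
    undefined, or numerically equal Z) resolve to the lower R_free, then
    to the first in input order (``a`` precedes ``b``).
    """
    za, zb = a[1], b[1]
    if za is None and zb is None:
        tie = True
    elif za is None:
        return b[0]
    elif zb is None:
        return a[0]
    elif za > zb:
        return a[0]
    elif zb > za:
        return b[0]
    else:
        tie = True
    if tie:
        if b[0].r_free < a[0].r_free:
            return b[0]
        return a[0]
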
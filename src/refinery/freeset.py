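"""R_free test-set management: validation, creation and bias detection.

A cross-validation set is only useful if it is genuinely "free", i.e. was
never used in refinement, and if it is large enough for σ(R_free) to be
small.  The rules implemented here validate a deposited set (swapping when
the flags are inverted, rejecting sets that are too small or too large),
create a fresh one when needed, and decide whether the recalculated R_free
is biased — in which case the expected value R_free,unb takes over as the
baseline and the refinement protocol is hardened (B factors reset to the
Wilson B, more cycles).
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field

from .errors import InvalidInputError
from .metrics import BaselineMetrics, expected_r_free

__all__ = [
    "FreeSetDecision",
    "validate_free_set",
    "create_free_set",
    "assess_bias",
    "baseline_adjustments",
    "MIN_FREE_REFLECTIONS",
    "MAX_FREE_FRACTION",
]

#: an R_free set with fewer reflections than this is rejected
MIN_FREE_REFLECTIONS = 500
#: an R_free set holding more than this fraction of all reflections is rejected
MAX_FREE_FRACTION = 0.25

_TARGET_FRACTION = 0.05
_TARGET_MIN_REFLECTIONS = 1000
_FRACTION_CEILING = 0.10


class FreeSetDecision(BaseModel):
    action: Literal["keep", "swap_then_keep", "reject", "created"]
    fraction_free: float = Field(default=0.0, ge=0.0)
    n_free: int = Field(default=0, ge=0)
    biased: bool = False
    baseline_r_free: Optional[float] = None
    protocol: Literal["normal", "reset_b_and_extend"] = "normal"


def validate_free_set(n_total: int, n_free: int) -> FreeSetDecision:
    """Validate an existing R_free set of ``n_free`` of ``n_total`` reflections.

    If the flagged free set is larger than the work set the two are swapped
    first.  The (possibly swapped) set is rejected if it holds more than
    25% of all reflections or fewer than 500.
    """
    if n_total < 1 or not (0 <= n_free <= n_total):
        raise InvalidInputError("require 0 <= n_free <= n_total, n_total >= 1")
    swapped = n_free > n_total - n_free
    k = n_total - n_free if swapped else n_free
    if k * 100 > 25 * n_total or k < MIN_FREE_REFLECTIONS:
        return FreeSetDecision(action="reject", fraction_free=0.0, n_free=0)
    return FreeSetDecision(
        action="swap_then_keep" if swapped else "keep",
        fraction_free=k / n_total,
        n_free=k,
    )


def created_set_size(n_total: int) -> int:
    """Size of a newly created free set: 5% by default, raised towards 1000
    reflections when 5% falls short, capped at 10%."""
    n5 = math.ceil(_TARGET_FRACTION * n_total)
    if n5 >= _TARGET_MIN_REFLECTIONS:
        return n5
    return max(1, min(_TARGET_MIN_REFLECTIONS,
                      math.floor(_FRACTION_CEILING * n_total)))


def create_free_set(n_total: int, seed: int) -> Tuple[np.ndarray, FreeSetDecision]:
    """Create a fresh R_free set; returns a boolean flag array and the decision.

    Selection is uniform without replacement from ``seed`` (bit-reproducible).
    A newly created set is always treated as biased: the reflections were in
    the work set of the deposited refinement.
    """
    if n_total < 1:
        raise InvalidInputError("n_total must be >= 1")
    n_free = created_set_size(n_total)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_total, size=n_free, replace=False)
    flags = np.zeros(n_total, dtype=bool)
    flags[idx] = True
    decision = FreeSetDecision(
        action="created",
        fraction_free=n_free / n_total,
        n_free=n_free,
        biased=True,
    )
    return flags, decision


def assess_bias(base: BaselineMetrics, set_was_created: bool) -> bool:
    """Decide whether the recalculated R_free is biased.

    Biased iff any of:

    1. the free set was newly created;
    2. R_free,calc < R_calc (free reflections fit *better* than worked ones);
    3. Z(R_free,calc) > 10.0 (far better than a converged unbiased
       refinement could be);
    4. the R_free − R gap is much smaller than the header gap:
       (R_free,calc − R_calc) < 0.33 × (R_free,head − R_head).

    Condition 4 is skipped when header R values are unavailable.
    """
    if set_was_created:
        return True
    if base.r_free_calc < base.r_calc:
        return True
    if base.z_r_free_calc > 10.0:
        return True
    if base.r_head is not None and base.r_free_head is not None:
        header_gap = base.r_free_head - base.r_head
        if (base.r_free_calc - base.r_calc) < 0.33 * header_gap:
            return True
    return False


def baseline_adjustments(biased: bool, base: BaselineMetrics) -> FreeSetDecision:
    """Pick the R_free baseline and protocol given the bias verdict.

    A biased set forces the expected value R_free,unb,calc as the baseline
    and hardens the protocol (atomic B factors reset to B_Wilson, extended
    cycle count via the ``new_free_set`` cycle context).
    """
    if biased:
        return FreeSetDecision(
            action="keep",
            biased=True,
            baseline_r_free=expected_r_free(base.r_calc, base.r_ratio),
            protocol="reset_b_and_extend",
        )
    return FreeSetDecision(
        action="keep",
        biased=False,
        baseline_r_free=base.r_free_calc,
        protocol="normal",
    )
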
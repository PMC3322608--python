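"""Model-quality metrics consumed by every decision algorithm.

The crystallographic R factor measures the agreement between observed
structure-factor amplitudes ``F_obs`` and those calculated from the model,
``F_calc``, after an optimal linear scale.  ``R_free`` is the same quantity
evaluated on a held-out test set of reflections and is the primary guard
against overfitting.  The helper quantities defined here — the expected
``R_free`` for a converged unbiased refinement (``R_free,unb = R × R_ratio``),
its estimated standard deviation ``σ(R_free) = R_free / sqrt(2·N_test)`` and
the Z score ``Z(R_free) = (R_free,unb − R_free)/σ(R_free)`` — let the
selection algorithms judge whether a drop in ``R_free`` is statistically
meaningful.  Note the sign convention: because lower ``R_free`` is better,
the Z score is positive when the model is *better* than expectation.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import InvalidInputError, UndefinedZError

__all__ = [
    "ModelStats",
    "BaselineMetrics",
    "r_factor",
    "sigma_r_free",
    "expected_r_free",
    "z_r_free",
    "estimate_r_ratio",
    "rmsz",
]


class ModelStats(BaseModel):
    """Per-refinement metric bundle produced by a refinement engine.

    ``ll_free`` is the free likelihood as reported by the engine; by
    convention here, lower is better.  ``r_free_weighted`` / ``r_weighted``
    (the Hamilton-test weighted R factors) are optional because only
    B-factor model selection consumes them.
    """

    label: str
    r: float = Field(ge=0.0, le=1.5)
    r_free: float = Field(ge=0.0, le=1.5)
    r_free_weighted: Optional[float] = Field(default=None, ge=0.0)
    r_weighted: Optional[float] = Field(default=None, ge=0.0)
    rmsz_bond: float = Field(ge=0.0)
    rmsz_angle: float = Field(ge=0.0)
    ll_free: float = 0.0
    n_test_reflections: int = Field(ge=0)


class BaselineMetrics(BaseModel):
    """Cutoff-defining quantities established before re-refinement.

    ``r_head`` / ``r_free_head`` come from the deposited file's header;
    ``r_calc`` / ``r_free_calc`` are recomputed from model and data.  The
    TLS variants (``r_tls`` / ``r_free_tls``) exist only when TLS-model
    optimization ran and feed the picker's ``tls_opt`` cutoff source.
    """

    r_head: Optional[float] = None
    r_free_head: Optional[float] = None
    r_calc: float = Field(ge=0.0)
    r_free_calc: float = Field(ge=0.0)
    r_ratio: float = Field(ge=1.0)
    r_free_unb_calc: float = Field(ge=0.0)
    sigma_r_free_calc: float = Field(ge=0.0)
    z_r_free_calc: float = 0.0
    rmsz_bond_calc: float = Field(default=0.0, ge=0.0)
    rmsz_angle_calc: float = Field(default=0.0, ge=0.0)
    b_wilson: float = Field(default=0.0, ge=0.0)
    free_set_biased: bool = False
    r_tls: Optional[float] = None
    r_free_tls: Optional[float] = None


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def r_factor(obs: Sequence[float], calc: Sequence[float]) -> float:
    """Standard R factor ``Σ|F_obs − m·F_calc| / Σ F_obs``.

    The linear scale ``m`` between calculated and observed amplitudes is
    chosen to minimize the absolute residual, by golden-section search on
    the (convex, piecewise-linear) objective.  The search terminates at a
    relative bracket width of 1e-12 so the result is scale-invariant in
    ``calc`` to well below 1e-9.

    Raises
    ------
    InvalidInputError
        on empty input, length mismatch, or all-zero observations.
    """
    o = np.asarray(obs, dtype=float)
    c = np.asarray(calc, dtype=float)
    if o.size == 0 or o.shape != c.shape:
        raise InvalidInputError("obs and calc must be equal-length, non-empty")
    denom = float(np.sum(o))
    if denom <= 0.0:
        raise InvalidInputError("sum of observed amplitudes must be positive")

    nz = c > 0
    if not np.any(nz):
        # no positive calculated amplitude: the scale is irrelevant
        return float(np.sum(np.abs(o))) / denom

    # the optimum lies within the range of obs/calc ratios
    ratios = o[nz] / c[nz]
    lo, hi = float(min(ratios.min(), 0.0)), float(ratios.max())

    def objective(m: float) -> float:
        return float(np.sum(np.abs(o - m * c)))

    a, b = lo, hi
    tol = 1e-12 * (hi - lo) + 1e-300
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = objective(x1), objective(x2)
    while (b - a) > tol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = objective(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = objective(x2)
    return objective(0.5 * (a + b)) / denom


def sigma_r_free(r_free: float, n_test: int) -> float:
    """Estimated standard deviation of R_free: ``R_free / sqrt(2·N_test)``."""
    if n_test < 1:
        raise InvalidInputError("n_test must be >= 1")
    return r_free / math.sqrt(2.0 * n_test)


def expected_r_free(r: float, r_ratio: float) -> float:
    """Expected R_free for a converged unbiased refinement: ``R × R_ratio``."""
    if r < 0 or r_ratio < 1.0:
        raise InvalidInputError("require r >= 0 and r_ratio >= 1")
    return r * r_ratio


def z_r_free(r_free: float, r_free_unb: float, sigma: float) -> float:
    """Z score of R_free, positive when better than expectation.

    The terms are ``(R_free,unb − R_free)/σ`` — swapped relative to the
    usual ``(x − x_expected)`` convention to compensate for the
    lower-is-better nature of R_free.
    """
    if sigma <= 0.0:
        raise UndefinedZError("sigma(R_free) must be positive")
    return (r_free_unb - r_free) / sigma


def estimate_r_ratio(n_obs: int, n_param_eff: int) -> float:
    """Default estimator of the expected R_free/R ratio.

    Uses the classical unrestrained data-to-parameter approximation
    ``sqrt((n_obs + n_param)/(n_obs − n_param))``.  Callers that have an
    externally computed ratio (e.g. one accounting for the effective
    restraint count) should pass it through instead of calling this.
    """
    if n_param_eff < 0 or n_obs <= n_param_eff:
        raise InvalidInputError("require n_obs > n_param_eff >= 0")
    return math.sqrt((n_obs + n_param_eff) / (n_obs - n_param_eff))


def rmsz(z_values: Sequence[float]) -> float:
    """Root-mean-square of restraint Z scores."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise InvalidInputError("z_values must be non-empty")
    return float(np.sqrt(np.mean(z * z)))
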
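"""B-factor parameterization choice: RPA routing and the bselect chain.

Anisotropic B factors need nine parameters per atom, isotropic four, one
overall B factor for all atoms three.  How much detail the data supports is
routed on reflections per atom (RPA): above 18 the anisotropic description
is twofold overdetermined and used outright; between 13.5 and 18 isotropic
and anisotropic trial refinements compete; between 3 and 13.5 isotropic is
used; below 3 an isotropic model competes against a single overall B
factor (with the TLS model optimized first).

The contest is decided by ``bselect``, whose core is the Hamilton R-factor
ratio test on weighted free R factors of the nested models.  Because the
effective number of restraints is unknown, the test is run over a whole
grid of restraint-weight assumptions (w1 for the shared restraints, w2 for
the complex model's extra ones) and the fraction of grid points accepting
the complex model feeds a three-band decision (< 30% simple, > 95%
complex, otherwise an overrefinement inspection of the complex model).
"""

from __future__ import annotations

import math
from typing import List, Literal, Optional

from pydantic import BaseModel, Field, model_validator
from scipy.stats import f as f_dist

from .errors import InvalidInputError
from .metrics import ModelStats

__all__ = [
    "ParameterizationRoute",
    "HamiltonInput",
    "route_parameterization",
    "hamilton_acceptance_fraction",
    "bselect",
    "RPA_ANISO",
    "RPA_CONTEST_LOW",
    "RPA_ISO_LOW",
    "PARAMS_PER_ATOM",
]

#: RPA above which anisotropic B factors are used outright
RPA_ANISO = 18.0
#: RPA above which the aniso-vs-iso contest runs (up to RPA_ANISO)
RPA_CONTEST_LOW = 13.5
#: RPA below which iso competes against one overall B factor
RPA_ISO_LOW = 3.0

PARAMS_PER_ATOM = {"aniso": 9, "iso": 4, "overall": 3}

_HAMILTON_SIMPLE_BAND = 0.30
_HAMILTON_COMPLEX_BAND = 0.95
_Z_TOO_LOW = -3.0
_GAP_CUTOFF = {"aniso": 0.04, "iso": 0.06}


class ParameterizationRoute(BaseModel):
    route: Literal[
        "aniso", "contest_aniso_vs_iso", "iso", "contest_iso_vs_overall",
        "iso_fallback",
    ]
    params_per_atom_simple: int
    params_per_atom_complex: int

    @model_validator(mode="after")
    def _check_params(self) -> "ParameterizationRoute":
        allowed = set(PARAMS_PER_ATOM.values())
        if {self.params_per_atom_simple, self.params_per_atom_complex} - allowed:
            raise ValueError("params per atom must be one of 3, 4, 9")
        return self


class HamiltonInput(BaseModel):
    r_free_w_simple: float = Field(gt=0.0)
    r_free_w_complex: float = Field(gt=0.0)
    n_obs: int = Field(ge=1)
    n_params_simple: int = Field(ge=1)
    n_params_complex: int = Field(ge=1)
    n_restraints_base: int = Field(ge=0)
    n_restraints_extra: int = Field(ge=0)
    w1_grid: List[float] = Field(min_length=1)
    w2_grid: List[float] = Field(min_length=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check(self) -> "HamiltonInput":
        if self.n_params_complex <= self.n_params_simple:
            raise ValueError("complex model must have more parameters")
        if any(not 0.0 <= w <= 1.0 for w in self.w1_grid + self.w2_grid):
            raise ValueError("restraint weights must lie in [0, 1]")
        return self


def default_weight_grid(step: float = 0.1) -> List[float]:
    """The default restraint-weight assumption grid, 0.0 to 1.0 inclusive."""
    n = int(round(1.0 / step))
    return [round(i * step, 10) for i in range(n + 1)]


def route_parameterization(rpa: float, tls_usable: bool = True) -> ParameterizationRoute:
    """Route the B-factor parameterization decision on reflections per atom."""
    if rpa < 0:
        raise InvalidInputError("rpa must be >= 0")
    if rpa > RPA_ANISO:
        return ParameterizationRoute(
            route="aniso", params_per_atom_simple=9, params_per_atom_complex=9)
    if rpa > RPA_CONTEST_LOW:
        return ParameterizationRoute(
            route="contest_aniso_vs_iso",
            params_per_atom_simple=4, params_per_atom_complex=9)
    if rpa >= RPA_ISO_LOW:
        return ParameterizationRoute(
            route="iso", params_per_atom_simple=4, params_per_atom_complex=4)
    if not tls_usable:
        return ParameterizationRoute(
            route="iso_fallback", params_per_atom_simple=4, params_per_atom_complex=4)
    return ParameterizationRoute(
        route="contest_iso_vs_overall",
        params_per_atom_simple=3, params_per_atom_complex=4)


def hamilton_critical_ratio(b: float, f: float, alpha: float) -> float:
    """Critical R-factor ratio ``sqrt((b/f)·F(α; b, f) + 1)``.

    ``b`` is the hypothesis dimension (extra parameters net of weighted
    extra restraints) and ``f`` the effective free degrees of the complex
    model; both may be non-integer because restraints enter with fractional
    weights.
    """
    quantile = float(f_dist.ppf(1.0 - alpha, b, f))
    return math.sqrt((b / f) * quantile + 1.0)


def hamilton_acceptance_fraction(inp: HamiltonInput) -> float:
    """Fraction of (w1, w2) grid points whose Hamilton test accepts the
    complex model.

    Per grid point: effective free degrees
    ``f = n_obs − n_params_complex + w1·n_restraints_base + w2·n_restraints_extra``
    and hypothesis dimension
    ``b = (n_params_complex − n_params_simple) − w2·n_restraints_extra``
    (floored at 1).  The test accepts iff the simple/complex weighted free
    R-factor ratio exceeds the critical ratio.  Points with ``f ≤ 0`` count
    as not acceptable — an under-determined complex model cannot be
    justified.
    """
    ratio = inp.r_free_w_simple / inp.r_free_w_complex
    dp = inp.n_params_complex - inp.n_params_simple
    accepted = 0
    total = 0
    for w1 in inp.w1_grid:
        for w2 in inp.w2_grid:
            total += 1
            f = (inp.n_obs - inp.n_params_complex
                 + w1 * inp.n_restraints_base + w2 * inp.n_restraints_extra)
            if f <= 0:
                continue
            b = max(1.0, dp - w2 * inp.n_restraints_extra)
            if ratio > hamilton_critical_ratio(b, f, inp.alpha):
                accepted += 1
    return accepted / total


def bselect(
    simple: ModelStats,
    complex: ModelStats,
    inp: Optional[HamiltonInput] = None,
    z_complex: Optional[float] = None,
    complex_kind: Literal["aniso", "iso"] = "aniso",
    acceptance_fraction: Optional[float] = None,
) -> Literal["simple", "complex"]:
    """Choose between two nested B-factor models.

    Decision chain:

    i.   if the complex model's weighted free R factor is higher, the
         simpler model wins outright (no Hamilton tests are run);
    ii.  the Hamilton acceptance fraction decides when conclusive:
         < 30% simple, > 95% complex;
    iii. in the inconclusive band the complex model is inspected for
         overrefinement: Z(R_free) < −3.0 → simple; when Z is unavailable,
         an R_free − R gap above 4% (aniso) / 6% (iso) → simple; and a gap
         more than 2.0× the simple model's gap → simple.  Otherwise the
         complex model is used.

    ``acceptance_fraction`` injects a precomputed fraction (step ii) so the
    chain can be exercised without a HamiltonInput.
    """
    rw_s = simple.r_free_weighted if simple.r_free_weighted is not None else simple.r_free
    rw_c = complex.r_free_weighted if complex.r_free_weighted is not None else complex.r_free
    if rw_c > rw_s:
        return "simple"

    if acceptance_fraction is None:
        if inp is None:
            raise InvalidInputError("need HamiltonInput or acceptance_fraction")
        acceptance_fraction = hamilton_acceptance_fraction(inp)
    if acceptance_fraction < _HAMILTON_SIMPLE_BAND:
        return "simple"
    if acceptance_fraction > _HAMILTON_COMPLEX_BAND:
        return "complex"

    if z_complex is not None:
        if z_complex < _Z_TOO_LOW:
            return "simple"
    else:
        if (complex.r_free - complex.r) > _GAP_CUTOFF[complex_kind]:
            return "simple"
    if (complex.r_free - complex.r) > 2.0 * (simple.r_free - simple.r):
        return "simple"
    return "complex"
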
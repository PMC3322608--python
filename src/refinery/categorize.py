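"""Resolution categories, restraint-weight search spaces and cycle counts.

Each input model is assigned to one of six categories from the data
resolution and the number of X-ray reflections per atom (RPA).  RPA takes
precedence over resolution because solvent content makes the two diverge:
at 3.0 Å, observed RPA ranges from roughly 2 to 8.  The category fixes the
geometric and B-factor restraint-weight search spaces and whether
jelly-body restraints stabilize the refinement (the two lowest categories
only).

Cycle counts per refinement task follow a fixed empirical rule table; the
combination precedence is legacy > anisotropic > new-free-set > default,
with the "+5 cycles without TLS" applying only to the 20- and 30-cycle
bases.
"""

from __future__ import annotations

from typing import Dict, List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import InvalidInputError

__all__ = [
    "Category",
    "CycleContext",
    "assign_category",
    "assign_cycles",
    "reflections_per_atom",
    "load_weight_config",
    "AUTO_WEIGHT",
    "RESOLUTION_BREAKPOINTS",
    "RPA_BREAKPOINTS",
]

CategoryName = Literal["xlow", "vlow", "low", "medium", "high", "atomic"]

#: sentinel weight meaning "let the engine weight automatically"
AUTO_WEIGHT = 0.0

RESOLUTION_BREAKPOINTS = (1.20, 1.70, 2.80, 3.50, 5.00)
RPA_BREAKPOINTS = (1.0, 2.5)


class Category(BaseModel):
    name: CategoryName
    jelly_body: bool
    weight_grid: List[float] = Field(min_length=1, max_length=7)
    b_weight_grid: List[float] = Field(max_length=7)

    @model_validator(mode="after")
    def _check_jelly(self) -> "Category":
        if self.jelly_body != (self.name in ("vlow", "xlow")):
            raise ValueError("jelly_body is set iff category is vlow/xlow")
        return self


class CycleContext(BaseModel):
    task: Literal[
        "rigid_reproduce", "tls_reproduce", "tls_optimize", "tls_final",
        "rerefine", "b_model_iso_vs_aniso", "b_weight_opt",
    ]
    legacy: bool = False
    tls_in_use: bool = False
    new_free_set: bool = False
    anisotropic: bool = False

    @model_validator(mode="after")
    def _check_flags(self) -> "CycleContext":
        if self.anisotropic and self.tls_in_use:
            raise ValueError("anisotropic B factors exclude TLS")
        return self


def _geomspace(hi: float, lo: float, n: int) -> List[float]:
    return [round(float(w), 6) for w in np.geomspace(hi, lo, n)]


# Log-spaced defaults; tighter restraints (smaller weights) and shorter
# grids at lower resolution.  The xlow grid is the automatic-weighting
# sentinel alone.  All overridable via load_weight_config.
_DEFAULT_WEIGHT_GRIDS: Dict[str, List[float]] = {
    "atomic": _geomspace(5.0, 0.05, 7),
    "high": _geomspace(5.0, 0.05, 7),
    "medium": _geomspace(3.0, 0.03, 6),
    "low": _geomspace(1.0, 0.03, 4),
    "vlow": _geomspace(0.5, 0.05, 3),
    "xlow": [AUTO_WEIGHT],
}
_DEFAULT_B_WEIGHT_GRIDS: Dict[str, List[float]] = {
    "atomic": _geomspace(10.0, 0.1, 7),
    "high": _geomspace(10.0, 0.1, 7),
    "medium": _geomspace(5.0, 0.2, 5),
    "low": _geomspace(2.0, 0.5, 3),
    "vlow": _geomspace(2.0, 1.0, 2),
    "xlow": [1.0],
}


def load_weight_config(path: str) -> Dict[str, Dict[str, List[float]]]:
    """Read per-category grid overrides from a YAML file.

    Layout: ``{category: {weight_grid: [...], b_weight_grid: [...]}}``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return data


def assign_category(
    resolution: float,
    rpa: float,
    overrides: Optional[Dict[str, Dict[str, List[float]]]] = None,
) -> Category:
    """Assign the structure-model category.

    The RPA rules win conflicts with the resolution bins; the remaining
    four categories are purely resolution-binned on half-open intervals.
    """
    if resolution <= 0 or rpa < 0:
        raise InvalidInputError("require resolution > 0 and rpa >= 0")
    if rpa < 1.0 or resolution >= 5.00:
        name: CategoryName = "xlow"
    elif 1.0 <= rpa < 2.5 or 3.50 <= resolution < 5.00:
        name = "vlow"
    elif resolution >= 2.80:
        name = "low"
    elif resolution >= 1.70:
        name = "medium"
    elif resolution >= 1.20:
        name = "high"
    else:
        name = "atomic"
    wg = list(_DEFAULT_WEIGHT_GRIDS[name])
    bg = list(_DEFAULT_B_WEIGHT_GRIDS[name])
    if overrides and name in overrides:
        wg = [float(w) for w in overrides[name].get("weight_grid", wg)]
        bg = [float(w) for w in overrides[name].get("b_weight_grid", bg)]
    return Category(
        name=name,
        jelly_body=name in ("vlow", "xlow"),
        weight_grid=wg,
        b_weight_grid=bg,
    )


def assign_cycles(ctx: CycleContext) -> int:
    """Number of internal refinement cycles for a task context."""
    t = ctx.task
    if t == "rigid_reproduce":
        return 15 if ctx.legacy else 10
    if t == "tls_reproduce":
        return 5
    if t == "tls_optimize":
        return 15 if ctx.legacy else 10
    if t == "tls_final":
        return 5
    if t == "rerefine":
        if ctx.legacy:
            return 60 if ctx.anisotropic else 50
        if ctx.anisotropic:
            return 40
        base = 30 if ctx.new_free_set else 20
        return base + (0 if ctx.tls_in_use else 5)
    if t == "b_model_iso_vs_aniso":
        return 50
    if t == "b_weight_opt":
        return 10 if ctx.tls_in_use else 15
    raise InvalidInputError(f"unknown task {t!r}")


def reflections_per_atom(n_reflections: int, n_atoms: int) -> float:
    if n_atoms < 1:
        raise InvalidInputError("n_atoms must be >= 1")
    return n_reflections / n_atoms
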
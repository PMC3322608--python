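"""Synthetic inputs: reflection sets, density maps with waters, and a
simulated refinement engine.

Everything the pipeline consumes can be generated here, seeded and
bit-reproducible, so every decision path is testable without downloads or
external refinement binaries.  The simulated engine's response family is
deliberately simple — the free R factor is quadratic in the log restraint
weight with a known argmin, geometry r.m.s. Z grows linearly as restraints
loosen, TLS lowers R_free by a configured increment — the simplest family
that exposes every selection branch, including the planted-optimum
recovery and the low-resolution gap tests.  It makes no attempt at
physical realism in structure-factor space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Dict, List, Optional, Tuple

import numpy as np

from .categorize import AUTO_WEIGHT
from .metrics import ModelStats
from .modelprep import AtomRecord, HeaderInfo
from .orchestrator import (
    EngineResult,
    PipelineInputs,
    QualityMetrics,
    RefinementSettings,
)
from .realspace import GridMap
from .reflections import Lattice, ReflectionRecord

__all__ = [
    "SyntheticProfile",
    "gen_reflections",
    "simulated_engine",
    "SimulatedEngine",
    "gen_map_and_waters",
    "make_pipeline_inputs",
]


@dataclass(frozen=True)
class SyntheticProfile:
    """Study conditions for one synthetic entry.

    Defaults describe a well-behaved medium-resolution entry: 2.0 Å data,
    ~13 reflections per atom, a reported R of 0.20 with a calculated value
    one point higher, and a deposited 5% free set.
    """

    seed: int = 0
    resolution: float = 2.0
    n_reflections: int = 13000
    n_atoms: int = 1000
    free_fraction: float = 0.05

    # header / baseline state
    r_head: float = 0.20
    r_free_head: float = 0.24
    planted_gap: float = 0.01          # R_calc − R_head
    calc_gap: float = 0.04             # R_free,calc − R_calc
    b_wilson: float = 25.0
    deposition_year: int = 2005

    # reflection error model and planted defects
    noise_sd: float = 0.05
    planted_negative_amplitudes: int = 0
    planted_zero_sigmas: int = 0
    duplicate_dataset: bool = False

    # engine response curve (restraint weight → R, R_free, rmsZ)
    weight_opt: float = 0.3            # argmin of R_free over log-weight
    r_free_best: float = 0.22          # R_free at the optimum
    curvature: float = 0.01            # per (decade of weight)^2
    r_free_gap: float = 0.04           # R_free − R after refinement
    rmsz_bond0: float = 0.80
    rmsz_angle0: float = 0.90
    rmsz_slope: float = 0.10           # per decade of weight (looser → higher)
    ll_scale: float = 1000.0

    # strategy increments
    tls_benefit: float = 0.005         # R_free drop of the best TLS candidate
    r_free_tls_offset: float = 0.03    # R_free,TLS − R_free at optimum
    aniso_r_free_delta: float = 0.002  # added to R_free for aniso B factors
    overall_b_penalty: float = 0.01    # added to R_free for one overall B

    # baseline-ladder rung gains (reduction of R_calc; 0 = rung is inert)
    twin_gain: float = 0.0
    rigid_gain: float = 0.0
    tls_rung_gain: float = 0.0

    # density map / waters
    map_size: int = 24
    map_spacing: float = 0.5
    n_peak_waters: int = 6
    n_bulk_waters: int = 4
    peak_height: float = 1.0
    peak_sigma: float = 0.8

    quality_before: QualityMetrics = field(default_factory=lambda: QualityMetrics(
        r_free=0.24, ramachandran_z=-1.30, rotamer_z=-1.21,
        coarse_packing_z=-0.24, fine_packing_z=-0.97,
        bumps=108, unsatisfied_donors=43))
    quality_after: QualityMetrics = field(default_factory=lambda: QualityMetrics(
        r_free=0.22, ramachandran_z=-0.61, rotamer_z=-0.24,
        coarse_packing_z=-0.12, fine_packing_z=-0.70,
        bumps=82, unsatisfied_donors=37))


def _toy_lattice(profile: SyntheticProfile) -> Lattice:
    # P1 cell sized so the resolution sphere holds about n_reflections
    # unique reflections (Friedel merged): N ≈ (4π/3)(a/d)³ / 2
    edge = (2.0 * profile.n_reflections / (4.0 * math.pi / 3.0)) ** (1.0 / 3.0) \
        * profile.resolution
    return Lattice(edge, edge, edge, d_min=profile.resolution)


def gen_reflections(
    profile: SyntheticProfile,
) -> Tuple[List[ReflectionRecord], Lattice]:
    """Generate a unique P1 reflection list with a Wilson-like amplitude
    distribution, σ values from a fractional error model, an existing free
    set, and optional planted defects for sanitation tests."""
    lattice = _toy_lattice(profile)
    from .reflections import unique_indices

    hkls = unique_indices(lattice)
    rng = np.random.default_rng(profile.seed)
    n = len(hkls)
    # Wilson statistics: intensities exponential, amplitudes their sqrt
    amps = np.sqrt(rng.exponential(scale=100.0, size=n))
    sigmas = profile.noise_sd * amps * (1.0 + 0.2 * rng.random(n))
    flags = np.zeros(n, dtype=int)
    if profile.free_fraction > 0:
        n_free = int(round(profile.free_fraction * n))
        flags[rng.choice(n, size=n_free, replace=False)] = 1

    for i in range(min(profile.planted_negative_amplitudes, n)):
        amps[i] = -abs(amps[i]) - 1e-6
    for i in range(min(profile.planted_zero_sigmas, n)):
        sigmas[n - 1 - i] = 0.0

    records = [
        ReflectionRecord(h=h, k=k, l=l, value=float(amps[i]),
                         sigma=float(sigmas[i]), kind="amplitude",
                         free_flag=int(flags[i]), dataset_id="1")
        for i, (h, k, l) in enumerate(hkls)
    ]
    if profile.duplicate_dataset:
        records += [r.model_copy(update={"dataset_id": "2"})
                    for r in records[: n // 10]]
    return records, lattice


class SimulatedEngine:
    """Deterministic stand-in for a reciprocal-space refinement program.

    The model handle is a plain dict carrying the current R / R_free state;
    all responses are closed-form functions of the settings, so identical
    inputs always give identical outputs.
    """

    def __init__(self, profile: SyntheticProfile):
        self.profile = profile
        self.n_test = int(round(profile.free_fraction * profile.n_reflections))
        self.twin_operators: List[Tuple[float, float]] = []

    # -- helpers ---------------------------------------------------------

    def initial_model(self) -> Dict[str, Any]:
        p = self.profile
        return {
            "r": p.r_head + p.planted_gap,
            "r_free": p.r_head + p.planted_gap + p.calc_gap,
            "rmsz_bond": p.rmsz_bond0,
            "rmsz_angle": p.rmsz_angle0,
        }

    def _stats(self, label: str, r: float, r_free: float,
               rmszb: float, rmsza: float) -> ModelStats:
        return ModelStats(
            label=label, r=max(0.0, r), r_free=max(0.0, r_free),
            r_free_weighted=max(0.0, r_free), r_weighted=max(0.0, r),
            rmsz_bond=max(0.0, rmszb), rmsz_angle=max(0.0, rmsza),
            ll_free=self.profile.ll_scale * r_free,
            n_test_reflections=max(1, self.n_test))

    def _response(self, weight: Optional[float]) -> Tuple[float, float, float, float]:
        p = self.profile
        w = p.weight_opt if weight is None or weight == AUTO_WEIGHT else weight
        dlog = math.log10(w / p.weight_opt)
        r_free = p.r_free_best + p.curvature * dlog * dlog
        r = r_free - p.r_free_gap
        rmszb = p.rmsz_bond0 + p.rmsz_slope * dlog
        rmsza = p.rmsz_angle0 + p.rmsz_slope * dlog
        return r, r_free, rmszb, rmsza

    # -- engine contract -------------------------------------------------

    def refine(self, model: Optional[Dict[str, Any]], data: Any,
               settings: RefinementSettings) -> EngineResult:
        model = dict(model) if model else self.initial_model()
        p = self.profile
        if settings.cycles == 0:
            r, r_free = model["r"], model["r_free"]
            if settings.twin:
                r -= p.twin_gain
                r_free -= p.twin_gain
            new = dict(model, r=r, r_free=r_free)
            return EngineResult(
                stats=self._stats(settings.label or "calc", r, r_free,
                                  model["rmsz_bond"], model["rmsz_angle"]),
                model=new)
        r, r_free, rmszb, rmsza = self._response(settings.weight)
        if settings.bfactor_model == "aniso":
            r_free += p.aniso_r_free_delta
            r -= 0.01  # more parameters always lower the working R
        elif settings.bfactor_model == "overall":
            r_free += p.overall_b_penalty
            r += p.overall_b_penalty
        if settings.use_tls:
            r_free -= p.tls_benefit
            r -= p.tls_benefit
        new = dict(model, r=r, r_free=r_free,
                   rmsz_bond=rmszb, rmsz_angle=rmsza)
        return EngineResult(
            stats=self._stats(settings.label or "refined", r, r_free,
                              rmszb, rmsza),
            model=new, quality=replace(p.quality_after, r_free=r_free))

    def rigid_body(self, model: Optional[Dict[str, Any]], data: Any,
                   settings: RefinementSettings) -> EngineResult:
        model = dict(model) if model else self.initial_model()
        r = model["r"] - self.profile.rigid_gain
        r_free = model["r_free"] - self.profile.rigid_gain
        new = dict(model, r=r, r_free=r_free)
        return EngineResult(
            stats=self._stats(settings.label or "rigid", r, r_free,
                              model["rmsz_bond"], model["rmsz_angle"]),
            model=new)

    def tls_refine(self, model: Optional[Dict[str, Any]], data: Any,
                   settings: RefinementSettings,
                   tls_model: Any = None) -> EngineResult:
        model = dict(model) if model else self.initial_model()
        p = self.profile
        if settings.cycles == 0 and settings.reset_b_to is not None:
            # evaluation right after the B reset: R_TLS / R_free,TLS
            r_free = p.r_free_best + p.r_free_tls_offset
            r = r_free - p.r_free_gap
            new = dict(model, r=r, r_free=r_free)
            return EngineResult(
                stats=self._stats("tls_baseline", r, r_free,
                                  model["rmsz_bond"], model["rmsz_angle"]),
                model=new)
        if settings.cycles <= 5 and settings.reset_b_to is None:
            # evaluation or baseline-ladder rung with the header tensors
            r = model["r"] - p.tls_rung_gain
            r_free = model["r_free"] - p.tls_rung_gain
            new = dict(model, r=r, r_free=r_free)
            return EngineResult(
                stats=self._stats(settings.label or "tls", r, r_free,
                                  model["rmsz_bond"], model["rmsz_angle"]),
                model=new)
        # TLS-model optimization: candidates improve on R_free,TLS by the
        # configured benefit, the per-chain model being the best one
        benefit = p.tls_benefit if tls_model == "per_chain" else p.tls_benefit / 2.0
        r_free = p.r_free_best + p.r_free_tls_offset - benefit
        r = r_free - p.r_free_gap
        new = dict(model, r=r, r_free=r_free, tls=True)
        return EngineResult(
            stats=self._stats(settings.label or "tls_opt", r, r_free,
                              model["rmsz_bond"], model["rmsz_angle"]),
            model=new)


def simulated_engine(profile: SyntheticProfile) -> SimulatedEngine:
    return SimulatedEngine(profile)


def gen_map_and_waters(
    profile: SyntheticProfile,
) -> Tuple[GridMap, List[AtomRecord], Dict[Tuple[str, int, str], str]]:
    """Gaussian-sum density over a toy grid with waters planted in peaks
    (high fit, intended class "keep") and in flat solvent (intended class
    "remove").  Returns (map, waters, intended class per water id)."""
    p = profile
    rng = np.random.default_rng(p.seed + 1)
    n = p.map_size
    spacing = (p.map_spacing,) * 3
    extent = p.map_spacing * (n - 1)
    values = np.zeros((n, n, n))
    axes = np.arange(n) * p.map_spacing
    gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")

    waters: List[AtomRecord] = []
    intended: Dict[Tuple[str, int, str], str] = {}
    margin = 2.0
    centers = margin + rng.random((p.n_peak_waters, 3)) * (extent - 2 * margin)
    for i, c in enumerate(centers):
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        values += p.peak_height * np.exp(-d2 / (2.0 * p.peak_sigma ** 2))
        w = AtomRecord(name="O", element="O", residue="HOH", chain="W",
                       res_seq=i + 1, position=tuple(c), is_water=True,
                       occupancy=1.0, b_factor=30.0)
        waters.append(w)
        intended[w.atom_id()] = "keep"
    bulk = margin + rng.random((p.n_bulk_waters, 3)) * (extent - 2 * margin)
    for j, c in enumerate(bulk):
        # push bulk waters away from every peak so they sit in flat density
        for c0 in centers:
            d = c - c0
            dist = np.linalg.norm(d)
            if dist < 3.0 * p.peak_sigma:
                c = np.clip(c0 + d / max(dist, 1e-6) * 3.5 * p.peak_sigma,
                            margin, extent - margin)
        w = AtomRecord(name="O", element="O", residue="HOH", chain="W",
                       res_seq=100 + j, position=tuple(c), is_water=True,
                       occupancy=1.0, b_factor=40.0)
        waters.append(w)
        intended[w.atom_id()] = "remove"
    grid = GridMap(origin=(0.0, 0.0, 0.0), spacing=spacing, values=values)
    return grid, waters, intended


def make_pipeline_inputs(profile: SyntheticProfile) -> PipelineInputs:
    """Assemble complete pipeline inputs for one synthetic entry."""
    records, lattice = gen_reflections(profile)
    rng = np.random.default_rng(profile.seed + 2)
    atoms: List[AtomRecord] = []
    names = ["N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C"]
    for i in range(profile.n_atoms):
        res_seq = i // 5 + 1
        atoms.append(AtomRecord(
            name=names[i % 5], element=elements[i % 5], residue="ALA",
            chain="A", res_seq=res_seq,
            position=tuple(rng.random(3) * 30.0),
            occupancy=1.0, b_factor=float(20.0 + 10.0 * rng.random())))
    header = HeaderInfo(
        r_head=profile.r_head, r_free_head=profile.r_free_head,
        deposition_year=profile.deposition_year)
    grid, waters, _ = gen_map_and_waters(profile)
    return PipelineInputs(
        reflections=records, atoms=atoms, header=header,
        resolution=profile.resolution, b_wilson=profile.b_wilson,
        lattice=lattice, density_map=grid, waters=waters,
        quality_before=profile.quality_before)
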
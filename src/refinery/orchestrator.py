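"""The decision pipeline: baseline reproduction, strategy assembly,
re-refine / rebuild / final-refine flow, abort rules and change
classification.

Everything here is driven through an abstract :class:`RefinementEngine`, so
every decision path can be exercised with a simulated engine and no
external refinement binary.  The engine contract is deliberately small:
three operations (restrained refinement, rigid-body refinement, TLS
refinement), each deterministic for fixed inputs and settings, each
returning a :class:`~refinery.metrics.ModelStats` bundle plus an updated
model handle.

Before any strategy decision the pipeline must reproduce the R factor
reported in the deposited file's header.  If the recalculated R differs by
more than 5 percentage points, an escalation ladder runs — twin target (if
a twin fraction above 5% was detected), rigid-body refinement, then a short
TLS refinement with the header tensors — and if the gap still exceeds 10
percentage points the entry is declared unreproducible and the pipeline
aborts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Literal, Optional, Protocol, Sequence, Tuple

from pydantic import BaseModel

from . import bfactor, categorize, freeset, picker, realspace
from .categorize import AUTO_WEIGHT, Category, CycleContext, assign_category, assign_cycles
from .errors import InvalidInputError, PipelineAbort, RefineryError
from .metrics import (
    BaselineMetrics,
    ModelStats,
    estimate_r_ratio,
    expected_r_free,
    sigma_r_free,
    z_r_free,
)
from .modelprep import AtomRecord, HeaderInfo
from .realspace import FitScore, GridMap
from .reflections import Lattice, ReflectionRecord, sanitize_reflections

__all__ = [
    "RefinementSettings",
    "EngineResult",
    "RefinementEngine",
    "QualityMetrics",
    "ChangeVerdict",
    "DecisionReport",
    "PipelineInputs",
    "PipelineResult",
    "reproduce_baseline",
    "twin_policy",
    "plan_tls",
    "classify_change",
    "run_pipeline",
    "BASELINE_GAP_LADDER",
    "BASELINE_GAP_ABORT",
]

#: R_calc − R_head gap (on the R scale) above which the fallback ladder runs
BASELINE_GAP_LADDER = 0.05
#: terminal gap above which the entry is declared unreproducible
BASELINE_GAP_ABORT = 0.10

_TWIN_FRACTION_GATE = 0.05
_TWIN_RMERGE_MAX = 0.44
_TWIN_FRACTION_MIN = 0.07


class RefinementSettings(BaseModel):
    """Settings handed to the engine; ``cycles = 0`` means evaluate only."""

    label: str = ""
    cycles: int = 0
    weight: Optional[float] = None  # None or AUTO_WEIGHT → automatic weighting
    b_weight: Optional[float] = None
    bfactor_model: Literal["iso", "aniso", "overall"] = "iso"
    use_tls: bool = False
    twin: bool = False
    reset_b_to: Optional[float] = None
    tight_b_restraints: bool = False
    jelly_body: bool = False


@dataclass
class QualityMetrics:
    """The seven model-quality metrics compared before/after optimization."""

    r_free: float
    ramachandran_z: float
    rotamer_z: float
    coarse_packing_z: float
    fine_packing_z: float
    bumps: int
    unsatisfied_donors: int


@dataclass
class EngineResult:
    stats: ModelStats
    model: Any
    quality: Optional[QualityMetrics] = None


class RefinementEngine(Protocol):
    """Contract for refinement backends (deterministic per inputs+settings)."""

    def refine(self, model: Any, data: Any, settings: RefinementSettings) -> EngineResult: ...

    def rigid_body(self, model: Any, data: Any, settings: RefinementSettings) -> EngineResult: ...

    def tls_refine(
        self, model: Any, data: Any, settings: RefinementSettings,
        tls_model: Optional[Any] = None,
    ) -> EngineResult: ...


class ChangeVerdict(BaseModel):
    r_free: Literal["better", "same", "worse"]
    ramachandran_z: Literal["better", "same", "worse"]
    rotamer_z: Literal["better", "same", "worse"]
    coarse_packing_z: Literal["better", "same", "worse"]
    fine_packing_z: Literal["better", "same", "worse"]
    bumps: Literal["better", "same", "worse"]
    unsatisfied_donors: Literal["better", "same", "worse"]


@dataclass
class DecisionReport:
    """Machine-readable trace of every branch the pipeline took."""

    entries: List[Dict[str, Any]] = field(default_factory=list)
    final_status: str = "completed"

    def record(self, point: str, rule: str, outcome: Any, **inputs: Any) -> None:
        self.entries.append({
            "decision_point": point,
            "rule": rule,
            "inputs": {k: _jsonable(v) for k, v in sorted(inputs.items())},
            "outcome": _jsonable(outcome),
        })

    def to_json(self) -> str:
        return json.dumps(
            {"final_status": self.final_status, "trace": self.entries},
            sort_keys=True, indent=2)


def _jsonable(v: Any) -> Any:
    if isinstance(v, BaseModel):
        return v.model_dump()
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return dataclasses.asdict(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, float):
        return round(v, 12)
    return v


# ---------------------------------------------------------------------------
# baseline reproduction (the escalation ladder)

def reproduce_baseline(
    engine: RefinementEngine,
    model: Any,
    data: Any,
    header: HeaderInfo,
    twin_fraction_external: float,
    *,
    legacy: bool = False,
    b_wilson: float = 0.0,
    r_ratio: Optional[float] = None,
    report: Optional[DecisionReport] = None,
) -> Tuple[BaselineMetrics, Any]:
    """Reproduce the header R factor and establish baseline metrics.

    Raises :class:`PipelineAbort` with status ``aborted_no_r_head`` when the
    header carries no R factor, or ``aborted_unreproducible`` when, after
    the full fallback ladder, R_calc − R_head still exceeds 10 percentage
    points.  Engine failures on a ladder rung are recorded and the ladder
    continues with the next rung.
    """
    rep = report if report is not None else DecisionReport()
    if header.r_head is None:
        rep.final_status = "aborted_no_r_head"
        rep.record("baseline", "baseline.r_head_required", "abort")
        raise PipelineAbort("aborted_no_r_head")

    # TLS ambiguity: deposited B factors may be 'total' or 'residual';
    # evaluate with and without the header TLS model, keep the lower R.
    evaluate = RefinementSettings(label="calc", cycles=0)
    if header.tls_groups:
        with_tls = engine.tls_refine(
            model, data, evaluate.model_copy(update={"use_tls": True}),
            tls_model=header.tls_groups)
        without = engine.refine(model, data, evaluate)
        if with_tls.stats.r <= without.stats.r:
            current, b_total = with_tls, "residual"
        else:
            current, b_total = without, "total"
        rep.record("baseline", "baseline.tls_ambiguity", b_total,
                   r_with=with_tls.stats.r, r_without=without.stats.r)
    else:
        current = engine.refine(model, data, evaluate)

    def gap() -> float:
        return current.stats.r - header.r_head

    rungs = []
    if twin_fraction_external > _TWIN_FRACTION_GATE:
        rungs.append(("twin", lambda: engine.refine(
            current.model, data,
            RefinementSettings(label="twin", cycles=0, twin=True))))
    rungs.append(("rigid_body", lambda: engine.rigid_body(
        current.model, data,
        RefinementSettings(
            label="rigid", cycles=assign_cycles(
                CycleContext(task="rigid_reproduce", legacy=legacy))))))
    if header.tls_groups:
        rungs.append(("tls_reproduce", lambda: engine.tls_refine(
            current.model, data,
            RefinementSettings(
                label="tls_reproduce",
                cycles=assign_cycles(CycleContext(task="tls_reproduce"))),
            tls_model=header.tls_groups)))

    for name, rung in rungs:
        if gap() <= BASELINE_GAP_LADDER:
            break
        try:
            attempt = rung()
        except RefineryError as exc:
            rep.record("baseline", f"baseline.ladder.{name}", f"failed: {exc}")
            continue
        improved = attempt.stats.r < current.stats.r
        rep.record("baseline", f"baseline.ladder.{name}",
                   "kept" if improved else "discarded",
                   r_before=current.stats.r, r_after=attempt.stats.r)
        if improved:
            current = attempt

    if gap() > BASELINE_GAP_ABORT:
        rep.final_status = "aborted_unreproducible"
        rep.record("baseline", "baseline.abort_gap", "abort",
                   gap=gap(), limit=BASELINE_GAP_ABORT)
        raise PipelineAbort("aborted_unreproducible",
                            f"R_calc - R_head = {gap():.3f} > {BASELINE_GAP_ABORT}")

    stats = current.stats
    ratio = r_ratio if r_ratio is not None else 1.0
    unb = expected_r_free(stats.r, ratio)
    if stats.n_test_reflections > 0 and stats.r_free > 0:
        sigma = sigma_r_free(stats.r_free, stats.n_test_reflections)
        z = z_r_free(stats.r_free, unb, sigma)
    else:
        sigma, z = 0.0, 0.0
    base = BaselineMetrics(
        r_head=header.r_head,
        r_free_head=header.r_free_head,
        r_calc=stats.r,
        r_free_calc=stats.r_free,
        r_ratio=ratio,
        r_free_unb_calc=unb,
        sigma_r_free_calc=sigma,
        z_r_free_calc=z,
        rmsz_bond_calc=stats.rmsz_bond,
        rmsz_angle_calc=stats.rmsz_angle,
        b_wilson=b_wilson,
    )
    rep.record("baseline", "baseline.established", "ok",
               r_calc=base.r_calc, r_free_calc=base.r_free_calc, gap=gap())
    return base, current.model


def twin_policy(
    external_fraction: float,
    engine_twin_ops: Sequence[Tuple[float, float]],
) -> bool:
    """Decide whether refinement uses twin target functions.

    True iff the external twin-fraction estimate exceeds 5% AND the engine
    reports at least one twin operator with R_merge < 44% and twin fraction
    > 7% (both operator inequalities strict, as specified).
    """
    if not 0.0 <= external_fraction <= 1.0:
        raise InvalidInputError("twin fraction must be in [0, 1]")
    if external_fraction <= _TWIN_FRACTION_GATE:
        return False
    return any(
        r_merge < _TWIN_RMERGE_MAX and frac > _TWIN_FRACTION_MIN
        for r_merge, frac in engine_twin_ops
    )


# ---------------------------------------------------------------------------
# TLS planning

@dataclass
class TlsDecision:
    use_tls: bool
    chosen_label: Optional[str]
    r_tls: float
    r_free_tls: float
    model: Any = None


def plan_tls(
    engine: RefinementEngine,
    model: Any,
    data: Any,
    header: HeaderInfo,
    user_models: Sequence[Any] = (),
    *,
    resolution: float,
    b_wilson: float,
    mean_b: float,
    base: BaselineMetrics,
    legacy: bool = False,
    report: Optional[DecisionReport] = None,
) -> TlsDecision:
    """Assemble and test TLS candidate models.

    Atomic B factors are reset to B_Wilson (or the mean model B at 4 Å
    resolution or worse) and R_TLS / R_free,TLS recorded.  Candidates — one
    group per chain, the header model if present, any user-provided models
    — are each TLS-refined and judged by the picker with tls_opt cutoffs.
    TLS is adopted only if the chosen candidate *decreases* R_free relative
    to R_free,TLS.
    """
    rep = report if report is not None else DecisionReport()
    reset_target = b_wilson if resolution < 4.0 else mean_b
    rep.record("tls", "tls.b_reset_target",
               "b_wilson" if resolution < 4.0 else "mean_b",
               resolution=resolution, target=reset_target)

    ref_settings = RefinementSettings(label="tls_baseline", cycles=0,
                                      reset_b_to=reset_target, use_tls=True)
    baseline = engine.tls_refine(model, data, ref_settings, tls_model=None)
    r_tls, r_free_tls = baseline.stats.r, baseline.stats.r_free

    candidates: List[Tuple[str, Any]] = [("per_chain", "per_chain")]
    if header.tls_groups:
        candidates.append(("header", header.tls_groups))
    for i, um in enumerate(user_models):
        candidates.append((f"user_{i}", um))

    cycles = assign_cycles(CycleContext(task="tls_optimize", legacy=legacy))
    results: List[EngineResult] = []
    stats_list: List[ModelStats] = []
    for label, tls_model in candidates:
        res = engine.tls_refine(
            model, data,
            RefinementSettings(label=label, cycles=cycles,
                               reset_b_to=reset_target, use_tls=True),
            tls_model=tls_model)
        res.stats = res.stats.model_copy(update={"label": label})
        results.append(res)
        stats_list.append(res.stats)

    tls_base = base.model_copy(update={"r_tls": r_tls, "r_free_tls": r_free_tls})
    cut = picker.establish_cutoffs(tls_base, source="tls_opt")
    selection = picker.pick(stats_list, cut, base.r_ratio)
    chosen_label = selection.chosen
    use = False
    chosen_model = None
    if chosen_label is not None:
        chosen = next(r for r in results if r.stats.label == chosen_label)
        use = chosen.stats.r_free < r_free_tls  # adoption requires a decrease
        chosen_model = chosen.model if use else None
    rep.record("tls", "tls.adoption", chosen_label if use else "declined",
               r_free_tls=r_free_tls, candidates=[s.label for s in stats_list],
               chosen=chosen_label)
    return TlsDecision(use_tls=use, chosen_label=chosen_label if use else None,
                       r_tls=r_tls, r_free_tls=r_free_tls, model=chosen_model)


# ---------------------------------------------------------------------------
# change classification

def classify_change(
    before: QualityMetrics, after: QualityMetrics, sigma_r_free_val: float
) -> ChangeVerdict:
    """Classify each quality metric as better / same / worse.

    "Same" bands: |ΔR_free| ≤ 2σ(R_free); |ΔZ| ≤ 0.1 for the four
    normality Z scores; |Δbumps| ≤ 10; |Δunsatisfied donors| ≤ 2.  Higher
    Z is better; fewer bumps, donors and lower R_free are better.
    """
    def lower_better(b: float, a: float, band: float) -> str:
        d = a - b
        if abs(d) <= band:
            return "same"
        return "better" if d < 0 else "worse"

    def higher_better(b: float, a: float, band: float) -> str:
        d = a - b
        if abs(d) <= band:
            return "same"
        return "better" if d > 0 else "worse"

    return ChangeVerdict(
        r_free=lower_better(before.r_free, after.r_free, 2.0 * sigma_r_free_val),
        ramachandran_z=higher_better(before.ramachandran_z, after.ramachandran_z, 0.1),
        rotamer_z=higher_better(before.rotamer_z, after.rotamer_z, 0.1),
        coarse_packing_z=higher_better(before.coarse_packing_z, after.coarse_packing_z, 0.1),
        fine_packing_z=higher_better(before.fine_packing_z, after.fine_packing_z, 0.1),
        bumps=lower_better(before.bumps, after.bumps, 10),
        unsatisfied_donors=lower_better(before.unsatisfied_donors,
                                        after.unsatisfied_donors, 2),
    )


# ---------------------------------------------------------------------------
# the full pipeline

_REBUILD_CATEGORIES = ("atomic", "high", "medium", "low")


@dataclass
class PipelineInputs:
    reflections: List[ReflectionRecord]
    atoms: List[AtomRecord]
    header: HeaderInfo
    resolution: float
    b_wilson: float
    lattice: Optional[Lattice] = None
    twin_fraction: float = 0.0
    twin_operators: List[Tuple[float, float]] = field(default_factory=list)
    user_tls: List[Any] = field(default_factory=list)
    model: Any = None
    n_restraints_base: Optional[int] = None
    n_restraints_extra: Optional[int] = None
    density_map: Optional[GridMap] = None
    waters: List[AtomRecord] = field(default_factory=list)
    linked_water_ids: set = field(default_factory=set)
    ss: Dict[Tuple[str, int], str] = field(default_factory=dict)
    altloc_residues: List[Tuple[str, int]] = field(default_factory=list)
    quality_before: Optional[QualityMetrics] = None


@dataclass
class PipelineResult:
    report: DecisionReport
    baseline: Optional[BaselineMetrics] = None
    category: Optional[Category] = None
    final_stats: Optional[ModelStats] = None
    final_model: Any = None
    change: Optional[ChangeVerdict] = None


def run_pipeline(
    engine: RefinementEngine,
    inputs: PipelineInputs,
    config: Optional[Dict[str, Any]] = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full decision pipeline with the given engine.

    The state machine is deterministic for a fixed engine, inputs and
    seed; every branch taken is recorded in the returned DecisionReport.
    """
    config = config or {}
    report = DecisionReport()
    result = PipelineResult(report=report)

    # --- data sanitation -------------------------------------------------
    clean, log = sanitize_reflections(inputs.reflections)
    report.record("sanitize", "sanitize.rules", log,
                  n_in=len(inputs.reflections), n_out=len(clean))

    # --- free-set handling ----------------------------------------------
    n_total = len(clean)
    n_atoms = len(inputs.atoms)
    n_free = sum(1 for r in clean if r.free_flag == 1)
    created = False
    if n_free > 0:
        decision = freeset.validate_free_set(n_total, n_free)
        report.record("freeset", "freeset.validate", decision.action,
                      n_total=n_total, n_free=n_free)
        if decision.action == "reject":
            flags, decision = freeset.create_free_set(n_total, seed)
            created = True
            clean = [r.model_copy(update={"free_flag": int(flags[i])})
                     for i, r in enumerate(clean)]
            report.record("freeset", "freeset.create", decision.n_free,
                          n_total=n_total)
    else:
        flags, decision = freeset.create_free_set(n_total, seed)
        created = True
        clean = [r.model_copy(update={"free_flag": int(flags[i])})
                 for i, r in enumerate(clean)]
        report.record("freeset", "freeset.create", decision.n_free,
                      n_total=n_total)

    # --- baseline reproduction ------------------------------------------
    legacy = inputs.header.legacy
    n_param_eff = 4 * n_atoms
    try:
        r_ratio = estimate_r_ratio(n_total, n_param_eff) if n_total > n_param_eff else 1.0
    except InvalidInputError:
        r_ratio = 1.0
    try:
        base, model = reproduce_baseline(
            engine, inputs.model, clean, inputs.header, inputs.twin_fraction,
            legacy=legacy, b_wilson=inputs.b_wilson, r_ratio=r_ratio,
            report=report)
    except PipelineAbort:
        return result

    # --- free-set bias ---------------------------------------------------
    biased = freeset.assess_bias(base, set_was_created=created)
    adjust = freeset.baseline_adjustments(biased, base)
    base = base.model_copy(update={"free_set_biased": biased})
    result.baseline = base
    report.record("freeset", "freeset.bias", biased,
                  baseline_r_free=adjust.baseline_r_free,
                  protocol=adjust.protocol)
    new_free_set = adjust.protocol == "reset_b_and_extend"

    # --- categorization --------------------------------------------------
    rpa = categorize.reflections_per_atom(n_total, n_atoms)
    category = assign_category(inputs.resolution, rpa,
                               overrides=config.get("weight_grids"))
    result.category = category
    report.record("categorize", "categorize.table", category.name,
                  resolution=inputs.resolution, rpa=rpa)

    # --- twin policy ------------------------------------------------------
    use_twin = twin_policy(inputs.twin_fraction, inputs.twin_operators)
    report.record("strategy", "strategy.twin", use_twin,
                  twin_fraction=inputs.twin_fraction)

    # --- B-model routing and TLS planning --------------------------------
    route = bfactor.route_parameterization(rpa, tls_usable=True)
    report.record("strategy", "strategy.b_route", route.route, rpa=rpa)

    tls_decision: Optional[TlsDecision] = None
    if route.route != "aniso":
        mean_b = (sum(a.b_factor for a in inputs.atoms) / n_atoms) if n_atoms else 0.0
        tls_decision = plan_tls(
            engine, model, clean, inputs.header, inputs.user_tls,
            resolution=inputs.resolution, b_wilson=inputs.b_wilson,
            mean_b=mean_b, base=base, legacy=legacy, report=report)
        if route.route == "contest_iso_vs_overall" and not tls_decision.use_tls:
            route = bfactor.route_parameterization(rpa, tls_usable=False)
            report.record("strategy", "strategy.b_route_fallback", route.route)
    tls_in_use = bool(tls_decision and tls_decision.use_tls)
    if tls_decision and tls_decision.use_tls and tls_decision.model is not None:
        model = tls_decision.model

    b_model = _resolve_b_model(
        engine, model, clean, inputs, route, base, r_ratio, tls_in_use,
        new_free_set, legacy, n_atoms, n_total, report)
    if b_model == "aniso":
        tls_in_use = False

    # --- B-restraint-weight optimization ---------------------------------
    cut = picker.establish_cutoffs(base, source="general")
    b_weight: Optional[float] = None
    if b_model == "iso":
        cycles = assign_cycles(CycleContext(task="b_weight_opt",
                                            tls_in_use=tls_in_use))
        cand = []
        for bw in category.b_weight_grid:
            res = engine.refine(model, clean, RefinementSettings(
                label=f"bw_{bw:g}", cycles=cycles, b_weight=bw,
                bfactor_model="iso", use_tls=tls_in_use,
                jelly_body=category.jelly_body))
            cand.append(res.stats)
        sel = picker.pick(cand, cut, base.r_ratio, category)
        if sel.chosen is not None:
            b_weight = float(sel.chosen.split("_", 1)[1])
        report.record("strategy", "strategy.b_weight", sel.chosen,
                      grid=category.b_weight_grid)

    # --- re-refinement ----------------------------------------------------
    rr_ctx = CycleContext(
        task="rerefine", legacy=legacy, tls_in_use=tls_in_use,
        new_free_set=new_free_set, anisotropic=(b_model == "aniso"))
    cycles = assign_cycles(rr_ctx)
    reset_b = inputs.b_wilson if new_free_set else None
    results: List[EngineResult] = []
    for w in category.weight_grid:
        res = engine.refine(model, clean, RefinementSettings(
            label=f"w_{w:g}", cycles=cycles, weight=w,
            b_weight=b_weight, bfactor_model=b_model, use_tls=tls_in_use,
            twin=use_twin, reset_b_to=reset_b,
            jelly_body=category.jelly_body))
        results.append(res)
    selection = picker.pick([r.stats for r in results], cut, base.r_ratio, category)
    report.record("rerefine", "picker.select", selection.chosen,
                  cycles=cycles, rejected=selection.rejected)

    if selection.chosen is not None:
        chosen_res = next(r for r in results if r.stats.label == selection.chosen)
        rebuild_model = chosen_res.model
        chosen_weight = float(selection.chosen.split("_", 1)[1])
        final_weights = _neighbor_weights(category.weight_grid, chosen_weight)
        auto_fallback = False
    else:
        # no refinement beat the baseline: rebuild from the original model
        # and fall back to automatic weighting in the final refinement
        rebuild_model = model
        final_weights = [AUTO_WEIGHT]
        auto_fallback = True
    report.record("rerefine", "picker.fallback", auto_fallback,
                  final_weights=final_weights)

    # --- rebuilding selection --------------------------------------------
    if inputs.waters and inputs.density_map is not None:
        scored = [(w, realspace.density_fit(inputs.density_map, [w]))
                  for w in inputs.waters]
        kept, removed = realspace.centrifuge(scored, inputs.linked_water_ids)
        report.record("rebuild", "centrifuge.prune",
                      {"kept": len(kept), "removed": len(removed)})
    if category.name in _REBUILD_CATEGORIES:
        residues = sorted({(a.chain, a.res_seq) for a in inputs.atoms
                           if not a.is_water})
        linked_atoms = [l.atom1 for l in inputs.header.links] + \
                       [l.atom2 for l in inputs.header.links]
        elig = realspace.rebuild_candidates(
            residues, linked_atoms, inputs.altloc_residues,
            {k: v for k, v in inputs.ss.items()})  # type: ignore[arg-type]
        report.record(
            "rebuild", "rebuild.candidates",
            {"peptide_flip": sum(e.peptide_flip for e in elig.values()),
             "sidechain": sum(e.sidechain for e in elig.values()),
             "total": len(elig)})
    else:
        report.record("rebuild", "rebuild.skip_low_resolution", category.name)

    # --- final refinement -------------------------------------------------
    if tls_in_use:
        engine.tls_refine(rebuild_model, clean, RefinementSettings(
            label="tls_final",
            cycles=assign_cycles(CycleContext(task="tls_final"))),
            tls_model="update")
    final_results: List[EngineResult] = []
    for w in final_weights:
        res = engine.refine(rebuild_model, clean, RefinementSettings(
            label=f"final_{w:g}", cycles=cycles, weight=w,
            b_weight=b_weight, bfactor_model=b_model, use_tls=tls_in_use,
            twin=use_twin, jelly_body=category.jelly_body))
        final_results.append(res)
    final_sel = picker.pick([r.stats for r in final_results], cut,
                            base.r_ratio, category)
    report.record("final", "picker.select_final", final_sel.chosen,
                  weights=final_weights)
    if final_sel.chosen is not None:
        final = next(r for r in final_results if r.stats.label == final_sel.chosen)
    else:
        final = EngineResult(stats=ModelStats(
            label="original", r=base.r_calc, r_free=base.r_free_calc,
            rmsz_bond=base.rmsz_bond_calc, rmsz_angle=base.rmsz_angle_calc,
            n_test_reflections=0), model=model)
    result.final_stats = final.stats
    result.final_model = final.model

    # --- change classification -------------------------------------------
    if inputs.quality_before is not None and final.quality is not None:
        sig = base.sigma_r_free_calc
        change = classify_change(inputs.quality_before, final.quality,
                                 sig if sig > 0 else 1e-9)
        result.change = change
        report.record("final", "final.change_verdict", change)

    report.final_status = "completed"
    return result


def _resolve_b_model(
    engine, model, data, inputs: PipelineInputs, route, base, r_ratio,
    tls_in_use: bool, new_free_set: bool, legacy: bool,
    n_atoms: int, n_obs: int, report: DecisionReport,
) -> str:
    """Run the B-model contest (when routed to one) and return the model."""
    if route.route == "aniso":
        return "aniso"
    if route.route in ("iso", "iso_fallback"):
        return "iso"

    if route.route == "contest_aniso_vs_iso":
        simple_kind, complex_kind = "iso", "aniso"
        cycles = assign_cycles(CycleContext(task="b_model_iso_vs_aniso"))
        reset = inputs.b_wilson
        tight = False
    else:  # contest_iso_vs_overall
        simple_kind, complex_kind = "overall", "iso"
        cycles = assign_cycles(CycleContext(
            task="rerefine", legacy=legacy, tls_in_use=tls_in_use,
            new_free_set=new_free_set))
        reset = None
        tight = True

    trial = {}
    for kind in (simple_kind, complex_kind):
        res = engine.refine(model, data, RefinementSettings(
            label=f"bmodel_{kind}", cycles=cycles, bfactor_model=kind,
            use_tls=tls_in_use and kind != "aniso", reset_b_to=reset,
            tight_b_restraints=tight))
        trial[kind] = res.stats

    pp = bfactor.PARAMS_PER_ATOM
    n_base = inputs.n_restraints_base if inputs.n_restraints_base is not None \
        else 2 * n_atoms
    n_extra = inputs.n_restraints_extra if inputs.n_restraints_extra is not None \
        else (pp[complex_kind] - pp[simple_kind]) * n_atoms
    grid = bfactor.default_weight_grid()
    inp = bfactor.HamiltonInput(
        r_free_w_simple=trial[simple_kind].r_free_weighted or trial[simple_kind].r_free,
        r_free_w_complex=trial[complex_kind].r_free_weighted or trial[complex_kind].r_free,
        n_obs=n_obs,
        n_params_simple=pp[simple_kind] * n_atoms,
        n_params_complex=pp[complex_kind] * n_atoms,
        n_restraints_base=n_base,
        n_restraints_extra=n_extra,
        w1_grid=grid, w2_grid=grid)
    cstats = trial[complex_kind]
    z_complex: Optional[float] = None
    if cstats.n_test_reflections > 0 and cstats.r_free > 0:
        z_complex = z_r_free(
            cstats.r_free, cstats.r * base.r_ratio,
            sigma_r_free(cstats.r_free, cstats.n_test_reflections))
    winner = bfactor.bselect(
        trial[simple_kind], trial[complex_kind], inp, z_complex,
        complex_kind="aniso" if complex_kind == "aniso" else "iso")
    chosen = complex_kind if winner == "complex" else simple_kind
    report.record("strategy", "bselect.contest", chosen,
                  simple=simple_kind, complex=complex_kind)
    return chosen


def _neighbor_weights(grid: Sequence[float], chosen: float) -> List[float]:
    """The chosen weight plus one grid step tighter and one looser."""
    ordered = sorted(grid)
    try:
        i = min(range(len(ordered)), key=lambda j: abs(ordered[j] - chosen))
    except ValueError:
        return [chosen]
    out = [ordered[i]]
    if i > 0:
        out.append(ordered[i - 1])
    if i + 1 < len(ordered):
        out.append(ordered[i + 1])
    return out
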
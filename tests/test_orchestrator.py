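"""Baseline ladder, twin policy, TLS planning, change classification and
full-pipeline behaviour with the simulated engine."""

import dataclasses

import pytest

from refinery.errors import PipelineAbort
from refinery.metrics import BaselineMetrics
from refinery.modelprep import HeaderInfo, TlsGroup
from refinery.orchestrator import (
    DecisionReport,
    QualityMetrics,
    classify_change,
    plan_tls,
    reproduce_baseline,
    run_pipeline,
    twin_policy,
)
from refinery.synthetic import (
    SyntheticProfile,
    make_pipeline_inputs,
    simulated_engine,
)


def quality(**kw):
    base = dict(r_free=0.24, ramachandran_z=-1.3, rotamer_z=-1.2,
                coarse_packing_z=-0.2, fine_packing_z=-1.0,
                bumps=100, unsatisfied_donors=40)
    base.update(kw)
    return QualityMetrics(**base)


HEADER = HeaderInfo(r_head=0.20, r_free_head=0.24, deposition_year=2005)


class TestTwinPolicy:
    @pytest.mark.parametrize("fraction,ops,expected", [
        (0.04, [(0.10, 0.50)], False),          # below the 5% gate
        (0.10, [(0.43, 0.08)], True),
        (0.10, [(0.44, 0.08)], False),          # strict R_merge < 44%
        (0.10, [(0.43, 0.07)], False),          # strict fraction > 7%
        (0.10, [], False),
        (0.10, [(0.60, 0.50), (0.30, 0.09)], True),
    ])
    def test_gates(self, fraction, ops, expected):
        assert twin_policy(fraction, ops) is expected


class TestReproduceBaseline:
    def engine(self, **kw):
        return simulated_engine(SyntheticProfile(**kw))

    def test_small_gap_skips_ladder(self):
        eng = self.engine(planted_gap=0.03)
        report = DecisionReport()
        base, _ = reproduce_baseline(eng, None, None, HEADER, 0.0,
                                     report=report, r_ratio=1.1)
        assert base.r_calc == pytest.approx(0.23)
        assert not any("ladder" in e["rule"] for e in report.entries)

    def test_twin_rung_attempted_first_when_twinned(self):
        eng = self.engine(planted_gap=0.07, twin_gain=0.04)
        report = DecisionReport()
        base, _ = reproduce_baseline(eng, None, None, HEADER, 0.06,
                                     report=report, r_ratio=1.1)
        rungs = [e["rule"] for e in report.entries if "ladder" in e["rule"]]
        assert rungs[0] == "baseline.ladder.twin"
        assert base.r_calc == pytest.approx(0.27 - 0.04)

    def test_rigid_rung_skipped_once_gap_closed(self):
        eng = self.engine(planted_gap=0.07, twin_gain=0.04, rigid_gain=0.02)
        report = DecisionReport()
        reproduce_baseline(eng, None, None, HEADER, 0.06, report=report,
                           r_ratio=1.1)
        rungs = [e["rule"] for e in report.entries if "ladder" in e["rule"]]
        assert "baseline.ladder.rigid_body" not in rungs

    def test_terminal_gap_aborts(self):
        eng = self.engine(planted_gap=0.105)
        report = DecisionReport()
        with pytest.raises(PipelineAbort) as exc:
            reproduce_baseline(eng, None, None, HEADER, 0.0, report=report)
        assert exc.value.status == "aborted_unreproducible"
        assert report.final_status == "aborted_unreproducible"

    def test_missing_r_head_aborts(self):
        eng = self.engine()
        with pytest.raises(PipelineAbort) as exc:
            reproduce_baseline(eng, None, None, HeaderInfo(), 0.0)
        assert exc.value.status == "aborted_no_r_head"

    def test_tls_ambiguity_resolved_by_lower_r(self):
        header = HeaderInfo(
            r_head=0.20, r_free_head=0.24,
            tls_groups=[TlsGroup(selections=(("A", 1, 50),))])
        eng = self.engine(planted_gap=0.01)
        report = DecisionReport()
        reproduce_baseline(eng, None, None, header, 0.0, report=report,
                           r_ratio=1.1)
        assert any(e["rule"] == "baseline.tls_ambiguity" for e in report.entries)


class TestPlanTls:
    def base(self):
        return BaselineMetrics(r_calc=0.21, r_free_calc=0.25, r_ratio=1.1,
                               r_free_unb_calc=0.231, sigma_r_free_calc=0.005,
                               rmsz_bond_calc=0.8, rmsz_angle_calc=0.9)

    def test_adopted_when_r_free_decreases(self):
        eng = simulated_engine(SyntheticProfile(tls_benefit=0.01))
        decision = plan_tls(eng, eng.initial_model(), None, HEADER,
                            resolution=2.0, b_wilson=25.0, mean_b=30.0,
                            base=self.base())
        assert decision.use_tls and decision.chosen_label == "per_chain"

    def test_equal_r_free_not_adopted(self):
        eng = simulated_engine(SyntheticProfile(tls_benefit=0.0))
        decision = plan_tls(eng, eng.initial_model(), None, HEADER,
                            resolution=2.0, b_wilson=25.0, mean_b=30.0,
                            base=self.base())
        assert not decision.use_tls

    def test_harmful_tls_declined(self):
        eng = simulated_engine(SyntheticProfile(tls_benefit=-0.02))
        decision = plan_tls(eng, eng.initial_model(), None, HEADER,
                            resolution=2.0, b_wilson=25.0, mean_b=30.0,
                            base=self.base())
        assert not decision.use_tls

    def test_reset_target_switches_at_four_angstrom(self):
        eng = simulated_engine(SyntheticProfile())
        for resolution, outcome in [(2.0, "b_wilson"), (4.2, "mean_b")]:
            report = DecisionReport()
            plan_tls(eng, eng.initial_model(), None, HEADER,
                     resolution=resolution, b_wilson=25.0, mean_b=30.0,
                     base=self.base(), report=report)
            entry = next(e for e in report.entries
                         if e["rule"] == "tls.b_reset_target")
            assert entry["outcome"] == outcome

    def test_candidate_list_without_header_or_user_models(self):
        eng = simulated_engine(SyntheticProfile())
        report = DecisionReport()
        plan_tls(eng, eng.initial_model(), None, HEADER,
                 resolution=2.0, b_wilson=25.0, mean_b=30.0,
                 base=self.base(), report=report)
        entry = next(e for e in report.entries if e["rule"] == "tls.adoption")
        assert entry["inputs"]["candidates"] == ["per_chain"]


class TestClassifyChange:
    def test_r_free_band(self):
        v = classify_change(quality(), quality(r_free=0.239), 0.004)
        assert v.r_free == "same"           # |−0.001| <= 2 x 0.004
        v = classify_change(quality(), quality(r_free=0.230), 0.004)
        assert v.r_free == "better"

    def test_bump_band(self):
        assert classify_change(quality(), quality(bumps=89), 0.004).bumps == "better"
        assert classify_change(quality(), quality(bumps=90), 0.004).bumps == "same"

    def test_z_band(self):
        v = classify_change(quality(), quality(ramachandran_z=-1.15), 0.004)
        assert v.ramachandran_z == "better"
        v = classify_change(quality(), quality(ramachandran_z=-1.25), 0.004)
        assert v.ramachandran_z == "same"

    def test_antisymmetry(self):
        before, after = quality(), quality(
            r_free=0.20, ramachandran_z=-0.5, rotamer_z=-2.0,
            coarse_packing_z=-0.2, fine_packing_z=-0.5, bumps=150,
            unsatisfied_donors=20)
        fwd = classify_change(before, after, 0.004)
        rev = classify_change(after, before, 0.004)
        flip = {"better": "worse", "worse": "better", "same": "same"}
        for name in type(fwd).model_fields:
            assert getattr(rev, name) == flip[getattr(fwd, name)]


class TestPipeline:
    def test_deterministic_reports(self):
        profile = SyntheticProfile(seed=5)
        r1 = run_pipeline(simulated_engine(profile),
                          make_pipeline_inputs(profile), seed=5)
        r2 = run_pipeline(simulated_engine(profile),
                          make_pipeline_inputs(profile), seed=5)
        assert r1.report.to_json() == r2.report.to_json()

    def test_trace_covers_every_stage_once(self):
        profile = SyntheticProfile(seed=1)
        res = run_pipeline(simulated_engine(profile),
                           make_pipeline_inputs(profile), seed=1)
        points = [e["decision_point"] for e in res.report.entries]
        for stage in ("sanitize", "freeset", "baseline", "categorize",
                      "strategy", "rerefine", "rebuild", "final"):
            assert stage in points
        assert res.report.final_status == "completed"

    def test_low_resolution_skips_rebuild_stages(self):
        profile = SyntheticProfile(seed=2, resolution=4.0, n_reflections=2000,
                                   n_atoms=1000)
        inputs = make_pipeline_inputs(profile)
        res = run_pipeline(simulated_engine(profile), inputs, seed=2)
        assert res.category.name == "vlow"
        rules = [e["rule"] for e in res.report.entries]
        assert "centrifuge.prune" in rules          # water pruning always runs
        assert "rebuild.skip_low_resolution" in rules
        assert "rebuild.candidates" not in rules

    def test_improving_engine_never_uses_auto_fallback(self):
        for seed in range(5):
            profile = SyntheticProfile(seed=seed)
            res = run_pipeline(simulated_engine(profile),
                               make_pipeline_inputs(profile), seed=seed)
            fallback = next(e for e in res.report.entries
                            if e["rule"] == "picker.fallback")
            assert fallback["outcome"] is False

    def test_failed_selection_falls_back_to_auto_weighting(self):
        # every candidate's R_free exceeds the baseline cutoff
        profile = SyntheticProfile(seed=3, r_free_best=0.30)
        res = run_pipeline(simulated_engine(profile),
                           make_pipeline_inputs(profile), seed=3)
        fallback = next(e for e in res.report.entries
                        if e["rule"] == "picker.fallback")
        assert fallback["outcome"] is True
        assert fallback["inputs"]["final_weights"] == [0.0]

    def test_abort_propagates_status(self):
        profile = SyntheticProfile(seed=4, planted_gap=0.2)
        res = run_pipeline(simulated_engine(profile),
                           make_pipeline_inputs(profile), seed=4)
        assert res.report.final_status == "aborted_unreproducible"
        assert res.final_stats is None
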
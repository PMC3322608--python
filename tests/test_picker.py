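"""Cutoff establishment, R_free,max arithmetic and pick-vs-oracle checks."""

import numpy as np
import pytest

from refinery.categorize import assign_category
from refinery.errors import InvalidInputError
from refinery.metrics import BaselineMetrics, ModelStats, sigma_r_free
from refinery.picker import Cutoffs, establish_cutoffs, pick, r_free_max


def make_baseline(**kw):
    base = dict(r_calc=0.200, r_free_calc=0.230, r_ratio=1.10,
                r_free_unb_calc=0.220, sigma_r_free_calc=0.004,
                rmsz_bond_calc=0.6, rmsz_angle_calc=0.7)
    base.update(kw)
    return BaselineMetrics(**base)


def candidate(label, r=0.19, r_free=0.225, rmszb=0.8, rmsza=0.9,
              ll=None, n_test=1000):
    return ModelStats(label=label, r=r, r_free=r_free, rmsz_bond=rmszb,
                      rmsz_angle=rmsza,
                      ll_free=ll if ll is not None else 1000 * r_free,
                      n_test_reflections=n_test)


class TestCutoffs:
    def test_geometry_defaults_to_one(self):
        cut = establish_cutoffs(make_baseline(rmsz_bond_calc=0.6))
        assert cut.rmsz_bond_co == 1.0

    def test_geometry_raised_to_calc_value(self):
        cut = establish_cutoffs(make_baseline(rmsz_angle_calc=1.8))
        assert cut.rmsz_angle_co == 1.8

    def test_biased_free_set_uses_unbiased_expectation(self):
        cut = establish_cutoffs(make_baseline(free_set_biased=True,
                                              r_free_unb_calc=0.23))
        assert cut.r_free_co == 0.23

    def test_tls_source(self):
        base = make_baseline(r_tls=0.25, r_free_tls=0.27)
        cut = establish_cutoffs(base, source="tls_opt")
        assert (cut.r_co, cut.r_free_co) == (0.25, 0.27)
        with pytest.raises(InvalidInputError):
            establish_cutoffs(make_baseline(), source="tls_opt")


class TestRFreeMax:
    def cutoffs(self, ratio=1.15):
        return Cutoffs(r_co=0.20, r_free_co=0.20 * ratio,
                       rmsz_bond_co=1.0, rmsz_angle_co=1.0)

    def test_three_stage_arithmetic(self):
        # 0.20 x 1.10 + 3.5 x 0.004 = 0.234; min(0.234, 0.26); max(., 0.230)
        assert r_free_max(0.20, 1.10, 0.004, self.cutoffs()) == pytest.approx(0.234)

    def test_cap_at_six_points(self):
        assert r_free_max(0.20, 2.0, 0.004, self.cutoffs()) == pytest.approx(0.26)

    def test_floor_for_high_initial_ratio(self):
        assert r_free_max(0.20, 1.10, 0.004,
                          self.cutoffs(ratio=1.40)) == pytest.approx(0.280)

    def test_unavailable_ratio_uses_cap_branch(self):
        assert r_free_max(0.20, None, None, self.cutoffs()) == pytest.approx(0.26)


def pick_oracle(candidates, cut, r_ratio, low_res=False):
    """Independent exhaustive filter + argmin implementation."""
    survivors = []
    for c in candidates:
        sigma = sigma_r_free(c.r_free, c.n_test_reflections) \
            if c.n_test_reflections > 0 and c.r_free > 0 else None
        if r_ratio is not None and sigma is not None:
            m = min(c.r * r_ratio + 3.5 * sigma, c.r + 0.06)
            z = (c.r * r_ratio - c.r_free) / sigma
        else:
            m = c.r + 0.06
            z = None
        m = max(m, cut.r_free_co / cut.r_co * c.r)
        bad = (c.rmsz_bond > cut.rmsz_bond_co or c.rmsz_angle > cut.rmsz_angle_co
               or c.r_free > m or c.r_free > cut.r_free_co)
        if low_res and (c.r_free - c.r) > 2.0 * (cut.r_free_co - cut.r_co):
            bad = True
        if not bad:
            survivors.append((c, z))
    if not survivors:
        return None
    best_ll = min(survivors, key=lambda t: t[0].ll_free)
    best_rf = min(survivors, key=lambda t: t[0].r_free)
    if best_ll[0].label == best_rf[0].label:
        return best_ll[0].label
    pair = [best_ll, best_rf]
    defined = [t for t in pair if t[1] is not None]
    if len(defined) == 1:
        return defined[0][0].label
    if len(defined) == 2 and pair[0][1] != pair[1][1]:
        return max(pair, key=lambda t: t[1])[0].label
    ordered = sorted(pair, key=lambda t: t[0].r_free)
    if ordered[0][0].r_free < ordered[1][0].r_free:
        return ordered[0][0].label
    return best_ll[0].label  # equal everywhere: first in input order wins


class TestPick:
    def cutoffs(self):
        return Cutoffs(r_co=0.20, r_free_co=0.23, rmsz_bond_co=1.0,
                       rmsz_angle_co=1.0)

    def test_geometry_violation_rejects_sole_candidate(self):
        sel = pick([candidate("a", rmszb=1.2)], self.cutoffs(), 1.10)
        assert sel.chosen is None
        assert sel.rejected[0][1] == ["rmsz_bond_above_cutoff"]

    def test_agreement_case(self):
        sel = pick([candidate("a", r_free=0.220), candidate("b", r_free=0.226)],
                   self.cutoffs(), 1.10)
        assert sel.chosen == "a"

    def test_split_minima_resolved_by_z(self):
        # 'a' has lowest R_free; 'b' has lowest LL_free
        a = candidate("a", r=0.196, r_free=0.220, ll=500.0)
        b = candidate("b", r=0.190, r_free=0.222, ll=400.0)
        sel = pick([a, b], self.cutoffs(), 1.10)
        assert sel.chosen == pick_oracle([a, b], self.cutoffs(), 1.10)

    def test_matches_oracle_on_randomized_sets(self):
        rng = np.random.default_rng(2024)
        cut = self.cutoffs()
        for _ in range(300):
            n = rng.integers(1, 8)
            cands = [
                candidate(
                    f"c{i}",
                    r=float(rng.uniform(0.15, 0.25)),
                    r_free=float(rng.uniform(0.16, 0.30)),
                    rmszb=float(rng.uniform(0.5, 1.3)),
                    rmsza=float(rng.uniform(0.5, 1.3)),
                    ll=float(rng.uniform(100, 999)),
                    n_test=int(rng.integers(0, 2000)),
                ) for i in range(n)
            ]
            sel = pick(cands, cut, 1.10)
            assert sel.chosen == pick_oracle(cands, cut, 1.10)

    def test_chosen_satisfies_every_limit(self):
        rng = np.random.default_rng(7)
        cut = self.cutoffs()
        for _ in range(200):
            cands = [candidate(f"c{i}", r=float(rng.uniform(0.15, 0.25)),
                               r_free=float(rng.uniform(0.16, 0.30)),
                               rmszb=float(rng.uniform(0.5, 1.3)))
                     for i in range(5)]
            sel = pick(cands, cut, 1.10)
            if sel.chosen is None:
                continue
            c = next(x for x in cands if x.label == sel.chosen)
            assert c.rmsz_bond <= cut.rmsz_bond_co
            assert c.r_free <= cut.r_free_co
            assert c.r_free <= sel.r_free_max_per_candidate[c.label]

    def test_tightening_cutoffs_never_grows_survivors(self):
        rng = np.random.default_rng(11)
        cands = [candidate(f"c{i}", r=float(rng.uniform(0.15, 0.25)),
                           r_free=float(rng.uniform(0.16, 0.30)),
                           rmszb=float(rng.uniform(0.5, 1.5)))
                 for i in range(7)]
        loose = Cutoffs(r_co=0.20, r_free_co=0.28, rmsz_bond_co=1.4,
                        rmsz_angle_co=1.4)
        tight = Cutoffs(r_co=0.20, r_free_co=0.24, rmsz_bond_co=1.0,
                        rmsz_angle_co=1.0)
        n_loose = 7 - len(pick(cands, loose, 1.10).rejected)
        n_tight = 7 - len(pick(cands, tight, 1.10).rejected)
        assert n_tight <= n_loose

    def test_low_resolution_gap_test(self):
        cat = assign_category(4.0, 5.0)  # vlow
        cut = Cutoffs(r_co=0.20, r_free_co=0.21, rmsz_bond_co=1.0,
                      rmsz_angle_co=1.0)
        wide = candidate("wide", r=0.18, r_free=0.21)  # gap 0.03 > 2 x 0.01
        sel = pick([wide], cut, 1.10, category=cat)
        assert sel.chosen is None
        assert "gap_above_low_resolution_limit" in sel.rejected[0][1]
        # same candidate passes without the category rule
        assert pick([wide], cut, 1.10).chosen == "wide"

    def test_order_invariance(self):
        cands = [candidate("a", r_free=0.221), candidate("b", r_free=0.222),
                 candidate("c", r_free=0.220)]
        labels = {pick(list(p), self.cutoffs(), 1.10).chosen
                  for p in ([cands[0], cands[1], cands[2]],
                            [cands[2], cands[1], cands[0]],
                            [cands[1], cands[2], cands[0]])}
        assert labels == {"c"}
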
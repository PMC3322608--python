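"""RPA routing, Hamilton-test grids and the bselect decision chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f as f_dist

from refinery.bfactor import (
    HamiltonInput,
    bselect,
    default_weight_grid,
    hamilton_acceptance_fraction,
    route_parameterization,
)
from refinery.metrics import ModelStats


def stats(label, r, r_free, r_free_w=None, n_test=1000):
    return ModelStats(label=label, r=r, r_free=r_free,
                      r_free_weighted=r_free_w if r_free_w is not None else r_free,
                      rmsz_bond=0.8, rmsz_angle=0.9, ll_free=1000 * r_free,
                      n_test_reflections=n_test)


class TestRouting:
    @pytest.mark.parametrize("rpa,route", [
        (18.1, "aniso"),
        (18.0, "contest_aniso_vs_iso"),
        (15.0, "contest_aniso_vs_iso"),
        (13.6, "contest_aniso_vs_iso"),
        (13.5, "iso"),
        (3.0, "iso"),
        (2.9, "contest_iso_vs_overall"),
        (0.0, "contest_iso_vs_overall"),
    ])
    def test_boundaries(self, rpa, route):
        assert route_parameterization(rpa).route == route

    def test_tls_unusable_falls_back_to_iso(self):
        assert route_parameterization(2.9, tls_usable=False).route == "iso_fallback"

    def test_parameter_counts(self):
        r = route_parameterization(15.0)
        assert (r.params_per_atom_simple, r.params_per_atom_complex) == (4, 9)
        r = route_parameterization(2.0)
        assert (r.params_per_atom_simple, r.params_per_atom_complex) == (3, 4)


def hamilton_oracle(inp: HamiltonInput) -> float:
    """Longhand per-grid-point reimplementation of the Hamilton sweep."""
    ok, total = 0, 0
    for w1 in inp.w1_grid:
        for w2 in inp.w2_grid:
            total += 1
            f = (inp.n_obs - inp.n_params_complex
                 + w1 * inp.n_restraints_base + w2 * inp.n_restraints_extra)
            if f <= 0:
                continue
            b = inp.n_params_complex - inp.n_params_simple \
                - w2 * inp.n_restraints_extra
            b = max(1.0, b)
            crit = math.sqrt(b / f * f_dist.ppf(1 - inp.alpha, b, f) + 1.0)
            if inp.r_free_w_simple / inp.r_free_w_complex > crit:
                ok += 1
    return ok / total


def hamilton_input(**kw):
    base = dict(r_free_w_simple=0.245, r_free_w_complex=0.240,
                n_obs=50_000, n_params_simple=4_000, n_params_complex=9_000,
                n_restraints_base=8_000, n_restraints_extra=5_000,
                w1_grid=default_weight_grid(), w2_grid=default_weight_grid())
    base.update(kw)
    return HamiltonInput(**base)


class TestHamilton:
    def test_equal_weighted_r_gives_zero(self):
        inp = hamilton_input(r_free_w_simple=0.24, r_free_w_complex=0.24)
        assert hamilton_acceptance_fraction(inp) == 0.0

    def test_dominant_ratio_gives_one(self):
        inp = hamilton_input(r_free_w_simple=2.4 / 2, r_free_w_complex=0.24 / 2)
        assert hamilton_acceptance_fraction(inp) == 1.0

    def test_toy_grid_matches_longhand_oracle(self):
        inp = hamilton_input(w1_grid=[0.0, 0.5, 1.0], w2_grid=[0.0, 0.5, 1.0])
        assert hamilton_acceptance_fraction(inp) == hamilton_oracle(inp)

    def test_fraction_in_unit_interval_and_monotone_in_ratio(self):
        fractions = [
            hamilton_acceptance_fraction(hamilton_input(r_free_w_simple=s))
            for s in (0.238, 0.241, 0.245, 0.25, 0.26)
        ]
        assert all(0.0 <= f <= 1.0 for f in fractions)
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_duplicated_grid_points_leave_fraction_unchanged(self):
        inp = hamilton_input()
        dup = hamilton_input(w1_grid=inp.w1_grid + inp.w1_grid,
                             w2_grid=inp.w2_grid)
        assert hamilton_acceptance_fraction(dup) == pytest.approx(
            hamilton_acceptance_fraction(inp))

    def test_underdetermined_points_count_as_rejections(self):
        inp = hamilton_input(n_obs=1_000_000, n_restraints_base=0,
                             n_restraints_extra=0,
                             r_free_w_simple=10.0, r_free_w_complex=0.1)
        # f > 0 at every grid point here; shrink n_obs below params:
        inp2 = hamilton_input(n_obs=2, n_restraints_base=0,
                              n_restraints_extra=0,
                              r_free_w_simple=10.0, r_free_w_complex=0.1)
        assert hamilton_acceptance_fraction(inp2) == 0.0
        assert hamilton_acceptance_fraction(inp) == 1.0


class TestBselect:
    def test_higher_weighted_complex_loses_outright(self):
        simple = stats("iso", 0.20, 0.23, r_free_w=0.230)
        complex_ = stats("aniso", 0.19, 0.231, r_free_w=0.231)
        # no Hamilton input supplied: step (i) must decide before step (ii)
        assert bselect(simple, complex_) == "simple"

    def test_band_edges(self):
        simple = stats("iso", 0.20, 0.23)
        complex_ = stats("aniso", 0.19, 0.228)
        assert bselect(simple, complex_, acceptance_fraction=0.96,
                       z_complex=-5.0) == "complex"
        assert bselect(simple, complex_, acceptance_fraction=0.29,
                       z_complex=5.0) == "simple"

    def test_low_z_in_inconclusive_band(self):
        simple = stats("iso", 0.20, 0.23)
        complex_ = stats("aniso", 0.19, 0.228)
        assert bselect(simple, complex_, acceptance_fraction=0.5,
                       z_complex=-3.1) == "simple"
        assert bselect(simple, complex_, acceptance_fraction=0.5,
                       z_complex=-2.9) == "complex"

    @pytest.mark.parametrize("kind,gap,expected", [
        ("aniso", 0.041, "simple"),
        ("aniso", 0.040, "complex"),   # boundary: proceeds to 2.0x test
        ("iso", 0.061, "simple"),
        ("iso", 0.060, "complex"),
    ])
    def test_gap_cutoff_when_z_unavailable(self, kind, gap, expected):
        simple = stats("s", 0.20, 0.25)   # simple gap 0.05: 2x test passes
        # r = 0 keeps the complex gap exactly representable at the boundary
        complex_ = stats("c", 0.0, gap, r_free_w=0.249)
        assert bselect(simple, complex_, acceptance_fraction=0.5,
                       z_complex=None, complex_kind=kind) == expected

    def test_double_gap_ratio_test(self):
        simple = stats("s", 0.22, 0.235)  # gap 0.015
        complex_ = stats("c", 0.20, 0.231)  # gap 0.031 > 2 x 0.015
        assert bselect(simple, complex_, acceptance_fraction=0.5,
                       z_complex=0.0) == "simple"
        complex_ok = stats("c", 0.202, 0.231, r_free_w=0.231)  # gap 0.029
        assert bselect(simple, complex_ok, acceptance_fraction=0.5,
                       z_complex=0.0) == "complex"

    @given(st.floats(0.1, 0.4), st.floats(0.1, 0.4), st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_step_one_never_returns_complex(self, rw_s, rw_c, frac):
        if rw_c <= rw_s:
            rw_c = rw_s + 0.001
        simple = stats("s", 0.2, 0.22, r_free_w=rw_s)
        complex_ = stats("c", 0.19, 0.21, r_free_w=rw_c)
        assert bselect(simple, complex_, acceptance_fraction=frac,
                       z_complex=5.0) == "simple"
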
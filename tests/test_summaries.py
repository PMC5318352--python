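"""P-box construction, interval summaries, and fractile membership functions."""

import itertools

import numpy as np
import pytest

from hybriduq import (
    CutInterval,
    GeneralizedFuzzyNumber,
    MembershipPass,
    ModelSpec,
    fractile_mf,
    interval_variance_bounds,
    pbox,
    pbox_mean,
    pbox_range,
    pbox_variance,
    propagate,
)

TRI = GeneralizedFuzzyNumber.triangular


def max_var_enumerate(lo, hi, ddof=0):
    """Exhaustive endpoint-selection variance extrema (oracle, n <= 12)."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    n = lo.size
    best_max, best_min = -np.inf, np.inf
    for mask in itertools.product((0, 1), repeat=n):
        x = np.where(mask, hi, lo)
        v = np.sum((x - x.mean()) ** 2) / (n - ddof)
        best_max = max(best_max, v)
        best_min = min(best_min, v)
    return best_min, best_max


@pytest.fixture(scope="module")
def const_family():
    m = ModelSpec(name="const", evaluator=lambda a: a["c"], constants={"c": 2.5})
    with pytest.warns(UserWarning):
        return propagate(m, n_mc=50, seed=3)


class TestPBox:
    def test_bounds_are_alpha_zero_curves(self, small_family):
        pb = pbox(small_family, MembershipPass.UMF)
        member = small_family.member(MembershipPass.UMF, 0.0)
        assert np.array_equal(pb.minima, member.minima)
        assert np.array_equal(pb.maxima, member.maxima)

    def test_left_bound_dominates_right_pointwise(self, small_family):
        pb = pbox(small_family, MembershipPass.LMF)
        xs = np.linspace(pb.minima.min(), pb.maxima.max(), 200)
        assert np.all(pb.ecdf_min(xs) >= pb.ecdf_max(xs))

    def test_alpha_zero_envelopes_higher_levels(self, small_family):
        pb = pbox(small_family, MembershipPass.UMF)
        top = small_family.member(MembershipPass.UMF, small_family.grid.w)
        xs = np.linspace(pb.minima.min(), pb.maxima.max(), 200)
        assert np.all(pb.ecdf_min(xs) >= top.ecdf_min(xs) - 1e-12)
        assert np.all(pb.ecdf_max(xs) <= top.ecdf_max(xs) + 1e-12)

    def test_constant_model_pbox_is_single_step(self, const_family):
        pb = pbox(const_family, MembershipPass.UMF)
        assert pbox_range(pb).width == 0.0
        assert pbox_mean(pb) == CutInterval(2.5, 2.5)
        assert pbox_variance(pb) == CutInterval(0.0, 0.0)


class TestPBoxRange:
    def test_widens_towards_sample_extremes(self, small_family):
        pb = pbox(small_family, MembershipPass.UMF)
        narrow = pbox_range(pb, 0.05, 0.95)
        wide = pbox_range(pb, 0.005, 0.995)
        assert wide.contains(narrow)
        support = CutInterval(pb.minima.min(), pb.maxima.max())
        assert support.contains(wide)

    def test_invalid_percentiles_rejected(self, small_family):
        pb = pbox(small_family, MembershipPass.UMF)
        for bad in ((0.9, 0.1), (0.0, 0.5), (0.5, 1.0)):
            with pytest.raises(ValueError):
                pbox_range(pb, *bad)

    def test_analytic_mode_matches_empirical_at_large_n(self, arsenic_family):
        pb = pbox(arsenic_family, MembershipPass.UMF)
        emp = pbox_range(pb, mode="empirical")
        ana = pbox_range(pb, mode="analytic")
        assert emp.lo == pytest.approx(ana.lo, rel=0.05)
        assert emp.hi == pytest.approx(ana.hi, rel=0.05)

    def test_analytic_mode_needs_single_probabilistic_parameter(self):
        from hybriduq import DistributionSpec

        m = ModelSpec(
            name="two",
            evaluator=lambda a: a["x"] + a["y"] + a["g"],
            probabilistic={
                "x": DistributionSpec.normal(0, 1),
                "y": DistributionSpec.normal(0, 1),
            },
            fuzzy={"g": TRI(0, 1, 2)},
        )
        fam = propagate(m, n_mc=100, seed=1)
        with pytest.raises(ValueError, match="analytic quantile mode"):
            pbox_range(pbox(fam, MembershipPass.UMF), mode="analytic")


class TestPBoxMean:
    def test_interval_endpoint_averages(self, small_family):
        pb = pbox(small_family, MembershipPass.UMF)
        mean = pbox_mean(pb)
        assert mean.lo == pytest.approx(pb.minima.mean())
        assert mean.hi == pytest.approx(pb.maxima.mean())
        assert mean.lo <= mean.hi

    def test_hand_built_intervals(self):
        m = ModelSpec(name="id", evaluator=lambda a: a["x"], fuzzy={"x": TRI(0, 0.5, 1)})
        # {[0,1]} from the single alpha=0 cut
        fam = propagate(m, n_mc=1, seed=0)
        mean = pbox_mean(pbox(fam, MembershipPass.UMF))
        assert (mean.lo, mean.hi) == (0.0, 1.0)


class TestIntervalVariance:
    def test_two_unit_intervals(self):
        lo_v, hi_v = interval_variance_bounds([0, 0], [1, 1])
        assert lo_v == 0.0
        assert hi_v == pytest.approx(0.25)  # 1/n convention, endpoints {0,1}

    def test_degenerate_intervals_give_point_variance(self):
        lo_v, hi_v = interval_variance_bounds([0, 1], [0, 1])
        assert lo_v == pytest.approx(0.25)
        assert hi_v == pytest.approx(0.25)

    def test_disjoint_intervals_force_positive_lower_bound(self):
        lo_v, hi_v = interval_variance_bounds([0, 5], [1, 6])
        oracle_min, oracle_max = max_var_enumerate([0, 5], [1, 6])
        assert lo_v > 0
        assert hi_v == pytest.approx(oracle_max)
        # min is attained at the nearest endpoints (1, 5), an endpoint selection here
        assert lo_v == pytest.approx(oracle_min)

    def test_interior_minimum_below_endpoint_selections(self):
        # [0,2] and [1,3] overlap: common point ⇒ exact zero, while every
        # endpoint-only selection has positive variance.
        lo_v, _ = interval_variance_bounds([0, 1], [2, 3])
        oracle_min, _ = max_var_enumerate([0, 1], [2, 3])
        assert lo_v == 0.0
        assert oracle_min > 0

    @pytest.mark.parametrize("n", [3, 6, 9, 12])
    def test_upper_bound_matches_enumeration(self, n, rng):
        for _ in range(20):
            lo = rng.uniform(-5, 5, n)
            hi = lo + rng.uniform(0, 4, n)
            _, oracle_max = max_var_enumerate(lo, hi)
            lo_v, hi_v = interval_variance_bounds(lo, hi)
            assert hi_v == pytest.approx(oracle_max, rel=1e-10)
            assert lo_v <= oracle_max + 1e-12

    @pytest.mark.parametrize("n", [3, 6, 9])
    def test_lower_bound_zero_iff_common_point(self, n, rng):
        for _ in range(20):
            lo = rng.uniform(-5, 5, n)
            hi = lo + rng.uniform(0, 4, n)
            lo_v, _ = interval_variance_bounds(lo, hi)
            if np.max(lo) <= np.min(hi):
                assert lo_v == 0.0
            else:
                assert lo_v > 0
                # never above the best endpoint selection
                oracle_min, _ = max_var_enumerate(lo, hi)
                assert lo_v <= oracle_min + 1e-12

    def test_ddof_rescales_bounds(self, rng):
        lo = rng.uniform(0, 1, 8)
        hi = lo + rng.uniform(0, 1, 8)
        pop = interval_variance_bounds(lo, hi, ddof=0)
        samp = interval_variance_bounds(lo, hi, ddof=1)
        assert samp[1] == pytest.approx(pop[1] * 8 / 7)

    def test_case_study_variance_lower_bound_zero(self, arsenic_family):
        # All per-draw [min,max] risk intervals overlap, so the sharp
        # variance lower bound is exactly 0 for both passes.
        for pass_ in MembershipPass:
            var = pbox_variance(pbox(arsenic_family, pass_))
            assert var.lo == 0.0
            assert 0 < var.hi < 1e-12  # hazard-quotient scale ~1e-7 squared


class TestFractileMF:
    def test_case_study_trapezoid_height(self, arsenic_family):
        mf = fractile_mf(arsenic_family, 0.95)
        assert mf.height == pytest.approx(0.8)
        assert mf.umf.w == mf.lmf.w == pytest.approx(0.8)

    def test_lmf_nested_in_umf(self, arsenic_family):
        mf = fractile_mf(arsenic_family, 0.95)
        assert mf.umf.a <= mf.lmf.a <= mf.lmf.d <= mf.umf.d
        assert mf.umf.support.contains(mf.lmf.support)

    def test_alpha_intervals_nest(self, arsenic_family):
        mf = fractile_mf(arsenic_family, 0.9)
        for rows in mf.alpha_table.values():
            for (a0, lo0, hi0), (a1, lo1, hi1) in zip(rows, rows[1:]):
                assert a0 < a1
                assert lo0 <= lo1 + 1e-18 and hi1 <= hi0 + 1e-18

    def test_monotone_in_fractile(self, arsenic_family):
        """Every knot at p=0.95 sits at or above the matching knot at p=0.85."""
        hi = fractile_mf(arsenic_family, 0.95)
        lo = fractile_mf(arsenic_family, 0.85)
        for mf_hi, mf_lo in ((hi.umf, lo.umf), (hi.lmf, lo.lmf)):
            for knot in "abcd":
                assert getattr(mf_hi, knot) >= getattr(mf_lo, knot)

    def test_intermediate_alpha_vs_trapezoid_interpolation(self, arsenic_family):
        """The reported trapezoid interpolates support↔core linearly, but the
        true quantile-interval endpoints are quadratic in α (product of two
        fuzzy parameters) and convex, so the linear cut endpoints sit at or
        above the true ones (chord above a convex curve), coincide at α=0 and
        α=w, and deviate by at most ~1.5% for this model."""
        mf = fractile_mf(arsenic_family, 0.95, mode="analytic")
        for pass_name, trap in (("UMF", mf.umf), ("LMF", mf.lmf)):
            rows = {round(a, 6): (lo, hi) for a, lo, hi in mf.alpha_table[pass_name]}
            for alpha, (lo, hi) in rows.items():
                cut = trap.alpha_cut(alpha)
                assert cut.lo >= lo * (1 - 1e-12)
                assert cut.hi >= hi * (1 - 1e-12)
                assert cut.lo == pytest.approx(lo, rel=0.02)
                assert cut.hi == pytest.approx(hi, rel=0.02)
            for alpha in (0.0, 0.8):
                lo, hi = rows[alpha]
                cut = trap.alpha_cut(alpha)
                assert cut.lo == pytest.approx(lo, rel=1e-12)
                assert cut.hi == pytest.approx(hi, rel=1e-12)

    def test_constant_model_yields_crisp_number(self, const_family):
        mf = fractile_mf(const_family, 0.95)
        for g in (mf.umf, mf.lmf):
            assert (g.a, g.b, g.c, g.d) == (2.5, 2.5, 2.5, 2.5)

    def test_fractile_bounds_enforced(self, small_family):
        for p in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                fractile_mf(small_family, p)

    def test_export_dict_shape(self, small_family):
        d = fractile_mf(small_family, 0.9).to_dict()
        assert set(d) == {"p", "height", "umf_knots", "lmf_knots", "alpha_table"}
        assert len(d["umf_knots"]) == 4
        assert len(d["alpha_table"]["UMF"]) == 11
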
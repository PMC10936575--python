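import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pyrofar as pf
from pyrofar.errors import LevelNotAttainedError

from conftest import lognormal_ensemble

probs = st.floats(min_value=1e-6, max_value=1.0)


class TestPointwiseMetrics:
    @given(probs)
    @settings(derandomize=True)
    def test_far_zero_and_rr_one_when_probabilities_equal(self, p):
        assert pf.far(p, p) == pytest.approx(0.0, abs=1e-12)
        assert pf.rr(p, p) == pytest.approx(1.0)

    @given(st.floats(min_value=1e-6, max_value=0.5))
    @settings(derandomize=True)
    def test_far_half_means_doubled_probability(self, p):
        assert pf.far(p, 2 * p) == pytest.approx(0.5)

    def test_far_and_rr_published_examples(self):
        assert pf.far(0.05, 0.10) == pytest.approx(0.5)
        assert pf.rr(0.10, 1.00) == pytest.approx(10.0)

    @given(probs, probs)
    @settings(derandomize=True)
    def test_far_rr_duality(self, p0, p1):
        f, r = pf.far(p0, p1), pf.rr(p0, p1)
        if np.isfinite(f) and np.isfinite(r) and r > 0:
            assert f == pytest.approx(1.0 - 1.0 / r, rel=1e-12, abs=1e-12)

    def test_zero_denominator_edges_are_flagged(self):
        assert np.isnan(pf.far(0.2, 0.0))          # p1 = 0: undefined
        assert pf.rr(0.0, 0.5) == np.inf           # p0 = 0 < p1: infinite
        assert np.isnan(pf.rr(0.0, 0.0))           # both zero: undefined
        assert np.isnan(pf.far(0.0, 0.0))

    def test_vectorized_with_masked_points(self):
        p0 = np.array([0.1, 0.0, 0.0])
        p1 = np.array([0.2, 0.4, 0.0])
        np.testing.assert_allclose(pf.far(p0, p1)[:2], [0.5, 1.0])
        assert np.isnan(pf.far(p0, p1)[2])
        r = pf.rr(p0, p1)
        assert r[0] == pytest.approx(2.0)
        assert r[1] == np.inf and np.isnan(r[2])


class TestAttributionCurves:
    def test_las_conchas_far_at_event_threshold(self, lc_curve):
        # RR ~ 10 at 86,000 ha implies FAR = 1 - 1/RR ~ 0.9
        assert lc_curve.far_at(86_000) == pytest.approx(0.90, abs=0.05)

    def test_rr_at_least_one_everywhere_valid(self, lc_curve):
        r = lc_curve.rr[lc_curve.valid_mask & np.isfinite(lc_curve.rr)]
        assert (r >= 1.0 - 1e-9).all()

    def test_identical_data_gives_null_attribution(self, las_conchas):
        a = las_conchas.p0_ensemble
        b = pf.FireSizeEnsemble("copy", a.sizes.copy())
        curve = pf.attribution_curves(pf.ScenarioPair(a, b, "identity"))
        v = curve.valid_mask
        np.testing.assert_allclose(curve.far[v], 0.0, atol=1e-9)
        finite = v & np.isfinite(curve.rr)
        np.testing.assert_allclose(curve.rr[finite], 1.0, atol=1e-9)

    def test_duality_holds_pointwise_on_curve(self, lc_curve):
        m = (lc_curve.valid_mask & np.isfinite(lc_curve.far)
             & np.isfinite(lc_curve.rr) & (lc_curve.rr > 0))
        np.testing.assert_allclose(
            lc_curve.far[m], 1.0 - 1.0 / lc_curve.rr[m], atol=1e-12)

    def test_dominance_implies_nonnegative_far(self, lc_curve):
        assert (lc_curve.p1 >= lc_curve.p0 - 1e-12).all()
        f = lc_curve.far[lc_curve.valid_mask]
        assert (f[np.isfinite(f)] >= -1e-9).all()

    def test_empirical_estimator_matches_hand_counting(self):
        """Brute-force oracle: attribution from the empirical estimator
        reproduces exact rational p0/p1/FAR/RR at every grid size."""
        rng = np.random.default_rng(5)
        e0 = pf.FireSizeEnsemble("s0", rng.uniform(10, 100, 7))
        e1 = pf.FireSizeEnsemble("s1", rng.uniform(10, 150, 9))
        curve = pf.attribution_curves(
            pf.ScenarioPair(e0, e1, "test"),
            pf.CurveSettings(estimator="empirical", n_points=301),
        )
        for s, p0, p1, f, r in zip(curve.grid, curve.p0, curve.p1,
                                   curve.far, curve.rr):
            c0 = sum(1 for x in e0.sizes if x > s) / 7
            c1 = sum(1 for x in e1.sizes if x > s) / 9
            assert p0 == pytest.approx(c0, abs=1e-15)
            assert p1 == pytest.approx(c1, abs=1e-15)
            if c1 > 0:
                assert f == pytest.approx(1 - c0 / c1, abs=1e-12)
            else:
                assert np.isnan(f)
            if c0 > 0:
                assert r == pytest.approx(c1 / c0, abs=1e-12)

    def test_kde_rr_recovers_analytic_lognormal_shift(self):
        """Known-truth recovery: two lognormals with a scale shift.

        At the reference median m0 = exp(mu), p0 = 0.5 and
        p1 = Phi(delta/sigma), so RR = 2 * Phi(delta/sigma).
        """
        mu, sigma, delta, n = 9.0, 0.5, 0.4, 10_000
        e0 = lognormal_ensemble("ref", n, mu, sigma, seed=21)
        e1 = lognormal_ensemble("shift", n, mu + delta, sigma, seed=22)
        curve = pf.attribution_curves(pf.ScenarioPair(e0, e1, "ln"))
        rr_true = 2.0 * stats.norm.cdf(delta / sigma)
        assert curve.rr_at(np.exp(mu)) == pytest.approx(rr_true, rel=0.10)


class TestFarCrossing:
    def test_las_conchas_far_crosses_half_near_actual_median(self, lc_curve):
        assert pf.far_crossing(lc_curve, 0.5) == pytest.approx(
            81_450, rel=0.03)

    def test_identity_pair_never_attains(self, las_conchas):
        a = las_conchas.p0_ensemble
        b = pf.FireSizeEnsemble("copy", a.sizes.copy())
        curve = pf.attribution_curves(pf.ScenarioPair(a, b, "identity"))
        with pytest.raises(LevelNotAttainedError, match="attained range"):
            pf.far_crossing(curve, 0.5)

    def test_exact_grid_point_level(self, lc_curve):
        f = lc_curve.far
        i = int(np.argmax(np.isfinite(f) & (f > 0.2) & (f < 0.8)))
        got = pf.far_crossing(lc_curve, float(f[i]))
        assert got <= lc_curve.grid[i] + 1e-9
        if got == pytest.approx(lc_curve.grid[i]):
            assert lc_curve.far_at(got) == pytest.approx(float(f[i]),
                                                         abs=1e-9)


class TestBootstrap:
    def test_same_seed_identical_bands(self, las_conchas):
        b1 = pf.bootstrap_bands(las_conchas, replicates=120, seed=42)
        b2 = pf.bootstrap_bands(las_conchas, replicates=120, seed=42)
        np.testing.assert_array_equal(b1.far_lo, b2.far_lo)
        np.testing.assert_array_equal(b1.far_hi, b2.far_hi)
        np.testing.assert_array_equal(b1.rr_lo, b2.rr_lo)
        np.testing.assert_array_equal(b1.rr_hi, b2.rr_hi)

    def test_point_estimate_mostly_inside_own_band(self, las_conchas,
                                                   lc_curve):
        b = pf.bootstrap_bands(las_conchas, replicates=400, seed=9)
        ok = b.available & np.isfinite(lc_curve.far)
        inside = ((lc_curve.far[ok] >= b.far_lo[ok] - 1e-12)
                  & (lc_curve.far[ok] <= b.far_hi[ok] + 1e-12))
        assert inside.mean() >= 0.95

    def test_band_width_shrinks_with_sample_size(self):
        # widths compared at the same thresholds (central quantiles of
        # the generating distribution), not over each grid separately
        from scipy import stats

        thresholds = np.exp(9.0 + 0.5 * stats.norm.ppf(
            np.linspace(0.1, 0.9, 9)))

        def median_width(n, seeds):
            e0 = lognormal_ensemble("a", n, 9.0, 0.5, seeds[0])
            e1 = lognormal_ensemble("b", n, 9.3, 0.5, seeds[1])
            b = pf.bootstrap_bands(
                pf.ScenarioPair(e0, e1, "syn"),
                pf.CurveSettings(n_points=128),
                replicates=150, seed=3)
            width = np.interp(thresholds, b.grid, b.far_hi - b.far_lo)
            return np.median(width)

        assert median_width(1000, (1, 2)) < median_width(10, (1, 2))

    def test_too_few_replicates_rejected(self, las_conchas):
        with pytest.raises(ValueError, match="replicates"):
            pf.bootstrap_bands(las_conchas, replicates=50, seed=1)


class TestBuildReport:
    def test_fixture_report_headline_numbers(self, las_conchas):
        rep = pf.build_report(las_conchas, thresholds=[86_000],
                              percentiles=(0.5, 0.9), far_levels=(0.5,))
        assert rep.event_threshold == 86_000
        assert rep.rr_at_threshold == pytest.approx(10, abs=2)
        assert rep.far_at_threshold == pytest.approx(
            1 - 1 / rep.rr_at_threshold, abs=1e-9)
        # counterfactual median fire size
        assert rep.percentile_events[0.5]["p1_size_ha"] == pytest.approx(
            104_200, rel=0.03)
        assert rep.far_crossings[0.5] == pytest.approx(81_450, rel=0.03)

    def test_report_regeneration_is_identity(self, las_conchas, tmp_path):
        kw = dict(thresholds=[86_000], percentiles=(0.5,),
                  far_levels=(0.5,), bootstrap_replicates=120, seed=17)
        pf.write_report(pf.build_report(las_conchas, **kw), tmp_path / "a")
        pf.write_report(pf.build_report(las_conchas, **kw), tmp_path / "b")
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()

    def test_default_threshold_is_p0_90th_percentile(self, las_conchas):
        rep = pf.build_report(las_conchas)
        assert rep.event_threshold == pytest.approx(86_000, rel=0.03)
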
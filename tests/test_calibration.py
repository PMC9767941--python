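import numpy as np
import pytest
from scipy import stats

from cgwas.calibration import (
    CgwasConfig,
    CoefCurve,
    apply_calibration,
    cgwas_pipeline,
    derive_studywide_threshold,
    estimate_n_independent,
    fit_quantile_coefficients,
    mingwas,
    simulate_null_panel,
    tippett_adjust,
)
from cgwas.simulator import ScenarioSpec, simulate_summary_scenario
from cgwas.summary_io import chi2_sf1

from conftest import exchangeable


class TestNullPanel:
    def test_moments(self):
        T = simulate_null_panel(exchangeable(0.5, 3), 100_000, 0)
        np.testing.assert_allclose(T.mean(0), 0.0, atol=0.02)
        np.testing.assert_allclose(T.std(0), 1.0, atol=0.02)

    def test_correlation_matches_psi(self):
        Psi = exchangeable(0.3, 4)
        T = simulate_null_panel(Psi, 100_000, 1)
        np.testing.assert_allclose(np.corrcoef(T.T), Psi, atol=3 / np.sqrt(100_000) * 3)

    def test_seed_determinism(self):
        a = simulate_null_panel(np.eye(2), 10_000, 7)
        b = simulate_null_panel(np.eye(2), 10_000, 7)
        np.testing.assert_array_equal(a, b)

    def test_small_ns_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_panel(np.eye(2), 500, 0)


class TestTippett:
    def test_identity_at_one(self):
        assert tippett_adjust(0.5, 1.0) == pytest.approx(0.5)

    def test_closed_form(self):
        assert tippett_adjust(0.01, 10.0) == pytest.approx(1 - 0.99**10)
        assert tippett_adjust(0.01, 10.0) == pytest.approx(0.095618, abs=1e-6)

    def test_edge_values(self):
        assert tippett_adjust(0.0, 5.0) == 0.0
        assert tippett_adjust(1.0, 5.0) == 1.0

    def test_small_p_linear_regime(self):
        # for tiny p the transform is Neff * p to first order
        assert tippett_adjust(1e-12, 20.0) == pytest.approx(2e-11, rel=1e-6)


class TestNIndependent:
    def test_uniform_gives_one(self, rng):
        assert estimate_n_independent(rng.uniform(size=200_000)) == pytest.approx(1.0, abs=0.05)

    def test_min_of_k_independent(self, rng):
        k = 5
        col = rng.uniform(size=(200_000, k)).min(axis=1)
        assert estimate_n_independent(col) == pytest.approx(k, rel=0.05)

    def test_perfect_dependence_gives_one(self, rng):
        u = rng.uniform(size=200_000)
        col = np.minimum(u, u)  # min of identical copies
        assert estimate_n_independent(col) == pytest.approx(1.0, abs=0.05)

    def test_too_few_entries(self, rng):
        with pytest.raises(ValueError):
            estimate_n_independent(rng.uniform(size=100))


class TestCoefCurve:
    def test_uniform_null_identity(self, rng):
        curve = fit_quantile_coefficients(rng.uniform(size=500_000))
        # empirical-quantile noise is ~1/sqrt(NS * u), so the tolerance widens
        # toward the tail
        np.testing.assert_allclose(curve.predict(np.geomspace(1e-2, 1, 30)), 1.0, rtol=0.05)
        np.testing.assert_allclose(curve.predict(np.geomspace(1e-4, 1e-2, 10)), 1.0, rtol=0.35)

    def test_squared_uniform_recalibrated(self, rng):
        null = rng.uniform(size=500_000) ** 2  # quantile u^2, so c(u) ~ 1/u
        curve = fit_quantile_coefficients(null)
        fresh = rng.uniform(size=50_000) ** 2
        cal = apply_calibration(fresh, curve)
        assert stats.kstest(cal, "uniform").pvalue > 0.01

    def test_min_of_two_uniforms_recalibrated(self, rng):
        null = rng.uniform(size=(500_000, 2)).min(axis=1)
        curve = fit_quantile_coefficients(null)
        fresh = rng.uniform(size=(50_000, 2)).min(axis=1)
        cal = apply_calibration(fresh, curve)
        assert stats.kstest(cal, "uniform").pvalue > 0.01

    def test_identity_curve_preserves_values(self, rng):
        curve = CoefCurve(log_u=np.log([1e-8, 1.0]), log_c=np.zeros(2))
        p = rng.uniform(size=1000)
        np.testing.assert_allclose(apply_calibration(p, curve), p, rtol=1e-12)

    def test_order_preserved(self, rng):
        null = rng.uniform(size=200_000) ** 1.5
        curve = fit_quantile_coefficients(null)
        p = rng.uniform(size=5000) ** 1.5
        cal = apply_calibration(p, curve)
        order = np.argsort(p)
        assert np.all(np.diff(cal[order]) >= 0)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            fit_quantile_coefficients(np.full(20_000, 0.3))


class TestMingwas:
    def test_single_gwas_identity(self, rng):
        p = rng.uniform(size=20_000)
        out = mingwas(p[:, None], np.eye(1), NS=200_000, seed=0)
        np.testing.assert_allclose(out, p, rtol=0.1, atol=0.01)

    def test_independent_matches_tippett(self, rng):
        K = 4
        P = rng.uniform(size=(30_000, K))
        out = mingwas(P, np.eye(K), NS=500_000, seed=1)
        expected = tippett_adjust(P.min(axis=1), K)
        # same correction in distribution: compare sorted values
        np.testing.assert_allclose(np.sort(out)[100:-100], np.sort(expected)[100:-100],
                                   rtol=0.05, atol=5e-4)

    def test_correlated_correction_below_k_fold(self, rng):
        K = 5
        Psi = exchangeable(0.5, K)
        T = simulate_null_panel(Psi, 30_000, rng)
        P = chi2_sf1(T**2)
        out = mingwas(P, Psi, NS=500_000, seed=2)
        ratio = np.median(out / np.maximum(tippett_adjust(P.min(axis=1), K), 1e-30))
        assert ratio < 1.0  # effective correction strictly below K independent tests
        assert stats.kstest(out, "uniform").pvalue > 0.01


class TestThreshold:
    def test_worked_values(self):
        assert derive_studywide_threshold(5e-8, 27.13, 2.22) == pytest.approx(3e-6, rel=0.01)
        assert derive_studywide_threshold(5e-8, 12.44, 2.17) == pytest.approx(1.35e-6, rel=0.01)

    def test_unit_burdens(self):
        assert derive_studywide_threshold(5e-8, 1.0, 1.0) == 5e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            derive_studywide_threshold(-1e-8, 1.0, 1.0)


class TestPipelineSmall:
    def test_single_gwas_passthrough(self):
        spec = ScenarioSpec(M=20_000, K=1, p_effect=0.0, seed=3)
        panel = simulate_summary_scenario(spec)
        res = cgwas_pipeline(panel, CgwasConfig(NS=100_000, seed=1, adjust_inflation=False))
        # nothing to combine: final p tracks the input p closely
        r = np.corrcoef(np.log(res.p), np.log(panel.p_matrix()[:, 0]))[0, 1]
        assert r > 0.999
        assert stats.kstest(res.p, "uniform").pvalue > 0.01

    def test_determinism(self):
        spec = ScenarioSpec(M=15_000, K=3, Psi=0.4, p_effect=0.0, seed=5)
        panel = simulate_summary_scenario(spec)
        cfg = CgwasConfig(NS=50_000, seed=9)
        a = cgwas_pipeline(panel, cfg)
        b = cgwas_pipeline(panel, cfg)
        np.testing.assert_array_equal(a.p, b.p)
        assert a.report == b.report

    def test_report_names_failing_stage(self):
        spec = ScenarioSpec(M=15_000, K=2, p_effect=0.0, seed=6)
        panel = simulate_summary_scenario(spec)
        bad = CgwasConfig(NS=50_000, known_psi=np.ones((2, 2)))  # singular Psi
        with pytest.raises(RuntimeError, match="stage"):
            cgwas_pipeline(panel, bad)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CgwasConfig(NS=100)
        with pytest.raises(ValueError):
            CgwasConfig(e_choice="bogus")
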
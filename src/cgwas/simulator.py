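"""Summary-statistic and cohort-level simulators plus a power/alpha harness.

The summary-level generator draws, per variant, a null K-vector from
N(0, Psi), optionally adds per-GWAS inflation noise N(0, I_k), and gives
the first floor(p*M) variants a true-effect draw from N(0, Pi o theta
theta') — so GWAS k has expected mean chi-squared 1 + p*theta_k^2 (+ I_k).
Variants are unlinked by construction, matching the summary-level theory
the estimators rely on.

The cohort-level generator builds synthetic unlinked genotypes and a
polygenic phenotype, runs per-cohort linear-regression GWASs for three
(possibly overlapping) sub-samples plus the union sample, and is the test
bed for the background-correlation theory psi = Nc/sqrt(N1*N2) * rho.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    apply_calibration,
    calibrate_scan,
    cgwas_pipeline,
    CgwasConfig,
    fit_quantile_coefficients,
    fit_twt_calibration,
    simulate_null_panel,
)
from .estimators import _sign_keep_zero_positive
from .summary_io import GwasPanel, GwasTable, chi2_sf1, table_from_arrays
from .twt import TwtConfig, twt_genome, wald_genome

logger = logging.getLogger("cgwas")


def _as_corr(x, K: int) -> np.ndarray:
    """Exchangeable correlation matrix from a scalar, or a validated matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        mat = np.full((K, K), float(x))
        np.fill_diagonal(mat, 1.0)
        return mat
    if x.shape != (K, K):
        raise ValueError(f"correlation matrix must be {K}x{K}")
    if np.abs(x).max() > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    return x


def _psd_sqrt(cov: np.ndarray, what: str) -> np.ndarray:
    """Symmetric square root with negative eigenvalues clipped (repair logged)."""
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() < -1e-8:
        logger.warning("%s not PSD (min eigenvalue %.3g); repaired to nearest PSD", what, vals.min())
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


@dataclass
class ScenarioSpec:
    """Configuration of one summary-statistics simulation cell."""

    M: int = 50_000
    K: int = 2
    Psi: float | np.ndarray = 0.0
    Pi: float | np.ndarray = 0.0
    p_effect: float = 0.0
    theta: float | np.ndarray = 0.0
    inflate: float | np.ndarray = 0.0
    replicates: int = 100
    alpha: float | None = None
    seed: int = 0
    n_nominal: int = 10_000

    @classmethod
    def from_mean_chi2(cls, e_chi2, p_effect: float, **kwargs) -> "ScenarioSpec":
        """Build a spec from target per-GWAS mean chi-squared values.

        Inverts E(chi2) = 1 + p * theta_k^2, so theta_k = sqrt((E_k - 1)/p).
        """
        e = np.asarray(e_chi2, dtype=float)
        if p_effect <= 0:
            raise ValueError("p_effect must be positive to place true effects")
        theta = np.sqrt(np.maximum(e - 1.0, 0.0) / p_effect)
        return cls(K=len(e), p_effect=p_effect, theta=theta, **kwargs)

    def theta_vector(self) -> np.ndarray:
        th = np.asarray(self.theta, dtype=float)
        return np.full(self.K, float(th)) if th.ndim == 0 else th

    def inflate_vector(self) -> np.ndarray:
        i = np.asarray(self.inflate, dtype=float)
        return np.full(self.K, float(i)) if i.ndim == 0 else i


def expected_mean_chi2(p_effect: float, theta_k: float) -> float:
    """Expected mean chi-squared of a simulated GWAS: 1 + p * theta^2."""
    if not 0 <= p_effect <= 1:
        raise ValueError("p_effect must lie in [0, 1]")
    return 1.0 + p_effect * float(theta_k) ** 2


def _simulate_t(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Raw M x K T-statistic matrix of one replicate (causal variants first)."""
    Psi = _as_corr(spec.Psi, spec.K)
    T = rng.standard_normal((spec.M, spec.K)) @ _psd_sqrt(Psi, "Psi").T
    infl = spec.inflate_vector()
    for k in np.flatnonzero(infl > 0):
        T[:, k] += rng.normal(0.0, np.sqrt(infl[k]), spec.M)
    n_causal = int(np.floor(spec.p_effect * spec.M))
    if n_causal:
        theta = spec.theta_vector()
        cov = _as_corr(spec.Pi, spec.K) * np.outer(theta, theta)
        T[:n_causal] += rng.standard_normal((n_causal, spec.K)) @ _psd_sqrt(cov, "Pi o theta theta'").T
    return T


def simulate_summary_scenario(
    spec: ScenarioSpec, rng: int | np.random.Generator | None = None
) -> GwasPanel:
    """One replicate panel; the first floor(p_effect * M) variants are causal.

    Standard errors are 1 (so beta == t) and sample sizes are the nominal
    constant unless overridden downstream.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    T = _simulate_t(spec, rng)
    ids = np.array([f"snp{i:07d}" for i in range(spec.M)])
    tables = [
        table_from_arrays(ids, T[:, k], np.ones(spec.M), np.full(spec.M, spec.n_nominal),
                          label=f"g{k + 1}")
        for k in range(spec.K)
    ]
    return GwasPanel(tables)


# ---------------------------------------------------------------------------
# overlapping-cohort generator (individual level)


@dataclass
class OverlapSpec:
    """Synthetic-cohort configuration for the sample-overlap scenario.

    Unlinked genotypes stand in for real chip data: the background
    correlation between two GWASs of one phenotype is ideally
    ``Nc / sqrt(N1 N2) * rho`` with Nc shared individuals, and that theory
    is LD-free.
    """

    n_individuals: int = 2_000
    m_snps: int = 20_000
    causal_frac: float = 0.01
    h2: float = 0.10
    cohort_sizes: tuple[int, int, int] = (1_980, 1_980, 1_980)
    overlap_pattern: str = "full"  # none | partial | full
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if any(c > self.n_individuals for c in self.cohort_sizes):
            raise ValueError("cohort sizes cannot exceed n_individuals")
        if self.overlap_pattern not in ("none", "partial", "full"):
            raise ValueError("overlap_pattern must be none, partial or full")
        if self.overlap_pattern == "none" and sum(self.cohort_sizes) > self.n_individuals:
            raise ValueError("non-overlapping cohorts cannot exceed the sample")


def _cohort_indices(spec: OverlapSpec) -> list[np.ndarray]:
    n = spec.n_individuals
    c = spec.cohort_sizes
    if spec.overlap_pattern == "none":
        starts = np.concatenate([[0], np.cumsum(c)[:-1]])
    elif spec.overlap_pattern == "full":
        starts = [0, 0, 0]
    else:  # partial: first, centered, last
        starts = [0, (n - c[1]) // 2, n - c[2]]
    return [np.arange(s, s + ci) for s, ci in zip(starts, c)]


def _regress_gwas(G: np.ndarray, y: np.ndarray, chunk: int = 5_000):
    """Per-variant simple linear regression, vectorized in chunks.

    Returns (slope, se, keep) with monomorphic variants flagged out.
    """
    n, m = G.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    slope = np.empty(m)
    sxx_all = np.empty(m)
    sxy_all = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        Gc = G[:, lo:hi].astype(np.float64)
        xm = Gc.mean(axis=0)
        sxy = yc @ Gc
        sxx = np.einsum("ij,ij->j", Gc, Gc) - n * xm**2
        sxy_all[lo:hi] = sxy
        sxx_all[lo:hi] = sxx
    keep = sxx_all > 1e-12
    slope = np.divide(sxy_all, sxx_all, out=np.zeros(m), where=keep)
    resid = np.maximum(syy - slope * sxy_all, 0.0) / (n - 2)
    se = np.sqrt(np.divide(resid, sxx_all, out=np.full(m, np.inf), where=keep))
    keep &= np.isfinite(se) & (se > 0)
    return slope, se, keep


def simulate_overlap_cohorts(spec: OverlapSpec) -> dict:
    """Three sub-sample GWASs of one polygenic phenotype plus the union GWAS.

    Genotypes are binomial(2, f) with f ~ Uniform(0.05, 0.5); the phenotype
    is a genetic value over ``causal_frac`` of variants scaled so that it
    explains ``h2`` of the phenotypic variance, plus normal noise. Variants
    monomorphic in any cohort are dropped from every table.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.m_snps
    f = rng.uniform(0.05, 0.5, m)
    G = rng.binomial(2, f, size=(n, m)).astype(np.int8)
    n_causal = max(1, int(round(spec.causal_frac * m)))
    causal = rng.choice(m, n_causal, replace=False)
    b = rng.standard_normal(n_causal)
    gv = G[:, causal].astype(np.float64) @ b
    gv -= gv.mean()
    var_g = gv.var()
    noise = rng.normal(0.0, np.sqrt(var_g * (1.0 - spec.h2) / spec.h2), n)
    y = gv + noise

    cohorts = _cohort_indices(spec)
    fits = [_regress_gwas(G[idx], y[idx]) for idx in cohorts]
    fits.append(_regress_gwas(G, y))
    keep = np.logical_and.reduce([k for _, _, k in fits])
    ids = np.array([f"snp{i:07d}" for i in np.flatnonzero(keep)])
    tables = []
    names = ["cohort1", "cohort2", "cohort3", "union"]
    for (slope, se, _), idx, name in zip(fits, cohorts + [np.arange(n)], names):
        tables.append(
            table_from_arrays(ids, slope[keep], se[keep], np.full(keep.sum(), len(idx)), label=name)
        )
    return {
        "cohorts": tables[:3],
        "union": tables[3],
        "cohort_indices": cohorts,
        "causal": causal,
        "h2_realized": float(var_g / y.var()),
        "kept_variants": int(keep.sum()),
    }


# ---------------------------------------------------------------------------
# power / type-I harness


def oracle_ebicow_coefficients(Psi: np.ndarray, Pi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Linear coefficients of the oracle full-K EbICoW statistic on t.

    Uses the true effect covariance H = Pi o theta theta' and the direction
    row of sign(Pi - Psi) at the strongest trait; with unit standard errors
    h o e = h, so t_E = c' t with c = Psi^{-1} h / sqrt(h' Psi^{-1} h).
    """
    H = np.asarray(Pi, float) * np.outer(theta, theta)
    k = int(np.argmax(np.abs(theta)))
    sgn = _sign_keep_zero_positive(np.asarray(Pi, float) - np.asarray(Psi, float))[k]
    h = sgn @ H
    if not np.any(h):
        h = np.ones(len(theta))
    w = np.linalg.solve(Psi, h)
    return w / np.sqrt(h @ w)


def run_power_study(
    spec: ScenarioSpec,
    methods: tuple[str, ...] = ("ebicow", "wald", "twt", "mingwas"),
    *,
    n_calib: int = 500_000,
    seed: int | None = None,
    cgwas_config: CgwasConfig | None = None,
) -> pd.DataFrame:
    """Power and type-I error of the combination methods on one scenario.

    Per replicate the causal variants (the first floor(p*M)) are tested at
    ``spec.alpha`` (default 0.05/M); the null stratum yields the per-variant
    false-positive rate and the study-wide alpha (any null variant passing
    0.05/M). EbICoW and the truncated Wald scan use the true Psi/Pi/theta
    (oracle weights), so the table isolates the power of the statistics from
    estimation error; min-p and the scan are matched to the same alpha via
    the simulated-null calibration, shared across replicates.
    """
    if spec.replicates < 1:
        raise ValueError("need at least one replicate")
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_cal, rng_rep = [np.random.default_rng(s) for s in ss.spawn(2)]
    Psi = _as_corr(spec.Psi, spec.K)
    Pi = _as_corr(spec.Pi, spec.K)
    theta = spec.theta_vector()
    alpha = spec.alpha if spec.alpha is not None else 0.05 / spec.M
    bonferroni = 0.05 / spec.M
    n_causal = int(np.floor(spec.p_effect * spec.M))
    twt_cfg = TwtConfig()

    coef = oracle_ebicow_coefficients(Psi, Pi, theta) if "ebicow" in methods else None
    twt_model = None
    min_curve = None
    inv_cache: dict = {}
    if "twt" in methods or "mingwas" in methods:
        t_null = simulate_null_panel(Psi, n_calib, rng_cal)
        p_null = chi2_sf1(t_null**2)
        if "twt" in methods:
            SP = twt_genome(t_null, p_null, Psi, twt_cfg, inv_cache=inv_cache)
            twt_model = fit_twt_calibration(SP, twt_cfg, min_entries=min(10_000, n_calib))
            del SP
        if "mingwas" in methods:
            min_curve = fit_quantile_coefficients(p_null.min(axis=1))
        del t_null, p_null

    hits = {m: [] for m in methods}
    fps = {m: [] for m in methods}
    any_fp = {m: [] for m in methods}
    for _ in range(spec.replicates):
        T = _simulate_t(spec, rng_rep)
        P = chi2_sf1(T**2)
        pvals = {}
        if "ebicow" in methods:
            t_e = T @ coef
            pvals["ebicow"] = chi2_sf1(t_e**2)
        if "wald" in methods:
            pvals["wald"] = wald_genome(T, Psi)
        if "twt" in methods:
            CP = twt_genome(T, P, Psi, twt_cfg, inv_cache=inv_cache)
            pvals["twt"], _, _ = calibrate_scan(CP, twt_model)
        if "mingwas" in methods:
            pvals["mingwas"] = apply_calibration(P.min(axis=1), min_curve)
        if "cgwas" in methods:
            panel = _panel_from_t(T, spec.n_nominal)
            cfg = cgwas_config or CgwasConfig(NS=max(10_000, n_calib), known_psi=Psi,
                                              adjust_inflation=False,
                                              seed=int(rng_rep.integers(2**31)))
            pvals["cgwas"] = cgwas_pipeline(panel, cfg).p
        for m, p in pvals.items():
            hits[m].append(p[:n_causal] <= alpha if n_causal else np.array([np.nan]))
            null_p = p[n_causal:]
            fps[m].append(float(np.mean(null_p <= alpha)))
            any_fp[m].append(bool(null_p.min() <= bonferroni))
    rows = []
    for m in methods:
        rows.append(
            {
                "method": m,
                "power": float(np.nanmean(np.concatenate(hits[m]))) if n_causal else np.nan,
                "fpr": float(np.mean(fps[m])),
                "study_alpha": float(np.mean(any_fp[m])),
            }
        )
    return pd.DataFrame(rows).set_index("method")


def _panel_from_t(T: np.ndarray, n_nominal: int) -> GwasPanel:
    M, K = T.shape
    ids = np.array([f"snp{i:07d}" for i in range(M)])
    return GwasPanel(
        [
            table_from_arrays(ids, T[:, k], np.ones(M), np.full(M, n_nominal), label=f"g{k + 1}")
            for k in range(K)
        ]
    )


# ---------------------------------------------------------------------------
# named presets


def load_scenario(name_or_path: str, **overrides) -> ScenarioSpec:
    """Load a named scenario preset (or a YAML file path) into a ScenarioSpec."""
    try:
        res = importlib.resources.files("cgwas") / "scenarios" / f"{name_or_path}.yaml"
        text = res.read_text() if res.is_file() else None
    except (FileNotFoundError, TypeError):
        text = None
    if text is None:
        with open(name_or_path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    raw.update(overrides)
    if "e_chi2" in raw:
        e = raw.pop("e_chi2")
        return ScenarioSpec.from_mean_chi2(e, raw.pop("p_effect"), **raw)
    return ScenarioSpec(**raw)


def available_scenarios() -> list[str]:
    base = importlib.resources.files("cgwas") / "scenarios"
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))
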
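"""Empirical null calibration and the end-to-end combined-GWAS pipeline.

The truncated Wald scan produces, per variant, Q+1 dependent combined
p-values; taking their minimum follows no standard distribution. Two
empirical corrections restore a uniform null:

1. *Effective-test correction.* NS null draws t ~ N(0, Psi) are pushed
   through the identical scan; per column the effective number of
   independent tests ``Neff`` is fitted so that Tippett's transform
   ``1 - (1 - p)**Neff`` maps the simulated null column onto the uniform
   distribution, and the same transform is applied to the real column.
2. *Quantile-coefficient calibration.* The row minima of the simulated,
   Tippett-adjusted null matrix give the true null of the min statistic;
   the ratio of the uniform quantile to the empirical null quantile defines
   a multiplicative coefficient curve c(u), and each real minimum is scaled
   by c evaluated at its own rank. The final p-value vector is then
   directly comparable with any single standard GWAS.

The same machinery calibrates the naive per-variant minimum over the K
input GWASs ("MinGWAS"), which is by construction inflated under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ebicow import IterationState, iterative_ebicow
from .estimators import (
    adjust_inflation,
    estimate_inflation,
    estimate_psi_matrix,
    nearest_positive_definite,
)
from .summary_io import GwasPanel, GwasTable, chi2_sf1, sample_unlinked
from .twt import TwtConfig, twt_genome

logger = logging.getLogger("cgwas")

_P_FLOOR = 1e-300
_MIN_NS = 10_000


# ---------------------------------------------------------------------------
# null simulation


def simulate_null_panel(Psi: np.ndarray, NS: int, seed: int | np.random.Generator) -> np.ndarray:
    """NS independent null T-vectors drawn from N(0, Psi); rows are variants."""
    if NS < _MIN_NS:
        raise ValueError(f"NS must be >= {_MIN_NS} for a usable calibration")
    Psi = nearest_positive_definite(np.asarray(Psi, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(Psi)
    return rng.standard_normal((int(NS), Psi.shape[0])) @ L.T


# ---------------------------------------------------------------------------
# effective-test count and Tippett


def tippett_adjust(p, Neff: float):
    """Tippett's transform 1 - (1 - p)**Neff, exact for the min of Neff
    independent uniforms; computed in log1p space so small p stay accurate."""
    if Neff < 1:
        raise ValueError("Neff must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(Neff * np.log1p(-np.asarray(p, dtype=float)))
    return out


def estimate_n_independent(
    p_column: np.ndarray,
    *,
    u_grid: np.ndarray | None = None,
    min_entries: int = _MIN_NS,
    max_neff: float = 1e4,
) -> float:
    """Effective independent-test count of a simulated null p-value column.

    Fits Neff >= 1 by least squares on a log-quantile grid: after Tippett's
    transform with the right Neff, the empirical u-quantile of the null
    column equals u.
    """
    col = np.asarray(p_column, dtype=float)
    col = col[np.isfinite(col)]
    if col.size < min_entries:
        raise ValueError(f"need at least {min_entries} usable null entries, got {col.size}")
    if u_grid is None:
        u_grid = np.geomspace(1e-4, 1e-1, 25)
    q_hat = np.maximum(np.quantile(col, u_grid), _P_FLOOR)

    def objective(log_n: float) -> float:
        z = np.maximum(tippett_adjust(q_hat, np.exp(log_n)), _P_FLOOR)
        return float(np.sum((np.log(z) - np.log(u_grid)) ** 2))

    res = optimize.minimize_scalar(
        objective, bounds=(0.0, np.log(max_neff)), method="bounded", options={"xatol": 1e-6}
    )
    return float(max(np.exp(res.x), 1.0))


# ---------------------------------------------------------------------------
# quantile-coefficient calibration (getCoef)


@dataclass
class CoefCurve:
    """Monotone multiplicative correction c(u) stored on a log-log grid."""

    log_u: np.ndarray
    log_c: np.ndarray

    def predict(self, u) -> np.ndarray:
        """c at quantile u; constant extrapolation beyond the grid ends."""
        lu = np.log(np.clip(np.asarray(u, dtype=float), _P_FLOOR, 1.0))
        return np.exp(np.interp(lu, self.log_u, self.log_c))


def fit_quantile_coefficients(null_min_p: np.ndarray, n_grid: int = 400) -> CoefCurve:
    """Fit c(u) = u / (empirical null quantile at u) on a log-spaced grid."""
    x = np.asarray(null_min_p, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_NS:
        raise ValueError("too few null minima for calibration")
    if np.ptp(x) == 0:
        raise ValueError("degenerate null: all simulated minima identical")
    # log-spaced points resolve the tail; the dense linear section tracks the
    # kinks the null-min CDF inherits from the empty-subset column structure
    u = np.unique(
        np.concatenate([np.geomspace(1.0 / x.size, 1.0, n_grid), np.linspace(0.0005, 1.0, 2000)])
    )
    q = np.maximum(np.quantile(x, u), _P_FLOOR)
    return CoefCurve(log_u=np.log(u), log_c=np.log(u / q))


def apply_calibration(p_vec: np.ndarray, curve: CoefCurve) -> np.ndarray:
    """Scale each p by c at its within-vector rank; isotonic in the p-order.

    Ranks use the average convention for ties; the multiplicative correction
    never reorders significance because a running maximum along increasing p
    repairs any local inversion introduced by the interpolated curve.
    """
    p = np.asarray(p_vec, dtype=float)
    ranks = stats.rankdata(p, method="average") / p.size
    out = np.clip(p * curve.predict(ranks), _P_FLOOR, 1.0)
    order = np.argsort(p, kind="stable")
    out[order] = np.maximum.accumulate(out[order])
    return np.minimum(out, 1.0)


# ---------------------------------------------------------------------------
# calibrated MinGWAS


def mingwas(
    panel_or_p,
    Psi: np.ndarray,
    NS: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-variant minimum of the K p-values, calibrated to a uniform null.

    The naive minimum is inflated under the null; its true null under the
    background correlation Psi is simulated and the quantile-coefficient
    curve maps it back onto the uniform distribution. With independent
    GWASs this reduces to Tippett's K-fold correction; correlation makes
    the effective correction strictly smaller.
    """
    P = panel_or_p.p_matrix() if isinstance(panel_or_p, GwasPanel) else np.asarray(panel_or_p, float)
    if P.ndim == 1:
        P = P[:, None]
    t_null = simulate_null_panel(Psi, NS, seed)
    null_min = chi2_sf1(t_null**2).min(axis=1)
    curve = fit_quantile_coefficients(null_min)
    return apply_calibration(P.min(axis=1), curve)


# ---------------------------------------------------------------------------
# the calibration model shared by pipeline and power studies


@dataclass
class CalibrationModel:
    """Simulated-null calibration of the truncated Wald scan under one Psi."""

    Neff: np.ndarray  # length Q+1
    curve: CoefCurve
    min_sp: np.ndarray  # NS adjusted null minima
    NS: int
    config: TwtConfig


def fit_twt_calibration(SP: np.ndarray, config: TwtConfig, *, min_entries: int = _MIN_NS) -> CalibrationModel:
    """Fit per-column Neff and the coefficient curve from a simulated null scan.

    Columns whose threshold is so small that too few simulated rows have a
    non-empty subset reuse the last well-estimated Neff: the choice cannot
    bias the final alpha (the identical transform is applied to the real
    and the simulated matrix before the coefficient fit), it only weighs
    how often such a column can win the row minimum.
    """
    Q1 = SP.shape[1]
    Neff = np.ones(Q1)
    last = 1.0
    for q in range(Q1):
        col = SP[:, q]
        col = col[np.isfinite(col)]
        if col.size < min_entries:
            logger.info("calibration column %d: %d entries; reusing Neff=%.2f", q, col.size, last)
            Neff[q] = last
            continue
        last = estimate_n_independent(col, min_entries=min(min_entries, col.size))
        Neff[q] = last
    SP_adj = np.column_stack([tippett_adjust(SP[:, q], Neff[q]) for q in range(Q1)])
    min_sp = np.nanmin(SP_adj, axis=1)
    curve = fit_quantile_coefficients(min_sp)
    return CalibrationModel(Neff=Neff, curve=curve, min_sp=min_sp, NS=SP.shape[0], config=config)


def calibrate_scan(CP: np.ndarray, model: CalibrationModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a fitted calibration to a real scan matrix.

    Returns (final p, raw row minima after Tippett, winning column index).
    """
    CP_adj = np.column_stack(
        [tippett_adjust(CP[:, q], model.Neff[q]) for q in range(CP.shape[1])]
    )
    all_nan = np.all(np.isnan(CP_adj), axis=1)
    if all_nan.any():  # cannot happen when the min-p column is present; guard anyway
        CP_adj[all_nan, -1] = 1.0
    min_cp = np.nanmin(CP_adj, axis=1)
    chosen_q = np.nanargmin(CP_adj, axis=1)
    return apply_calibration(min_cp, model.curve), min_cp, chosen_q


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CgwasConfig:
    """All tunables of the end-to-end pipeline."""

    F: float = 0.05
    force_psi2: float = 0.5
    twt: TwtConfig = field(default_factory=TwtConfig)
    NS: int = 1_000_000
    seed: int = 0
    min_frac: float = 0.6
    L: float = 1e-5
    e_choice: str = "inv_se"  # or "sqrt_n"
    adjust_inflation: bool = True
    known_psi: np.ndarray | None = None
    unlinked_target: int | None = None
    unlinked_rounds: int = 5
    keep_cp: bool = False

    def __post_init__(self) -> None:
        if self.e_choice not in ("inv_se", "sqrt_n"):
            raise ValueError("e_choice must be 'inv_se' or 'sqrt_n'")
        if self.NS < _MIN_NS:
            raise ValueError(f"NS must be >= {_MIN_NS}")


@dataclass
class CgwasResult:
    """Final p-values plus the full run report."""

    p: np.ndarray
    variant_index: pd.Index
    min_cp: np.ndarray
    chosen_q: np.ndarray
    subset_size: np.ndarray
    p_mingwas: np.ndarray
    s: np.ndarray
    Psi: np.ndarray
    Psi_reduced: np.ndarray
    state: IterationState
    calibration: CalibrationModel
    ntest_burden: float
    coef_burden: float
    report: dict
    CP: np.ndarray | None = None


def _sqrt_n_tables(panel: GwasPanel) -> GwasPanel:
    """Swap the weight convention from 1/se to sqrt(n) by redefining sigma."""
    tables = []
    for t in panel.tables:
        d = t.df.copy()
        d["se"] = 1.0 / np.sqrt(np.asarray(d["n"], dtype=float))
        d["beta"] = d["t"] * d["se"]
        tables.append(GwasTable(d, t.label))
    return GwasPanel(tables, labels=list(panel.labels))


def simulate_scan_null(
    Psi0: np.ndarray,
    lineage: np.ndarray,
    Psi_reduced: np.ndarray,
    NS: int,
    seed: int | np.random.Generator,
    config: TwtConfig,
) -> np.ndarray:
    """Null scan matrix obtained by replaying the combination weights.

    Null T-vectors of the original K GWASs are drawn from N(0, Psi0) and
    combined with the stored i-EbICoW weights, so the simulated null carries
    exactly the miscalibration (if any) that the weights introduce into the
    real data; the scan then uses the same reduced-panel Psi as the real CP.
    """
    T0 = simulate_null_panel(Psi0, NS, seed)
    T_sim = T0 @ np.asarray(lineage, dtype=float).T
    P_sim = chi2_sf1(T_sim**2)
    return twt_genome(T_sim, P_sim, Psi_reduced, config)


def derive_studywide_threshold(base_alpha: float, ntest_burden: float, coef_burden: float) -> float:
    """Study-wide threshold on the final p scale, at 3 significant digits.

    A variant at the conventional per-GWAS genome-wide level appears in the
    final combined vector multiplied by the effective-test burden (Tippett)
    and the coefficient burden (quantile calibration); their product converts
    the conventional threshold onto the combined scale.
    """
    if base_alpha <= 0 or ntest_burden <= 0 or coef_burden <= 0:
        raise ValueError("all inputs must be positive")
    return float(f"{base_alpha * ntest_burden * coef_burden:.3g}")


def cgwas_pipeline(panel: GwasPanel, config: CgwasConfig | None = None) -> CgwasResult:
    """Run the full combination pipeline on a harmonized, filtered panel.

    Stages: inflation estimation and adjustment; background/effect
    correlation estimation; iterative pairwise combination; truncated Wald
    scan on the reduced panel; effective-test correction and quantile
    calibration against a replayed simulated null; calibrated MinGWAS for
    comparison. Deterministic given ``config.seed``.
    """
    config = config or CgwasConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_subsets, rng_null, rng_min = [np.random.default_rng(s) for s in ss.spawn(3)]
    stage = "inflation"
    try:
        work = _sqrt_n_tables(panel) if config.e_choice == "sqrt_n" else panel
        s_vec = np.ones(work.K)
        if config.adjust_inflation:
            fits = [estimate_inflation(t.df["t"].to_numpy()) for t in work.tables]
            s_vec = np.array([f.s for f in fits])
            work = GwasPanel(
                [adjust_inflation(t, s) for t, s in zip(work.tables, s_vec)],
                labels=list(work.labels),
            )

        stage = "background correlation"
        subsets = sample_unlinked(work.M, config.unlinked_target, config.unlinked_rounds, rng_subsets)
        if config.known_psi is not None:
            Psi0 = np.asarray(config.known_psi, dtype=float)
        else:
            Psi0 = estimate_psi_matrix(work.t_matrix(), subsets)

        stage = "i-EbICoW"
        reduced, state = iterative_ebicow(
            work,
            F=config.F,
            force_psi2=config.force_psi2,
            L=config.L,
            Psi0=Psi0,
            exact_psi=config.known_psi is not None,
            unlinked_target=config.unlinked_target,
            unlinked_rounds=config.unlinked_rounds,
            seed=rng_subsets,
        )
        Psi_red = state.Psi

        stage = "truncated Wald scan"
        T_red, P_red = reduced.t_matrix(), reduced.p_matrix()
        CP = twt_genome(T_red, P_red, Psi_red, config.twt)

        stage = "null calibration"
        SP = simulate_scan_null(Psi0, state.lineage, Psi_red, config.NS, rng_null, config.twt)
        model = fit_twt_calibration(SP, config.twt)
        del SP
        final, min_cp, chosen_q = calibrate_scan(CP, model)

        stage = "MinGWAS comparison"
        p_min = mingwas(panel.p_matrix(), Psi0, NS=config.NS, seed=rng_min)

        counts = (P_red[:, None, :] <= config.twt.r[None, :, None]).sum(axis=2)
        subset_size = np.where(
            chosen_q < config.twt.Q,
            counts[np.arange(len(chosen_q)), np.minimum(chosen_q, config.twt.Q - 1)],
            1,
        )
        ntest_burden = float(model.Neff[-1])
        coef_burden = float(model.curve.predict(max(5e-8 * ntest_burden, 1.0 / config.NS)))
        report = {
            "K_in": panel.K,
            "K_out": reduced.K,
            "M": panel.M,
            "s": s_vec.tolist(),
            "Psi": Psi0.tolist(),
            "Psi_reduced": Psi_red.tolist(),
            "iterations": state.log,
            "Neff": model.Neff.tolist(),
            "ntest_burden": ntest_burden,
            "coef_burden": coef_burden,
            "studywide_threshold": derive_studywide_threshold(5e-8, ntest_burden, coef_burden),
            "NS": config.NS,
            "tail_quantile_floor": 10.0 / config.NS,  # below this the coefficient is extrapolated
        }
        return CgwasResult(
            p=final,
            variant_index=panel.variant_index,
            min_cp=min_cp,
            chosen_q=chosen_q,
            subset_size=subset_size,
            p_mingwas=p_min,
            s=s_vec,
            Psi=Psi0,
            Psi_reduced=Psi_red,
            state=state,
            calibration=model,
            ntest_burden=ntest_burden,
            coef_burden=coef_burden,
            report=report,
            CP=CP if config.keep_cp else None,
        )
    except Exception as exc:
        raise RuntimeError(f"combined-GWAS pipeline failed at stage: {stage}") from exc
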
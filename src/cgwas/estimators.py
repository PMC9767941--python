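"""Moment/quantile estimators for inflation, background and effect correlations.

Under the null the K-vector of T statistics of a variant is distributed
N(0, s * Psi): ``Psi`` is the *background* correlation (sample overlap and
non-genetic phenotype correlation; for two GWASs ideally
``psi = Nc / sqrt(N1 N2) * rho``), and ``s = I + 1`` is the per-GWAS
inflation factor (stratification / relatedness). True allelic effects add a
second covariance component whose correlation across GWASs is the *effect*
correlation ``Pi``. All three are estimated here from summary statistics
alone — no LD information is used, which is what keeps the whole method fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .summary_io import GwasPanel, GwasTable, chi2_sf1

logger = logging.getLogger("cgwas")

_CHI2_1_MEDIAN = stats.chi2.median(1)  # 0.45493...
_CHI2_2_MEDIAN = stats.chi2.median(2)  # 2 ln 2
_DIAG_FLOOR = 1.001  # floor on mean chi-squared so the effect rule stays defined


# ---------------------------------------------------------------------------
# inflation (getI)


@dataclass
class InflationFit:
    """Mixture fit of squared T statistics.

    The model is a two-component scale mixture of 1-df chi-squares:
    a fraction ``1 - p_effect`` of variants has ``t^2 ~ s * chi2(1)`` and a
    fraction ``p_effect`` has ``t^2 ~ (s + Lambda) * chi2(1)``, so that
    ``E(t^2) = 1 + I + p * Lambda`` and
    ``Var(t^2) = 2 E(t^2)^2 + 3 Lambda^2 p (1 - p)``.
    """

    s: float
    I: float
    Lambda: float
    p_effect: float
    s_raw: float = None  # type: ignore[assignment]  # pre-clamp value, used for sanity checks
    converged: bool = True

    def __post_init__(self) -> None:
        if self.s_raw is None:
            self.s_raw = self.s


def genomic_control_lambda(t: np.ndarray) -> float:
    """Classical genomic-control inflation: median(t^2) over the chi2(1) median.

    Biased upward in the presence of true effects; kept as a comparator and
    as the fallback when the mixture fit fails.
    """
    t = np.asarray(t, dtype=float)
    return float(np.median(t**2) / _CHI2_1_MEDIAN)


def _moment_lambda_p(I: float, m1: float, m2c: float) -> tuple[float, float]:
    """Solve the two moment equations for (Lambda, p) at a candidate I."""
    x = m1 - (1.0 + I)  # p * Lambda
    if x <= 0:
        return 0.0, 0.0
    c = (m2c - 2.0 * m1 * m1) / 3.0  # Lambda^2 p (1 - p)
    if c <= 0:
        return x, 1.0
    p = x * x / (c + x * x)
    return (c + x * x) / x, p


def _mixture_quantile(u: float, s: float, lam: float, p: float) -> float:
    """Quantile of the two-component scaled chi-squared mixture."""
    if p <= 0 or lam <= 0:
        return s * stats.chi2.ppf(u, 1)

    def cdf(x: float) -> float:
        return (1 - p) * stats.chi2.cdf(x / s, 1) + p * stats.chi2.cdf(x / (s + lam), 1)

    hi = (s + lam) * stats.chi2.ppf(min(u + 1e-9, 1 - 1e-12), 1) + 1.0
    return optimize.brentq(lambda x: cdf(x) - u, 0.0, hi, xtol=1e-10)


def estimate_inflation(
    t: np.ndarray,
    *,
    levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    allow_deflation: bool = False,
) -> InflationFit:
    """Estimate the inflation factor s = I + 1 of a T-statistic vector.

    Method of moments combined with quantile matching: for a candidate I the
    moment equations pin down (Lambda, p) in closed form; I is then chosen to
    minimize the squared mismatch between empirical quantiles of ``t**2`` and
    the quantiles of the fitted mixture at the lower probability levels,
    where true-effect contamination is minimal. Unlike genomic control, the
    fit explicitly models the effect component and stays unbiased when true
    effects are present.

    ``allow_deflation`` opens the search below I = 0; the returned ``s`` is
    always clamped to >= 1 but ``s_raw`` keeps the unclamped value.
    """
    t = np.asarray(t, dtype=float)
    t = t[np.isfinite(t)]
    if t.size < 1000:
        logger.warning("estimate_inflation: only %d statistics; estimate is noisy", t.size)
    t2 = t**2
    m1 = float(t2.mean())
    m2c = float(t2.var())
    if not (np.isfinite(m1) and np.isfinite(m2c)):
        raise ValueError("non-finite moments of t^2")
    emp_q = np.quantile(t2, levels)

    def objective(I: float) -> float:
        lam, p = _moment_lambda_p(I, m1, m2c)
        s = 1.0 + I
        fit = sum(
            (_mixture_quantile(u, s, lam, p) - q) ** 2 for u, q in zip(levels, emp_q)
        )
        # an effect component with p -> 1 is indistinguishable from inflation
        # (the fitted mixtures coincide); the tiny penalty on the effect mass
        # breaks that ridge toward inflation without moving identifiable fits
        return fit + 1e-4 * max(m1 - 1.0 - I, 0.0)

    lower = -0.5 if allow_deflation else 0.0
    upper = max(m1 - 1.0, lower) + 0.25
    try:
        res = optimize.minimize_scalar(
            objective, bounds=(lower, upper), method="bounded", options={"xatol": 1e-5}
        )
        I_hat = float(res.x)
        converged = bool(res.success)
    except Exception:  # numerical failure: fall back to genomic control
        I_hat = genomic_control_lambda(t) - 1.0
        converged = False
    if not converged:
        logger.warning("estimate_inflation did not converge; falling back to genomic control")
        I_hat = max(genomic_control_lambda(t) - 1.0, lower)
    lam, p = _moment_lambda_p(I_hat, m1, m2c)
    s_raw = 1.0 + I_hat
    s = max(s_raw, 1.0)
    return InflationFit(s=s, I=s - 1.0, Lambda=lam, p_effect=p, s_raw=s_raw, converged=converged)


def adjust_inflation(table: GwasTable, s: float) -> GwasTable:
    """Divide T by sqrt(s) (standard errors absorb the factor; beta unchanged)."""
    if s < 1:
        raise ValueError("inflation factor s must be >= 1")
    d = table.df.copy()
    root = np.sqrt(s)
    d["t"] = d["t"] / root
    d["se"] = d["se"] * root
    d["p"] = chi2_sf1(d["t"].to_numpy() ** 2)
    return GwasTable(d, table.label)


# ---------------------------------------------------------------------------
# background correlation (getPsi)


def estimate_psi(
    t1: np.ndarray,
    t2: np.ndarray,
    *,
    eps: float = 1e-4,
    max_iter: int = 100,
    min_keep: int = 100,
) -> float:
    """Background correlation between two T-statistic vectors.

    Iteratively restricts to variants that are jointly insignificant under
    the current estimate — those whose 2-df Mahalanobis chi-squared falls
    below its median, i.e. whose joint upper-tail probability exceeds 0.5 —
    and recomputes the correlation on that set. Radial truncation in the
    whitened space preserves the correlation, so the fixed point is the true
    psi even when a fraction of variants carries correlated true effects
    (those are preferentially excluded by the joint criterion).
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("length mismatch")
    if t1.size < 1000:
        logger.warning("estimate_psi: only %d variants; estimate is noisy", t1.size)
    psi = float(np.corrcoef(t1, t2)[0, 1])
    for _ in range(max_iter):
        r2 = min(psi**2, 0.999**2)
        ct = (t1**2 - 2.0 * psi * t1 * t2 + t2**2) / (1.0 - r2)
        keep = ct < _CHI2_2_MEDIAN
        if keep.sum() < min_keep:
            raise ValueError("fewer than %d jointly insignificant variants" % min_keep)
        new = float(np.corrcoef(t1[keep], t2[keep])[0, 1])
        done = abs(new - psi) <= eps
        psi = new
        if done:
            break
    else:
        logger.warning("estimate_psi: no convergence in %d iterations (last %.4f)", max_iter, psi)
    return float(np.clip(psi, -0.999, 0.999))


def nearest_positive_definite(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floored repair keeping a unit diagonal."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    if vals.min() > floor:
        return mat
    logger.info("correlation matrix repaired: min eigenvalue %.2e floored at %.0e", vals.min(), floor)
    fixed = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def estimate_psi_matrix(
    panel_or_t,
    subsets: list[np.ndarray] | None = None,
    **psi_kwargs,
) -> np.ndarray:
    """Pairwise psi on unlinked subsets, median across rounds, PD-repaired."""
    T = panel_or_t.t_matrix() if isinstance(panel_or_t, GwasPanel) else np.asarray(panel_or_t, float)
    K = T.shape[1]
    if subsets is None:
        subsets = [np.arange(T.shape[0])]
    Psi = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            est = np.median([estimate_psi(T[idx, i], T[idx, j], **psi_kwargs) for idx in subsets])
            Psi[i, j] = Psi[j, i] = est
    return nearest_positive_definite(Psi)


# ---------------------------------------------------------------------------
# effect correlation and effect vector (getPi / getH)


@dataclass
class CorrModel:
    """Genome-wide correlation matrices of a panel."""

    Psi: np.ndarray
    Pi: np.ndarray
    Z: np.ndarray
    Psi_nosig: np.ndarray | None = None
    variant: str = "all"


@dataclass
class EffectModel:
    """Per-variant effect rule H = A o sigma sigma^T with A fixed genome-wide.

    ``A`` is the sigma-free part of the expected true-effect covariance
    (``Z - Psi`` for the genome-wide rule, ``Z_sig - Psi_nosig`` for the
    significant-variant rule, and the rank-one outer product for the
    stabilized all-ones rule). ``sign_row`` is the fixed row k of
    sign(Pi - Psi) (sign(0) = +1) that sets the combination direction.
    """

    A: np.ndarray
    sign_row: np.ndarray
    Pi: np.ndarray
    variant: str = "all"
    sign_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def h_times_e(self, sigma: np.ndarray) -> np.ndarray:
        """Return the M x K matrix of (h o e) rows for per-variant sigma.

        With ``h_j = sum_i sgn_i A_ij sigma_i sigma_j`` and ``e_j = 1/sigma_j``,
        the product reduces to ``(sigma * sgn) @ A``.
        """
        sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
        return (sigma * self.sign_row) @ self.A


def _sign_keep_zero_positive(x: np.ndarray) -> np.ndarray:
    s = np.sign(x)
    s[s == 0] = 1.0
    return s


def _mean_outer(T: np.ndarray) -> np.ndarray:
    """Uncentered covariance E(t_i t_j) over the variant axis."""
    return T.T @ T / T.shape[0]


def estimate_effect_model(
    panel_or_t,
    Psi: np.ndarray,
    variant: str = "all",
    L: float = 1e-5,
    subsets: list[np.ndarray] | None = None,
    sign_k: int = 0,
    min_sig: int = 100,
) -> tuple[np.ndarray, EffectModel, CorrModel]:
    """Estimate the effect-correlation matrix Pi and the effect rule.

    ``variant`` selects among three rules:

    - ``all``  — genome-wide: ``H = (Z - Psi) o sigma sigma^T`` with Z the
      uncentered T covariance over all (subset) variants; best under
      polygenicity.
    - ``sig``  — major-gene oriented: Z over variants significant by the
      Wald test at threshold L, Psi replaced by the covariance of the
      non-significant variants; falls back to ``all`` below ``min_sig``
      significant variants.
    - ``stb``  — stabilized: Pi is the all-ones matrix and H the rank-one
      outer product of ``sigma_k * sqrt(Z_kk - 1)``; robust when H is noisy.

    Mean chi-squared below 1.001 is floored at 1.001 so the normalization of
    Pi never divides by a vanishing diagonal.
    """
    T = panel_or_t.t_matrix() if isinstance(panel_or_t, GwasPanel) else np.asarray(panel_or_t, float)
    if subsets is not None:
        T = T[np.unique(np.concatenate(subsets))]
    K = T.shape[1]
    Psi = np.asarray(Psi, dtype=float)

    Z = _mean_outer(T)
    zdiag = np.maximum(np.diag(Z).copy(), _DIAG_FLOOR)
    Z = Z.copy()
    np.fill_diagonal(Z, zdiag)
    psi_nosig = None

    if variant == "sig":
        Psi_inv = np.linalg.inv(Psi)
        stat = np.einsum("mi,ij,mj->m", T, Psi_inv, T)
        sig = stats.chi2.sf(stat, df=K) < L
        if sig.sum() < min_sig:
            logger.warning(
                "estimate_effect_model: %d significant variants (< %d); falling back to 'all'",
                int(sig.sum()),
                min_sig,
            )
            variant = "all"
        else:
            Z = _mean_outer(T[sig])
            np.fill_diagonal(Z, np.maximum(np.diag(Z), _DIAG_FLOOR))
            psi_nosig = _mean_outer(T[~sig])

    if variant == "stb":
        root = np.sqrt(np.maximum(np.diag(Z) - 1.0, _DIAG_FLOOR - 1.0))
        A = np.outer(root, root)
        Pi = np.ones((K, K))
    else:
        base = psi_nosig if psi_nosig is not None else Psi
        A = Z - base
        d = np.sqrt(np.maximum(np.diag(A), _DIAG_FLOOR - 1.0))
        Pi = np.clip(A / np.outer(d, d), -1.0, 1.0)
        np.fill_diagonal(Pi, 1.0)

    sign_matrix = _sign_keep_zero_positive(Pi - Psi)
    model = EffectModel(
        A=A, sign_row=sign_matrix[sign_k].copy(), Pi=Pi, variant=variant, sign_matrix=sign_matrix
    )
    corr = CorrModel(Psi=Psi, Pi=Pi, Z=Z, Psi_nosig=psi_nosig, variant=variant)
    return Pi, model, corr
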
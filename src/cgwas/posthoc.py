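"""Post-hoc statistics: multi-trait-effect score, power-gain ratio, Fisher test.

The multi-trait-effect (MTE) score asks whether a significant variant acts
on many independent trait directions or on few. The T-vector is projected
onto the leading eigenvectors of the background correlation Psi (which are
uncorrelated under the null) and rescaled by the eigenvalues so every
projection has unit null variance; the squared projections are then 1-df
chi-squares whose skewness is exactly 2*sqrt(2) under the null. The score
is ``MTE = 2*sqrt(2) - Skew(pt o pt)``: a variant whose effect spreads over
many directions has low skewness (large MTE), a single dominant direction
gives skewness far above the null (MTE < 0, no multi-trait evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("cgwas")

#: skewness of a 1-df chi-squared variable: (15 - 6 - 1) / (2*sqrt(2)) = 2*sqrt(2)
NULL_SKEW = 2.0 * np.sqrt(2.0)
_P_FLOOR = 1e-300


@dataclass
class MteModel:
    """Null-space projection fitted from Psi."""

    V: np.ndarray  # K x R eigenvectors
    g: np.ndarray  # R eigenvalues, descending
    var_threshold: float = 0.95
    null_skew: float = NULL_SKEW

    @property
    def R(self) -> int:
        return self.V.shape[1]


def fit_mte_model(Psi: np.ndarray, var_threshold: float = 0.95) -> MteModel:
    """Keep the minimal set of top eigenvectors reaching the variance threshold."""
    Psi = np.asarray(Psi, dtype=float)
    if not np.allclose(Psi, Psi.T, atol=1e-8):
        raise ValueError("Psi must be symmetric")
    vals, vecs = np.linalg.eigh(Psi)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    cum = np.cumsum(vals) / vals.sum()
    R = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    V = vecs[:, :R]
    # reproducible sign convention: largest-magnitude entry positive
    flip = V[np.abs(V).argmax(axis=0), np.arange(R)] < 0
    V[:, flip] *= -1.0
    return MteModel(V=V, g=vals[:R], var_threshold=var_threshold)


def _population_skew(x: np.ndarray) -> float:
    xc = x - x.mean()
    m2 = float(np.mean(xc**2))
    if m2 == 0:
        return 0.0
    return float(np.mean(xc**3) / m2**1.5)


def mte(t_vec: np.ndarray, model: MteModel) -> float:
    """Multi-trait-effect score of one variant's K-vector of T statistics."""
    if model.R < 3:
        raise ValueError("need at least 3 retained eigenvectors for a stable skewness")
    t_vec = np.asarray(t_vec, dtype=float)
    pt = (model.V.T @ t_vec) / np.sqrt(model.g)
    return float(model.null_skew - _population_skew(pt**2))


def power_gain_ratio(
    mean_chi2_a: float, intercept_a: float, mean_chi2_b: float, intercept_b: float
) -> float:
    """Relative power of two GWASs from mean chi-squared above the null line.

    The excess of the mean chi-squared over the no-effect intercept is
    proportional to effective sample size, so the ratio of excesses is the
    power gain of study a over study b.
    """
    num = mean_chi2_a - intercept_a
    den = mean_chi2_b - intercept_b
    if den <= 0 or num <= 0:
        raise ValueError("mean chi-squared must exceed its null intercept")
    return num / den


def fisher_combined(p_list) -> tuple[float, float]:
    """Fisher's combined test over independent p-values: T = -2 sum log p ~ chi2(2N)."""
    p = np.asarray(p_list, dtype=float)
    if np.any(p <= 0):
        logger.warning("non-positive p-values floored at %.0e", _P_FLOOR)
        p = np.maximum(p, _P_FLOOR)
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    t_f = float(-2.0 * np.sum(np.log(p)))
    return t_f, float(stats.chi2.sf(t_f, df=2 * p.size))


def bonferroni_min(p_vec, n_independent: float) -> float:
    """Bonferroni-adjusted minimum of a set of trait p-values."""
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    return float(min(np.min(np.asarray(p_vec, dtype=float)) * n_independent, 1.0))


def replication_combine(p_lists, n_independent_list) -> tuple[float, float]:
    """Combine replication evidence across cohorts.

    Each cohort contributes the Bonferroni-adjusted minimum of its per-trait
    p-values (adjusted by that study's reported number of independent
    traits); the adjusted minima are then combined with Fisher's test.
    """
    adjusted = [bonferroni_min(p, n) for p, n in zip(p_lists, n_independent_list)]
    return fisher_combined(adjusted)
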
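"""Wald test on GWAS subsets and the per-variant truncated Wald scan (TWT).

For a variant with T-vector t over K GWASs and background correlation Psi,
the Wald statistic ``t' Psi^{-1} t`` is chi-squared with K df under the
null. TWT runs the Wald test on the nested per-variant subsets defined by a
descending grid of p-value thresholds ``r_q = 10**(-q/3)`` (q = 1..Q,
Q = 18 by default): at threshold q only the GWASs with input p <= r_q
enter the quadratic form. The scan yields Q+1 combined p-values per
variant — the last entry is simply the minimum input p (a one-element
subset) — which the calibration stage later makes comparable at a common
alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import _P_FLOOR


@dataclass
class TwtConfig:
    """Threshold grid of the truncated Wald scan."""

    Q: int = 18
    r: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r is None:
            self.r = 10.0 ** (-np.arange(1, self.Q + 1) / 3.0)
        self.r = np.asarray(self.r, dtype=float)
        self.Q = len(self.r)
        if np.any(self.r >= 1) or np.any(self.r < 0) or np.any(np.diff(self.r) >= 0):
            raise ValueError("thresholds must be strictly descending in [0, 1)")


def wald_statistic(t_sub: np.ndarray, Psi_sub: np.ndarray) -> tuple[float, int, float]:
    """Quadratic-form Wald test of H0: no effect in any of the subset GWASs."""
    t_sub = np.asarray(t_sub, dtype=float)
    Psi_sub = np.atleast_2d(np.asarray(Psi_sub, dtype=float))
    df = t_sub.size
    if Psi_sub.shape != (df, df):
        raise ValueError("Psi_sub dimensions do not match t_sub")
    stat = float(t_sub @ np.linalg.solve(Psi_sub, t_sub))
    return stat, df, max(float(stats.chi2.sf(stat, df)), _P_FLOOR)


def wald_genome(T: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    """Full-set Wald p-values for every row of an M x K statistic matrix."""
    T = np.asarray(T, dtype=float)
    Psi_inv = np.linalg.inv(Psi)
    stat = np.einsum("mi,ij,mj->m", T, Psi_inv, T)
    return np.maximum(stats.chi2.sf(stat, df=T.shape[1]), _P_FLOOR)


def twt_scan(
    p_vec: np.ndarray, t_vec: np.ndarray, Psi: np.ndarray, config: TwtConfig | None = None
) -> np.ndarray:
    """One variant's combined-p vector over the Q thresholds plus the min-p entry.

    Entry q is NaN when no input p-value reaches r_q (empty subset).
    """
    config = config or TwtConfig()
    p_vec = np.asarray(p_vec, dtype=float)
    t_vec = np.asarray(t_vec, dtype=float)
    Psi = np.asarray(Psi, dtype=float)
    cp = np.full(config.Q + 1, np.nan)
    for q, rq in enumerate(config.r):
        idx = np.flatnonzero(p_vec <= rq)
        if idx.size:
            stat, df, p = wald_statistic(t_vec[idx], Psi[np.ix_(idx, idx)])
            cp[q] = p
    cp[config.Q] = p_vec.min()
    return cp


def twt_genome(
    T: np.ndarray,
    P: np.ndarray,
    Psi: np.ndarray,
    config: TwtConfig | None = None,
    chunk_size: int = 200_000,
    inv_cache: dict | None = None,
) -> np.ndarray:
    """Row-wise truncated Wald scan of an M x K panel, returning M x (Q+1).

    Rows are grouped by subset size; the principal-submatrix inverse of each
    subset pattern is computed once (pass ``inv_cache`` to share it across
    repeated calls with the same Psi) and gathered per row, so the quadratic
    forms evaluate as one einsum per (threshold, size) group. Evaluation is
    chunked so memory stays bounded for large M.
    """
    config = config or TwtConfig()
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    M, K = T.shape
    if K > 62:
        raise ValueError("subset patterns are encoded in 64-bit codes: K must be <= 62")
    bits = 1 << np.arange(K, dtype=np.int64)
    cache = inv_cache if inv_cache is not None else {}
    CP = np.full((M, config.Q + 1), np.nan)
    CP[:, config.Q] = P.min(axis=1)

    for start in range(0, M, chunk_size):
        stop = min(start + chunk_size, M)
        Tc, Pc = T[start:stop], P[start:stop]
        for q, rq in enumerate(config.r):
            mask = Pc <= rq
            sizes = mask.sum(axis=1)
            codes = mask @ bits
            for s in np.unique(sizes):
                if s == 0:
                    continue
                rows = np.flatnonzero(sizes == s)
                uniq, imap = np.unique(codes[rows], return_inverse=True)
                for code in uniq:
                    if code not in cache:
                        cols = np.flatnonzero((code >> np.arange(K)) & 1)
                        cache[code] = np.linalg.inv(Psi[np.ix_(cols, cols)])
                inv_rows = np.stack([cache[c] for c in uniq])[imap]
                # active-column order is ascending, matching the cached inverses
                idx = np.argsort(~mask[rows], axis=1, kind="stable")[:, :s]
                b = np.take_along_axis(Tc[rows], idx, axis=1)
                stat = np.einsum("nij,ni,nj->n", inv_rows, b, b)
                CP[start + rows, q] = np.maximum(stats.chi2.sf(stat, df=int(s)), _P_FLOOR)
    return CP
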
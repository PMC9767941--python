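"""Effect-based inverse-covariance weighting (EbICoW) and its iterative driver.

EbICoW generalizes inverse-variance-weighted (IVW) meta-analysis to K
correlated GWASs. Per variant, with weights e = 1/sigma, background
correlation Psi and effect vector h (a row projection of the expected
true-effect covariance), the combined statistic is::

    t_E = (h o e') Psi^{-1} t / sqrt((h o e') Psi^{-1} (h o e')')

which is standard normal under the null for ANY h; h only moves power.
With Psi = I and h proportional to the all-ones vector this is exactly
classical IVW; with h proportional to ones and general Psi it matches the
1-df homogeneous cross-phenotype statistic (S_Hom). The combination
direction follows sign(Pi - Psi): when the effect correlation is below the
background correlation, the second trait enters with flipped sign, which
strictly gains power.

The iterative driver (i-EbICoW) repeatedly combines the pair with the
largest |Pi - Psi| entry, accepting a combination only when it dominates
both the pairwise Wald test and the per-variant minimum p-value on a
threshold grid while staying null-calibrated; pairs with psi^2 above a
collinearity threshold are combined unconditionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (
    EffectModel,
    estimate_effect_model,
    estimate_inflation,
    estimate_psi_matrix,
    nearest_positive_definite,
)
from .summary_io import GwasPanel, GwasTable, chi2_sf1, sample_unlinked
from .twt import wald_genome

logger = logging.getLogger("cgwas")

_TINY = 1e-30
#: preference order of the three effect-rule variants on ties
VARIANT_ORDER = ("all", "sig", "stb")
PROBE_THRESHOLDS = (1e-3, 1e-4, 1e-5, 1e-6)
NULL_BAND = (0.95, 1.05)


# ---------------------------------------------------------------------------
# the statistic


def ebicow_statistic(
    t: np.ndarray,
    sigma: np.ndarray,
    Psi: np.ndarray,
    h: np.ndarray,
    sign_row: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Combine one variant's K statistics; returns (t_E, beta_c, se_c).

    ``beta_c = w' beta`` with weights normalized so that ``w' sign_row = 1``
    (direction-preserving); ``se_c = sqrt(w' C w)`` with C = Psi o sigma
    sigma'; ``t_E = beta_c / se_c``.
    """
    t = np.asarray(t, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    h = np.asarray(h, dtype=float)
    if sign_row is None:
        sign_row = np.ones_like(h)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    he = h / sigma
    w_dir = np.linalg.solve(Psi, he)  # (h o e) Psi^{-1}
    den = float(he @ w_dir)
    if den <= _TINY:
        raise ValueError("degenerate effect vector: h'C^{-1}h is not positive")
    d = float((w_dir / sigma) @ sign_row)  # h C^{-1} sign_row'
    d = d if abs(d) > _TINY else _TINY
    num = float(w_dir @ t)
    beta_c = num / d
    se_c = np.sqrt(den) / abs(d)
    return beta_c / se_c, beta_c, se_c


def _combine_arrays(
    T: np.ndarray, SE: np.ndarray, Psi: np.ndarray, model: EffectModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EbICoW over M variants; returns (t_E, beta_c, se_c) arrays."""
    HE = model.h_times_e(SE)  # M x K rows of (h o e)
    W = HE @ np.linalg.inv(Psi)
    num = np.einsum("mk,mk->m", W, T)
    den = np.einsum("mk,mk->m", W, HE)
    den = np.maximum(den, _TINY)
    d = np.einsum("mk,mk->m", W / SE, np.broadcast_to(model.sign_row, SE.shape))
    d = np.where(np.abs(d) > _TINY, d, _TINY)
    beta_c = num / d
    se_c = np.sqrt(den) / np.abs(d)
    return np.sign(d) * num / np.sqrt(den), beta_c, se_c


def combine_pair(
    g_i: GwasTable,
    g_j: GwasTable,
    Psi_pair: np.ndarray,
    model: EffectModel,
    label: str | None = None,
) -> GwasTable:
    """Combine two aligned GWAS tables into one EbICoW GWAS."""
    if not g_i.variant_id.equals(g_j.variant_id):
        raise ValueError("tables are not aligned on the same variants")
    T = np.column_stack([g_i.df["t"], g_j.df["t"]])
    SE = np.column_stack([g_i.df["se"], g_j.df["se"]])
    t_e, beta_c, se_c = _combine_arrays(T, SE, Psi_pair, model)
    n_pair = np.asarray(g_i.df["n"], float) + np.asarray(g_j.df["n"], float)
    # effective n: 1/se_c^2 rescaled onto the input sample-size scale (bookkeeping only)
    kappa = float(np.median(n_pair * se_c**2))
    d = g_i.df[["variant_id", "effect_allele", "other_allele"]].copy()
    d["beta"] = beta_c
    d["se"] = se_c
    d["n"] = kappa / se_c**2
    d["t"] = t_e
    d["p"] = chi2_sf1(t_e**2)
    for col in ("chrom", "pos"):
        if col in g_i.df.columns:
            d[col] = g_i.df[col].to_numpy()
    return GwasTable(d.reset_index(drop=True), label or f"{g_i.label}+{g_j.label}")


# ---------------------------------------------------------------------------
# decision machinery


def null_calibration_s(t_e: np.ndarray) -> float:
    """Estimated null variance of a combined statistic (deflation allowed).

    The plain mean of t_E^2 is contaminated by true effects, so the null
    variance is read off the same mixture quantile fit used for inflation
    estimation, with the clamp at 1 released.
    """
    return estimate_inflation(np.asarray(t_e, float), allow_deflation=True).s_raw


def _tippett2(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return -np.expm1(2.0 * np.log1p(-np.asarray(p, float)))


def optimize_pair(
    g_i: GwasTable,
    g_j: GwasTable,
    Psi_pair: np.ndarray,
    L: float = 1e-5,
    probe: float = 1e-5,
) -> tuple[GwasTable, str, bool, dict]:
    """Build the three candidate combinations and pick the most powerful one.

    Candidates use the genome-wide (``all``), significant-variant (``sig``)
    and stabilized all-ones (``stb``) effect rules. Among candidates whose
    estimated null variance lies in the calibration band, the one detecting
    the most variants at the probe threshold wins; ties keep the earlier
    rule in the stability order all > sig > stb. When every candidate fails
    the calibration band the best-count candidate is still returned, flagged
    for rejection upstream.
    """
    T = np.column_stack([g_i.df["t"], g_j.df["t"]])
    details = {}
    best_key = None
    for variant in VARIANT_ORDER:
        _, model, _ = estimate_effect_model(T, Psi_pair, variant=variant, L=L)
        tbl = combine_pair(g_i, g_j, Psi_pair, model)
        s_raw = null_calibration_s(tbl.df["t"].to_numpy())
        ok = NULL_BAND[0] <= s_raw <= NULL_BAND[1]
        count = int((tbl.df["p"] < probe).sum())
        details[variant] = {"table": tbl, "ok": ok, "count": count, "s_raw": s_raw}
        key = (ok, count)
        if best_key is None or key > best_key:
            best_key, best_variant = key, variant
    info = details[best_variant]
    return info["table"], best_variant, bool(info["ok"]), details


def evaluate_combination(
    g_E: GwasTable,
    p_wald: np.ndarray,
    p_min: np.ndarray,
    *,
    s_raw: float | None = None,
    thresholds: tuple[float, ...] = PROBE_THRESHOLDS,
) -> bool:
    """Accept a combined GWAS only if it dominates Wald and min-p in power.

    At each probe threshold the count of variants passed by the combination
    must be at least the count passed by the pairwise Wald test and by the
    per-variant minimum p (Tippett-normalized to the same alpha); on top of
    that the improvement at the densest threshold must clear a Poisson-scale
    noise margin — without it, count ties on effect-free pairs let pure
    noise through — and the combination's estimated null variance must sit
    in the calibration band.
    """
    p_e = g_E.df["p"].to_numpy()
    p_min_adj = _tippett2(p_min)
    for k, a in enumerate(thresholds):
        c_e = int((p_e < a).sum())
        c_other = max(int((np.asarray(p_wald) < a).sum()), int((p_min_adj < a).sum()))
        if c_e < c_other:
            return False
        if k == 0 and c_e - c_other < 2.0 * np.sqrt(c_other + 1.0):
            return False
    if s_raw is None:
        s_raw = null_calibration_s(g_E.df["t"].to_numpy())
    return NULL_BAND[0] <= s_raw <= NULL_BAND[1]


# ---------------------------------------------------------------------------
# the iteration


@dataclass
class IterationState:
    """Outcome of the i-EbICoW loop."""

    D: np.ndarray
    F: float
    U: int
    force_psi2: float
    log: list[dict] = field(default_factory=list)
    Psi: np.ndarray = None  # type: ignore[assignment]  # final K_out x K_out estimate
    lineage: np.ndarray = None  # type: ignore[assignment]  # K_out x K_in linear weights on inputs
    labels: list[str] = field(default_factory=list)


def _argmax_pair(mat: np.ndarray) -> tuple[int, int]:
    """Lexicographically smallest (i, j) attaining the matrix maximum."""
    i, j = np.unravel_index(int(np.argmax(mat)), mat.shape)
    return (i, j) if i < j else (j, i)


def _lineage_coeffs(model: EffectModel, Psi_pair: np.ndarray, sigma_ref: np.ndarray) -> np.ndarray:
    """Linear coefficients of the combined t on the two input t's at reference sigma."""
    he = model.h_times_e(sigma_ref[None, :])[0]
    w = np.linalg.solve(Psi_pair, he)
    den = max(float(he @ w), _TINY)
    d = float((w / sigma_ref) @ model.sign_row)
    sign = 1.0 if d >= 0 else -1.0
    return sign * w / np.sqrt(den)


def iterative_ebicow(
    panel: GwasPanel,
    F: float = 0.05,
    force_psi2: float = 0.5,
    *,
    L: float = 1e-5,
    Psi0: np.ndarray | None = None,
    exact_psi: bool = False,
    unlinked_target: int | None = None,
    unlinked_rounds: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[GwasPanel, IterationState]:
    """Iteratively combine GWAS pairs while any |Pi - Psi| entry exceeds F.

    Each round first force-combines any pair with psi^2 above ``force_psi2``
    (collinearity guard, bypassing the accept/reject decision), otherwise
    takes the pair with the maximum D = |Pi - Psi| entry, combines it via
    :func:`optimize_pair` and keeps the result only when
    :func:`evaluate_combination` accepts; a rejected pair has its D entry
    zeroed. Psi, Pi and D are re-estimated after every accepted combination.

    With ``Psi0`` given and ``exact_psi`` set, Psi for combined sets is
    propagated analytically through the stored combination weights instead
    of being re-estimated — the no-estimation-error mode used in null
    studies. The state's ``lineage`` matrix maps the original K input
    T-vectors onto the output GWASs and is what the calibration stage
    replays on simulated null draws.
    """
    tables = list(panel.tables)
    K0 = len(tables)
    M = panel.M
    subsets = sample_unlinked(M, unlinked_target, unlinked_rounds, seed)
    lineage = [np.eye(K0)[k] for k in range(K0)]

    def t_matrix() -> np.ndarray:
        return np.column_stack([t.df["t"].to_numpy() for t in tables])

    def psi_for(tabs_lineage: list[np.ndarray]) -> np.ndarray:
        if exact_psi and Psi0 is not None:
            Wl = np.asarray(tabs_lineage)
            cov = Wl @ Psi0 @ Wl.T
            d = np.sqrt(np.maximum(np.diag(cov), _TINY))
            cov = cov / np.outer(d, d)
            np.fill_diagonal(cov, 1.0)
            return nearest_positive_definite(cov)
        return estimate_psi_matrix(t_matrix(), subsets)

    Psi = np.asarray(Psi0, float) if Psi0 is not None else estimate_psi_matrix(t_matrix(), subsets)
    state = IterationState(D=None, F=F, U=0, force_psi2=force_psi2)  # type: ignore[arg-type]

    def refresh_pi() -> np.ndarray:
        Pi, _, _ = estimate_effect_model(t_matrix(), Psi, variant="all", subsets=subsets)
        D = np.abs(Pi - Psi)
        np.fill_diagonal(D, 0.0)
        return D

    D = refresh_pi()
    while len(tables) > 1:
        off2 = Psi**2
        np.fill_diagonal(off2, 0.0)
        forced = off2.max() > force_psi2
        if forced:
            i, j = _argmax_pair(off2)
        elif D.max() > F:
            i, j = _argmax_pair(D)
        else:
            break
        pair_ix = np.ix_([i, j], [i, j])
        best, variant, calib_ok, _ = optimize_pair(tables[i], tables[j], Psi[pair_ix], L=L)
        if forced:
            accepted = True
        else:
            Tpair = np.column_stack([tables[i].df["t"], tables[j].df["t"]])
            p_wald = wald_genome(Tpair, Psi[pair_ix])
            p_min = np.minimum(tables[i].df["p"].to_numpy(), tables[j].df["p"].to_numpy())
            accepted = calib_ok and evaluate_combination(best, p_wald, p_min)
        state.log.append(
            {
                "pair": (tables[i].label, tables[j].label),
                "variant": variant,
                "status": "forced" if forced else ("accepted" if accepted else "rejected"),
                "psi": float(Psi[i, j]),
                "D": float(D[i, j]),
            }
        )
        if not accepted:
            D[i, j] = D[j, i] = 0.0
            continue
        # rebuild the winning candidate's lineage coefficients
        _, model, _ = estimate_effect_model(
            np.column_stack([tables[i].df["t"], tables[j].df["t"]]), Psi[pair_ix], variant=variant, L=L
        )
        sigma_ref = np.array(
            [float(np.median(tables[i].df["se"])), float(np.median(tables[j].df["se"]))]
        )
        c = _lineage_coeffs(model, Psi[pair_ix], sigma_ref)
        new_lin = c[0] * lineage[i] + c[1] * lineage[j]
        for idx in sorted((i, j), reverse=True):
            tables.pop(idx)
            lineage.pop(idx)
        tables.append(best)
        lineage.append(new_lin)
        state.U += 1
        Psi = psi_for(lineage)
        D = refresh_pi()

    state.D = D
    state.Psi = Psi
    state.lineage = np.asarray(lineage)
    state.labels = [t.label for t in tables]
    out = GwasPanel(tables, labels=state.labels)
    return out, state
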
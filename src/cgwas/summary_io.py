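"""Reading, harmonizing, filtering and writing GWAS summary statistics.

A *GWAS summary-statistics table* carries, per variant, the effect allele,
the other allele, the per-allele effect size ``beta``, its standard error
``se``, the sample size ``n``, the T statistic ``t = beta/se`` and the
two-sided p-value ``p`` (upper tail of a 1-df chi-squared at ``t**2``).
A *panel* is an ordered collection of K such tables aligned on a shared
variant index; every per-variant operation downstream needs the full
K-vector, so variants missing from any table are dropped panel-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cgwas")

#: canonical column order of a summary-statistics table
CORE_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "n", "t", "p"]
OPTIONAL_COLUMNS = ["chrom", "pos"]

_P_FLOOR = 1e-300


def chi2_sf1(x):
    """Upper-tail probability of a 1-df chi-squared variable, floored away from 0."""
    return np.maximum(stats.chi2.sf(x, df=1), _P_FLOOR)


@dataclass
class GwasTable:
    """One GWAS's per-variant summary statistics.

    ``df`` holds at least the :data:`CORE_COLUMNS`; ``chrom``/``pos`` are
    optional (the method never uses LD, so coordinates are bookkeeping only).
    """

    df: pd.DataFrame
    label: str = "gwas"

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"GwasTable missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id values in table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_id(self) -> pd.Index:
        return pd.Index(self.df["variant_id"])

    def validate(self, tol: float = 1e-6) -> None:
        """Check the internal t = beta/se and p = sf(t^2) contracts."""
        d = self.df
        ok = np.isfinite(d["se"]) & (d["se"] > 0)
        if not ok.all():
            raise ValueError("non-positive or non-finite standard errors")
        t_implied = d["beta"] / d["se"]
        if not np.allclose(t_implied, d["t"], atol=tol, rtol=tol):
            raise ValueError("t inconsistent with beta/se")
        p_implied = chi2_sf1(np.asarray(d["t"]) ** 2)
        if not np.allclose(p_implied, d["p"], rtol=1e-4, atol=1e-12):
            raise ValueError("p inconsistent with chi-squared upper tail of t^2")


@dataclass
class GwasPanel:
    """K aligned GWAS tables over M shared variants."""

    tables: list[GwasTable]
    variant_index: pd.Index = field(default=None)  # type: ignore[assignment]
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("panel needs at least one table")
        if self.variant_index is None:
            self.variant_index = self.tables[0].variant_id
        if self.labels is None:
            self.labels = [t.label for t in self.tables]
        for t in self.tables:
            if not t.variant_id.equals(pd.Index(self.variant_index)):
                raise ValueError(f"table {t.label!r} not aligned with the panel variant index")

    @property
    def K(self) -> int:
        return len(self.tables)

    @property
    def M(self) -> int:
        return len(self.variant_index)

    def _stack(self, col: str) -> np.ndarray:
        return np.column_stack([t.df[col].to_numpy(dtype=float) for t in self.tables])

    def t_matrix(self) -> np.ndarray:
        return self._stack("t")

    def p_matrix(self) -> np.ndarray:
        return self._stack("p")

    def se_matrix(self) -> np.ndarray:
        return self._stack("se")

    def beta_matrix(self) -> np.ndarray:
        return self._stack("beta")

    def n_matrix(self) -> np.ndarray:
        return self._stack("n")

    def subset_variants(self, mask_or_idx) -> "GwasPanel":
        tables = [
            GwasTable(t.df.iloc[mask_or_idx].reset_index(drop=True), t.label) for t in self.tables
        ]
        return GwasPanel(tables, labels=list(self.labels))


def table_from_arrays(
    variant_id,
    beta,
    se,
    n,
    *,
    effect_allele=None,
    other_allele=None,
    chrom=None,
    pos=None,
    label: str = "gwas",
) -> GwasTable:
    """Build a table from raw arrays, filling in t and p."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    t = beta / se
    df = pd.DataFrame(
        {
            "variant_id": np.asarray(variant_id),
            "effect_allele": effect_allele if effect_allele is not None else "A",
            "other_allele": other_allele if other_allele is not None else "G",
            "beta": beta,
            "se": se,
            "n": np.asarray(n),
            "t": t,
            "p": chi2_sf1(t**2),
        }
    )
    if chrom is not None:
        df["chrom"] = chrom
    if pos is not None:
        df["pos"] = pos
    return GwasTable(df, label)


# ---------------------------------------------------------------------------
# reading / writing


DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
    "t": "T",
    "p": "P",
    "chrom": "CHR",
    "pos": "POS",
}


def read_gwas(path, column_map: dict | None = None, *, label: str | None = None, sep: str = "\t") -> GwasTable:
    """Read one delimited summary-statistics file into a :class:`GwasTable`.

    ``column_map`` maps canonical names (``variant_id``, ``beta``, ...) to the
    file's header names; unmapped canonical names fall back to
    :data:`DEFAULT_COLUMN_MAP`. Either (``beta``, ``se``) or ``t`` must be
    present; ``t`` and ``p`` are recomputed from ``beta``/``se`` when absent.
    Rows with missing or non-finite required fields (or ``se <= 0``) are
    dropped and counted in the log.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    inv = {v: k for k, v in cmap.items() if v in raw.columns}
    df = raw.rename(columns=inv)

    required = ["variant_id", "effect_allele", "other_allele"]
    missing = [c for c in required if c not in df.columns]
    have_beta = {"beta", "se"}.issubset(df.columns)
    if not have_beta and "t" not in df.columns:
        missing.append("beta/se or t")
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (mapped via {cmap})")

    if not have_beta:
        # t-only input: adopt unit standard errors so beta == t
        df["se"] = 1.0
        df["beta"] = pd.to_numeric(df["t"], errors="coerce")
    for c in ("beta", "se", "n", "t", "p"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    if "n" not in df.columns:
        df["n"] = 1
    keep = (
        df["variant_id"].notna()
        & np.isfinite(df["beta"])
        & np.isfinite(df["se"])
        & (df["se"] > 0)
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("%s: dropped %d rows with missing/invalid fields", path, n_drop)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: zero usable rows")
    df["t"] = df["beta"] / df["se"]
    df["p"] = chi2_sf1(df["t"].to_numpy() ** 2)
    cols = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    name = label if label is not None else str(path)
    return GwasTable(df[cols].copy(), name)


def write_panel(panel: GwasPanel, outdir) -> None:
    """Write a panel as one TSV per GWAS plus a JSON manifest."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for t in panel.tables:
        fname = f"{t.label}.tsv"
        t.df.to_csv(out / fname, sep="\t", index=False, float_format="%.10g")
        files.append(fname)
    (out / "panel.json").write_text(json.dumps({"labels": panel.labels, "files": files}, indent=1))


def read_panel(indir) -> GwasPanel:
    """Read a panel written by :func:`write_panel`."""
    import json
    from pathlib import Path

    src = Path(indir)
    manifest = json.loads((src / "panel.json").read_text())
    tables = [
        GwasTable(pd.read_csv(src / f, sep="\t"), label)
        for label, f in zip(manifest["labels"], manifest["files"])
    ]
    return GwasPanel(tables, labels=manifest["labels"])


def write_results(variant_index, p_values, annotations: pd.DataFrame | None, path) -> None:
    """Write a per-variant results table (TSV, >= 6 significant digits on p)."""
    p_values = np.asarray(p_values, dtype=float)
    if len(variant_index) != len(p_values):
        raise ValueError("variant_index and p_values length mismatch")
    out = pd.DataFrame({"variant_id": np.asarray(variant_index), "p_cgwas": p_values})
    if annotations is not None and len(annotations.columns):
        if len(annotations) != len(out):
            raise ValueError("annotation length mismatch")
        out = pd.concat([out, annotations.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.8e")


# ---------------------------------------------------------------------------
# harmonization and filtering


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def harmonize_panel(tables: list[GwasTable]) -> GwasPanel:
    """Align K tables on their variant intersection with a common allele convention.

    The first table fixes the variant order and the effect/other allele
    orientation. In every other table a variant whose allele pair is the
    swap of the reference pair has beta and t sign-flipped and its alleles
    swapped; a variant with any other allele pair is removed panel-wide.
    Strand-ambiguous variants (A/T, C/G) are kept as-is with a warning.
    """
    if not tables:
        raise ValueError("no tables to harmonize")
    ref = tables[0]
    shared = ref.variant_id
    for t in tables[1:]:
        shared = shared.intersection(t.variant_id)
    if shared.empty:
        raise ValueError("empty variant intersection across tables")
    # keep the first table's order
    shared = ref.variant_id[ref.variant_id.isin(shared)]

    ref_df = ref.df.set_index("variant_id").loc[shared]
    ea0 = ref_df["effect_allele"].astype(str).str.upper()
    oa0 = ref_df["other_allele"].astype(str).str.upper()
    n_ambig = int(sum((a, b) in _AMBIGUOUS for a, b in zip(ea0, oa0)))
    if n_ambig:
        logger.warning("%d strand-ambiguous (A/T or C/G) variants kept as-is", n_ambig)

    aligned = []
    bad = np.zeros(len(shared), dtype=bool)
    for t in tables:
        d = t.df.set_index("variant_id").loc[shared].copy()
        ea = d["effect_allele"].astype(str).str.upper()
        oa = d["other_allele"].astype(str).str.upper()
        same = (ea == ea0) & (oa == oa0)
        swapped = (ea == oa0) & (oa == ea0)
        bad |= (~same & ~swapped).to_numpy()
        flip = swapped.to_numpy()
        d.loc[flip, ["beta", "t"]] *= -1.0
        d.loc[flip, "effect_allele"] = ea0[flip]
        d.loc[flip, "other_allele"] = oa0[flip]
        aligned.append((t.label, d))

    if bad.any():
        logger.warning("removed %d variants with incompatible allele pairs", int(bad.sum()))
    keep = ~bad
    out = []
    for label, d in aligned:
        d = d.loc[keep].reset_index()
        cols = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in d.columns]
        out.append(GwasTable(d[cols], label))
    if not len(out[0]):
        raise ValueError("no variants left after allele harmonization")
    return GwasPanel(out)


def filter_by_sample_size(panel: GwasPanel, min_frac: float = 0.6) -> GwasPanel:
    """Drop, panel-wide, variants under-sampled in any GWAS.

    A variant is removed when its ``n`` in any table is below
    ``min_frac`` times that table's maximum ``n``. Reduced per-variant sample
    sizes inflate the estimation error of the effect-correlation matrix, so
    such variants are excluded before any estimation.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    n = panel.n_matrix()
    keep = (n >= min_frac * n.max(axis=0, keepdims=True)).all(axis=1)
    if not keep.any():
        raise ValueError("sample-size filter removed all variants")
    if not keep.all():
        logger.info("sample-size filter removed %d of %d variants", int((~keep).sum()), panel.M)
        return panel.subset_variants(np.flatnonzero(keep))
    return panel


def sample_unlinked(
    panel_or_m, target_count: int | None = None, rounds: int = 5, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Systematic-sampling subsets of the variant index for the estimators.

    Returns ``rounds`` index arrays, each taking every ``floor(M/target)``-th
    variant in input (genomic) order from a distinct random start offset.
    Estimates computed per round are combined downstream by the median, which
    damps the residual correlation within any single systematic draw.
    """
    M = panel_or_m if isinstance(panel_or_m, (int, np.integer)) else panel_or_m.M
    if target_count is None:
        target_count = min(M, 100_000)
    if target_count < 2:
        raise ValueError("target_count must be >= 2")
    if M < target_count:
        raise ValueError("fewer variants than target_count")
    stride = max(M // target_count, 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_offsets = min(rounds, stride)
    offsets = rng.choice(stride, size=n_offsets, replace=False)
    if rounds > stride:  # more rounds than distinct offsets: reuse cyclically
        offsets = np.resize(offsets, rounds)
    return [np.arange(off, M, stride)[:target_count] for off in offsets]
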
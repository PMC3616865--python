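"""Feature trends across phylostrata.

Operations on a gene table (one row per locus: age stratum, chromosome,
strand, TSS, structural features):

* per-stratum distribution summaries (count, median, quartiles);
* Spearman rank correlation of per-stratum *means* against stratum index,
  the single-number trend summary used to compare genomes;
* permutation-calibrated two-sample Kolmogorov-Smirnov tests asking, for
  each stratum, whether a feature's distribution differs from the rest of
  the genome (labels are shuffled over loci to build the null);
* a positional-randomness test asking whether genes of one stratum are
  scattered over a chromosome like genes in general, or clustered.

Empirical p-values use the add-one estimator p = (1 + #{D* >= D}) / (B + 1)
so that a finite number of permutations can never report p = 0.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENE_TABLE_COLUMNS",
    "NUMERIC_FEATURES",
    "validate_gene_table",
    "summarize_by_stratum",
    "stratum_means",
    "spearman_trend",
    "feature_trend_table",
    "permutation_ks_by_stratum",
    "chromosomal_randomness",
    "exon_length_youngest_ttest",
]

GENE_TABLE_COLUMNS = (
    "id",
    "stratum",
    "chromosome",
    "strand",
    "tss",
    "gene_length",
    "orf_length",
    "exon_count",
    "mean_exon_length",
    "domain_count",
)

NUMERIC_FEATURES = (
    "gene_length",
    "orf_length",
    "exon_count",
    "mean_exon_length",
    "domain_count",
)


def validate_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and internal consistency of a gene table."""
    missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()[:5]
        raise ValueError(f"duplicate locus ids: {dupes}")
    if not table["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if (table["exon_count"] < 1).any():
        raise ValueError("exon_count must be >= 1")
    if (table["orf_length"] > table["gene_length"]).any():
        raise ValueError("orf_length may not exceed gene_length")
    if (table["mean_exon_length"] > table["gene_length"]).any():
        raise ValueError("mean_exon_length may not exceed gene_length")
    return table


def _feature_values(table: pd.DataFrame, feature: str) -> pd.Series:
    if feature not in NUMERIC_FEATURES:
        raise KeyError(
            f"unknown feature {feature!r}; choose one of {NUMERIC_FEATURES}"
        )
    return table[feature]


def summarize_by_stratum(
    table: pd.DataFrame, feature: str, n_strata: int | None = None
) -> pd.DataFrame:
    """Count, median and quartiles of ``feature`` for every stratum.

    Strata with no genes are reported with n = 0 and NaN summaries so the
    output always spans 1..P.
    """
    values = _feature_values(table, feature)
    p = int(n_strata or table["stratum"].max())
    grouped = values.groupby(table["stratum"])
    out = pd.DataFrame(index=pd.RangeIndex(1, p + 1, name="stratum"))
    out["n"] = grouped.size().reindex(out.index, fill_value=0).astype(int)
    out["median"] = grouped.median().reindex(out.index)
    out["q1"] = grouped.quantile(0.25).reindex(out.index)
    out["q3"] = grouped.quantile(0.75).reindex(out.index)
    out["mean"] = grouped.mean().reindex(out.index)
    return out.reset_index()


def stratum_means(
    table: pd.DataFrame, feature: str, n_strata: int | None = None
) -> pd.Series:
    """Per-stratum means of a feature, indexed 1..P (NaN for empty strata)."""
    values = _feature_values(table, feature)
    p = int(n_strata or table["stratum"].max())
    means = values.groupby(table["stratum"]).mean()
    return means.reindex(pd.RangeIndex(1, p + 1, name="stratum"))


def spearman_trend(per_stratum_means: Sequence[float] | pd.Series) -> float:
    """Spearman's rho between stratum index and per-stratum mean value.

    Strata with undefined means (no genes) are excluded; at least three
    usable strata are required. Average ranks are used under ties; if the
    means are constant the correlation is undefined and NaN is returned
    with a warning.
    """
    means = pd.Series(per_stratum_means).astype(float)
    if not isinstance(means.index, pd.RangeIndex) or means.index.start == 0:
        # treat positional input as strata 1..P
        means.index = pd.RangeIndex(1, len(means) + 1)
    usable = means.dropna()
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 strata with defined means, got {len(usable)}"
        )
    if usable.nunique() == 1:
        warnings.warn("constant per-stratum means: Spearman rho undefined")
        return float("nan")
    rho, _ = stats.spearmanr(usable.index.to_numpy(), usable.to_numpy())
    return float(rho)


def feature_trend_table(
    table: pd.DataFrame,
    features: Iterable[str] = NUMERIC_FEATURES,
    n_strata: int | None = None,
) -> pd.DataFrame:
    """Trend summary across features: Spearman rho of per-stratum means."""
    rows = []
    for feature in features:
        means = stratum_means(table, feature, n_strata=n_strata)
        rows.append({"feature": feature, "spearman_rho": spearman_trend(means)})
    return pd.DataFrame(rows)


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample KS statistic D = sup |F_x - F_y|.

    Small vectorized routine used inside permutation loops, where the
    overhead of a full test call dominates; agrees with
    ``scipy.stats.ks_2samp(...).statistic``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def _permutation_pvalue(observed: float, null: np.ndarray) -> float:
    return float((1 + np.sum(null >= observed)) / (null.size + 1))


def permutation_ks_by_stratum(
    table: pd.DataFrame,
    feature: str,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    flag_alpha: float = 0.01,
) -> pd.DataFrame:
    """Stratum-vs-rest KS test with a label-shuffling permutation null.

    For each stratum s the observed statistic is D between the feature
    values of genes in s and those of all other genes. The null shuffles
    stratum labels over loci: each permutation draws a random subset of the
    same size and recomputes D against its complement. Strata with fewer
    than 2 genes are skipped with a warning.

    Returns a frame with stratum, n, D, p and a ``flagged`` column marking
    p < ``flag_alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = _feature_values(table, feature).to_numpy(dtype=float)
    strata = table["stratum"].to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    for s in np.unique(strata):
        mask = strata == s
        m = int(mask.sum())
        if m < 2 or m > values.size - 2:
            warnings.warn(
                f"stratum {s}: {m} usable values, skipping KS test"
            )
            continue
        observed = ks_statistic(values[mask], values[~mask])
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(values.size)
            sel = np.zeros(values.size, dtype=bool)
            sel[perm[:m]] = True
            null[b] = ks_statistic(values[sel], values[~sel])
        p = _permutation_pvalue(observed, null)
        rows.append(
            {"stratum": int(s), "n": m, "D": observed, "p": p, "flagged": p < flag_alpha}
        )
    return pd.DataFrame(rows, columns=["stratum", "n", "D", "p", "flagged"])


def chromosomal_randomness(
    table: pd.DataFrame,
    stratum: int,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    flag_alpha: float = 0.01,
) -> pd.DataFrame:
    """Are stratum-s genes positioned like a random draw of genes?

    Per chromosome: KS statistic between TSS positions of stratum-s genes
    and TSS positions of all genes on the chromosome; the null resamples
    equally sized random gene subsets of that chromosome. Chromosomes with
    fewer than 2 stratum-s genes are skipped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub in table.groupby("chromosome", sort=True):
        pool = sub["tss"].to_numpy(dtype=float)
        focal = sub.loc[sub["stratum"] == stratum, "tss"].to_numpy(dtype=float)
        m = focal.size
        if m < 2:
            warnings.warn(
                f"chromosome {chrom}: {m} genes of stratum {stratum}, skipping"
            )
            continue
        observed = ks_statistic(focal, pool)
        null = np.empty(n_perm)
        for b in range(n_perm):
            sample = rng.choice(pool, size=m, replace=False)
            null[b] = ks_statistic(sample, pool)
        p = _permutation_pvalue(observed, null)
        rows.append(
            {
                "chromosome": chrom,
                "n_stratum": m,
                "n_total": pool.size,
                "D": observed,
                "p": p,
                "flagged": p < flag_alpha,
            }
        )
    return pd.DataFrame(
        rows, columns=["chromosome", "n_stratum", "n_total", "D", "p", "flagged"]
    )


def exon_length_youngest_ttest(
    table: pd.DataFrame, n_strata: int | None = None
) -> tuple[float, float]:
    """Welch t-test of mean exon length: youngest stratum vs all others.

    Returns (t, p). The youngest stratum is P (default: max observed).
    """
    p = int(n_strata or table["stratum"].max())
    young = table.loc[table["stratum"] == p, "mean_exon_length"]
    rest = table.loc[table["stratum"] != p, "mean_exon_length"]
    if len(young) < 2 or len(rest) < 2:
        raise ValueError("need at least 2 values in each group")
    t, pval = stats.ttest_ind(young, rest, equal_var=False)
    return float(t), float(pval)
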
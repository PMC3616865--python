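"""Per-stratum enrichment of binary gene properties.

Covers two analyses: association of gene transcription start sites with
promoter marks (CpG islands, H3K4me3 peaks, DNaseI hotspots; a gene is
associated when its TSS lies within 1,250 bp of a mark interval), and
membership in expression sets (one gene id per line). Enrichment per
stratum is the log2 odds ratio of the 2x2 table (stratum vs rest, with vs
without the property), tested with the hypergeometric distribution and
corrected across strata (Benjamini-Hochberg for mark profiles, Bonferroni
for expression profiles).

Promoters can additionally be split into unidirectional and bidirectional:
a locus is bidirectional when another locus on the same chromosome and
opposite strand has its TSS within a configurable window (default 1,000
bp, the scale of a shared nucleosome-free region).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MarkSet",
    "EnrichmentProfile",
    "read_bed",
    "read_id_set",
    "associate_tss_with_marks",
    "classify_promotor_directionality",
    "log_odds_enrichment",
    "hypergeom_test",
    "adjust_pvalues",
    "enrichment_profile",
]

DEFAULT_TSS_DISTANCE = 1250
DEFAULT_BIDIRECTIONAL_WINDOW = 1000


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3 (0-based, half-open) with line-numbered validation."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1:3]}"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} must be < end {end}"
                )
            rows.append({"chromosome": fields[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


@dataclass
class MarkSet:
    """A named set of genomic mark intervals (0-based, half-open)."""

    mark_type: str
    intervals: pd.DataFrame  # chromosome, start, end

    def __post_init__(self) -> None:
        missing = {"chromosome", "start", "end"} - set(self.intervals.columns)
        if missing:
            raise ValueError(f"mark intervals lack columns: {sorted(missing)}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("mark intervals must satisfy start < end")

    @classmethod
    def from_bed(cls, path: str | Path, mark_type: str | None = None) -> "MarkSet":
        name = mark_type or Path(path).stem
        return cls(mark_type=name, intervals=read_bed(path))


def read_id_set(path: str | Path) -> set[str]:
    """Read an expression set: one id per line, blank lines ignored."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def _point_interval_distances(
    points: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Min distance from each point to any half-open interval [s, e).

    Distance is 0 inside an interval, otherwise base pairs to the nearest
    covered base. Handles overlapping intervals via a running maximum of
    interval ends in start order.
    """
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    ends = np.maximum.accumulate(ends[order])
    idx = np.searchsorted(starts, points, side="right")
    dist = np.full(points.shape, np.inf)
    has_left = idx > 0
    left_end = ends[np.clip(idx - 1, 0, None)]
    covered = has_left & (points < left_end)
    left_dist = np.where(has_left, points - (left_end - 1), np.inf)
    right_dist = np.where(
        idx < starts.size, starts[np.clip(idx, None, starts.size - 1)] - points, np.inf
    )
    dist = np.minimum(np.maximum(left_dist, 0), np.maximum(right_dist, 0))
    dist[covered] = 0
    return dist


def associate_tss_with_marks(
    table: pd.DataFrame,
    marks: MarkSet,
    max_dist: int = DEFAULT_TSS_DISTANCE,
) -> pd.Series:
    """Boolean per locus: TSS within ``max_dist`` bases of any mark interval.

    The boundary is inclusive (a TSS exactly ``max_dist`` away counts).
    Chromosomes present in the gene table but absent from the marks are
    treated as unassociated and logged once.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    out = pd.Series(False, index=table.index, name=marks.mark_type)
    by_chrom = {c: g for c, g in marks.intervals.groupby("chromosome")}
    missing = []
    for chrom, sub in table.groupby("chromosome"):
        if chrom not in by_chrom:
            missing.append(chrom)
            continue
        iv = by_chrom[chrom]
        dist = _point_interval_distances(
            sub["tss"].to_numpy(dtype=float),
            iv["start"].to_numpy(dtype=float),
            iv["end"].to_numpy(dtype=float),
        )
        out.loc[sub.index] = dist <= max_dist
    if missing:
        logger.warning(
            "%s: no intervals on chromosome(s) %s; genes there treated as unassociated",
            marks.mark_type,
            ",".join(map(str, sorted(missing))),
        )
    return out


def classify_promotor_directionality(
    table: pd.DataFrame, window: int = DEFAULT_BIDIRECTIONAL_WINDOW
) -> pd.Series:
    """Label each locus 'bidirectional' or 'unidirectional'.

    A locus is bidirectional when some other locus on the same chromosome
    and opposite strand has its TSS within ``window`` bases; the relation
    is symmetric.
    """
    labels = pd.Series("unidirectional", index=table.index, name="directionality")
    for _, sub in table.groupby("chromosome"):
        plus = sub[sub["strand"] == "+"]
        minus = sub[sub["strand"] == "-"]
        if plus.empty or minus.empty:
            continue
        minus_sorted = np.sort(minus["tss"].to_numpy(dtype=float))
        plus_tss = plus["tss"].to_numpy(dtype=float)
        lo = np.searchsorted(minus_sorted, plus_tss - window, side="left")
        hi = np.searchsorted(minus_sorted, plus_tss + window, side="right")
        plus_bidi = hi > lo
        labels.loc[plus.index[plus_bidi]] = "bidirectional"
        plus_sorted = np.sort(plus_tss)
        minus_tss = minus["tss"].to_numpy(dtype=float)
        lo = np.searchsorted(plus_sorted, minus_tss - window, side="left")
        hi = np.searchsorted(plus_sorted, minus_tss + window, side="right")
        labels.loc[minus.index[hi > lo]] = "bidirectional"
    return labels


def log_odds_enrichment(k: int, n: int, K: int, N: int) -> float:
    """log2 odds ratio of property frequency in a stratum versus the rest.

    2x2 table: (k, n-k) in the stratum, (K-k, (N-n)-(K-k)) outside. When
    any cell is zero the Haldane-Anscombe correction (+0.5 to every cell)
    keeps the estimate finite. Returns NaN for an empty stratum (n = 0).
    """
    _check_counts(k, n, K, N)
    if n == 0:
        return float("nan")
    a, b = k, n - k
    c, d = K - k, (N - n) - (K - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log2((a * d) / (b * c))


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid totals: n={n}, K={K}, N={N}")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if k > K:
        raise ValueError(f"k={k} exceeds total successes K={K}")
    if n - k > N - K:
        raise ValueError(f"n-k={n - k} exceeds total failures N-K={N - K}")


def hypergeom_test(k: int, n: int, K: int, N: int, tail: str = "over") -> float:
    """Hypergeometric tail probability for k successes in a stratum of n.

    X ~ Hypergeometric(N, K, n). ``tail='over'`` gives P(X >= k),
    ``tail='under'`` gives P(X <= k).
    """
    _check_counts(k, n, K, N)
    dist = stats.hypergeom(N, K, n)
    if tail == "over":
        return float(dist.sf(k - 1))
    if tail == "under":
        return float(dist.cdf(k))
    raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")


def adjust_pvalues(p, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg or Bonferroni."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p <= 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in (0, 1]")
    method = {"bh": "fdr_bh", "fdr": "fdr_bh", "fdr_bh": "fdr_bh",
              "bonferroni": "bonferroni"}.get(method.lower())
    if method is None:
        raise ValueError("method must be 'fdr_bh' (BH) or 'bonferroni'")
    if p.size == 0:
        return p
    return multipletests(p, method=method)[1]


@dataclass
class EnrichmentProfile:
    """Per-stratum enrichment of one binary property."""

    property_name: str
    correction: str
    alpha: float
    K: int
    N: int
    table: pd.DataFrame  # stratum, k, n, log_odds, p_raw, p_adjusted, significant

    def significant_strata(self) -> list[int]:
        return self.table.loc[self.table["significant"], "stratum"].tolist()


def enrichment_profile(
    table: pd.DataFrame,
    prop: pd.Series,
    property_name: str = "property",
    correction: str = "fdr_bh",
    alpha: float = 0.01,
    n_strata: int | None = None,
) -> EnrichmentProfile:
    """Assemble the per-stratum enrichment profile of a boolean property.

    The two-sided p-value is twice the smaller hypergeometric tail, capped
    at 1; the direction of the effect is read from the sign of the log-odds.
    Correction is applied across the P strata.
    """
    prop = prop.reindex(table.index)
    if prop.isna().any():
        raise ValueError("property must be defined for every locus")
    prop = prop.astype(bool)
    p_total = int(n_strata or table["stratum"].max())
    N = len(table)
    K = int(prop.sum())

    rows = []
    for s in range(1, p_total + 1):
        mask = table["stratum"] == s
        n = int(mask.sum())
        k = int(prop[mask].sum())
        lo = log_odds_enrichment(k, n, K, N)
        if n == 0:
            rows.append(
                {"stratum": s, "k": k, "n": n, "log_odds": lo, "p_raw": np.nan}
            )
            continue
        p_over = hypergeom_test(k, n, K, N, tail="over")
        p_under = hypergeom_test(k, n, K, N, tail="under")
        p_two = min(1.0, 2.0 * min(p_over, p_under))
        rows.append(
            {"stratum": s, "k": k, "n": n, "log_odds": lo, "p_raw": p_two}
        )
    out = pd.DataFrame(rows)
    testable = out["p_raw"].notna()
    out["p_adjusted"] = np.nan
    if testable.any():
        out.loc[testable, "p_adjusted"] = adjust_pvalues(
            out.loc[testable, "p_raw"].to_numpy(), method=correction
        )
    out["significant"] = out["p_adjusted"] < alpha
    return EnrichmentProfile(
        property_name=property_name,
        correction=correction,
        alpha=alpha,
        K=K,
        N=N,
        table=out,
    )
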
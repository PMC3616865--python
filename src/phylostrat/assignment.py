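"""Oldest-qualifying-hit age assignment for products and loci.

Each protein product's age is the oldest (smallest-index) phylostratum
containing a homology hit with e-value strictly below the cutoff that
applies to that stratum (default 1e-3 everywhere, overridable per stratum,
e.g. a stricter 1e-15 for strata whose evidence comes from translated
nucleotide searches). Products with no qualifying hit are assigned the
youngest stratum P — they look like lineage-specific orphans. A locus is
as old as its oldest product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phylostrat.lineage import LineageError, PhylostratumMap, normalize_taxon

__all__ = [
    "HomologyHit",
    "AgeAssignment",
    "HitTableError",
    "DEFAULT_CUTOFF",
    "DEFAULT_HIT_COLUMNS",
    "read_hit_table",
    "assign_product_age",
    "assign_product_ages",
    "assign_locus_ages",
]

DEFAULT_CUTOFF = 1e-3

#: BLAST-tabular-style column order with a subject-taxon column inserted.
DEFAULT_HIT_COLUMNS = (
    "query",
    "subject",
    "subject_taxon",
    "pident",
    "length",
    "evalue",
    "bitscore",
)


class HitTableError(ValueError):
    """Malformed homology-hit table."""


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    subject_taxon: str
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not self.query or not self.subject:
            raise HitTableError("query and subject ids must be non-empty")
        if not (self.evalue >= 0) or math.isnan(self.evalue):
            raise HitTableError(
                f"e-value must be a non-negative number, got {self.evalue!r}"
            )


@dataclass
class AgeAssignment:
    """Product and locus ages plus the cutoffs that produced them."""

    product_ages: dict[str, int]
    locus_ages: dict[str, int]
    cutoffs_used: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": pid, "level": "product", "stratum": s}
            for pid, s in sorted(self.product_ages.items())
        ] + [
            {"id": lid, "level": "locus", "stratum": s}
            for lid, s in sorted(self.locus_ages.items())
        ]
        return pd.DataFrame(rows, columns=["id", "level", "stratum"])


def read_hit_table(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_HIT_COLUMNS,
) -> list[HomologyHit]:
    """Parse a TSV hit table into :class:`HomologyHit` records.

    ``columns`` declares the file's column order; it must include ``query``,
    ``subject``, ``subject_taxon`` and ``evalue``. Lines starting with ``#``
    are skipped. Errors carry 1-based line numbers.
    """
    required = {"query", "subject", "subject_taxon", "evalue"}
    missing = required - set(columns)
    if missing:
        raise HitTableError(f"column map lacks required columns: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(columns)}

    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(columns):
                raise HitTableError(
                    f"{path}:{lineno}: expected {len(columns)} columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[idx["evalue"]])
            except ValueError:
                raise HitTableError(
                    f"{path}:{lineno}: malformed e-value {fields[idx['evalue']]!r}"
                ) from None
            try:
                bitscore = float(fields[idx["bitscore"]]) if "bitscore" in idx else 0.0
            except ValueError:
                raise HitTableError(
                    f"{path}:{lineno}: malformed bit score {fields[idx['bitscore']]!r}"
                ) from None
            try:
                hits.append(
                    HomologyHit(
                        query=fields[idx["query"]],
                        subject=fields[idx["subject"]],
                        subject_taxon=fields[idx["subject_taxon"]],
                        evalue=evalue,
                        bitscore=bitscore,
                    )
                )
            except HitTableError as exc:
                raise HitTableError(f"{path}:{lineno}: {exc}") from None
    return hits


def resolve_cutoffs(
    pmap: PhylostratumMap,
    cutoffs: float | Mapping[int, float] | None,
) -> dict[int, float]:
    """Per-stratum e-value thresholds: default everywhere, plus overrides."""
    if cutoffs is None:
        return {s: DEFAULT_CUTOFF for s in range(1, pmap.n_strata + 1)}
    if isinstance(cutoffs, (int, float)):
        return {s: float(cutoffs) for s in range(1, pmap.n_strata + 1)}
    full = {s: DEFAULT_CUTOFF for s in range(1, pmap.n_strata + 1)}
    for stratum, value in cutoffs.items():
        if stratum not in full:
            raise LineageError(f"cutoff override for unknown stratum {stratum}")
        full[int(stratum)] = float(value)
    return full


def assign_product_age(
    hits: Iterable[HomologyHit],
    pmap: PhylostratumMap,
    cutoffs: float | Mapping[int, float] | None = None,
) -> int:
    """Age of one product: the oldest stratum with a qualifying hit.

    A hit qualifies when its e-value is strictly below the cutoff of the
    stratum its subject taxon belongs to. Self-hits (subject taxon equal to
    the focal taxon) carry no age information and are ignored. If nothing
    qualifies the product is an orphan and gets the youngest stratum P.
    """
    table = resolve_cutoffs(pmap, cutoffs)
    focal = normalize_taxon(pmap.focal_taxon)
    best = pmap.n_strata
    for hit in hits:
        taxon = normalize_taxon(hit.subject_taxon)
        if taxon == focal:
            continue
        stratum = pmap.stratum_of(hit.subject_taxon)  # raises on unknown taxa
        if hit.evalue < table[stratum]:
            best = min(best, stratum)
    return best


def assign_product_ages(
    hits: Iterable[HomologyHit],
    pmap: PhylostratumMap,
    cutoffs: float | Mapping[int, float] | None = None,
    products: Iterable[str] | None = None,
) -> dict[str, int]:
    """Vectorized age assignment for a whole hit table.

    ``products`` may list ids with no hits at all (orphans); they are
    assigned the youngest stratum.
    """
    table = resolve_cutoffs(pmap, cutoffs)
    p = pmap.n_strata
    focal = normalize_taxon(pmap.focal_taxon)

    records = [
        (h.query, normalize_taxon(h.subject_taxon), h.evalue) for h in hits
    ]
    ages: dict[str, int] = {}
    if records:
        df = pd.DataFrame(records, columns=["query", "taxon", "evalue"])
        df = df[df["taxon"] != focal]
        if not df.empty:
            unknown = sorted(set(df["taxon"]) - set(pmap.taxa))
            if unknown:
                raise LineageError(
                    f"hit table references taxa absent from the map: {unknown}"
                )
            df["stratum"] = df["taxon"].map(pmap.stratum_of)
            df["cutoff"] = df["stratum"].map(table)
            qualifying = df[df["evalue"] < df["cutoff"]]
            ages.update(qualifying.groupby("query")["stratum"].min().astype(int))
        # products seen in the table but with no qualifying hit
        for pid in df["query"].unique() if not df.empty else []:
            ages.setdefault(pid, p)
        for pid, _, _ in records:
            ages.setdefault(pid, p)
    if products is not None:
        for pid in products:
            ages.setdefault(pid, p)
    return ages


def assign_locus_ages(
    product_ages: Mapping[str, int],
    locus_membership: Mapping[str, Sequence[str]],
    cutoffs_used: Mapping[int, float] | None = None,
) -> AgeAssignment:
    """Locus age = oldest (minimum-index) age among its products.

    Every product must belong to exactly one locus and have an assigned age.
    """
    seen: dict[str, str] = {}
    locus_ages: dict[str, int] = {}
    for locus, members in locus_membership.items():
        if not members:
            raise HitTableError(f"locus {locus!r} has no products")
        ages = []
        for pid in members:
            if pid in seen:
                raise HitTableError(
                    f"product {pid!r} assigned to loci {seen[pid]!r} and {locus!r}"
                )
            seen[pid] = locus
            if pid not in product_ages:
                raise HitTableError(f"product {pid!r} has no assigned age")
            ages.append(product_ages[pid])
        locus_ages[locus] = min(ages)
    orphans = sorted(set(product_ages) - set(seen))
    if orphans:
        raise HitTableError(f"products with no locus: {orphans}")
    return AgeAssignment(
        product_ages=dict(product_ages),
        locus_ages=locus_ages,
        cutoffs_used=dict(cutoffs_used or {}),
    )
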
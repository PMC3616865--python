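"""Detection of overprinted genes (alternative reading frames, ARFs).

A locus is a candidate for overprinting when its annotated protein
products map to phylostrata at least two strata apart: a younger protein
apparently born inside an older gene. For every such locus, each younger
product is compared against every product of the oldest stratum, at the
nucleotide and the protein level, with both global and local alignments.

The decision rule follows directly from the biology of a frame shift: the
two ORFs share the underlying DNA, so their nucleotide alignment matches,
but translation in a shifted frame scrambles the amino-acid sequence, so
the protein alignment does not. A pair is called

* ``arf``        - nucleotide-match AND protein-non-match;
* ``same_frame`` - nucleotide-match AND protein-match (e.g. splice
                   variants sharing their frame);
* ``unresolved`` - anything else (including unrelated sequences).

For an ``arf`` verdict the frame offset (1 or 2) is inferred from the
modulo-3 phase of the best local nucleotide alignment's coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phylostrat.align import (
    AlignmentResult,
    ScoringScheme,
    global_align,
    local_align,
    translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Product",
    "LocusProducts",
    "ARFThresholds",
    "ARFCandidate",
    "screen_loci",
    "classify_pair",
    "run_overprint_screen",
    "build_loci",
    "load_table1",
    "screen_stratum_pairs",
]


@dataclass(frozen=True)
class Product:
    """One annotated protein product: ORF nucleotides plus translation."""

    product_id: str
    stratum: int
    orf_nt: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.protein == "" and self.orf_nt:
            object.__setattr__(self, "protein", translate(self.orf_nt, 0))


@dataclass
class LocusProducts:
    locus_id: str
    products: list[Product]

    def __post_init__(self) -> None:
        if not self.products:
            raise ValueError(f"locus {self.locus_id!r} has no products")

    @property
    def age_gap(self) -> int:
        strata = [p.stratum for p in self.products]
        return max(strata) - min(strata)

    @property
    def oldest_stratum(self) -> int:
        return min(p.stratum for p in self.products)


@dataclass(frozen=True)
class ARFThresholds:
    """Match thresholds for the alignment-discordance rule.

    ``t_nt``: minimum local nucleotide percent identity; ``l_min``: minimum
    aligned nucleotide columns; ``t_aa``: minimum local protein percent
    identity (over at least ``l_min``/3 columns). Defaults separate
    same-frame homology from frame-shifted translation with wide margin.
    """

    t_nt: float = 80.0
    l_min: int = 60
    t_aa: float = 40.0


@dataclass
class ARFCandidate:
    locus_id: str
    older: Product
    newer: Product
    verdict: str  # 'arf' | 'same_frame' | 'unresolved'
    frame_offset: int | None
    nt_local: AlignmentResult | None = None
    nt_global: AlignmentResult | None = None
    aa_local: AlignmentResult | None = None
    aa_global: AlignmentResult | None = None
    comment: str = ""

    def to_row(self) -> dict:
        return {
            "locus": self.locus_id,
            "newer_product": self.newer.product_id,
            "older_product": self.older.product_id,
            "newer_stratum": self.newer.stratum,
            "older_stratum": self.older.stratum,
            "verdict": self.verdict,
            "frame_offset": self.frame_offset,
            "nt_local_identity": _fmt(self.nt_local),
            "nt_global_identity": _fmt(self.nt_global),
            "aa_local_identity": _fmt(self.aa_local),
            "aa_global_identity": _fmt(self.aa_global),
            "comment": self.comment,
        }


def _fmt(result: AlignmentResult | None) -> float | None:
    return round(result.identity, 2) if result is not None else None


def screen_loci(
    loci: Iterable[LocusProducts], min_gap: int = 2
) -> list[LocusProducts]:
    """Keep loci whose product ages differ by at least ``min_gap`` strata.

    The gap guard avoids screening borderline classifications between
    adjacent phylostrata.
    """
    return [loc for loc in loci if loc.age_gap >= min_gap]


def candidate_pairs(locus: LocusProducts) -> list[tuple[Product, Product]]:
    """(older, newer) pairs: every younger product against every product of
    the oldest stratum."""
    oldest = locus.oldest_stratum
    olders = [p for p in locus.products if p.stratum == oldest]
    newers = [p for p in locus.products if p.stratum > oldest]
    return list(itertools.product(olders, newers))


def classify_pair(
    older: Product,
    newer: Product,
    thresholds: ARFThresholds | None = None,
    nt_scheme: ScoringScheme | None = None,
    aa_scheme: ScoringScheme | None = None,
) -> ARFCandidate:
    """Classify one (older, newer) product pair by alignment discordance.

    Local alignments drive the match decisions; global alignments are
    computed and reported for transparency.
    """
    thr = thresholds or ARFThresholds()
    nt_scheme = nt_scheme or ScoringScheme.nucleotide_default()
    aa_scheme = aa_scheme or ScoringScheme.protein_default()

    if not older.orf_nt or not newer.orf_nt:
        return ARFCandidate(
            locus_id="",
            older=older,
            newer=newer,
            verdict="unresolved",
            frame_offset=None,
            comment="missing sequence",
        )

    nt_local = local_align(older.orf_nt, newer.orf_nt, nt_scheme)
    nt_global = global_align(older.orf_nt, newer.orf_nt, nt_scheme)
    aa_local = local_align(older.protein, newer.protein, aa_scheme)
    aa_global = global_align(older.protein, newer.protein, aa_scheme)

    nt_match = nt_local.identity >= thr.t_nt and nt_local.n_columns >= thr.l_min
    aa_match = (
        aa_local.identity >= thr.t_aa
        and aa_local.n_columns >= thr.l_min / 3
    )

    if nt_match and not aa_match:
        verdict = "arf"
        offset = (nt_local.a_start - nt_local.b_start) % 3
    elif nt_match and aa_match:
        verdict, offset = "same_frame", None
    else:
        verdict, offset = "unresolved", None

    return ARFCandidate(
        locus_id="",
        older=older,
        newer=newer,
        verdict=verdict,
        frame_offset=offset,
        nt_local=nt_local,
        nt_global=nt_global,
        aa_local=aa_local,
        aa_global=aa_global,
    )


def build_loci(
    locus_membership: Mapping[str, Sequence[str]],
    product_ages: Mapping[str, int],
    sequences: Mapping[str, str],
) -> list[LocusProducts]:
    """Assemble LocusProducts from ids, ages and ORF sequences.

    Products with no sequence are carried with an empty ORF so the screen
    can report them as unresolved rather than dropping them silently.
    """
    loci = []
    for locus_id, members in sorted(locus_membership.items()):
        products = []
        for pid in sorted(members):
            if pid not in product_ages:
                raise KeyError(f"product {pid!r} has no assigned age")
            orf = sequences.get(pid, "")
            if not orf:
                logger.warning("product %s: no ORF sequence available", pid)
            products.append(
                Product(product_id=pid, stratum=int(product_ages[pid]), orf_nt=orf)
            )
        loci.append(LocusProducts(locus_id=locus_id, products=products))
    return loci


def run_overprint_screen(
    loci: Iterable[LocusProducts],
    min_gap: int = 2,
    thresholds: ARFThresholds | None = None,
    nt_scheme: ScoringScheme | None = None,
    aa_scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Run the full screen and return a report, one row per product pair.

    The report is sorted by locus and product ids, so shuffled input
    produces an identical table.
    """
    rows = []
    for locus in screen_loci(loci, min_gap=min_gap):
        for older, newer in candidate_pairs(locus):
            cand = classify_pair(older, newer, thresholds, nt_scheme, aa_scheme)
            cand.locus_id = locus.locus_id
            rows.append(cand.to_row())
    columns = [
        "locus",
        "newer_product",
        "older_product",
        "newer_stratum",
        "older_stratum",
        "verdict",
        "frame_offset",
        "nt_local_identity",
        "nt_global_identity",
        "aa_local_identity",
        "aa_global_identity",
        "comment",
    ]
    report = pd.DataFrame(rows, columns=columns)
    return report.sort_values(
        ["locus", "newer_product", "older_product"], ignore_index=True
    )


def load_table1() -> pd.DataFrame:
    """The packaged 13-row worked-example table of overprinted mouse genes.

    Columns include the (newer, older) stratum pair per locus and a
    ``previously_known`` flag for the two literature-described cases
    (Cdkn2a, Gnas).
    """
    data = resources.files("phylostrat.data") / "table1_overprints.tsv"
    with resources.as_file(data) as path:
        df = pd.read_csv(path, sep="\t")
    df["previously_known"] = df["previously_known"].astype(bool)
    return df


def screen_stratum_pairs(pairs: pd.DataFrame, min_gap: int = 2) -> pd.DataFrame:
    """Apply the age-difference filter to a table of stratum pairs.

    Expects columns ``newer_stratum`` and ``older_stratum``; keeps rows
    with newer - older >= ``min_gap``.
    """
    gap = pairs["newer_stratum"] - pairs["older_stratum"]
    return pairs[gap >= min_gap].reset_index(drop=True)
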
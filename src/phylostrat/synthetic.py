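"""Synthetic genomes with known ground truth.

The generator emulates the statistical structure of the real inputs of a
phylostratigraphic study — without any external downloads — so that every
pipeline stage has a testable oracle:

* per-stratum gene features drawn from log-normal (lengths) and shifted
  Poisson (counts) families whose means interpolate log-linearly between a
  ps1 value and a psP value: young genes are shorter, have fewer exons and
  fewer domains when the trend endpoints say so;
* homology-hit tables in which a gene of true stratum s hits taxa of
  strata s..P (minus configurable false negatives), plus non-qualifying
  decoy hits at or above the e-value cutoff;
* promoter-mark intervals placed within 1,250 bp of associated TSSs, with
  the association odds boosted in the youngest stratum and concentrated on
  bidirectional (divergent-pair) promoters;
* overprinted loci built by a frame-shift constructor: a new ORF embedded
  in an existing one at frame offset 1 or 2, sharing its nucleotides but
  not its protein.

Gene placement leaves at least ``min_tss_spacing`` between unrelated
transcription units, so a mark planted for one gene can never leak into
another gene's promoter window and the emitted files reproduce the truth
exactly under noise-free settings.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from phylostrat.align import write_fasta
from phylostrat.assignment import DEFAULT_HIT_COLUMNS, HomologyHit
from phylostrat.enrichment import MarkSet
from phylostrat.lineage import PhylostratumMap, load_lineage, mouse_lineage

__all__ = [
    "FeatureTrend",
    "MarkParams",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_gene_table",
    "make_overprint_pair",
    "make_synthetic_lineage",
    "write_fixture_tables",
    "noise_free_preset",
    "paper_like_preset",
    "zero_trend_preset",
    "get_preset",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
MARK_TYPES = ("cpg", "h3k4me3", "dnase")


@dataclass(frozen=True)
class FeatureTrend:
    """Mean value at ps1 and psP plus dispersion; interpolation is
    log-linear in the stratum index."""

    start: float
    end: float
    sigma: float = 0.4

    def mean_at(self, stratum: int, p: int) -> float:
        if p == 1:
            return self.start
        frac = (stratum - 1) / (p - 1)
        return float(self.start * (self.end / self.start) ** frac)


@dataclass(frozen=True)
class MarkParams:
    """Promoter-mark association rates.

    ``background_rate`` applies everywhere; in the youngest stratum the
    association odds are multiplied by ``top_stratum_odds`` for
    unidirectional loci and additionally by ``bidirectional_boost`` for
    bidirectional ones — young genes ride on existing (mostly divergent)
    promoters.
    """

    background_rate: float = 0.30
    top_stratum_odds: float = 2.0
    bidirectional_boost: float = 4.0

    def rate(self, stratum: int, p: int, bidirectional: bool) -> float:
        odds = self.background_rate / (1.0 - self.background_rate)
        if stratum == p:
            odds *= self.top_stratum_odds
            if bidirectional:
                odds *= self.bidirectional_boost
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class GeneratorConfig:
    n_strata: int = 20
    genes_per_stratum: int = 300
    gene_length: FeatureTrend = FeatureTrend(30_000, 2_500, 0.6)
    orf_length: FeatureTrend = FeatureTrend(1_500, 450, 0.35)
    exon_count: FeatureTrend = FeatureTrend(9.0, 1.3)
    domain_count: FeatureTrend = FeatureTrend(3.0, 0.25)
    exon_length: FeatureTrend = FeatureTrend(250.0, 250.0, 0.3)
    youngest_exon_boost: float = 1.5
    marks: MarkParams = MarkParams()
    bidirectional_fraction: float = 0.25
    bidirectional_window: int = 1_000
    expression_background: float = 0.20
    expression_enriched_from: int = 15
    expression_odds: float = 3.0
    hit_false_negative_rate: float = 0.0
    nonqualifying_hit_rate: float = 0.2
    self_hit_rate: float = 0.1
    n_overprints: int = 13
    overprint_shared_length: int = 150
    n_sameframe_decoys: int = 2
    n_unrelated_decoys: int = 3
    n_chromosomes: int = 5
    min_tss_spacing: int = 10_000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_strata < 3:
            raise ValueError("need at least 3 strata")
        for name in (
            "bidirectional_fraction",
            "expression_background",
            "hit_false_negative_rate",
            "nonqualifying_hit_rate",
            "self_hit_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a rate in [0, 1], got {value}")
        if self.genes_per_stratum < 1 or self.n_chromosomes < 1:
            raise ValueError("genes_per_stratum and n_chromosomes must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth consistent with the emitted files."""

    product_ages: dict[str, int]
    locus_ages: dict[str, int]
    mark_assoc: pd.DataFrame  # index: locus id; one bool column per mark
    bidirectional: pd.Series  # bool per locus (intended divergent pairs)
    expressed: set[str]
    overprints: list[dict]
    decoys: list[dict]


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    pmap: PhylostratumMap
    newick: str
    stratum_spec: pd.DataFrame
    gene_table: pd.DataFrame
    products: pd.DataFrame  # product_id, locus_id, stratum_true
    hits: list[HomologyHit]
    marks: dict[str, MarkSet]
    expressed: set[str]
    sequences: dict[str, str]
    truth: SyntheticTruth

    def locus_membership(self) -> dict[str, list[str]]:
        return {
            locus: sorted(group["product_id"])
            for locus, group in self.products.groupby("locus_id")
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_table.to_csv(outdir / "gene_table.tsv", sep="\t", index=False)
        self.products.to_csv(outdir / "products.tsv", sep="\t", index=False)
        with open(outdir / "hits.tsv", "w") as fh:
            fh.write("#" + "\t".join(DEFAULT_HIT_COLUMNS) + "\n")
            for h in self.hits:
                fh.write(
                    f"{h.query}\t{h.subject}\t{h.subject_taxon}\t100.0\t100\t"
                    f"{h.evalue:.3e}\t{h.bitscore:.1f}\n"
                )
        for name, ms in self.marks.items():
            iv = ms.intervals.sort_values(["chromosome", "start"])
            iv.to_csv(outdir / f"{name}.bed", sep="\t", index=False, header=False)
        with open(outdir / "expressed.txt", "w") as fh:
            for gid in sorted(self.expressed):
                fh.write(gid + "\n")
        write_fasta(self.sequences, outdir / "sequences.fasta")
        (outdir / "lineage.nwk").write_text(self.newick)
        self.stratum_spec.to_csv(outdir / "strata.tsv", sep="\t", index=False)
        truth = {
            "product_ages": self.truth.product_ages,
            "locus_ages": self.truth.locus_ages,
            "mark_assoc": {
                mark: sorted(self.truth.mark_assoc.index[self.truth.mark_assoc[mark]])
                for mark in self.truth.mark_assoc.columns
            },
            "bidirectional": sorted(
                self.truth.bidirectional.index[self.truth.bidirectional]
            ),
            "expressed": sorted(self.truth.expressed),
            "overprints": self.truth.overprints,
            "decoys": self.truth.decoys,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def make_synthetic_lineage(
    n_strata: int, focal: str = "Focal_species"
) -> tuple[str, pd.DataFrame]:
    """A caterpillar lineage with two placeholder taxa per stratum."""
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    rows = []
    inner = f"(s{n_strata}a,{focal})"
    rows.append({"taxon": f"s{n_strata}a", "stratum": n_strata,
                 "stratum_name": f"ps{n_strata}"})
    rows.append({"taxon": focal, "stratum": n_strata,
                 "stratum_name": f"ps{n_strata}"})
    for i in range(n_strata - 1, 0, -1):
        inner = f"((s{i}a,s{i}b),{inner})"
        for suffix in ("a", "b"):
            rows.append({"taxon": f"s{i}{suffix}", "stratum": i,
                         "stratum_name": f"ps{i}"})
    spec = pd.DataFrame(rows).sort_values(["stratum", "taxon"], ignore_index=True)
    return inner + ";", spec


def _lineage_for(config: GeneratorConfig) -> tuple[PhylostratumMap, str, pd.DataFrame]:
    if config.n_strata == 20:
        # reuse the packaged mouse fixture so synthetic hit tables exercise
        # the same taxon labels as real data
        data = resources.files("phylostrat.data")
        newick = (data / "mouse20.nwk").read_text()
        spec = pd.read_csv(data / "mouse20_strata.tsv", sep="\t")
        return mouse_lineage(), newick, spec
    newick, spec = make_synthetic_lineage(config.n_strata)
    pmap = load_lineage(newick, spec, focal_taxon="Focal_species")
    return pmap, newick, spec


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.integers(0, len(_CODONS), size=max(n_codons - 2, 1))
    return "ATG" + "".join(_CODONS[i] for i in body) + "TAA"


def generate_gene_table(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene table plus the intended-bidirectional flag per locus.

    Loci are laid out site by site along chromosomes with at least
    ``min_tss_spacing`` between unrelated sites; a bidirectional site holds
    two divergent loci with TSSs within the bidirectional window.
    """
    p = config.n_strata
    n = p * config.genes_per_stratum
    strata = np.repeat(np.arange(1, p + 1), config.genes_per_stratum)
    ids = np.array([f"L{i:05d}" for i in range(1, n + 1)])

    def lognormal(trend: FeatureTrend, boost_top: float = 1.0) -> np.ndarray:
        means = np.array([trend.mean_at(s, p) for s in strata], dtype=float)
        means[strata == p] *= boost_top
        mu = np.log(means) - trend.sigma**2 / 2.0
        return rng.lognormal(mean=mu, sigma=trend.sigma)

    orf_draw = lognormal(config.orf_length)
    orf_length = 3 * np.maximum(np.round(orf_draw / 3).astype(int), 30)
    gene_length = np.maximum(
        np.round(lognormal(config.gene_length)).astype(int), orf_length
    )
    exon_lam = np.array(
        [config.exon_count.mean_at(s, p) for s in strata], dtype=float
    )
    exon_count = 1 + rng.poisson(np.maximum(exon_lam - 1.0, 0.0))
    domain_lam = np.array(
        [config.domain_count.mean_at(s, p) for s in strata], dtype=float
    )
    domain_count = rng.poisson(domain_lam)
    mean_exon = np.minimum(
        np.round(lognormal(config.exon_length, config.youngest_exon_boost)).astype(int),
        gene_length,
    )
    mean_exon = np.maximum(mean_exon, 1)

    # chromosome layout: divergent pairs share a site, singles stand alone
    order = rng.permutation(n)
    n_pairs = int(config.bidirectional_fraction * n / 2)
    pair_members = order[: 2 * n_pairs]
    singles = order[2 * n_pairs :]
    sites: list[tuple[int, ...]] = [
        (pair_members[2 * i], pair_members[2 * i + 1]) for i in range(n_pairs)
    ] + [(g,) for g in singles]
    site_order = rng.permutation(len(sites))

    chromosome = np.empty(n, dtype=object)
    tss = np.zeros(n, dtype=int)
    strand = np.empty(n, dtype=object)
    bidirectional = np.zeros(n, dtype=bool)
    positions = {c: 0 for c in range(config.n_chromosomes)}
    for rank, site_idx in enumerate(site_order):
        chrom = rank % config.n_chromosomes
        positions[chrom] += int(
            rng.integers(config.min_tss_spacing, 2 * config.min_tss_spacing)
        )
        site = sites[site_idx]
        name = f"chr{chrom + 1}"
        if len(site) == 2:
            a, b = site
            gap = int(rng.integers(100, config.bidirectional_window - 100))
            chromosome[a], chromosome[b] = name, name
            tss[a], tss[b] = positions[chrom], positions[chrom] + gap
            strand[a], strand[b] = "-", "+"
            bidirectional[a] = bidirectional[b] = True
            positions[chrom] += gap
        else:
            (a,) = site
            chromosome[a] = name
            tss[a] = positions[chrom]
            strand[a] = "+" if rng.random() < 0.5 else "-"

    table = pd.DataFrame(
        {
            "id": ids,
            "stratum": strata,
            "chromosome": chromosome,
            "strand": strand,
            "tss": tss,
            "gene_length": gene_length,
            "orf_length": orf_length,
            "exon_count": exon_count,
            "mean_exon_length": mean_exon,
            "domain_count": domain_count,
        }
    )
    return table, pd.Series(bidirectional, index=ids, name="bidirectional")


def make_overprint_pair(
    base_orf: str, offset: int, length: int
) -> tuple[str, str, dict]:
    """Construct a younger ORF overprinted on ``base_orf`` at a frame shift.

    The new ORF copies ``length`` nucleotides of the base starting at a
    position congruent to ``offset`` (mod 3), with the minimal edits needed
    to begin with ATG and to remove in-frame stop codons; a terminator is
    appended. The edit budget is 2% of the shared stretch (at least 3
    bases); the start position minimizing the edit count is chosen.

    Returns (older ORF, newer ORF, truth record).
    """
    if offset not in (1, 2):
        raise ValueError("frame offset must be 1 or 2 (0 is not an overprint)")
    if length < 30 or length % 3:
        raise ValueError("shared length must be a multiple of 3 and >= 30")
    if len(base_orf) < offset + length + 3:
        raise ValueError(
            f"base ORF of {len(base_orf)} nt too short for a {length} nt "
            f"overprint at offset {offset}"
        )

    best: tuple[int, int] | None = None  # (cost, pos)
    for pos in range(offset, len(base_orf) - length - 2, 3):
        window = base_orf[pos : pos + length]
        cost = sum(1 for x, y in zip(window[:3], "ATG") if x != y)
        cost += sum(
            1
            for i in range(3, length, 3)
            if window[i : i + 3] in _STOPS
        )
        if best is None or cost < best[0]:
            best = (cost, pos)
        if cost == 0:
            break
    assert best is not None
    cost, pos = best
    budget = max(3, length // 50)
    if cost > budget:
        raise ValueError(
            f"cannot build overprint within edit budget: {cost} edits needed, "
            f"{budget} allowed"
        )

    window = list(base_orf[pos : pos + length])
    window[0:3] = "ATG"
    for i in range(3, length, 3):
        codon = "".join(window[i : i + 3])
        if codon in _STOPS:
            # one-base fix per stop: TAA/TAG -> TAC (Tyr), TGA -> TGC (Cys)
            window[i + 2] = "C"
    newer = "".join(window) + "TAA"
    truth = {
        "offset": offset,
        "shared_start": pos,
        "shared_length": length,
        "n_edits": cost,
    }
    return base_orf, newer, truth


def _generate_products(
    config: GeneratorConfig,
    rng: np.random.Generator,
    gene_table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, str], list[dict], list[dict]]:
    p = config.n_strata
    rows: list[dict] = []
    sequences: dict[str, str] = {}
    for locus, orf_len in zip(gene_table["id"], gene_table["orf_length"]):
        pid = f"{locus}.p1"
        rows.append({"product_id": pid, "locus_id": locus})
        sequences[pid] = _random_orf(rng, int(orf_len) // 3)

    eligible = gene_table[
        (gene_table["stratum"] <= p - 2)
        & (gene_table["orf_length"] >= config.overprint_shared_length + 66)
    ]
    n_special = (
        config.n_overprints + config.n_sameframe_decoys + config.n_unrelated_decoys
    )
    if n_special > len(eligible):
        raise ValueError(
            f"infeasible config: {n_special} multi-product loci requested but "
            f"only {len(eligible)} eligible loci generated"
        )
    chosen = rng.choice(eligible.index.to_numpy(), size=n_special, replace=False)
    ages = {row["product_id"]: 0 for row in rows}  # filled below
    by_locus = gene_table.set_index("id")

    overprints: list[dict] = []
    decoys: list[dict] = []
    for j, gi in enumerate(chosen):
        locus = gene_table.at[gi, "id"]
        older_age = int(by_locus.at[locus, "stratum"])
        newer_age = int(rng.integers(older_age + 2, p + 1))
        older_pid, newer_pid = f"{locus}.p1", f"{locus}.p2"
        base = sequences[older_pid]
        if j < config.n_overprints:
            offset = int(rng.integers(1, 3))
            _, newer_orf, rec = make_overprint_pair(
                base, offset, config.overprint_shared_length
            )
            overprints.append(
                {
                    "locus": locus,
                    "older_product": older_pid,
                    "newer_product": newer_pid,
                    "older_stratum": older_age,
                    "newer_stratum": newer_age,
                    **rec,
                }
            )
        elif j < config.n_overprints + config.n_sameframe_decoys:
            # same-frame annotation variant: an in-frame suffix of the base
            n_codons = len(base) // 3
            start_codon = int(rng.integers(1, max(n_codons - 25, 2)))
            newer_orf = "ATG" + base[3 * start_codon + 3 :]
            decoys.append(
                {
                    "locus": locus,
                    "kind": "same_frame",
                    "newer_product": newer_pid,
                    "older_stratum": older_age,
                    "newer_stratum": newer_age,
                }
            )
        else:
            # unrelated second annotation at an age-discordant locus
            newer_orf = _random_orf(rng, 100)
            decoys.append(
                {
                    "locus": locus,
                    "kind": "unrelated",
                    "newer_product": newer_pid,
                    "older_stratum": older_age,
                    "newer_stratum": newer_age,
                }
            )
        rows.append({"product_id": newer_pid, "locus_id": locus})
        sequences[newer_pid] = newer_orf
        ages[newer_pid] = newer_age

    products = pd.DataFrame(rows)
    locus_strata = by_locus["stratum"]
    products["stratum_true"] = [
        ages[pid] if ages.get(pid) else int(locus_strata[locus])
        for pid, locus in zip(products["product_id"], products["locus_id"])
    ]
    products = products.sort_values("product_id", ignore_index=True)
    return products, sequences, overprints, decoys


def _generate_hits(
    config: GeneratorConfig,
    rng: np.random.Generator,
    products: pd.DataFrame,
    pmap: PhylostratumMap,
) -> list[HomologyHit]:
    p = pmap.n_strata
    focal = pmap.focal_taxon
    taxa_by_stratum = {
        s.index: sorted(s.taxa - {focal.casefold()}) for s in pmap.strata
    }
    hits: list[HomologyHit] = []
    counter = 0
    for pid, age in zip(products["product_id"], products["stratum_true"]):
        for j in range(int(age), p + 1):
            if config.hit_false_negative_rate and (
                rng.random() < config.hit_false_negative_rate
            ):
                continue
            taxa = taxa_by_stratum[j]
            taxon = taxa[int(rng.integers(0, len(taxa)))]
            counter += 1
            hits.append(
                HomologyHit(
                    query=pid,
                    subject=f"{taxon}_prot{counter:06d}",
                    subject_taxon=taxon,
                    evalue=float(10.0 ** rng.uniform(-150.0, -3.5)),
                    bitscore=float(rng.uniform(60.0, 800.0)),
                )
            )
        if age > 1 and rng.random() < config.nonqualifying_hit_rate:
            j = int(rng.integers(1, int(age)))
            taxa = taxa_by_stratum[j]
            taxon = taxa[int(rng.integers(0, len(taxa)))]
            counter += 1
            hits.append(
                HomologyHit(
                    query=pid,
                    subject=f"{taxon}_prot{counter:06d}",
                    subject_taxon=taxon,
                    evalue=float(10.0 ** rng.uniform(-3.0, 1.0)),
                    bitscore=float(rng.uniform(20.0, 60.0)),
                )
            )
        if rng.random() < config.self_hit_rate:
            counter += 1
            hits.append(
                HomologyHit(
                    query=pid,
                    subject=f"{focal}_prot{counter:06d}",
                    subject_taxon=focal,
                    evalue=1e-180,
                    bitscore=1500.0,
                )
            )
    return hits


def _generate_marks(
    config: GeneratorConfig,
    rng: np.random.Generator,
    gene_table: pd.DataFrame,
    bidirectional: pd.Series,
) -> tuple[dict[str, MarkSet], pd.DataFrame]:
    p = config.n_strata
    table = gene_table.set_index("id")
    # reconstruct divergent pairs from placement: same chromosome, opposite
    # strand, adjacent TSS within the window
    pair_of: dict[str, str] = {}
    bidi_ids = [g for g in table.index if bidirectional[g]]
    bidi = table.loc[bidi_ids].sort_values(["chromosome", "tss"])
    it = iter(range(0, len(bidi) - 1, 2))
    for i in it:
        a, b = bidi.index[i], bidi.index[i + 1]
        pair_of[a], pair_of[b] = b, a

    assoc = pd.DataFrame(False, index=table.index, columns=list(MARK_TYPES))
    marks: dict[str, MarkSet] = {}
    for mark in MARK_TYPES:
        intervals = []
        done: set[str] = set()
        for gid in table.index:
            if gid in done:
                continue
            stratum = int(table.at[gid, "stratum"])
            is_bidi = bool(bidirectional[gid])
            partner = pair_of.get(gid)
            rate = config.marks.rate(stratum, p, is_bidi)
            if partner is not None:
                rate = max(
                    rate,
                    config.marks.rate(int(table.at[partner, "stratum"]), p, True),
                )
            hit = rng.random() < rate
            width = int(rng.integers(150, 600))
            if partner is not None:
                done.update({gid, partner})
                if hit:
                    assoc.loc[[gid, partner], mark] = True
                    mid = int((table.at[gid, "tss"] + table.at[partner, "tss"]) // 2)
                    start = max(mid - width // 2, 0)
                    intervals.append(
                        (table.at[gid, "chromosome"], start, start + width)
                    )
            else:
                done.add(gid)
                if hit:
                    assoc.at[gid, mark] = True
                    d = int(rng.integers(0, 1200))
                    tss = int(table.at[gid, "tss"])
                    if rng.random() < 0.5:
                        start = tss + d
                    else:
                        start = max(tss - d - width, 0)
                    intervals.append(
                        (table.at[gid, "chromosome"], start, start + width)
                    )
        df = pd.DataFrame(intervals, columns=["chromosome", "start", "end"])
        df = df.sort_values(["chromosome", "start"], ignore_index=True)
        marks[mark] = MarkSet(mark_type=mark, intervals=df)
    return marks, assoc


def _generate_expression(
    config: GeneratorConfig, rng: np.random.Generator, gene_table: pd.DataFrame
) -> set[str]:
    base_odds = config.expression_background / (1 - config.expression_background)
    expressed = set()
    for gid, stratum in zip(gene_table["id"], gene_table["stratum"]):
        odds = base_odds
        if stratum >= config.expression_enriched_from:
            odds *= config.expression_odds
        if rng.random() < odds / (1 + odds):
            expressed.add(gid)
    return expressed


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic input bundle with ground truth.

    Identical configs (including the seed) produce byte-identical outputs.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    pmap, newick, spec = _lineage_for(config)
    gene_table, bidirectional = generate_gene_table(config, rng)
    products, sequences, overprints, decoys = _generate_products(
        config, rng, gene_table
    )
    hits = _generate_hits(config, rng, products, pmap)
    marks, mark_assoc = _generate_marks(config, rng, gene_table, bidirectional)
    expressed = _generate_expression(config, rng, gene_table)

    product_ages = dict(
        zip(products["product_id"], products["stratum_true"].astype(int))
    )
    locus_ages = {
        locus: int(group["stratum_true"].min())
        for locus, group in products.groupby("locus_id")
    }
    truth = SyntheticTruth(
        product_ages=product_ages,
        locus_ages=locus_ages,
        mark_assoc=mark_assoc,
        bidirectional=bidirectional,
        expressed=expressed,
        overprints=overprints,
        decoys=decoys,
    )
    return SyntheticDataset(
        config=config,
        pmap=pmap,
        newick=newick,
        stratum_spec=spec,
        gene_table=gene_table,
        products=products,
        hits=hits,
        marks=marks,
        expressed=expressed,
        sequences=sequences,
        truth=truth,
    )


def write_fixture_tables(outdir: str | Path) -> list[Path]:
    """Copy the packaged worked-example fixtures into ``outdir``.

    Emits the 13-row overprint stratum-pair table (with the two
    literature-known rows flagged) and the mouse-20 / fish-14 lineage
    fixtures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = resources.files("phylostrat.data")
    written = []
    for name in (
        "table1_overprints.tsv",
        "mouse20.nwk",
        "mouse20_strata.tsv",
        "fish14.nwk",
        "fish14_strata.tsv",
    ):
        target = outdir / name
        with resources.as_file(data / name) as src:
            shutil.copyfile(src, target)
        written.append(target)
    return written


def noise_free_preset(seed: int = 7) -> GeneratorConfig:
    """100 loci, 5 planted overprints, no hit noise: every stage should
    recover the truth exactly."""
    return GeneratorConfig(
        n_strata=20,
        genes_per_stratum=5,
        n_overprints=5,
        n_sameframe_decoys=2,
        n_unrelated_decoys=3,
        hit_false_negative_rate=0.0,
        nonqualifying_hit_rate=0.0,
        self_hit_rate=0.0,
        seed=seed,
    )


def paper_like_preset(seed: int = 42) -> GeneratorConfig:
    """20 strata x 300 genes with strong age trends, youngest-stratum mark
    enrichment concentrated on bidirectional promoters, and 13 overprints."""
    return GeneratorConfig(seed=seed)


def zero_trend_preset(seed: int = 42) -> GeneratorConfig:
    """Null generator: flat feature trends and no mark boost."""
    return GeneratorConfig(
        gene_length=FeatureTrend(8_000, 8_000, 0.6),
        orf_length=FeatureTrend(900, 900, 0.35),
        exon_count=FeatureTrend(4.0, 4.0),
        domain_count=FeatureTrend(1.0, 1.0),
        youngest_exon_boost=1.0,
        marks=MarkParams(top_stratum_odds=1.0, bidirectional_boost=1.0),
        expression_odds=1.0,
        seed=seed,
    )


PRESETS = {
    "noise-free": noise_free_preset,
    "paper-like": paper_like_preset,
    "zero-trend": zero_trend_preset,
}


def get_preset(name: str, seed: int | None = None) -> GeneratorConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    config = factory() if seed is None else factory(seed=seed)
    return config
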
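"""End-to-end workflow: assign -> trends -> enrichment -> overprint.

The pipeline consumes a declarative configuration (paths plus thresholds),
runs the requested stages and writes one TSV per result, each with a
schema-versioned comment line. Re-running with identical inputs and seed
produces byte-identical outputs; all tables are explicitly sorted.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from phylostrat import align, assignment, enrichment, overprint, trends
from phylostrat.lineage import load_lineage

logger = logging.getLogger(__name__)

SCHEMA_COMMENT = "# phylostrat schema v1"

ALL_STAGES = ("assign", "trends", "enrich", "overprint")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "write_tsv"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    ``marks`` maps a mark name (e.g. 'cpg') to a BED3 path. ``stages``
    selects a subset of the default assign/trends/enrich/overprint chain.
    """

    lineage_tree: str
    lineage_spec: str
    focal_taxon: str | None = None
    hits: str | None = None
    gene_table: str | None = None
    products: str | None = None
    sequences: str | None = None
    marks: dict[str, str] = field(default_factory=dict)
    expressed: str | None = None
    outdir: str = "phylostrat_out"
    stages: tuple[str, ...] = ALL_STAGES
    cutoff: float = assignment.DEFAULT_CUTOFF
    cutoff_overrides: dict[int, float] = field(default_factory=dict)
    max_dist: int = enrichment.DEFAULT_TSS_DISTANCE
    bidirectional_window: int = enrichment.DEFAULT_BIDIRECTIONAL_WINDOW
    min_gap: int = 2
    alpha: float = 0.01
    n_perm: int = 10_000
    ks_features: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "ks_features" in raw:
            raw["ks_features"] = tuple(raw["ks_features"])
        if "cutoff_overrides" in raw:
            raw["cutoff_overrides"] = {
                int(k): float(v) for k, v in raw["cutoff_overrides"].items()
            }
        return cls(**raw)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _require(config: PipelineConfig, attr: str, stage: str) -> str:
    value = getattr(config, attr)
    if not value:
        raise ValueError(f"stage {stage!r} requires config field {attr!r}")
    if not Path(value).exists():
        raise FileNotFoundError(f"stage {stage!r}: {attr} file not found: {value}")
    return value


def _read_products(path: str) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"product_id", "locus_id"} - set(df.columns)
    if missing:
        raise ValueError(f"products table lacks columns {sorted(missing)}")
    return df


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the configured stages; returns the result tables by name.

    Writes per-stage TSVs plus a per-stratum summary under
    ``config.outdir``. Errors abort with stage-named diagnostics.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    pmap = load_lineage(
        _require(config, "lineage_tree", "setup"),
        _require(config, "lineage_spec", "setup"),
        focal_taxon=config.focal_taxon,
    )
    cutoffs = {
        s: float(config.cutoff_overrides.get(s, config.cutoff))
        for s in range(1, pmap.n_strata + 1)
    }

    gene_table = None
    if config.gene_table:
        gene_table = read_tsv(_require(config, "gene_table", "setup"))

    ages = None
    if "assign" in config.stages:
        t0 = time.perf_counter()
        hits = assignment.read_hit_table(_require(config, "hits", "assign"))
        products = _read_products(_require(config, "products", "assign"))
        product_ages = assignment.assign_product_ages(
            hits, pmap, cutoffs, products=products["product_id"]
        )
        membership = {
            locus: sorted(g["product_id"])
            for locus, g in products.groupby("locus_id")
        }
        ages = assignment.assign_locus_ages(product_ages, membership, cutoffs)
        results["assignments"] = ages.to_frame()
        write_tsv(results["assignments"], outdir / "assignments.tsv")
        if gene_table is not None:
            gene_table = gene_table.copy()
            gene_table["stratum"] = gene_table["id"].map(ages.locus_ages)
            if gene_table["stratum"].isna().any():
                missing = gene_table.loc[gene_table["stratum"].isna(), "id"]
                raise ValueError(
                    f"assign: gene-table loci without products/ages: "
                    f"{missing.tolist()[:5]}"
                )
            gene_table["stratum"] = gene_table["stratum"].astype(int)
        counts = (
            results["assignments"]
            .query("level == 'locus'")
            .groupby("stratum")
            .size()
            .reindex(range(1, pmap.n_strata + 1), fill_value=0)
        )
        summary = pd.DataFrame(
            {
                "stratum": counts.index,
                "name": [pmap.name_of(s) for s in counts.index],
                "n_loci": counts.to_numpy(),
            }
        )
        results["summary"] = summary
        write_tsv(summary, outdir / "summary.tsv")
        logger.info("assign: %d products in %.2fs", len(product_ages),
                    time.perf_counter() - t0)

    if "trends" in config.stages:
        if gene_table is None:
            raise ValueError("stage 'trends' requires a gene table")
        t0 = time.perf_counter()
        trends.validate_gene_table(gene_table)
        summaries = []
        for feature in trends.NUMERIC_FEATURES:
            s = trends.summarize_by_stratum(
                gene_table, feature, n_strata=pmap.n_strata
            )
            s.insert(0, "feature", feature)
            summaries.append(s)
        results["feature_summaries"] = pd.concat(summaries, ignore_index=True)
        write_tsv(results["feature_summaries"], outdir / "feature_summaries.tsv")
        results["trend_table"] = trends.feature_trend_table(
            gene_table, n_strata=pmap.n_strata
        )
        write_tsv(results["trend_table"], outdir / "trend_table.tsv")
        ks_frames = []
        for feature in config.ks_features:
            ks = trends.permutation_ks_by_stratum(
                gene_table, feature, n_perm=config.n_perm, seed=config.seed,
                flag_alpha=config.alpha,
            )
            ks.insert(0, "feature", feature)
            ks_frames.append(ks)
        if ks_frames:
            results["ks_tests"] = pd.concat(ks_frames, ignore_index=True)
            write_tsv(results["ks_tests"], outdir / "ks_tests.tsv")
        logger.info("trends: %.2fs", time.perf_counter() - t0)

    if "enrich" in config.stages:
        if gene_table is None:
            raise ValueError("stage 'enrich' requires a gene table")
        t0 = time.perf_counter()
        profiles = []
        mark_flags: dict[str, pd.Series] = {}
        directionality = enrichment.classify_promotor_directionality(
            gene_table, window=config.bidirectional_window
        )
        for name, path in sorted(config.marks.items()):
            ms = enrichment.MarkSet.from_bed(
                _require_path(path, "enrich"), mark_type=name
            )
            mark_flags[name] = enrichment.associate_tss_with_marks(
                gene_table, ms, max_dist=config.max_dist
            )
        if mark_flags:
            union = pd.concat(mark_flags.values(), axis=1).any(axis=1)
            todo = [("any_mark", union)] + sorted(mark_flags.items())
            for name, flags in todo:
                for subset, label in (
                    (slice(None), "all"),
                    (directionality == "unidirectional", "unidirectional"),
                    (directionality == "bidirectional", "bidirectional"),
                ):
                    sub_table = gene_table.loc[subset]
                    if sub_table.empty:
                        continue
                    profile = enrichment.enrichment_profile(
                        sub_table,
                        flags.loc[subset],
                        property_name=f"{name}:{label}",
                        correction="fdr_bh",
                        alpha=config.alpha,
                        n_strata=pmap.n_strata,
                    )
                    frame = profile.table.copy()
                    frame.insert(0, "property", profile.property_name)
                    profiles.append(frame)
        if config.expressed:
            ids = enrichment.read_id_set(_require(config, "expressed", "enrich"))
            flags = gene_table["id"].isin(ids)
            flags.index = gene_table.index
            profile = enrichment.enrichment_profile(
                gene_table, flags, property_name="expressed",
                correction="bonferroni", alpha=config.alpha,
                n_strata=pmap.n_strata,
            )
            frame = profile.table.copy()
            frame.insert(0, "property", profile.property_name)
            profiles.append(frame)
        if profiles:
            results["enrichment"] = pd.concat(profiles, ignore_index=True)
            write_tsv(results["enrichment"], outdir / "enrichment.tsv")
        logger.info("enrich: %.2fs", time.perf_counter() - t0)

    if "overprint" in config.stages:
        t0 = time.perf_counter()
        products = _read_products(_require(config, "products", "overprint"))
        sequences = align.read_fasta(_require(config, "sequences", "overprint"))
        if ages is not None:
            product_ages = ages.product_ages
        else:
            hits = assignment.read_hit_table(_require(config, "hits", "overprint"))
            product_ages = assignment.assign_product_ages(
                hits, pmap, cutoffs, products=products["product_id"]
            )
        membership = {
            locus: sorted(g["product_id"])
            for locus, g in products.groupby("locus_id")
        }
        loci = overprint.build_loci(membership, product_ages, sequences)
        results["arf_report"] = overprint.run_overprint_screen(
            loci, min_gap=config.min_gap
        )
        write_tsv(results["arf_report"], outdir / "arf_report.tsv")
        logger.info("overprint: %.2fs", time.perf_counter() - t0)

    return results


def _require_path(path: str, stage: str) -> str:
    if not Path(path).exists():
        raise FileNotFoundError(f"stage {stage!r}: file not found: {path}")
    return path


def validate_inputs(config: PipelineConfig) -> list[tuple[str, str]]:
    """Cross-check inputs without running the pipeline.

    Returns (level, message) diagnostics; level is 'error' or 'warning'.
    """
    diagnostics: list[tuple[str, str]] = []

    def error(msg: str) -> None:
        diagnostics.append(("error", msg))

    def warning(msg: str) -> None:
        diagnostics.append(("warning", msg))

    for attr in ("lineage_tree", "lineage_spec", "hits", "gene_table",
                 "products", "sequences", "expressed"):
        value = getattr(config, attr)
        if value and not Path(value).exists():
            error(f"{attr}: file not found: {value}")
    for name, path in sorted(config.marks.items()):
        if not Path(path).exists():
            error(f"marks[{name}]: file not found: {path}")
    if diagnostics:
        return diagnostics

    pmap = None
    try:
        pmap = load_lineage(
            config.lineage_tree, config.lineage_spec,
            focal_taxon=config.focal_taxon,
        )
    except Exception as exc:
        error(f"lineage: {exc}")

    products = None
    if config.products:
        try:
            products = _read_products(config.products)
        except Exception as exc:
            error(f"products: {exc}")

    if config.hits and pmap is not None:
        try:
            hits = assignment.read_hit_table(config.hits)
        except Exception as exc:
            error(f"hits: {exc}")
        else:
            unknown = sorted(
                {h.subject_taxon for h in hits if h.subject_taxon not in pmap}
            )
            for taxon in unknown:
                error(f"hits: subject taxon {taxon!r} not in the lineage map")
            if products is not None:
                known = set(products["product_id"])
                stray = sorted({h.query for h in hits} - known)
                if stray:
                    warning(
                        f"hits: {len(stray)} query product(s) absent from the "
                        f"products table, e.g. {stray[:3]}"
                    )

    if config.gene_table:
        try:
            table = trends.validate_gene_table(read_tsv(config.gene_table))
        except Exception as exc:
            error(f"gene_table: {exc}")
        else:
            if products is not None:
                stray = sorted(set(products["locus_id"]) - set(table["id"]))
                if stray:
                    error(
                        f"products reference loci absent from the gene table, "
                        f"e.g. {stray[:3]}"
                    )

    for name, path in sorted(config.marks.items()):
        try:
            enrichment.read_bed(path)
        except Exception as exc:
            error(f"marks[{name}]: {exc}")

    return diagnostics
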
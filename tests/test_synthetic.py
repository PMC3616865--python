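import filecmp

import numpy as np
import pytest

from phylostrat import synthetic, trends
from phylostrat.align import translate
from phylostrat.enrichment import associate_tss_with_marks, read_id_set
from phylostrat.lineage import load_lineage
from phylostrat.assignment import read_hit_table, assign_product_ages
from phylostrat.synthetic import (
    GeneratorConfig,
    MarkParams,
    generate_dataset,
    generate_gene_table,
    make_overprint_pair,
    make_synthetic_lineage,
    write_fixture_tables,
    zero_trend_preset,
)


class TestMakeOverprintPair:
    def setup_method(self):
        self.rng = np.random.default_rng(21)

    def _base(self, n=150):
        from test_overprint import random_orf

        return random_orf(self.rng, n)

    @pytest.mark.parametrize("offset", [1, 2])
    def test_shared_stretch_high_nt_identity_discordant_protein(self, offset):
        base = self._base()
        older, newer, truth = make_overprint_pair(base, offset, 150)
        assert older == base  # base is never edited
        shared_old = base[truth["shared_start"] : truth["shared_start"] + 150]
        matches = sum(x == y for x, y in zip(shared_old, newer[:150]))
        assert matches / 150 >= 0.98
        assert translate(newer, 0) not in translate(older, 0)

    def test_offset_zero_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            make_overprint_pair(self._base(), 0, 60)

    def test_sixty_shared_bases_make_at_least_twenty_residues(self):
        _, newer, _ = make_overprint_pair(self._base(), 1, 60)
        assert len(translate(newer, 0)) >= 20

    def test_newer_orf_is_a_clean_reading_frame(self):
        _, newer, _ = make_overprint_pair(self._base(), 2, 120)
        assert newer.startswith("ATG")
        protein = translate(newer, 0)
        assert len(protein) == len(newer) // 3 - 1  # runs to the terminator

    def test_too_short_base_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_overprint_pair("ATGAAATAA", 1, 60)


class TestGeneratorConfig:
    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            GeneratorConfig(bidirectional_fraction=1.5)

    def test_too_many_special_loci_is_infeasible(self):
        config = GeneratorConfig(
            n_strata=5, genes_per_stratum=2, n_overprints=50, seed=0
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_dataset(config)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        config = synthetic.noise_free_preset(seed=3)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(config).write(out1)
        generate_dataset(config).write(out2)
        files = sorted(p.name for p in out1.iterdir())
        assert files == sorted(p.name for p in out2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(out1, out2, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ(self):
        a = generate_dataset(synthetic.noise_free_preset(seed=1))
        b = generate_dataset(synthetic.noise_free_preset(seed=2))
        assert not a.gene_table.equals(b.gene_table)


class TestTruthConsistency:
    def test_written_files_reproduce_truth(self, tmp_path, noise_free_dataset):
        """Re-reading the emitted bundle reproduces the ground truth under
        noise-free settings: ages from hits, mark association from BEDs,
        expression from the id list."""
        ds = noise_free_dataset
        out = tmp_path / "bundle"
        ds.write(out)

        pmap = load_lineage(out / "lineage.nwk", out / "strata.tsv",
                            focal_taxon="Mus_musculus")
        hits = read_hit_table(out / "hits.tsv")
        ages = assign_product_ages(
            hits, pmap, products=ds.products["product_id"]
        )
        assert ages == ds.truth.product_ages

        import pandas as pd

        table = pd.read_csv(out / "gene_table.tsv", sep="\t")
        for mark in synthetic.MARK_TYPES:
            from phylostrat.enrichment import MarkSet

            ms = MarkSet.from_bed(out / f"{mark}.bed", mark)
            got = associate_tss_with_marks(table, ms).set_axis(table["id"])
            expected = ds.truth.mark_assoc[mark]
            assert got.sort_index().equals(expected.sort_index())

        assert read_id_set(out / "expressed.txt") == ds.truth.expressed

    def test_gene_table_satisfies_schema_invariants(self, paper_like_dataset):
        trends.validate_gene_table(paper_like_dataset.gene_table)

    def test_products_protein_matches_orf_translation(self, noise_free_dataset):
        ds = noise_free_dataset
        for rec in ds.truth.overprints:
            newer = ds.sequences[rec["newer_product"]]
            assert translate(newer, 0)  # non-empty, no internal stop before end
            assert rec["newer_stratum"] - rec["older_stratum"] >= 2


class TestSyntheticLineage:
    def test_nonstandard_stratum_count_builds_valid_map(self):
        newick, spec = make_synthetic_lineage(7)
        pmap = load_lineage(newick, spec, focal_taxon="Focal_species")
        assert pmap.n_strata == 7
        assert pmap.stratum_of("s3a") == 3

    def test_generator_uses_mouse_labels_at_twenty_strata(self, noise_free_dataset):
        taxa = {h.subject_taxon for h in noise_free_dataset.hits}
        assert taxa <= noise_free_dataset.pmap.taxa


class TestTrendCalibration:
    def test_paper_like_preset_shows_strong_negative_trends(
        self, paper_like_dataset
    ):
        gt = paper_like_dataset.gene_table
        assert trends.spearman_trend(trends.stratum_means(gt, "orf_length")) <= -0.9
        assert trends.spearman_trend(trends.stratum_means(gt, "gene_length")) <= -0.8

    def test_strong_trend_recovery_across_seeds(self):
        """spearman(orf_length) <= -0.9 and spearman(gene_length) <= -0.8 in
        at least 95% of seeds under the strong-trend settings."""
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table, _ = generate_gene_table(GeneratorConfig(seed=seed), rng)
            rho_orf = trends.spearman_trend(trends.stratum_means(table, "orf_length"))
            rho_gene = trends.spearman_trend(
                trends.stratum_means(table, "gene_length")
            )
            ok += (rho_orf <= -0.9) and (rho_gene <= -0.8)
        assert ok >= 0.95 * n_seeds

    def test_zero_trend_preset_has_no_spurious_trend(self):
        """|rho| < 0.5 in >= 95% of seeds when the generator is flat."""
        config = zero_trend_preset()
        small = GeneratorConfig(
            **{
                **{f: getattr(config, f) for f in config.__dataclass_fields__},
                "genes_per_stratum": 30,
            }
        )
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table, _ = generate_gene_table(small, rng)
            rho = trends.spearman_trend(trends.stratum_means(table, "orf_length"))
            ok += abs(rho) < 0.5
        assert ok >= 0.95 * n_seeds


class TestMarkCalibration:
    def test_realized_youngest_stratum_odds_near_configuration(self):
        """Empirical association odds ratio at psP tracks the configured
        multiplier within +-25% (averaged over seeds, unidirectional)."""
        ratios = []
        for seed in range(3):
            config = GeneratorConfig(
                genes_per_stratum=500, seed=seed,
                marks=MarkParams(top_stratum_odds=3.0, bidirectional_boost=1.0),
            )
            rng = np.random.default_rng(seed)
            table, bidi = generate_gene_table(config, rng)
            from phylostrat.synthetic import _generate_marks

            _, assoc = _generate_marks(config, rng, table, bidi)
            flat = assoc["cpg"].set_axis(table["id"])
            uni = ~bidi
            young = table.set_index("id")["stratum"] == config.n_strata
            p_top = flat[uni & young].mean()
            p_bg = flat[uni & ~young].mean()
            ratios.append(
                (p_top / (1 - p_top)) / (p_bg / (1 - p_bg))
            )
        assert abs(np.mean(ratios) - 3.0) <= 0.75


def test_fixture_writer_emits_worked_example_tables(tmp_path):
    written = write_fixture_tables(tmp_path)
    names = {p.name for p in written}
    assert "table1_overprints.tsv" in names
    import pandas as pd

    table = pd.read_csv(tmp_path / "table1_overprints.tsv", sep="\t")
    row = table.set_index("gene_name").loc["Hoxa9"]
    assert (row["newer_stratum"], row["older_stratum"]) == (18, 2)
    reep6 = table.set_index("gene_name").loc["Reep6"]
    assert (reep6["newer_stratum"], reep6["older_stratum"]) == (17, 2)
    spec = pd.read_csv(tmp_path / "mouse20_strata.tsv", sep="\t")
    assert spec["stratum"].max() == 20
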
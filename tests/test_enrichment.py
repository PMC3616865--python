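import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylostrat import enrichment
from conftest import make_gene_table


def genes_on(chrom, rows):
    """rows: (id, tss, strand)"""
    return pd.DataFrame(
        {
            "id": [r[0] for r in rows],
            "stratum": 1,
            "chromosome": chrom,
            "strand": [r[2] for r in rows],
            "tss": [r[1] for r in rows],
            "gene_length": 1000,
            "orf_length": 300,
            "exon_count": 1,
            "mean_exon_length": 100,
            "domain_count": 0,
        }
    )


class TestTssMarkAssociation:
    def make_marks(self, intervals):
        return enrichment.MarkSet(
            mark_type="test",
            intervals=pd.DataFrame(
                intervals, columns=["chromosome", "start", "end"]
            ),
        )

    def test_boundary_distance_is_inclusive(self):
        table = genes_on("chr1", [("a", 1000, "+")])
        marks = self.make_marks([("chr1", 2000, 2100)])
        assert enrichment.associate_tss_with_marks(table, marks, 1250).all()

    def test_tss_inside_interval_is_distance_zero(self):
        table = genes_on("chr1", [("a", 2050, "+")])
        marks = self.make_marks([("chr1", 2000, 2100)])
        assert enrichment.associate_tss_with_marks(table, marks, 0).all()

    def test_one_base_past_the_limit_misses(self):
        table = genes_on("chr1", [("a", 1000, "+")])
        marks = self.make_marks([("chr1", 2251, 2400)])
        assert not enrichment.associate_tss_with_marks(table, marks, 1250).any()

    def test_chromosome_missing_from_marks_means_unassociated(self):
        table = genes_on("chr2", [("a", 1000, "+")])
        marks = self.make_marks([("chr1", 900, 1100)])
        assert not enrichment.associate_tss_with_marks(table, marks).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_distance_scan(self, seed):
        """Vectorized interval distances equal a per-interval brute force,
        including overlapping intervals."""
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 50_000, size=30)
        widths = rng.integers(1, 3_000, size=30)
        marks = self.make_marks(
            [("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)]
        )
        tss = rng.integers(0, 55_000, size=40)
        table = genes_on("chr1", [(f"g{i}", int(t), "+") for i, t in enumerate(tss)])
        got = enrichment.associate_tss_with_marks(table, marks, max_dist=700)
        for i, t in enumerate(tss):
            dists = []
            for s, w in zip(starts, widths):
                if s <= t < s + w:
                    dists.append(0)
                elif t < s:
                    dists.append(s - t)
                else:
                    dists.append(t - (s + w - 1))
            assert got.iloc[i] == (min(dists) <= 700), f"tss {t}"


class TestDirectionality:
    def test_opposite_strands_within_window_are_bidirectional(self):
        table = genes_on("chr1", [("a", 1000, "+"), ("b", 1300, "-")])
        labels = enrichment.classify_promotor_directionality(table, window=1000)
        assert (labels == "bidirectional").all()

    def test_same_strand_neighbours_stay_unidirectional(self):
        table = genes_on("chr1", [("a", 1000, "+"), ("b", 1300, "+")])
        labels = enrichment.classify_promotor_directionality(table, window=1000)
        assert (labels == "unidirectional").all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        table = genes_on(
            "chr1",
            [
                (f"g{i}", int(rng.integers(0, 40_000)),
                 "+" if rng.random() < 0.5 else "-")
                for i in range(n)
            ],
        )
        table["chromosome"] = rng.choice(["chr1", "chr2"], size=n)
        got = enrichment.classify_promotor_directionality(table, window=800)
        for i in range(n):
            expected = any(
                j != i
                and table["chromosome"][j] == table["chromosome"][i]
                and table["strand"][j] != table["strand"][i]
                and abs(int(table["tss"][j]) - int(table["tss"][i])) <= 800
                for j in range(n)
            )
            assert (got.iloc[i] == "bidirectional") == expected


class TestLogOdds:
    def test_worked_two_by_two_table(self):
        # (30,70) vs (200,1700): log2 of (30*1700)/(70*200)
        expected = math.log2((30 * 1700) / (70 * 200))
        assert enrichment.log_odds_enrichment(30, 100, 230, 2000) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(1.87, abs=0.01)

    def test_background_proportion_gives_zero(self):
        assert enrichment.log_odds_enrichment(10, 100, 100, 1000) == pytest.approx(0.0)

    def test_zero_cell_correction_is_finite_and_negative(self):
        value = enrichment.log_odds_enrichment(0, 50, 200, 1000)
        assert np.isfinite(value) and value < 0

    def test_empty_stratum_is_undefined(self):
        assert np.isnan(enrichment.log_odds_enrichment(0, 0, 10, 100))

    def test_strictly_increasing_in_k(self):
        values = [enrichment.log_odds_enrichment(k, 40, 60, 200) for k in range(41)]
        assert all(a < b for a, b in zip(values, values[1:]))

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_sign_matches_proportion_comparison(self, data):
        """log-odds is positive exactly when the stratum's property rate
        exceeds the rest-of-genome rate (for non-degenerate tables)."""
        N = data.draw(st.integers(4, 400))
        n = data.draw(st.integers(1, N - 1))
        K = data.draw(st.integers(1, N - 1))
        lo, hi = max(0, n - (N - K)), min(n, K)
        k = data.draw(st.integers(lo, hi))
        value = enrichment.log_odds_enrichment(k, n, K, N)
        rate_in = k / n
        rate_out = (K - k) / (N - n) if N > n else None
        if rate_out is not None and not math.isclose(rate_in, rate_out):
            continuity = min(k, n - k, K - k, (N - n) - (K - k)) == 0
            if not continuity:
                assert (value > 0) == (rate_in > rate_out)


class TestHypergeom:
    def test_exact_small_case(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        assert enrichment.hypergeom_test(4, 4, 5, 10, "over") == pytest.approx(
            5 / 210, abs=1e-12
        )

    def test_under_tail_at_zero_closed_form(self):
        n, K, N = 6, 8, 20
        expected = comb(N - K, n) / comb(N, n)
        assert enrichment.hypergeom_test(0, n, K, N, "under") == pytest.approx(
            expected, abs=1e-12
        )

    def test_tails_overlap_at_observed_value(self):
        p = enrichment.hypergeom_test(3, 10, 8, 30, "over")
        q = enrichment.hypergeom_test(3, 10, 8, 30, "under")
        assert p + q >= 1.0

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            enrichment.hypergeom_test(6, 5, 10, 20)
        with pytest.raises(ValueError):
            enrichment.hypergeom_test(5, 5, 4, 20)

    def test_over_tail_decreasing_in_k(self):
        values = [enrichment.hypergeom_test(k, 12, 15, 40, "over") for k in range(13)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_enumeration(self, seed):
        """Both tails agree with direct combinatorial sums to 1e-12 for
        N <= 25."""
        rng = np.random.default_rng(seed)
        for _ in range(150):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            total = comb(N, n)
            over = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, hi + 1))
            under = sum(comb(K, x) * comb(N - K, n - x) for x in range(lo, k + 1))
            assert enrichment.hypergeom_test(k, n, K, N, "over") == pytest.approx(
                over / total, abs=1e-12
            )
            assert enrichment.hypergeom_test(k, n, K, N, "under") == pytest.approx(
                under / total, abs=1e-12
            )


class TestAdjustPvalues:
    def test_bh_step_up_worked_example(self):
        got = enrichment.adjust_pvalues([0.01, 0.02, 0.04], method="fdr_bh")
        assert np.allclose(got, [0.03, 0.03, 0.04])

    def test_bonferroni_multiplies_by_m(self):
        got = enrichment.adjust_pvalues([0.01, 0.5, 1.0, 0.2, 0.9],
                                        method="bonferroni")
        assert got[0] == pytest.approx(0.05)

    def test_all_ones_stay_capped(self):
        assert (enrichment.adjust_pvalues([1.0, 1.0], method="fdr_bh") == 1.0).all()

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            enrichment.adjust_pvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            enrichment.adjust_pvalues([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_bh_matches_hand_rolled_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 15)))
        m = p.size
        order = np.argsort(p)
        adjusted = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            adjusted[idx] = running
        assert np.allclose(
            enrichment.adjust_pvalues(p, method="fdr_bh"), adjusted, atol=1e-12
        )


class TestEnrichmentProfile:
    def test_self_property_is_maximally_enriched(self):
        rng = np.random.default_rng(0)
        table = make_gene_table(rng, n_strata=5, genes_per_stratum=50)
        prop = table["stratum"] == 5
        profile = enrichment.enrichment_profile(table, prop, "is_ps5")
        t = profile.table.set_index("stratum")
        assert t.at[5, "log_odds"] > 0 and t.at[5, "significant"]
        assert (t.drop(5)["log_odds"] < 0).all()

    def test_planted_odds_ratio_flags_youngest_stratum(self):
        """Property planted with odds ratio 4 in the youngest stratum at
        n=200 per stratum is a significant positive flag."""
        rng = np.random.default_rng(1)
        table = make_gene_table(rng, n_strata=5, genes_per_stratum=200)
        base = 0.25
        boosted = (4 * base / (1 - base)) / (1 + 4 * base / (1 - base))
        prop = pd.Series(rng.random(len(table)) < base, index=table.index)
        young = table["stratum"] == 5
        prop[young] = rng.random(int(young.sum())) < boosted
        profile = enrichment.enrichment_profile(table, prop, "planted")
        row = profile.table.set_index("stratum").loc[5]
        assert row["significant"] and row["log_odds"] > 0

    def test_counts_partition_the_background(self):
        rng = np.random.default_rng(2)
        table = make_gene_table(rng)
        prop = pd.Series(rng.random(len(table)) < 0.3, index=table.index)
        profile = enrichment.enrichment_profile(table, prop)
        assert profile.table["n"].sum() == profile.N == len(table)
        assert profile.table["k"].sum() == profile.K == int(prop.sum())

    def test_undefined_property_rejected(self):
        rng = np.random.default_rng(3)
        table = make_gene_table(rng)
        prop = pd.Series(True, index=table.index[:-1])
        with pytest.raises(ValueError, match="every locus"):
            enrichment.enrichment_profile(table, prop)


class TestBedReader:
    def test_start_not_below_end_rejected_with_line(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t10\t20\nchr1\t30\t30\n")
        with pytest.raises(ValueError, match=":2"):
            enrichment.read_bed(bed)

    def test_round_trips_through_markset(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t10\t20\nchr2\t5\t500\n")
        ms = enrichment.MarkSet.from_bed(bed, "cpg")
        assert len(ms.intervals) == 2 and ms.mark_type == "cpg"
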
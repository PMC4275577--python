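import numpy as np
import pandas as pd
import pytest

from interleave import (FeatureTable, GenomeFeature, assign_neighbors,
                        count_convergent_overlaps, median_convergent_overlap,
                        orientation, orientation_counts, overlap_3prime,
                        summarize_categories, ymc_adjacency,
                        ymc_adjacency_counts)

from conftest import make_table


def feat(fid, chrom, start, end, strand, klass="ORF_T", phase="NC"):
    return GenomeFeature(fid, chrom, start, end, strand, klass, phase, {})


class TestOrientation:
    # hand-enumerated truth table: 4 strand combinations x 3 gap signs
    TRUTH = {("+", "+"): "TANDEM", ("-", "-"): "TANDEM",
             ("+", "-"): "CONVERGENT", ("-", "+"): "DIVERGENT"}

    @pytest.mark.parametrize("s1,s2", list(TRUTH))
    @pytest.mark.parametrize("gap", [-10, 0, 50])
    def test_truth_table(self, s1, s2, gap):
        a = feat("a", "chrI", 100, 200, s1)
        b = feat("b", "chrI", 201 + gap, 400 + gap, s2)
        assert orientation(a, b) == self.TRUTH[(s1, s2)]

    def test_different_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            orientation(feat("a", "chrI", 1, 10, "+"),
                        feat("b", "chrII", 1, 10, "+"))


class TestAssignNeighbors:
    def test_gap_arithmetic_and_eligibility(self):
        t = make_table([
            ("a", "chrI", 1, 100, "+", "ORF_T", "NC", 1.0, 1.0),
            ("b", "chrI", 151, 300, "+", "ORF_T", "NC", 1.0, 1.0),
            ("c", "chrI", 1302, 1500, "+", "ORF_T", "NC", 1.0, 1.0),
        ])
        rel = assign_neighbors(t, max_gap=1000)
        ab = rel[(rel["focal_id"] == "a") & (rel["neighbor_id"] == "b")]
        assert int(ab["gap_bp"].iloc[0]) == 50 and bool(ab["eligible"].iloc[0])
        bc = rel[(rel["focal_id"] == "b") & (rel["neighbor_id"] == "c")]
        assert int(bc["gap_bp"].iloc[0]) == 1001
        assert not bool(bc["eligible"].iloc[0])   # rule is <= 1000, strict

    def test_sides_follow_focal_strand(self):
        t = make_table([
            ("a", "chrI", 1, 100, "+", "ORF_T", "NC", 1.0, 1.0),
            ("b", "chrI", 200, 300, "-", "ORF_T", "NC", 1.0, 1.0),
        ])
        rel = assign_neighbors(t).set_index("focal_id")
        assert rel.loc["a", "side"] == "DOWNSTREAM_3P"
        assert rel.loc["b", "side"] == "DOWNSTREAM_3P"  # '-' focal, left nbr
        assert set(rel["orientation"]) == {"CONVERGENT"}

    def test_matches_all_pairs_brute_force(self, small_genome):
        table, _ = small_genome
        rel = assign_neighbors(table, max_gap=1000)
        # independent oracle: per feature, scan all others on its chromosome
        df = table.df
        expected = set()
        order = {fid: (s, e, fid) for fid, s, e in
                 zip(df["feature_id"], df["start"], df["end"])}
        for chrom, sl in table.chrom_slices():
            block = df.iloc[sl]
            for _, row in block.iterrows():
                others = block[block["feature_id"] != row["feature_id"]]
                before = others[[order[f] < order[row["feature_id"]]
                                 for f in others["feature_id"]]]
                after = others[[order[f] > order[row["feature_id"]]
                                for f in others["feature_id"]]]
                if len(before):
                    left = before.iloc[-1]
                    expected.add((row["feature_id"], left["feature_id"],
                                  int(row["start"] - left["end"] - 1)))
                if len(after):
                    right = after.iloc[0]
                    expected.add((row["feature_id"], right["feature_id"],
                                  int(right["start"] - row["end"] - 1)))
        got = set(zip(rel["focal_id"], rel["neighbor_id"],
                      rel["gap_bp"].astype(int)))
        assert got == expected

    def test_relation_graph_is_symmetric(self, small_genome):
        table, _ = small_genome
        rel = assign_neighbors(table)
        pairs = set(zip(rel["focal_id"], rel["neighbor_id"]))
        assert all((b, a) in pairs for a, b in pairs)
        counts = rel["focal_id"].value_counts()
        assert counts.max() <= 2


class TestOverlap3Prime:
    def test_convergent_overlap_example(self):
        a = feat("a", "chrI", 1, 100, "+")
        b = feat("b", "chrI", 80, 200, "-")
        r = overlap_3prime(a, b)
        assert r == {"overlapping": True, "overlap_bp": 21}

    def test_same_strand_not_overlapping(self):
        a = feat("a", "chrI", 1, 100, "+")
        b = feat("b", "chrI", 80, 200, "+")
        assert overlap_3prime(a, b)["overlapping"] is False

    def test_divergent_intersection_needs_relaxed_rule(self):
        # 3' ends point away from the shared region
        a = feat("a", "chrI", 1, 100, "-")
        b = feat("b", "chrI", 80, 200, "+")
        assert overlap_3prime(a, b)["overlapping"] is False
        assert overlap_3prime(a, b, strict=False)["overlapping"] is True

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s1, e1 = sorted(rng.integers(1, 500, 2) + [0, 1])
            s2, e2 = sorted(rng.integers(1, 500, 2) + [0, 1])
            a = feat("a", "chrI", int(s1), int(e1),
                     rng.choice(["+", "-"]))
            b = feat("b", "chrI", int(s2), int(e2),
                     rng.choice(["+", "-"]))
            assert overlap_3prime(a, b) == overlap_3prime(b, a)

    def test_planted_median_overlap_recovered(self):
        from interleave import SyntheticGenomeParams, generate_genome
        params = SyntheticGenomeParams(seed=21, n_chrom=4,
                                       genes_per_chrom=200,
                                       convergent_overlap_rate=0.3)
        table, truth = generate_genome(params)
        planted = [o["overlap_bp"] for o in truth["overlaps"]
                   if o["convergent"]]
        got = median_convergent_overlap(table)
        assert got == pytest.approx(np.median(planted), rel=0.25)


class TestYmcAdjacency:
    def test_flanked_and_single(self):
        t = make_table([
            ("a", "chrI", 1, 100, "+", "ORF_T", "NC", 1.0, 1.0),
            ("b", "chrI", 200, 300, "+", "ORF_T", "OX", 1.0, 1.0),
            ("c", "chrI", 400, 500, "+", "ORF_T", "NC", 1.0, 1.0),
            ("d", "chrI", 600, 700, "+", "ORF_T", "RC", 1.0, 1.0),
            ("e", "chrI", 800, 900, "+", "ORF_T", "RB", 1.0, 1.0),
        ])
        adj = ymc_adjacency(t).set_index("feature_id")
        assert adj.loc["b", "klass"] == "FLANKED_NONCYCLING"
        assert adj.loc["d", "klass"] == "SINGLE_PARTNER"
        # chromosome-terminal cycling gene with one cycling neighbour
        assert adj.loc["e", "klass"] == "SINGLE_PARTNER"
        assert "a" not in adj.index  # non-cycling features unclassified

    def test_matches_per_gene_recount(self, small_genome):
        table, _ = small_genome
        adj = ymc_adjacency(table, max_gap=1000).set_index("feature_id")
        orf = table.df[table.df["feature_class"] == "ORF_T"].reset_index(
            drop=True)
        for chrom in orf["chrom"].unique():
            block = orf[orf["chrom"] == chrom].reset_index(drop=True)
            for i, row in block.iterrows():
                if row["ymc_phase"] == "NC":
                    continue
                n = 0
                for j in (i - 1, i + 1):
                    if 0 <= j < len(block):
                        other = block.iloc[j]
                        gap = (max(row["start"], other["start"])
                               - min(row["end"], other["end"]) - 1)
                        if gap <= 1000 and other["ymc_phase"] != "NC":
                            n += 1
                assert adj.loc[row["feature_id"],
                               "n_cycling_neighbors"] == n

    def test_counts_partition_cycling_genes(self, small_genome):
        table, _ = small_genome
        counts = ymc_adjacency_counts(table)
        orf = table.df[table.df["feature_class"] == "ORF_T"]
        n_cycling = int((orf["ymc_phase"] != "NC").sum())
        assert sum(counts.values()) == n_cycling


class TestSummarizeCategories:
    def test_median_of_even_group(self):
        t = make_table([
            ("a", "chrI", 1, 100, "+", "ORF_T", "OX", 4.0, 1.0),
            ("b", "chrI", 200, 300, "+", "ORF_T", "RC", 2.0, 1.0),
            ("c", "chrII", 1, 100, "+", "ORF_T", "OX", 10.0, 1.0),
            ("d", "chrII", 200, 300, "+", "ORF_T", "RC", 2.0, 1.0),
        ])
        rel = assign_neighbors(t)
        summary = summarize_categories(t, rel, "ymc_phase", "glu")
        row = summary[(summary["orientation"] == "TANDEM")
                      & (summary["focal_attr"] == "OX")
                      & (summary["neighbor_attr"] == "RC")]
        assert int(row["count"].iloc[0]) == 2
        assert float(row["median_expr"].iloc[0]) == 7.0

    def test_empty_categories_absent(self, tiny_table):
        rel = assign_neighbors(tiny_table)
        summary = summarize_categories(tiny_table, rel, "ymc_phase", "glu")
        assert (summary["count"] > 0).all()

    def test_counts_match_groupby_recount(self, small_genome):
        table, _ = small_genome
        rel = assign_neighbors(table)
        summary = summarize_categories(table, rel, "feature_class", "gal")
        phase = table.df.set_index("feature_id")["feature_class"]
        elig = rel[rel["eligible"]]
        brute = {}
        for _, r in elig.iterrows():
            key = (r["orientation"], phase[r["focal_id"]],
                   phase[r["neighbor_id"]])
            brute[key] = brute.get(key, 0) + 1
        got = {(r["orientation"], r["focal_attr"], r["neighbor_attr"]):
               int(r["count"]) for _, r in summary.iterrows()}
        assert got == brute

    def test_orientation_totals_match_relation_counts(self, small_genome):
        table, _ = small_genome
        rel = assign_neighbors(table)
        summary = summarize_categories(table, rel, "ymc_phase", "glu")
        elig = rel[rel["eligible"]]
        for orient in ("TANDEM", "CONVERGENT", "DIVERGENT"):
            total = summary.loc[summary["orientation"] == orient,
                                "count"].sum()
            assert total == (elig["orientation"] == orient).sum()


class TestCountConvergentOverlaps:
    def test_counts_only_strict_geometry(self):
        t = make_table([
            ("a", "chrI", 1, 100, "+", "ORF_T", "NC", 1.0, 1.0),
            ("b", "chrI", 80, 200, "-", "ORF_T", "NC", 1.0, 1.0),   # hit
            ("c", "chrI", 400, 500, "-", "ORF_T", "NC", 1.0, 1.0),
            ("d", "chrI", 450, 600, "+", "ORF_T", "NC", 1.0, 1.0),  # div.
        ])
        assert count_convergent_overlaps(t) == 1
        assert count_convergent_overlaps(t, strict=False) == 2

    def test_orientation_counts_sum_to_eligible_pairs(self, small_genome):
        table, _ = small_genome
        counts = orientation_counts(table, max_gap=10**9)
        n_pairs = sum(max(0, sl.stop - sl.start - 1)
                      for _, sl in table.chrom_slices())
        assert sum(counts.values()) == n_pairs
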
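import numpy as np
import pytest

from interleave import (SyntheticGenomeParams, count_antisense,
                        generate_coverage, generate_factor_matrix,
                        generate_genome)


class TestParams:
    def test_bad_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            SyntheticGenomeParams(class_proportions=(0.5, 0.5, 0.5, 0.5))

    def test_impossible_enrichment_rejected(self):
        with pytest.raises(ValueError, match="enrichment"):
            SyntheticGenomeParams(planted_overlap_enrichment=5.0)

    def test_oversized_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap length"):
            SyntheticGenomeParams(overlap_length_log_mean=np.log(5000.0))

    def test_background_rate_from_enrichment(self):
        p = SyntheticGenomeParams(convergent_overlap_rate=0.2,
                                  planted_overlap_enrichment=3.0)
        # observed/null = 4 p_c / (p_c + 3 p_b) = 3  =>  p_b = p_c / 9
        assert p.effective_background_overlap_rate == \
            pytest.approx(0.2 / 9)
        q = SyntheticGenomeParams(planted_overlap_enrichment=1.0,
                                  convergent_overlap_rate=0.2)
        assert q.effective_background_overlap_rate == pytest.approx(0.2)


class TestGenerateGenome:
    def test_single_gene_genome(self):
        p = SyntheticGenomeParams(seed=1, n_chrom=1, genes_per_chrom=1)
        table, truth = generate_genome(p)
        assert len(table) == 1
        f = next(table.features())
        assert f.start >= 1 and f.end >= f.start
        assert truth["overlaps"] == []

    def test_all_ox_when_proportions_degenerate(self):
        p = SyntheticGenomeParams(seed=1, n_chrom=1, genes_per_chrom=40,
                                  ymc_proportions=(1.0, 0.0, 0.0, 0.0))
        table, _ = generate_genome(p)
        assert (table.df["ymc_phase"] == "OX").all()

    def test_class_proportions_within_sampling_error(self):
        props = (0.7, 0.15, 0.1, 0.05)
        p = SyntheticGenomeParams(seed=8, n_chrom=4, genes_per_chrom=500,
                                  class_proportions=props)
        table, _ = generate_genome(p)
        n = len(table)
        counts = table.df["feature_class"].value_counts()
        for klass, prob in zip(("ORF_T", "SUT", "CUT", "OTHER"), props):
            se = np.sqrt(prob * (1 - prob) / n)
            assert counts[klass] / n == pytest.approx(prob, abs=3 * se)

    def test_identical_params_byte_identical_output(self):
        p = SyntheticGenomeParams(seed=4, n_chrom=2, genes_per_chrom=50)
        t1, truth1 = generate_genome(p)
        t2, truth2 = generate_genome(p)
        assert t1.df.equals(t2.df)
        assert truth1["overlaps"] == truth2["overlaps"]

    def test_planted_overlaps_match_geometry(self):
        p = SyntheticGenomeParams(seed=6, n_chrom=2, genes_per_chrom=150,
                                  convergent_overlap_rate=0.3)
        table, truth = generate_genome(p)
        coords = table.df.set_index("feature_id")
        assert truth["n_overlaps"] > 0
        for o in truth["overlaps"]:
            a, b = coords.loc[o["left"]], coords.loc[o["right"]]
            inter = min(a["end"], b["end"]) - max(a["start"], b["start"]) + 1
            assert inter == o["overlap_bp"] > 0

    def test_ymc_clustering_raises_partner_rate(self):
        base = dict(n_chrom=4, genes_per_chrom=400, seed=13)
        t0, _ = generate_genome(SyntheticGenomeParams(ymc_clustering=0.0,
                                                      **base))
        t1, _ = generate_genome(SyntheticGenomeParams(ymc_clustering=0.8,
                                                      **base))

        def adjacent_cycling_rate(t):
            cyc = (t.df["ymc_phase"] != "NC").to_numpy()
            chrom = t.df["chrom"].to_numpy()
            same = chrom[:-1] == chrom[1:]
            return (cyc[:-1] & cyc[1:] & same).sum() / (cyc[:-1] &
                                                        same).sum()
        assert adjacent_cycling_rate(t1) > adjacent_cycling_rate(t0) + 0.1


class TestGenerateCoverage:
    def test_zero_antisense_fraction(self):
        p = SyntheticGenomeParams(seed=2, n_chrom=1, genes_per_chrom=30,
                                  antisense_fraction=0.0,
                                  convergent_overlap_rate=0.0,
                                  background_overlap_rate=0.0)
        table, _ = generate_genome(p)
        cov_p, cov_m = generate_coverage(table, p)
        counts = count_antisense(cov_p, cov_m, table)
        assert (counts["antisense_count"] == 0).all()

    def test_zero_expression_gives_empty_coverage(self):
        p = SyntheticGenomeParams(seed=2, n_chrom=1, genes_per_chrom=10)
        table, _ = generate_genome(p)
        table.df["expr_glu"] = 0.0
        cov_p, cov_m = generate_coverage(table, p, condition="glu")
        assert cov_p.total() == 0 and cov_m.total() == 0

    def test_sense_mass_tracks_expression(self):
        p = SyntheticGenomeParams(seed=3, n_chrom=1, genes_per_chrom=100,
                                  antisense_fraction=0.0,
                                  convergent_overlap_rate=0.0,
                                  background_overlap_rate=0.0,
                                  coverage_depth=5.0)
        table, _ = generate_genome(p)
        cov_p, cov_m = generate_coverage(table, p, condition="glu")
        counts = count_antisense(cov_p, cov_m, table)
        expected = 5.0 * table.expr("glu").sum()
        assert counts["sense_count"].sum() == pytest.approx(expected,
                                                            rel=0.05)


class TestGenerateFactorMatrix:
    def test_zero_baseline_all_unbound(self):
        p = SyntheticGenomeParams(seed=2, n_chrom=1, genes_per_chrom=40,
                                  n_factors=10, factor_baseline_rate=0.0)
        table, _ = generate_genome(p)
        matrix, _ = generate_factor_matrix(table, p)
        assert not matrix.bound.to_numpy().any()

    def test_planted_factor_binds_set_more(self):
        p = SyntheticGenomeParams(
            seed=9, n_chrom=2, genes_per_chrom=200, n_factors=5,
            factor_baseline_rate=0.1,
            planted_factors=(("F001", "RC", 8.0),))
        table, _ = generate_genome(p)
        matrix, truth = generate_factor_matrix(table, p)
        assert truth["planted"][0]["factor"] == "F001"
        phase = table.df.set_index("feature_id")["ymc_phase"]
        in_set = [phase[g] == "RC" for g in matrix.genes]
        row = matrix.bound.loc["F001"].to_numpy()
        assert row[in_set].mean() > row[np.logical_not(in_set)].mean() + 0.2

    def test_reproducible(self):
        p = SyntheticGenomeParams(seed=2, n_chrom=1, genes_per_chrom=40,
                                  n_factors=8)
        table, _ = generate_genome(p)
        m1, _ = generate_factor_matrix(table, p)
        m2, _ = generate_factor_matrix(table, p)
        assert m1.bound.equals(m2.bound)
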
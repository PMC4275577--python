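import numpy as np
import pandas as pd
import pytest

from interleave import FeatureTable, SyntheticGenomeParams, generate_genome


def make_table(rows, conditions=("glu", "gal")):
    """Build a FeatureTable from (id, chrom, start, end, strand, class,
    phase, expr...) tuples."""
    cols = ["feature_id", "chrom", "start", "end", "strand",
            "feature_class", "ymc_phase"] + [f"expr_{c}" for c in conditions]
    return FeatureTable(pd.DataFrame(rows, columns=cols))


@pytest.fixture
def tiny_table():
    return make_table([
        ("g1", "chrI", 100, 400, "+", "ORF_T", "OX", 10.0, 2.0),
        ("g2", "chrI", 451, 900, "+", "ORF_T", "RC", 3.0, 30.0),
        ("g3", "chrI", 950, 1500, "-", "SUT", "NC", 5.0, 5.0),
        ("g4", "chrII", 10, 200, "-", "ORF_T", "RB", 7.0, 7.0),
        ("g5", "chrII", 260, 600, "+", "CUT", "NC", 0.0, 1.0),
    ])


@pytest.fixture(scope="session")
def small_genome():
    """A 200-feature synthetic genome with default (structured) settings."""
    params = SyntheticGenomeParams(seed=11, n_chrom=2, genes_per_chrom=100)
    table, truth = generate_genome(params)
    return table, truth


@pytest.fixture(scope="session")
def unstructured_params():
    """No planted structure: attributes exchangeable within chromosomes."""
    return SyntheticGenomeParams(seed=5, n_chrom=4, genes_per_chrom=60,
                                 ymc_clustering=0.0,
                                 planted_overlap_enrichment=1.0)


def per_chrom_multisets(table):
    """(chrom -> sorted interval list, chrom -> attribute Counters)."""
    from collections import Counter
    intervals, counters = {}, {}
    for chrom, sl in table.chrom_slices():
        block = table.df.iloc[sl]
        intervals[chrom] = list(zip(block["start"], block["end"]))
        counters[chrom] = {
            col: Counter(block[col]) for col in
            ("strand", "feature_class", "ymc_phase")
        }
    return intervals, counters
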
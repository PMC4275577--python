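"""Sense/antisense quantification from stranded per-base coverage.

For every feature, sense signal is the same-strand coverage summed over the
feature interval and antisense the opposite-strand coverage over the same
interval — no flank extension.  Inputs are per-base nascent-transcription
signals (3'OH-clipped), so sums are signal mass rather than read counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FeatureTable, StrandedCoverage


def count_antisense(cov_plus: StrandedCoverage, cov_minus: StrandedCoverage,
                    table: FeatureTable) -> pd.DataFrame:
    """Sense and antisense coverage mass per feature.

    Returns a DataFrame ``feature_id, sense_count, antisense_count,
    antisense_ratio`` where the ratio is antisense/(sense+antisense)
    (NaN when both are zero).  A feature extending beyond either coverage
    track raises an error naming the feature.
    """
    if cov_plus.strand != "+" or cov_minus.strand != "-":
        raise ValueError("pass the '+' track first and the '-' track second")
    # prefix sums give O(1) window sums per feature
    cums = {}
    for cov in (cov_plus, cov_minus):
        for chrom, arr in cov.data.items():
            cums[(cov.strand, chrom)] = np.concatenate(
                ([0.0], np.cumsum(arr)))
    records = []
    for f in table.features():
        sums = {}
        for strand in "+-":
            key = (strand, f.chrom)
            if key not in cums:
                raise ValueError(
                    f"feature {f.feature_id}: chromosome {f.chrom} absent "
                    f"from the {strand} coverage track")
            cs = cums[key]
            if f.end > len(cs) - 1:
                raise ValueError(
                    f"feature {f.feature_id} ({f.chrom}:{f.start}-{f.end}) "
                    f"extends beyond the {strand} coverage track "
                    f"(length {len(cs) - 1})")
            sums[strand] = float(cs[f.end] - cs[f.start - 1])
        sense = sums[f.strand]
        anti = sums["-" if f.strand == "+" else "+"]
        total = sense + anti
        records.append((f.feature_id, sense, anti,
                        anti / total if total > 0 else float("nan")))
    return pd.DataFrame(records, columns=["feature_id", "sense_count",
                                          "antisense_count",
                                          "antisense_ratio"])


def mean_antisense_fraction(counts: pd.DataFrame) -> float:
    """Mean per-feature antisense fraction, ignoring zero-signal features."""
    return float(counts["antisense_ratio"].dropna().mean())
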
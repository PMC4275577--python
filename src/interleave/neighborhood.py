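"""Gene-pair orientation, 3'-end overlap, and metabolic-cycle adjacency.

Adjacent features on a chromosome form pairs in one of three orientations:
tandem (same strand), convergent (3' ends facing) or divergent (5' ends
facing).  Pairs separated by more than ``max_gap`` (default 1,000 bp) are
recorded but flagged ineligible, so downstream statistics consider only
genes with a close neighbour.  Convergent pairs whose 3' ends run into the
same stretch of the genome are called 3'-overlapping.

For features annotated with a yeast-metabolic-cycle (YMC) phase, each
cycling gene is classed by how many of its eligible neighbours also cycle:
flanked by non-cycling genes, a single cycling partner, or cycling partners
on both sides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EXPR_PREFIX, FeatureTable

ORIENTATIONS = ("DIVERGENT", "TANDEM", "CONVERGENT")
SIDES = ("UPSTREAM_5P", "DOWNSTREAM_3P")
YMC_ADJACENCY_CLASSES = ("FLANKED_NONCYCLING", "SINGLE_PARTNER",
                         "DOUBLE_PARTNER")

DEFAULT_MAX_GAP = 1000


def orientation(first, second) -> str:
    """Orientation of a genomically ordered pair (first.start <= second.start).

    Same strand -> TANDEM; (+,-) -> CONVERGENT (3' ends face each other);
    (-,+) -> DIVERGENT (5' ends face each other).
    """
    if first.chrom != second.chrom:
        raise ValueError(
            f"features on different chromosomes: {first.chrom} vs "
            f"{second.chrom}")
    if first.start > second.start:
        raise ValueError("pair must be genomically ordered by start")
    if first.strand == second.strand:
        return "TANDEM"
    return "CONVERGENT" if first.strand == "+" else "DIVERGENT"


def _pair_orientation(strand_left: np.ndarray,
                      strand_right: np.ndarray) -> np.ndarray:
    out = np.where(strand_left == strand_right, "TANDEM",
                   np.where(strand_left == "+", "CONVERGENT", "DIVERGENT"))
    return out


def assign_neighbors(table: FeatureTable, max_gap: int = DEFAULT_MAX_GAP,
                     classes=None) -> pd.DataFrame:
    """Nearest-neighbour relations for every feature, both genomic sides.

    Neighbour search runs over the class-filtered, position-sorted table;
    each feature gets at most one relation per genomic side (chromosome-
    terminal features lack one).  ``gap_bp = second.start - first.end - 1``
    for 1-based closed intervals, so touching features have gap 0 and
    overlapping ones a negative gap; relations with ``gap_bp > max_gap``
    are flagged ineligible.

    Returns a DataFrame with columns ``focal_id, neighbor_id, side,
    orientation, gap_bp, eligible`` — two rows per adjacent pair (one per
    focal feature).
    """
    sub = table.subset(classes)
    frames = []
    df = sub.df
    for _chrom, sl in sub.chrom_slices():
        block = df.iloc[sl]
        n = len(block)
        if n < 2:
            continue
        ids = block["feature_id"].to_numpy()
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        strands = block["strand"].to_numpy()
        gap = starts[1:] - ends[:-1] - 1
        orient = _pair_orientation(strands[:-1], strands[1:])
        eligible = gap <= max_gap
        # left member of the pair: the neighbour sits on its genomic right,
        # which is its 3' side on "+" and its 5' side on "-"
        side_left = np.where(strands[:-1] == "+", "DOWNSTREAM_3P",
                             "UPSTREAM_5P")
        side_right = np.where(strands[1:] == "+", "UPSTREAM_5P",
                              "DOWNSTREAM_3P")
        frames.append(pd.DataFrame({
            "focal_id": np.concatenate([ids[:-1], ids[1:]]),
            "neighbor_id": np.concatenate([ids[1:], ids[:-1]]),
            "side": np.concatenate([side_left, side_right]),
            "orientation": np.concatenate([orient, orient]),
            "gap_bp": np.concatenate([gap, gap]),
            "eligible": np.concatenate([eligible, eligible]),
        }))
    if not frames:
        return pd.DataFrame(columns=["focal_id", "neighbor_id", "side",
                                     "orientation", "gap_bp", "eligible"])
    return pd.concat(frames, ignore_index=True)


def overlap_3prime(a, b, strict: bool = True) -> dict:
    """3'-end overlap call for two features on one chromosome.

    Overlapping means: opposite strands, a non-empty interval
    intersection and — under the strict (default) rule — both features'
    3'-terminal bases inside that intersection, i.e. the convergent
    read-into-each-other geometry.  ``strict=False`` relaxes the call to
    any opposite-strand intersection.
    """
    if a.chrom != b.chrom:
        raise ValueError("features on different chromosomes")
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    inter = max(0, hi - lo + 1)
    if a.strand == b.strand or inter == 0:
        return {"overlapping": False, "overlap_bp": inter}
    if strict:
        ok = (lo <= a.three_prime <= hi) and (lo <= b.three_prime <= hi)
    else:
        ok = True
    return {"overlapping": bool(ok), "overlap_bp": inter}


def _pair_arrays(sub: FeatureTable):
    """Consecutive same-chromosome pairs of the sorted table, as arrays."""
    df = sub.df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    strands = df["strand"].to_numpy()
    chroms = df["chrom"].to_numpy()
    if len(df) < 2:
        z = np.empty(0)
        return z, z, z, z, z, z, np.empty(0, dtype=bool)
    same = chroms[:-1] == chroms[1:]
    return (starts[:-1], ends[:-1], strands[:-1],
            starts[1:], ends[1:], strands[1:], same)


def _convergent_overlap_mask(sub: FeatureTable, strict: bool = True
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised 3'-overlap call over consecutive sorted pairs."""
    s1, e1, st1, s2, e2, st2, same = _pair_arrays(sub)
    if same.size == 0:
        return same, np.empty(0, dtype=int)
    lo = np.maximum(s1, s2)
    hi = np.minimum(e1, e2)
    inter = np.maximum(0, hi - lo + 1)
    opp = st1 != st2
    if strict:
        tp1 = np.where(st1 == "+", e1, s1)
        tp2 = np.where(st2 == "+", e2, s2)
        geom = (lo <= tp1) & (tp1 <= hi) & (lo <= tp2) & (tp2 <= hi)
    else:
        geom = np.ones_like(opp)
    return same & opp & (inter > 0) & geom, inter


def count_convergent_overlaps(table: FeatureTable, classes=None,
                              strict: bool = True) -> int:
    """Number of consecutive pairs called 3'-overlapping (convergent)."""
    mask, _ = _convergent_overlap_mask(table.subset(classes), strict)
    return int(mask.sum())


def median_convergent_overlap(table: FeatureTable, classes=None,
                              strict: bool = True) -> float:
    """Median overlapped bases among 3'-overlapping consecutive pairs."""
    mask, inter = _convergent_overlap_mask(table.subset(classes), strict)
    if not mask.any():
        return float("nan")
    return float(np.median(inter[mask]))


def orientation_counts(table: FeatureTable, max_gap: int = DEFAULT_MAX_GAP,
                       classes=None) -> dict[str, int]:
    """Eligible adjacent-pair counts per orientation (pairs, not relations)."""
    sub = table.subset(classes)
    counts = {o: 0 for o in ORIENTATIONS}
    s1, e1, st1, s2, _e2, st2, same = _pair_arrays(sub)
    if same.size == 0:
        return counts
    gap = s2 - e1 - 1
    orient = _pair_orientation(st1, st2)
    keep = same & (gap <= max_gap)
    for o in ORIENTATIONS:
        counts[o] = int(((orient == o) & keep).sum())
    return counts


def ymc_adjacency(table: FeatureTable, max_gap: int = DEFAULT_MAX_GAP,
                  classes=("ORF_T",)) -> pd.DataFrame:
    """Class each cycling feature by its number of cycling neighbours.

    Neighbourhood is computed on the class-filtered table (default:
    ORF-Ts only, the coding-gene adjacency analysis); a neighbour counts
    only if eligible under ``max_gap``.  Absent or ineligible neighbours
    count as non-cycling, so chromosome-terminal genes can reach at most
    SINGLE_PARTNER.

    Returns ``feature_id, n_cycling_neighbors, klass`` for features with
    ``ymc_phase != NC``.
    """
    sub = table.subset(classes)
    df = sub.df
    records = []
    for _chrom, sl in sub.chrom_slices():
        block = df.iloc[sl]
        n = len(block)
        ids = block["feature_id"].to_numpy()
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        cycling = (block["ymc_phase"].to_numpy() != "NC")
        gap = starts[1:] - ends[:-1] - 1 if n > 1 else np.empty(0, dtype=int)
        ok = gap <= max_gap
        left_partner = np.zeros(n, dtype=int)
        right_partner = np.zeros(n, dtype=int)
        if n > 1:
            right_partner[:-1] = (ok & cycling[1:]).astype(int)
            left_partner[1:] = (ok & cycling[:-1]).astype(int)
        total = left_partner + right_partner
        for i in np.flatnonzero(cycling):
            records.append((ids[i], int(total[i])))
    klass_map = {0: "FLANKED_NONCYCLING", 1: "SINGLE_PARTNER",
                 2: "DOUBLE_PARTNER"}
    out = pd.DataFrame(records, columns=["feature_id", "n_cycling_neighbors"])
    out["klass"] = out["n_cycling_neighbors"].map(klass_map)
    return out


def ymc_adjacency_counts(table: FeatureTable,
                         max_gap: int = DEFAULT_MAX_GAP,
                         classes=("ORF_T",)) -> dict[str, int]:
    adj = ymc_adjacency(table, max_gap=max_gap, classes=classes)
    counts = adj["klass"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in YMC_ADJACENCY_CLASSES}


def summarize_categories(table: FeatureTable, relations: pd.DataFrame,
                         attribute: str = "ymc_phase",
                         condition: str | None = None,
                         labels: pd.Series | dict | None = None
                         ) -> pd.DataFrame:
    """Per-category counts and median focal expression over eligible
    relations.

    Categories are keyed by (orientation, focal attribute, neighbour
    attribute).  ``attribute`` may be ``feature_class``, ``ymc_phase`` or
    ``switch``; for ``switch``, pass the per-feature labels (e.g. from
    :func:`interleave.switching.classify_switch`) via ``labels``.  Empty
    categories are omitted.  Median of an even-sized group is the mean of
    the two central values (numpy convention).
    """
    if attribute in ("feature_class", "ymc_phase"):
        attr = table.df.set_index("feature_id")[attribute]
    elif attribute == "switch":
        if labels is None:
            raise ValueError("attribute 'switch' needs per-feature labels")
        attr = pd.Series(labels)
    else:
        raise ValueError(f"unknown attribute {attribute!r}")
    if condition is None:
        condition = table.conditions[0]
    if condition not in table.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    expr = table.df.set_index("feature_id")[EXPR_PREFIX + condition]

    rel = relations.loc[relations["eligible"]].copy()
    rel["focal_attr"] = rel["focal_id"].map(attr)
    rel["neighbor_attr"] = rel["neighbor_id"].map(attr)
    rel["expr"] = rel["focal_id"].map(expr)
    grouped = rel.groupby(["orientation", "focal_attr", "neighbor_attr"],
                          observed=True)["expr"]
    out = grouped.agg(count="size", median_expr="median").reset_index()
    out["condition"] = condition
    return out.sort_values(["orientation", "focal_attr", "neighbor_attr"]
                           ).reset_index(drop=True)
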
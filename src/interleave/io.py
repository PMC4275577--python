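"""Reading, validating and writing genome feature tables and coverage tracks.

The canonical in-memory container is :class:`FeatureTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per transcript feature
(ORF-T, SUT, CUT or other).  Coordinates are held 1-based and fully closed,
the GFF3 convention; BED input is converted at the boundary.  Per-condition
normalized transcription levels live in ``expr_<condition>`` columns and are
assumed to be already normalized upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

logger = logging.getLogger("interleave")

STRANDS = ("+", "-")
FEATURE_CLASSES = ("ORF_T", "SUT", "CUT", "OTHER")
YMC_PHASES = ("OX", "RB", "RC", "NC")
#: phases that cycle during the yeast metabolic cycle (everything but NC)
CYCLING_PHASES = ("OX", "RB", "RC")

CORE_COLUMNS = ("feature_id", "chrom", "start", "end", "strand",
                "feature_class", "ymc_phase")
EXPR_PREFIX = "expr_"


class GenomeFeature(NamedTuple):
    """One transcript feature in 1-based closed coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    ymc_phase: str
    expr: Mapping[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the 3'-terminal base."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


class FeatureTable:
    """Validated, chromosome-grouped, start-sorted table of genome features.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``feature_id, chrom, start, end, strand, feature_class,
        ymc_phase`` plus one ``expr_<condition>`` column per condition.
    validate : bool
        Check invariants (coordinates, enumerations, unique ids).  Skipped
        on internal fast paths where validity is guaranteed by construction.
    sort : bool
        Sort by (chrom, start, end, feature_id).
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True,
                 sort: bool = True) -> None:
        if sort:
            df = df.sort_values(
                ["chrom", "start", "end", "feature_id"], kind="mergesort"
            ).reset_index(drop=True)
        self.df = df
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy(), validate=False, sort=False)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if df["feature_id"].duplicated().any():
            dups = df.loc[df["feature_id"].duplicated(), "feature_id"]
            raise ValueError(f"duplicate feature_id: {sorted(set(dups))}")
        if (df["start"] < 1).any():
            raise ValueError("start coordinates must be >= 1 (1-based closed)")
        if (df["end"] < df["start"]).any():
            bad = df.loc[df["end"] < df["start"], "feature_id"].tolist()
            raise ValueError(f"end < start for features {bad}")
        for col, allowed in (("strand", STRANDS),
                             ("feature_class", FEATURE_CLASSES),
                             ("ymc_phase", YMC_PHASES)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise ValueError(
                    f"unknown {col} value(s) {sorted(bad)}; "
                    f"allowed: {allowed}")
        for cond in self.conditions:
            col = EXPR_PREFIX + cond
            if (df[col] < 0).any():
                raise ValueError(f"negative expression in column {col}")

    # -- accessors ---------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        """Condition names taken from the ``expr_*`` columns, in order."""
        return [c[len(EXPR_PREFIX):] for c in self.df.columns
                if c.startswith(EXPR_PREFIX)]

    def expr(self, condition: str) -> np.ndarray:
        col = EXPR_PREFIX + condition
        if col not in self.df.columns:
            raise KeyError(
                f"unknown condition {condition!r}; have {self.conditions}")
        return self.df[col].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def features(self) -> Iterator[GenomeFeature]:
        conds = self.conditions
        for row in self.df.itertuples(index=False):
            expr = {c: getattr(row, EXPR_PREFIX + c) for c in conds}
            yield GenomeFeature(row.feature_id, row.chrom, int(row.start),
                                int(row.end), row.strand, row.feature_class,
                                row.ymc_phase, expr)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous row-slices per chromosome, in sorted order."""
        chroms = self.df["chrom"].to_numpy()
        if len(chroms) == 0:
            return []
        names, starts = np.unique(chroms, return_index=True)
        order = np.argsort(starts)
        starts = starts[order]
        names = names[order]
        bounds = np.append(starts, len(chroms))
        return [(str(names[i]), slice(int(bounds[i]), int(bounds[i + 1])))
                for i in range(len(names))]

    def subset(self, classes=None) -> "FeatureTable":
        """Restrict to the given feature classes (None keeps everything)."""
        if classes is None:
            return self
        keep = self.df["feature_class"].isin(list(classes))
        return FeatureTable(self.df.loc[keep].reset_index(drop=True),
                            validate=False, sort=False)

    def equals(self, other: "FeatureTable") -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if a[col].dtype.kind == "f":
                if not np.allclose(a[col], b[col], rtol=0, atol=1e-9):
                    return False
            elif not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        return True

    def __repr__(self) -> str:
        return (f"FeatureTable({len(self)} features, "
                f"{len(self.chrom_slices())} chromosomes, "
                f"conditions={self.conditions})")


@dataclass
class StrandedCoverage:
    """Dense per-base coverage for one strand, 1-based positions.

    ``data[chrom][i]`` is the signal at base ``i + 1``.
    """

    strand: str
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum over the closed 1-based interval [start, end]."""
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} absent from coverage track")
        arr = self.data[chrom]
        if start < 1 or end > len(arr):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside covered region "
                f"(1-{len(arr)})")
        return float(arr[start - 1:end].sum())


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

def _finalize(df: pd.DataFrame) -> FeatureTable:
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    expr_cols = [c for c in df.columns if c.startswith(EXPR_PREFIX)]
    for col in expr_cols:
        vals = pd.to_numeric(df[col].mask(df[col] == "."), errors="raise")
        n_missing = int(vals.isna().sum())
        if n_missing:
            logger.warning("column %s: %d missing expression values set to 0",
                           col, n_missing)
            vals = vals.fillna(0.0)
        df[col] = vals.astype(float)
    return FeatureTable(df)


def _read_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "chrom": str})
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.start) or pd.isna(row.end):
            raise ValueError(f"{path}: malformed row at line {i}")
    return df


def _read_gff3(path: Path) -> pd.DataFrame:
    records: list[dict] = []
    for feat in DataIterator(str(path)):
        attrs = feat.attributes
        rec = {
            "feature_id": (attrs.get("ID") or [feat.id or ""])[0],
            "chrom": feat.seqid,
            "start": feat.start,   # gffutils keeps 1-based closed
            "end": feat.end,
            "strand": feat.strand,
            "feature_class": (attrs.get("feature_class") or ["OTHER"])[0],
            "ymc_phase": (attrs.get("ymc_phase") or ["NC"])[0],
        }
        for key in attrs:
            if key.startswith(EXPR_PREFIX):
                rec[key] = float(attrs[key][0])
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=list(CORE_COLUMNS))
    return pd.DataFrame.from_records(records)


def _read_bed(path: Path) -> pd.DataFrame:
    """BED6(+): cols 7/8 may carry feature_class / ymc_phase, col 9 a
    semicolon-separated ``expr_<cond>=<value>`` attribute string."""
    records: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}: malformed BED row at line {lineno} "
                    f"(need >= 6 columns, got {len(parts)})")
            chrom, cstart, cend, name, _score, strand = parts[:6]
            rec = {
                "feature_id": name,
                "chrom": chrom,
                # BED is 0-based half-open; canonical form is 1-based closed
                "start": int(cstart) + 1,
                "end": int(cend),
                "strand": strand,
                "feature_class": parts[6] if len(parts) > 6 else "OTHER",
                "ymc_phase": parts[7] if len(parts) > 7 else "NC",
            }
            if len(parts) > 8 and parts[8] not in (".", ""):
                for item in parts[8].split(";"):
                    key, _, value = item.partition("=")
                    if not key.startswith(EXPR_PREFIX):
                        raise ValueError(
                            f"{path}: line {lineno}: unknown attribute "
                            f"{key!r} (expected {EXPR_PREFIX}*)")
                    rec[key] = float(value)
            records.append(rec)
    if not records:
        return pd.DataFrame(columns=list(CORE_COLUMNS))
    return pd.DataFrame.from_records(records)


def read_features(path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from ``tsv``, ``gff3`` or ``bed``.

    Returns a validated :class:`FeatureTable` in 1-based closed coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"tsv": _read_tsv, "gff3": _read_gff3, "bed": _read_bed}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; choose from "
                         f"{sorted(readers)}")
    df = readers[format](path)
    return _finalize(df)


def write_features(table: FeatureTable, path, format: str = "tsv") -> None:
    """Write a feature table as canonical TSV (lossless) or GFF3."""
    path = Path(path)
    if format == "tsv":
        out = table.df.copy()
        table_cols = list(CORE_COLUMNS) + [EXPR_PREFIX + c
                                           for c in table.conditions]
        out[table_cols].to_csv(path, sep="\t", index=False,
                               float_format="%.10g")
    elif format == "gff3":
        conds = table.conditions
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in table.features():
                attrs = [f"ID={f.feature_id}",
                         f"feature_class={f.feature_class}",
                         f"ymc_phase={f.ymc_phase}"]
                attrs += [f"{EXPR_PREFIX}{c}={f.expr[c]:.10g}" for c in conds]
                fh.write("\t".join([
                    f.chrom, "interleave", "transcript", str(f.start),
                    str(f.end), ".", f.strand, ".", ";".join(attrs),
                ]) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; choose tsv or gff3")


# ---------------------------------------------------------------------------
# coverage I/O (bedGraph-like, 0-based half-open on disk)
# ---------------------------------------------------------------------------

def read_coverage(path, strand: str,
                  chrom_sizes: Mapping[str, int] | None = None
                  ) -> StrandedCoverage:
    """Read a 4-column bedGraph into dense per-base counts.

    Unlisted positions are zero.  Track extent per chromosome is the largest
    listed end unless ``chrom_sizes`` says otherwise.
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be one of {STRANDS}")
    path = Path(path)
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            chrom, a, b, value = parts[0], int(parts[1]), int(parts[2]), \
                float(parts[3])
            if value < 0:
                raise ValueError(
                    f"{path}: negative coverage value at line {lineno}")
            if b <= a:
                raise ValueError(
                    f"{path}: empty or inverted interval at line {lineno}")
            intervals.setdefault(chrom, []).append((a, b, value))
    data: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (a1, b1, _), (a2, _, _) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom} "
                    f"({a1}-{b1} and from {a2})")
        size = max(b for _, b, _ in ivs)
        if chrom_sizes and chrom in chrom_sizes:
            size = max(size, chrom_sizes[chrom])
        arr = np.zeros(size, dtype=float)
        for a, b, value in ivs:
            arr[a:b] = value
        data[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            if chrom not in data:
                data[chrom] = np.zeros(size, dtype=float)
    return StrandedCoverage(strand=strand, data=data)


def write_coverage(cov: StrandedCoverage, path) -> None:
    """Write dense coverage back to bedGraph (run-length encoded)."""
    with open(path, "w") as fh:
        for chrom in sorted(cov.data):
            arr = cov.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for a, b in zip(starts, ends):
                v = arr[a]
                if v != 0:
                    fh.write(f"{chrom}\t{a}\t{b}\t{v:.10g}\n")
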
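"""Readers, writers and container types for the tabular formats the pipeline touches.

The pipeline deals in three kinds of on-disk data: feature x sample integer
count tables (sgRNA, ORF and clonal-barcode read counts) stored as TSV,
genomic intervals (gene models, aligned reads) stored as BED, and
per-chromosome coverage step functions stored as bedGraph.  All genomic
coordinates are 0-based half-open internally; BED/bedGraph are native to that
convention so no conversion happens at this boundary.

Parsing is deliberately hand-rolled on top of plain text so that malformed
cells can be reported with their row/column or line number, which the error
contracts here require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "IntervalSet",
    "CoverageTrack",
    "ParseError",
    "read_count_table",
    "write_count_table",
    "read_feature_meta",
    "read_intervals",
    "write_intervals",
    "read_bedgraph",
    "write_bedgraph",
]

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when an input file violates its documented schema."""


@dataclass
class CountTable:
    """Feature x sample matrix of non-negative integer read counts.

    ``feature_meta`` optionally maps feature id -> (gene symbol, is_control);
    screens use it as the guide->gene / ORF->gene map, with ``is_control``
    marking non-targeting features.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_meta: dict[str, tuple[str, bool]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def gene_of(self, feature: str) -> str | None:
        if self.feature_meta is None:
            return None
        meta = self.feature_meta.get(feature)
        return None if meta is None else meta[0]


def read_count_table(path, meta_path=None) -> CountTable:
    """Read a TSV count table: first column feature id, header row sample ids.

    Every data cell must be a non-negative integer; violations name the
    offending feature row and sample column.  ``meta_path`` optionally points
    to a feature->(gene, is_control) side table (TSV: feature, gene,
    is_control as 0/1 or true/false).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}: duplicate sample ids in header")
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} columns, found {len(parts)}"
                )
            fid = parts[0]
            row = []
            for sample, cell in zip(sample_ids, parts[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"(feature {fid!r}, sample {sample!r})"
                    ) from None
                if value < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative count {value} "
                        f"(feature {fid!r}, sample {sample!r})"
                    )
                row.append(value)
            feature_ids.append(fid)
            rows.append(row)
    if len(set(feature_ids)) != len(feature_ids):
        raise ParseError(f"{path}: duplicate feature ids")
    counts = np.asarray(rows, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    meta = read_feature_meta(meta_path) if meta_path is not None else None
    return CountTable(feature_ids, sample_ids, counts, feature_meta=meta)


def write_count_table(table: CountTable, path, meta_path=None) -> None:
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(table.sample_ids) + "\n")
        for i, fid in enumerate(table.feature_ids):
            fh.write(fid + "\t" + "\t".join(str(int(c)) for c in table.counts[i]) + "\n")
    if meta_path is not None and table.feature_meta is not None:
        with open(meta_path, "w") as fh:
            fh.write("feature\tgene\tis_control\n")
            for fid in table.feature_ids:
                gene, is_control = table.feature_meta[fid]
                fh.write(f"{fid}\t{gene}\t{int(is_control)}\n")


_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def read_feature_meta(path) -> dict[str, tuple[str, bool]]:
    meta: dict[str, tuple[str, bool]] = {}
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            flag = parts[2].strip().lower()
            if flag in _TRUTHY:
                is_control = True
            elif flag in _FALSY:
                is_control = False
            else:
                raise ParseError(f"{path}:{lineno}: bad is_control flag {parts[2]!r}")
            meta[parts[0]] = (parts[1], is_control)
    return meta


@dataclass
class IntervalSet:
    """BED-style genomic intervals, 0-based half-open."""

    records: pd.DataFrame  # columns: chrom, start, end, name, strand

    COLUMNS = ["chrom", "start", "end", "name", "strand"]

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"interval frame missing columns {missing}")
        self.records = df = df[self.COLUMNS].reset_index(drop=True)
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("interval start < 0")
            if (df["end"] <= df["start"]).any():
                raise ValueError("interval end <= start")
            bad = set(df["strand"]) - VALID_STRANDS
            if bad:
                raise ValueError(f"invalid strand value(s) {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tuples(cls, tuples) -> "IntervalSet":
        df = pd.DataFrame(list(tuples), columns=cls.COLUMNS)
        if not len(df):
            df = pd.DataFrame(columns=cls.COLUMNS)
        return cls(df)


def read_intervals(path) -> IntervalSet:
    """Read a BED file (>=3 columns; missing name -> '', missing strand -> '.')."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in VALID_STRANDS:
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, start, end, name, strand))
    return IntervalSet.from_tuples(rows)


def write_intervals(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for rec in intervals.records.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t0\t{rec.strand}\n")


@dataclass
class CoverageTrack:
    """Per-chromosome step function of rpm/bp read density.

    ``segments`` maps chrom -> (starts, ends, values) where the arrays describe
    sorted non-overlapping half-open intervals with value > 0 between them and
    implicit zero elsewhere.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (starts, ends, values) in self.segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: segment array length mismatch")
            if len(starts):
                if np.any(ends <= starts):
                    raise ValueError(f"{chrom}: empty or inverted segment")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"{chrom}: overlapping or unsorted segments")
                if np.any(values < 0):
                    raise ValueError(f"{chrom}: negative coverage value")
            self.segments[chrom] = (starts, ends, values)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of the step function over [start, end) in value*bp units."""
        if chrom not in self.segments or end <= start:
            return 0.0
        starts, ends, values = self.segments[chrom]
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        overlap = np.clip(hi - lo, 0, None)
        return float(np.dot(overlap, values))

    def total_mass(self) -> float:
        return sum(
            float(np.dot(ends - starts, values))
            for starts, ends, values in self.segments.values()
        )


def read_bedgraph(path) -> CoverageTrack:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph record") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage")
            per_chrom.setdefault(parts[0], []).append((start, end, value))
    segments = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts, ends, values = (np.asarray(x) for x in zip(*rows))
        segments[chrom] = (starts, ends, values)
    return CoverageTrack(segments)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.segments):
            starts, ends, values = track.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
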
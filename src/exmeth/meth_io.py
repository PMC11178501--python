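"""Reading, validation, filtering and replicate merging of per-CpG
methylation call tables, plus BED-style genomic interval I/O.

Methylation calls use a 6-column tab-separated bedGraph dialect
(chrom, start, end, rate, meth_count, total_count) with 0-based
half-open coordinates; ``end == start + 1`` and the position is the C
of a CpG on the plus strand (strand-collapsed calls are assumed).
Header lines starting with ``#`` are tolerated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

CALL_COLUMNS = ["chrom", "pos", "rate", "meth", "total"]

#: chromosome names treated as non-autosomal when ``autosomes_only`` is set
SEX_MITO_PATTERN = r"^(chr)?(X|Y|M|MT)$"

RATE_COUNT_TOLERANCE = 0.01


@dataclass
class CpGCallTable:
    """Per-CpG methylation calls for one sample.

    ``df`` holds columns ``chrom`` (str), ``pos`` (int, 0-based),
    ``rate`` (float in [0, 1]), ``meth`` (int), ``total`` (int),
    sorted by (chrom, pos) with unique positions.
    """

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _normalize_calls(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["pos"].to_numpy()

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g.reset_index(drop=True) for c, g in self.df.groupby("chrom", sort=True)}


def _normalize_calls(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, CALL_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "meth", "total"):
        df[col] = df[col].astype(np.int64)
    df["rate"] = df["rate"].astype(float)
    if (df["pos"] < 0).any():
        raise ValidationError("negative CpG position")
    if (df["total"] < 1).any():
        raise ValidationError("total_count must be >= 1")
    if (df["meth"] < 0).any():
        raise ValidationError("meth_count must be >= 0")
    bad = df["meth"] > df["total"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"meth_count > total_count at {df['chrom'].iat[i]}:{df['pos'].iat[i]}"
        )
    mismatch = (df["rate"] - df["meth"] / df["total"]).abs() > RATE_COUNT_TOLERANCE
    if mismatch.any():
        i = int(np.flatnonzero(mismatch.to_numpy())[0])
        raise ValidationError(
            f"rate inconsistent with counts (>{RATE_COUNT_TOLERANCE}) at "
            f"{df['chrom'].iat[i]}:{df['pos'].iat[i]}"
        )
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValidationError(f"duplicate CpG position {dup['chrom']}:{dup['pos']}")
    return df


@dataclass(frozen=True)
class CoverageFilter:
    """Read-depth bounds, both inclusive (``at least`` / ``at most``)."""

    min_reads: int
    max_reads: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_reads <= self.max_reads):
            raise ValidationError(
                f"require 1 <= min_reads <= max_reads, got {self.min_reads}, {self.max_reads}"
            )


FEATURE_KINDS = ("cgi", "tile", "promoter", "gene")


@dataclass
class FeatureSet:
    """Genomic intervals (0-based half-open) with strand and attributes.

    ``df`` holds ``feature_id``, ``chrom``, ``start``, ``end``, ``strand``,
    ``kind`` plus optional attribute columns such as ``obs_exp``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("feature_id", "chrom"):
            df[col] = df[col].astype(str)
        for col in ("start", "end"):
            df[col] = df[col].astype(np.int64)
        if "strand" not in df.columns:
            df["strand"] = "."
        if "kind" not in df.columns:
            raise ValidationError("FeatureSet requires a 'kind' column")
        if (df["start"] < 0).any():
            raise ValidationError("negative feature coordinate")
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"start >= end for feature {row['feature_id']} "
                f"({row['chrom']}:{row['start']}-{row['end']})"
            )
        if df["feature_id"].duplicated().any():
            dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValidationError(f"duplicate feature_id {dup!r}")
        bad_strand = ~df["strand"].isin(["+", "-", "."])
        if bad_strand.any():
            raise ValidationError(f"invalid strand value {df.loc[bad_strand, 'strand'].iloc[0]!r}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, ids: Iterable[str]) -> "FeatureSet":
        ids = set(ids)
        return FeatureSet(self.df[self.df["feature_id"].isin(ids)])

    def lookup(self, feature_id: str) -> pd.Series:
        hit = self.df[self.df["feature_id"] == feature_id]
        if hit.empty:
            raise KeyError(feature_id)
        return hit.iloc[0]


def is_autosome(chrom: str) -> bool:
    import re

    return re.match(SEX_MITO_PATTERN, chrom) is None


# ---------------------------------------------------------------------------
# methylation call I/O


def read_cpg_calls(path, sample_id: str) -> CpGCallTable:
    """Read a 6-column methylation bedGraph dialect file.

    Columns: chrom, start, end, rate, meth_count, total_count, with
    ``end == start + 1``. Raises :class:`ParseError` naming the line on
    malformed input and :class:`ValidationError` on inconsistent counts.
    """
    rows = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 tab-separated fields")
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
                rate = float(parts[3])
                meth = int(parts[4])
                total = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if end != start + 1:
                raise ParseError(f"{path}: line {lineno}: end must equal start + 1")
            rows.append((chrom, start, rate, meth, total))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CpGCallTable(sample_id=sample_id, df=df)


def write_cpg_calls(table: CpGCallTable, path) -> None:
    """Write calls in the same 6-column dialect read by :func:`read_cpg_calls`."""
    df = table.df
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\trate\tmeth_count\ttotal_count\n")
        for chrom, pos, rate, meth, total in df.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{rate:.6f}\t{meth}\t{total}\n")


def filter_coverage(table: CpGCallTable, filt: CoverageFilter) -> CpGCallTable:
    """Keep CpGs with ``min_reads <= total_count <= max_reads`` (inclusive)."""
    keep = (table.df["total"] >= filt.min_reads) & (table.df["total"] <= filt.max_reads)
    return CpGCallTable(sample_id=table.sample_id, df=table.df[keep])


def merge_replicates(tables: Sequence[CpGCallTable], merged_id: str) -> CpGCallTable:
    """Combine replicates at the raw count level.

    Per (chrom, pos), methylated and total counts are summed over the
    replicates covering that position (union of positions) and the merged
    rate is recomputed from the summed counts. Merging precedes any
    coverage filtering intended for the merged table.
    """
    if not tables:
        raise ValidationError("merge_replicates requires at least one table")
    frames = [t.df[["chrom", "pos", "meth", "total"]] for t in tables]
    cat = pd.concat(frames, ignore_index=True)
    agg = (
        cat.groupby(["chrom", "pos"], sort=True, as_index=False)[["meth", "total"]]
        .sum()
    )
    agg["rate"] = agg["meth"] / agg["total"]
    return CpGCallTable(sample_id=merged_id, df=agg[CALL_COLUMNS])


# ---------------------------------------------------------------------------
# feature (BED) I/O


def read_features(path, kind: str) -> FeatureSet:
    """Read BED3+ intervals; column 4 (if present) is the feature name.

    Missing names are auto-generated as ``kind_chrom_start_end``. A header
    line starting with ``#`` may name extra columns (e.g. ``obs_exp`` for
    CGI tables); recognised extras are carried as attributes.
    """
    if kind not in FEATURE_KINDS:
        raise ValidationError(f"unknown feature kind {kind!r}")
    header: list[str] | None = None
    rows = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                cols = line.lstrip("#").split("\t")
                if len(cols) >= 3 and cols[0].lower() in ("chrom", "chr"):
                    header = cols
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if start < 0:
                raise ValidationError(f"{path}: line {lineno}: negative coordinate")
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else (
                f"{kind}_{chrom}_{start}_{end}"
            )
            strand = "."
            if len(parts) > 5 and parts[5] in ("+", "-", "."):
                strand = parts[5]
            row = {
                "feature_id": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "kind": kind,
            }
            if header is not None:
                for col, val in zip(header[6:], parts[6:]):
                    row[col] = float(val) if col == "obs_exp" else val
            rows.append(row)
    return FeatureSet(pd.DataFrame(rows))


def write_features(features: FeatureSet, path) -> None:
    """Write a FeatureSet as BED6(+obs_exp); round-trips coordinates exactly."""
    df = features.df
    has_oe = "obs_exp" in df.columns
    with open(path, "wt") as fh:
        cols = "chrom\tstart\tend\tname\tscore\tstrand"
        fh.write("#" + cols + ("\tobs_exp" if has_oe else "") + "\n")
        for _, row in df.iterrows():
            line = (
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"{row['feature_id']}\t0\t{row['strand']}"
            )
            if has_oe:
                oe = row["obs_exp"]
                line += f"\t{'' if pd.isna(oe) else format(float(oe), '.6f')}"
            fh.write(line + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "wt") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
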
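"""Readers/writers for the text formats the toolkit consumes, plus genome
binning and per-bin aggregation of cytosine counts.

Formats
-------
* chrom.sizes      two-column TSV: chromosome name, length
* BED6             0-based half-open intervals
* bedGraph         chrom, start, end, value; non-overlapping per track
* cytosine report  per-cytosine TSV with 1-based positions and columns
                   chrom, pos, strand, context (CG/CHG/CHH),
                   count_methylated, count_total
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet

__all__ = [
    "CONTEXTS",
    "CX_COLUMNS",
    "CoverageTrack",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "make_bins",
    "aggregate_bins",
]

CONTEXTS = ("CG", "CHG", "CHH")
CX_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]
_CX_DTYPES = {
    "chrom": str,
    "pos": np.int64,
    "strand": str,
    "context": str,
    "count_methylated": np.int64,
    "count_total": np.int64,
}


@dataclass
class CoverageTrack:
    """A bedGraph-style step track: per-interval raw counts plus the
    library size used for per-million normalization.

    ``data`` columns: chrom, start, end, value. Intervals must not overlap
    within the track.
    """

    data: pd.DataFrame
    total_mapped: float | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"track missing columns {missing}")
        if (self.data["value"] < 0).any():
            raise ValueError("track values must be non-negative")
        for chrom, grp in self.data.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")

    def scaled(self, factor: float) -> "CoverageTrack":
        out = self.data.copy()
        out["value"] = out["value"] * factor
        return replace(self, data=out)

    def value_array(self, chrom: str, length: int) -> np.ndarray:
        """Dense per-bp value vector for one chromosome (0 where no interval)."""
        arr = np.zeros(length, dtype=np.float64)
        sub = self.data[self.data["chrom"] == chrom]
        for s, e, v in zip(sub["start"].values, sub["end"].values, sub["value"].values):
            arr[max(0, int(s)) : min(length, int(e))] = v
        return arr


# ---------------------------------------------------------------------------
# cytosine reports


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a per-cytosine count table; validates every record.

    Raises ``ValueError`` naming the offending 1-based line number for
    malformed lines or records with count_methylated > count_total.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            chrom, pos, strand, context, meth, total = parts
            try:
                pos_i, meth_i, total_i = int(pos), int(meth), int(total)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if pos_i < 1:
                raise ValueError(f"{path}: line {lineno}: position must be >= 1")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ValueError(f"{path}: line {lineno}: bad context {context!r}")
            if meth_i < 0 or total_i < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if meth_i > total_i:
                raise ValueError(
                    f"{path}: line {lineno}: count_methylated ({meth_i}) > "
                    f"count_total ({total_i}) at {chrom}:{pos_i}"
                )
            rows.append((chrom, pos_i, strand, context, meth_i, total_i))
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    return df.astype(_CX_DTYPES) if len(df) else df


def write_cytosine_report(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


# ---------------------------------------------------------------------------
# chrom sizes / BED / bedGraph


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'name length'")
            name, length = parts[0], int(parts[1])
            if length <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive length")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path, chrom_sizes: Mapping[str, int] | None = None,
             label: str | None = None) -> RegionSet:
    """Read a BED3-6 file. If chrom_sizes is given, out-of-bounds intervals
    are rejected."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] != "." else None
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise ValueError(
                        f"{path}: line {lineno}: end {end} exceeds length "
                        f"{chrom_sizes[chrom]} of {chrom}"
                    )
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return RegionSet(intervals, label=label or str(path))


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            strand = iv.strand if iv.strand is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")


def read_bedgraph(path, total_mapped: float | None = None,
                  chrom_sizes: Mapping[str, int] | None = None) -> CoverageTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        comment="#",
    )
    if chrom_sizes is not None:
        for chrom, grp in df.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}: unknown chromosome {chrom!r}")
            if int(grp["end"].max()) > chrom_sizes[chrom]:
                raise ValueError(f"{path}: interval beyond end of {chrom}")
    return CoverageTrack(df, total_mapped=total_mapped)


def write_bedgraph(track: CoverageTrack, path) -> None:
    track.data.to_csv(path, sep="\t", header=False, index=False,
                      columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# binning


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int = 100) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins; the last bin of each
    chromosome is truncated at the chromosome end.

    Returns a DataFrame with columns chrom, start, end in genome order.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, starts, ends = [], [], []
    for chrom, length in chrom_sizes.items():
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": np.concatenate(starts) if starts else np.array([], dtype=np.int64),
            "end": np.concatenate(ends) if ends else np.array([], dtype=np.int64),
        }
    )


def aggregate_bins(
    cytosines: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    context: str,
    bin_size: int = 100,
    read_floor: int = 4,
) -> pd.DataFrame:
    """Pool per-cytosine counts of one context into fixed-size bins.

    A cytosine at 1-based position ``p`` belongs to the bin containing
    0-based ``p - 1``. Every cytosine's reads contribute to the pooled
    ``meth_reads``/``total_reads``; ``n_cytosines_covered`` counts only
    cytosines with ``count_total >= read_floor`` (bin-eligibility filter;
    under-covered cytosines still contribute reads).

    Returns the full bin grid with columns chrom, start, end, meth_reads,
    total_reads, n_cytosines_covered, level (NaN where total_reads == 0).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    bins = make_bins(chrom_sizes, bin_size)
    bins = bins.assign(
        meth_reads=np.int64(0), total_reads=np.int64(0), n_cytosines_covered=np.int64(0)
    )
    # genome-wide flat bin index
    offsets: dict[str, int] = {}
    acc = 0
    for chrom, length in chrom_sizes.items():
        offsets[chrom] = acc
        acc += int(np.ceil(length / bin_size))

    sub = cytosines[cytosines["context"] == context]
    if len(sub):
        for chrom, grp in sub.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"cytosine on unknown chromosome {chrom!r}")
            if int(grp["pos"].max()) > chrom_sizes[chrom]:
                raise ValueError(
                    f"cytosine beyond end of {chrom} "
                    f"(pos {int(grp['pos'].max())} > {chrom_sizes[chrom]})"
                )
            idx = offsets[chrom] + (grp["pos"].values - 1) // bin_size
            nb = len(bins)
            meth = np.bincount(idx, weights=grp["count_methylated"].values, minlength=nb)
            total = np.bincount(idx, weights=grp["count_total"].values, minlength=nb)
            cov = np.bincount(
                idx, weights=(grp["count_total"].values >= read_floor), minlength=nb
            )
            bins["meth_reads"] += meth.astype(np.int64)
            bins["total_reads"] += total.astype(np.int64)
            bins["n_cytosines_covered"] += cov.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        bins["level"] = np.where(
            bins["total_reads"] > 0, bins["meth_reads"] / bins["total_reads"], np.nan
        )
    bins["context"] = context
    return bins
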
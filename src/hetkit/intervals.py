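"""Genomic interval primitives shared by every module.

Intervals follow BED conventions: 0-based, half-open ``[start, end)``.
A :class:`RegionSet` is an ordered, labelled collection of intervals with
fast per-chromosome overlap arithmetic built on sorted numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = ["GenomicInterval", "RegionSet", "merge_intervals", "coverage_index"]


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic interval, 0-based half-open.

    ``name`` carries free-form annotation (e.g. a TE family label);
    ``attributes`` is an optional mapping for anything richer.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    attributes: Mapping | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted-by-start intervals into a disjoint set."""
    if len(starts) == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    # new run begins wherever the start exceeds the running max of prior ends
    run_max = np.maximum.accumulate(e)
    new_run = np.ones(len(s), dtype=bool)
    new_run[1:] = s[1:] > run_max[:-1]
    idx = np.flatnonzero(new_run)
    merged_starts = s[idx]
    merged_ends = np.append(run_max[idx[1:] - 1], run_max[-1])
    return merged_starts, merged_ends


class coverage_index:
    """Prefix-sum index over a merged (disjoint, sorted) interval set on one
    chromosome; answers 'how many covered bp fall below position x' in O(log n)."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts, self.ends = merge_intervals(
            np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)
        )
        self.prefix = np.concatenate(
            [[0], np.cumsum(self.ends - self.starts)]
        )

    def covered_below(self, x) -> np.ndarray:
        """Covered bp in [0, x) for scalar or array x."""
        x = np.asarray(x, dtype=np.int64)
        if len(self.starts) == 0:
            return np.zeros_like(x)
        i = np.searchsorted(self.starts, x, side="right")
        full = self.prefix[i]
        # subtract the part of the last overlapping interval at/after x
        trim = np.where(
            i > 0, np.maximum(0, self.ends[np.maximum(i - 1, 0)] - x), 0
        )
        return full - trim

    def overlap_bp(self, starts, ends) -> np.ndarray:
        """Covered bp inside each query [start, end)."""
        return self.covered_below(ends) - self.covered_below(starts)


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` with a label.

    Iteration order is genomic sort order (chrom, start, end). Internal
    overlaps are allowed unless the caller flattens first.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str | None = None):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.label = label
        self._cov: dict[str, coverage_index] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str | None = None) -> "RegionSet":
        cols = df.columns
        return cls(
            (
                GenomicInterval(
                    chrom=str(r.chrom),
                    start=int(r.start),
                    end=int(r.end),
                    name=str(r.name_) if "name_" in cols and pd.notna(r.name_) else None,
                    score=float(r.score) if "score" in cols and pd.notna(r.score) else None,
                    strand=str(r.strand) if "strand" in cols and pd.notna(r.strand) else None,
                )
                for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
            ),
            label=label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)

    def total_bp(self) -> int:
        """Sum of interval lengths (double-counts internal overlaps)."""
        return int(self.lengths().sum()) if len(self) else 0

    def flattened_bp(self) -> int:
        """Unioned (merged) bp of the set."""
        return sum(
            int((c.ends - c.starts).sum()) for c in (self._coverage(ch) for ch in self.chroms)
        )

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        ivs = [iv for iv in self.intervals if iv.chrom == chrom]
        return (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )

    def _coverage(self, chrom: str) -> coverage_index:
        if chrom not in self._cov:
            self._cov[chrom] = coverage_index(*self.by_chrom(chrom))
        return self._cov[chrom]

    # -- overlap arithmetic -------------------------------------------
    def overlap_bp_per_interval(self, other: "RegionSet") -> np.ndarray:
        """For each interval of self (in sorted order), bp covered by the
        union of ``other``."""
        out = np.zeros(len(self), dtype=np.int64)
        for i, iv in enumerate(self.intervals):
            out[i] = int(self._other_cov(other, iv.chrom).overlap_bp(iv.start, iv.end))
        return out

    @staticmethod
    def _other_cov(other: "RegionSet", chrom: str) -> coverage_index:
        return other._coverage(chrom)

    def count_overlapping(self, other: "RegionSet", min_bp: int = 1) -> np.ndarray:
        """Boolean mask: which intervals of self share >= min_bp with other."""
        return self.overlap_bp_per_interval(other) >= min_bp

    def validate_against(self, chrom_sizes: Mapping[str, int]) -> None:
        """Raise if any interval escapes the genome described by chrom_sizes."""
        for iv in self.intervals:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {chrom_sizes[iv.chrom]}"
                )
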
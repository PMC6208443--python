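"""Coverage-track arithmetic: per-million normalization, scale-region
metaplots with fixed-width flanks, per-region statistics, mark association
against shuffled controls, and track-track correlation.

Two signal kinds are supported throughout:

* a :class:`~hetkit.io.CoverageTrack` (bedGraph step function), averaged
  length-weighted;
* a cytosine count table plus a context, pooled as
  sum(methylated)/sum(total) reads per positional bin (weighted pooling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RegionSet
from .io import CONTEXTS, CoverageTrack

__all__ = [
    "Metaplot",
    "normalize_per_million",
    "metaplot",
    "region_stats",
    "h3_normalized_density",
    "mark_association",
    "track_correlation",
]


def normalize_per_million(track: CoverageTrack) -> CoverageTrack:
    """Scale raw counts by 1e6 / total_mapped."""
    if not track.total_mapped or track.total_mapped <= 0:
        raise ValueError("normalize_per_million requires total_mapped > 0")
    out = track.scaled(1e6 / track.total_mapped)
    out.total_mapped = 1e6
    return out


# ---------------------------------------------------------------------------
# dense per-bp accumulators with fractional-position integrals


class _Cumulative:
    """Prefix integrals of a per-bp signal, queryable at fractional
    coordinates (the signal is piecewise constant on each bp)."""

    def __init__(self, values: np.ndarray):
        self.n = len(values)
        self.cum = np.concatenate([[0.0], np.cumsum(values, dtype=np.float64)])

    def integral(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Integral over [a, b) clipped to the chromosome; fractional ends
        are linearly interpolated within their bp."""
        a = np.clip(np.asarray(a, dtype=np.float64), 0, self.n)
        b = np.clip(np.asarray(b, dtype=np.float64), 0, self.n)

        def at(x):
            i = np.floor(x).astype(np.int64)
            i = np.minimum(i, self.n - 1)
            i = np.maximum(i, 0)
            frac = x - i
            return self.cum[i] + frac * (self.cum[i + 1] - self.cum[i])

        return at(b) - at(a)


def _track_arrays(track: CoverageTrack, chrom_sizes: Mapping[str, int]) -> dict[str, _Cumulative]:
    return {
        chrom: _Cumulative(track.value_array(chrom, length))
        for chrom, length in chrom_sizes.items()
    }


def _methylation_arrays(
    cytosines: pd.DataFrame, context: str, chrom_sizes: Mapping[str, int]
) -> tuple[dict[str, _Cumulative], dict[str, _Cumulative]]:
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = cytosines[cytosines["context"] == context]
    meth_idx, tot_idx = {}, {}
    for chrom, length in chrom_sizes.items():
        meth = np.zeros(length)
        tot = np.zeros(length)
        grp = sub[sub["chrom"] == chrom]
        if len(grp):
            pos0 = grp["pos"].values - 1  # 1-based -> 0-based
            np.add.at(meth, pos0, grp["count_methylated"].values)
            np.add.at(tot, pos0, grp["count_total"].values)
        meth_idx[chrom] = _Cumulative(meth)
        tot_idx[chrom] = _Cumulative(tot)
    return meth_idx, tot_idx


def _feature_bin_edges(
    start: int, end: int, flank_bp: int, body_bins: int, flank_bins: int
) -> np.ndarray:
    """Fractional bin edges (genome coordinates) for one plus-strand
    feature: upstream flank, scaled body, downstream flank."""
    up = np.linspace(start - flank_bp, start, flank_bins + 1)
    body = np.linspace(start, end, body_bins + 1)
    down = np.linspace(end, end + flank_bp, flank_bins + 1)
    return np.concatenate([up[:-1], body[:-1], down])


@dataclass
class Metaplot:
    """Feature-by-bin signal matrix with its aggregate curve.

    ``matrix`` rows are features in the sorted order of the input set; the
    bin axis runs 5'->3' (minus-strand features are reversed). ``mean`` is
    the aggregate per-bin curve: nan-mean of rows for track signals, or
    pooled sum(meth)/sum(total) for methylation signals. ``counts`` is the
    number of features contributing data to each bin.
    """

    matrix: np.ndarray
    mean: np.ndarray
    counts: np.ndarray
    flank_bp: int
    body_bins: int
    flank_bins: int
    kind: str  # "track" | "methylation"
    meth_matrix: np.ndarray | None = None
    total_matrix: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def metaplot(
    signal,
    features: RegionSet,
    chrom_sizes: Mapping[str, int],
    flank_bp: int = 2000,
    body_bins: int = 60,
    flank_bins: int = 20,
    context: str | None = None,
) -> Metaplot:
    """Scale-region average profile over a feature set.

    ``signal`` is a CoverageTrack, or a cytosine table (then ``context`` is
    required). Bodies are rescaled to ``body_bins`` equal fractional bins
    (features shorter than body_bins bp are stretched, not dropped); flanks
    are fixed-width, ``flank_bp / flank_bins`` bp per bin. Bins falling
    entirely outside the chromosome are missing (NaN) and excluded from the
    aggregate's denominator.
    """
    if len(features) == 0:
        raise ValueError("metaplot requires a non-empty feature set")
    n_bins = 2 * flank_bins + body_bins
    n_feat = len(features)

    is_track = isinstance(signal, CoverageTrack)
    if is_track:
        cum = _track_arrays(signal, chrom_sizes)
    else:
        if context is None:
            raise ValueError("context is required for methylation signals")
        meth_cum, tot_cum = _methylation_arrays(signal, context, chrom_sizes)

    matrix = np.full((n_feat, n_bins), np.nan)
    meth_m = np.zeros((n_feat, n_bins)) if not is_track else None
    tot_m = np.zeros((n_feat, n_bins)) if not is_track else None

    for i, iv in enumerate(features):
        length = chrom_sizes[iv.chrom]
        edges = _feature_bin_edges(iv.start, iv.end, flank_bp, body_bins, flank_bins)
        lo, hi = edges[:-1], edges[1:]
        clo, chi = np.clip(lo, 0, length), np.clip(hi, 0, length)
        width = chi - clo
        valid = width > 1e-9
        if is_track:
            ints = cum[iv.chrom].integral(clo, chi)
            row = np.where(valid, ints / np.where(valid, width, 1.0), np.nan)
        else:
            m = meth_cum[iv.chrom].integral(clo, chi)
            t = tot_cum[iv.chrom].integral(clo, chi)
            m = np.where(valid, m, 0.0)
            t = np.where(valid, t, 0.0)
            row = np.where(t > 0, m / np.where(t > 0, t, 1.0), np.nan)
        if iv.strand == "-":
            row = row[::-1]
            if not is_track:
                m, t = m[::-1], t[::-1]
        matrix[i] = row
        if not is_track:
            meth_m[i], tot_m[i] = m, t

    if is_track:
        counts = np.sum(~np.isnan(matrix), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, np.nansum(matrix, axis=0) / np.maximum(counts, 1), np.nan)
        return Metaplot(matrix, mean, counts, flank_bp, body_bins, flank_bins, "track")
    tot_sum = tot_m.sum(axis=0)
    meth_sum = meth_m.sum(axis=0)
    mean = np.where(tot_sum > 0, meth_sum / np.where(tot_sum > 0, tot_sum, 1.0), np.nan)
    counts = np.sum(tot_m > 0, axis=0)
    return Metaplot(matrix, mean, counts, flank_bp, body_bins, flank_bins,
                    "methylation", meth_matrix=meth_m, total_matrix=tot_m)


# ---------------------------------------------------------------------------
# per-region statistics


def region_stats(
    signal,
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
    context: str | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-region value plus a box-plot summary.

    For a track: length-weighted mean of values over the region. For a
    cytosine table (+context): pooled sum(meth)/sum(total) over the region,
    missing (NaN) when no covered cytosine falls inside.

    Returns (per-region table, summary dict with quartiles and the count of
    missing regions).
    """
    is_track = isinstance(signal, CoverageTrack)
    if is_track:
        cum = _track_arrays(signal, chrom_sizes)
    else:
        if context is None:
            raise ValueError("context is required for methylation signals")
        meth_cum, tot_cum = _methylation_arrays(signal, context, chrom_sizes)
    vals = np.full(len(regions), np.nan)
    for i, iv in enumerate(regions):
        if is_track:
            vals[i] = cum[iv.chrom].integral(iv.start, iv.end) / iv.length
        else:
            t = float(tot_cum[iv.chrom].integral(iv.start, iv.end))
            if t > 0:
                vals[i] = float(meth_cum[iv.chrom].integral(iv.start, iv.end)) / t
    table = regions.to_dataframe()
    table["value"] = vals
    ok = vals[~np.isnan(vals)]
    summary = {
        "n": int(len(regions)),
        "n_missing": int(np.isnan(vals).sum()),
        "min": float(np.min(ok)) if len(ok) else np.nan,
        "q1": float(np.percentile(ok, 25)) if len(ok) else np.nan,
        "median": float(np.median(ok)) if len(ok) else np.nan,
        "q3": float(np.percentile(ok, 75)) if len(ok) else np.nan,
        "max": float(np.max(ok)) if len(ok) else np.nan,
        "mean": float(np.mean(ok)) if len(ok) else np.nan,
    }
    return table, summary


def h3_normalized_density(
    mark_track: CoverageTrack,
    h3_track: CoverageTrack,
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
) -> np.ndarray:
    """Per-region ratio of length-weighted mean mark signal to mean H3
    signal; NaN where the H3 mean is zero. Both tracks should already be
    normalized per million."""
    mark_cum = _track_arrays(mark_track, chrom_sizes)
    h3_cum = _track_arrays(h3_track, chrom_sizes)
    out = np.full(len(regions), np.nan)
    for i, iv in enumerate(regions):
        h3 = h3_cum[iv.chrom].integral(iv.start, iv.end) / iv.length
        if h3 > 0:
            out[i] = (mark_cum[iv.chrom].integral(iv.start, iv.end) / iv.length) / h3
    return out


def _set_mean(cum: dict[str, _Cumulative], regions: RegionSet) -> float:
    """bp-weighted mean of the signal over a region set (sum of integrals /
    sum of lengths)."""
    total = 0.0
    bp = 0
    for iv in regions:
        total += float(cum[iv.chrom].integral(iv.start, iv.end))
        bp += iv.length
    if bp == 0:
        raise ValueError("region set has zero total bp")
    return total / bp


def mark_association(
    peaks: RegionSet,
    mark_tracks: Mapping[str, CoverageTrack] | CoverageTrack,
    control_sets: Sequence[RegionSet],
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """log2(mean signal over peaks / mean signal over controls) per mark.

    The control mean is the average of the per-set means. Positive values
    mean the mark is enriched at peaks. Invariant to per-million scaling of
    any individual mark (the scale factor cancels in the ratio).
    """
    if len(peaks) == 0:
        raise ValueError("mark_association requires a non-empty peak set")
    if not control_sets:
        raise ValueError("at least one control set is required")
    if isinstance(mark_tracks, CoverageTrack):
        mark_tracks = {"mark": mark_tracks}
    rows = []
    for name, track in mark_tracks.items():
        cum = _track_arrays(track, chrom_sizes)
        peak_mean = _set_mean(cum, peaks)
        ctrl_means = [_set_mean(cum, cs) for cs in control_sets]
        ctrl_mean = float(np.mean(ctrl_means))
        log2 = np.log2(peak_mean / ctrl_mean) if peak_mean > 0 and ctrl_mean > 0 else np.nan
        rows.append({
            "mark": name, "peak_mean": peak_mean, "control_mean": ctrl_mean,
            "log2_ratio": log2, "n_control_sets": len(control_sets),
        })
    return pd.DataFrame(rows)


def track_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10_000,
) -> dict[str, float]:
    """Pearson and Spearman correlation of two tracks on a fixed bin grid.

    Bins with zero signal in *both* tracks are excluded; the number of
    bins used is reported as ``n``.
    """
    cum_a = _track_arrays(track_a, chrom_sizes)
    cum_b = _track_arrays(track_b, chrom_sizes)
    va, vb = [], []
    for chrom, length in chrom_sizes.items():
        edges = np.arange(0, length + bin_size, bin_size, dtype=np.float64)
        edges[-1] = min(edges[-1], length)
        lo, hi = edges[:-1], edges[1:]
        w = hi - lo
        keep = w > 0
        va.append(cum_a[chrom].integral(lo[keep], hi[keep]) / w[keep])
        vb.append(cum_b[chrom].integral(lo[keep], hi[keep]) / w[keep])
    a = np.concatenate(va)
    b = np.concatenate(vb)
    nonzero = (a != 0) | (b != 0)
    a, b = a[nonzero], b[nonzero]
    if len(a) < 2:
        raise ValueError("fewer than two informative bins")
    pearson = float(np.corrcoef(a, b)[0, 1])
    spearman = float(stats.spearmanr(a, b).statistic)
    return {"pearson": pearson, "spearman": spearman, "n": int(len(a))}
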
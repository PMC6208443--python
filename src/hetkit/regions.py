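"""Region-set statistics and null models.

Covers pairwise overlap summaries of the Venn style, genomic-context
composition of a region set, TE-family enrichment, classification of
peak-bound TEs, length-matched shuffled control sets, and chromosome-wide
density profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, RegionSet, coverage_index

__all__ = [
    "OccupancyParams",
    "OverlapResult",
    "overlap_sets",
    "annotate_composition",
    "te_family_enrichment",
    "classify_bound_tes",
    "shuffle_regions",
    "chromosome_density",
]


@dataclass
class OccupancyParams:
    """Thresholds for the peak-occupancy analyses."""

    bound_te_min_overlap_fraction: float = 0.8  # strict '>' at the boundary
    long_te_threshold: int = 4000
    n_control_sets: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.bound_te_min_overlap_fraction <= 1:
            raise ValueError("bound_te_min_overlap_fraction must be in (0, 1]")
        if self.long_te_threshold <= 0:
            raise ValueError("long_te_threshold must be positive")


@dataclass
class OverlapResult:
    """Membership-level overlap summary of two region sets.

    Percentages are given at full precision (``pct_a``) and truncated to
    the integer part (``pct_a_int``), matching how such figures are
    conventionally quoted (11 of 12 -> 91%).
    """

    n_a: int
    n_b: int
    n_a_overlapping_b: int
    n_b_overlapping_a: int
    pct_a: float
    pct_b: float
    pct_a_int: int
    pct_b_int: int
    a_shared: RegionSet = field(repr=False)
    a_unique: RegionSet = field(repr=False)
    b_shared: RegionSet = field(repr=False)
    b_unique: RegionSet = field(repr=False)


def overlap_sets(a: RegionSet, b: RegionSet, min_bp: int = 1) -> OverlapResult:
    """Count members of each set that share at least ``min_bp`` with the
    other set, and partition each set into shared/unique subsets."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    mask_a = a.count_overlapping(b, min_bp=min_bp)
    mask_b = b.count_overlapping(a, min_bp=min_bp)
    n_ab = int(mask_a.sum())
    n_ba = int(mask_b.sum())
    pct_a = 100.0 * n_ab / len(a) if len(a) else 0.0
    pct_b = 100.0 * n_ba / len(b) if len(b) else 0.0
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_a_overlapping_b=n_ab,
        n_b_overlapping_a=n_ba,
        pct_a=pct_a,
        pct_b=pct_b,
        pct_a_int=int(math.floor(pct_a)),
        pct_b_int=int(math.floor(pct_b)),
        a_shared=RegionSet([iv for iv, m in zip(a, mask_a) if m], label="a_shared"),
        a_unique=RegionSet([iv for iv, m in zip(a, mask_a) if not m], label="a_unique"),
        b_shared=RegionSet([iv for iv, m in zip(b, mask_b) if m], label="b_shared"),
        b_unique=RegionSet([iv for iv, m in zip(b, mask_b) if not m], label="b_unique"),
    )


def annotate_composition(
    regions: RegionSet, genes: RegionSet, tes: RegionSet
) -> tuple[dict[str, float], pd.DataFrame]:
    """Assign each region to one genomic category by plurality of bp.

    Categories: ``te``, ``gene``, ``intergenic``. Ties are broken toward
    ``te`` then ``gene``. Returns (fractions over regions, per-region
    table). Fractions sum to 1 for a non-empty input; the ``mixed`` key is
    kept in the dict for interface stability but is always 0 under the
    plurality rule.
    """
    te_bp = regions.overlap_bp_per_interval(tes)
    gene_bp = regions.overlap_bp_per_interval(genes)
    # intergenic bp needs the union of TE+gene coverage, not max(t, g)
    both = RegionSet(list(tes) + list(genes), label="annot")
    union_bp = regions.overlap_bp_per_interval(both)
    rows = []
    for iv, t, g, u in zip(regions, te_bp, gene_bp, union_bp):
        t, g = int(t), int(g)
        inter = iv.length - int(u)
        best = max(t, g, inter)
        if t == best:
            cat = "te"
        elif g == best:
            cat = "gene"
        else:
            cat = "intergenic"
        rows.append(
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "te_bp": t, "gene_bp": g, "intergenic_bp": inter, "category": cat}
        )
    table = pd.DataFrame(rows)
    n = len(regions)
    fractions = {"te": 0.0, "gene": 0.0, "intergenic": 0.0, "mixed": 0.0}
    if n:
        counts = table["category"].value_counts()
        for cat in ("te", "gene", "intergenic"):
            fractions[cat] = float(counts.get(cat, 0)) / n
    return fractions, table


def te_family_enrichment(dmrs: RegionSet, tes: RegionSet, min_bp: int = 1) -> pd.DataFrame:
    """Per-family enrichment of DMR-overlapped TEs.

    fold = (family bp fraction among DMR-overlapped TE bp) /
           (family bp fraction among all TE bp);
    p from a hypergeometric test on TE counts (population = all TEs,
    successes = family TEs, draws = DMR-overlapped TEs).

    TE family labels are taken from each TE's ``name``. Empty DMR set ->
    empty result.
    """
    if len(dmrs) == 0:
        return pd.DataFrame(
            columns=["family", "n_tes", "n_overlapped", "bp_total", "bp_overlapped",
                     "fold", "p_value"]
        )
    hit = tes.count_overlapping(dmrs, min_bp=min_bp)
    fams = np.array([iv.name or "unknown" for iv in tes])
    lens = tes.lengths()
    total_bp_all = lens.sum()
    total_bp_hit = lens[hit].sum()
    n_all = len(tes)
    n_hit = int(hit.sum())
    rows = []
    for fam in sorted(set(fams)):
        m = fams == fam
        fam_bp = lens[m].sum()
        fam_bp_hit = lens[m & hit].sum()
        frac_all = fam_bp / total_bp_all if total_bp_all else np.nan
        frac_hit = fam_bp_hit / total_bp_hit if total_bp_hit else np.nan
        fold = frac_hit / frac_all if frac_all and not np.isnan(frac_hit) else np.nan
        k = int((m & hit).sum())
        # P(X >= k) under hypergeom(N=n_all, K=family count, n=n_hit)
        p = float(stats.hypergeom.sf(k - 1, n_all, int(m.sum()), n_hit))
        rows.append({
            "family": fam, "n_tes": int(m.sum()), "n_overlapped": k,
            "bp_total": int(fam_bp), "bp_overlapped": int(fam_bp_hit),
            "fold": fold, "p_value": p,
        })
    return pd.DataFrame(rows)


@dataclass
class BoundTEResult:
    bound: RegionSet
    unbound: RegionSet
    coverage_fraction: np.ndarray  # per TE, sorted order of the input set
    length_summary: pd.DataFrame   # median/mean/quartiles for bound vs all


def classify_bound_tes(
    tes: RegionSet, peaks: RegionSet, params: OccupancyParams | None = None
) -> BoundTEResult:
    """Partition TEs into bound/unbound by fractional peak coverage.

    A TE is bound iff (bp covered by the union of peaks) / (TE length) is
    strictly greater than ``bound_te_min_overlap_fraction``.
    """
    params = params or OccupancyParams()
    cov = tes.overlap_bp_per_interval(peaks)
    lens = tes.lengths()
    frac = np.where(lens > 0, cov / lens, 0.0)
    mask = frac > params.bound_te_min_overlap_fraction
    bound = RegionSet([iv for iv, m in zip(tes, mask) if m], label="bound_tes")
    unbound = RegionSet([iv for iv, m in zip(tes, mask) if not m], label="unbound_tes")

    def _summ(lengths: np.ndarray, label: str) -> dict:
        if len(lengths) == 0:
            return {"set": label, "n": 0, "median": np.nan, "mean": np.nan,
                    "q1": np.nan, "q3": np.nan}
        return {
            "set": label, "n": len(lengths),
            "median": float(np.median(lengths)), "mean": float(np.mean(lengths)),
            "q1": float(np.percentile(lengths, 25)),
            "q3": float(np.percentile(lengths, 75)),
        }

    summary = pd.DataFrame([_summ(bound.lengths(), "bound"), _summ(lens, "all")])
    return BoundTEResult(bound=bound, unbound=unbound, coverage_fraction=frac,
                         length_summary=summary)


def shuffle_regions(
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
    seed: int,
    n_sets: int = 3,
    exclude: RegionSet | None = None,
    max_tries: int = 1000,
) -> list[RegionSet]:
    """Generate control sets with the identical length multiset, placed
    uniformly at random.

    For each region, a chromosome is chosen with probability proportional
    to its length (among chromosomes long enough to hold the region) and
    the start is uniform over valid positions. Control regions may overlap
    each other. If ``exclude`` is given, placements intersecting it are
    rejection-sampled.
    """
    sizes = dict(chrom_sizes)
    names = list(sizes)
    lengths = np.array([sizes[c] for c in names], dtype=np.float64)
    max_len = int(lengths.max()) if names else 0
    for iv in regions:
        if iv.length > max_len:
            raise ValueError(
                f"region of length {iv.length} exceeds the longest chromosome ({max_len})"
            )
    excl_cov = (
        {c: exclude._coverage(c) for c in names} if exclude is not None else None
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for s in range(n_sets):
        placed = []
        for iv in regions:
            ok_mask = lengths >= iv.length
            weights = lengths * ok_mask
            weights = weights / weights.sum()
            for _ in range(max_tries):
                ci = int(rng.choice(len(names), p=weights))
                chrom = names[ci]
                start = int(rng.integers(0, sizes[chrom] - iv.length + 1))
                end = start + iv.length
                if excl_cov is not None and int(excl_cov[chrom].overlap_bp(start, end)) > 0:
                    continue
                placed.append(GenomicInterval(chrom, start, end, name=iv.name))
                break
            else:
                raise RuntimeError(
                    f"could not place region of length {iv.length} after {max_tries} tries"
                )
        out.append(RegionSet(placed, label=f"shuffle_{s}"))
    return out


def chromosome_density(
    regions: RegionSet, chrom_sizes: Mapping[str, int], window: int = 100_000
) -> pd.DataFrame:
    """Count regions per tiling window, assigning each region by midpoint.

    The counts sum to ``len(regions)``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        n_win = int(np.ceil(length / window))
        counts = np.zeros(n_win, dtype=np.int64)
        for iv in regions:
            if iv.chrom == chrom:
                counts[min(iv.midpoint // window, n_win - 1)] += 1
        for w in range(n_win):
            rows.append({
                "chrom": chrom, "start": w * window,
                "end": min((w + 1) * window, length), "count": int(counts[w]),
            })
    return pd.DataFrame(rows)
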
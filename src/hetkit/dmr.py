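"""Binwise differential-methylation calling between two samples.

Pipeline: pool reads per 100-bp bin and context, keep bins with enough
covered cytosines in *both* samples, run a two-sided Fisher exact test on
the pooled methylated/unmethylated read counts, adjust p-values with
Benjamini-Hochberg per context over the tested set, and select bins whose
absolute level difference clears a context-specific threshold
(CG 0.4, CHG 0.2, CHH 0.1) at FDR < 0.01. Direction is the sign of
(sample B level - sample A level): hypo means B lost methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DMRParams", "fisher_bin", "bh_adjust", "call_dmrs", "merge_adjacent"]

DEFAULT_DELTA_MIN = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}


@dataclass
class DMRParams:
    """Thresholds controlling bin eligibility and significance."""

    bin_size: int = 100
    delta_min: dict = field(default_factory=lambda: dict(DEFAULT_DELTA_MIN))
    fdr_max: float = 0.01
    min_cytosines: int = 4
    read_floor: int = 4

    def __post_init__(self) -> None:
        for ctx, d in self.delta_min.items():
            if not 0 < d <= 1:
                raise ValueError(f"delta_min[{ctx}] must be in (0, 1]")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")


def fisher_bin(meth_a: int, total_a: int, meth_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table
    [[meth_a, total_a - meth_a], [meth_b, total_b - meth_b]].

    Undefined when either sample has zero pooled reads.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("fisher_bin undefined for zero-total bins")
    table = [[meth_a, total_a - meth_a], [meth_b, total_b - meth_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; order-preserving.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _check_same_grid(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> None:
    if len(bins_a) != len(bins_b) or not (
        (bins_a["chrom"].values == bins_b["chrom"].values).all()
        and (bins_a["start"].values == bins_b["start"].values).all()
        and (bins_a["end"].values == bins_b["end"].values).all()
    ):
        raise ValueError("samples are aggregated on different bin grids")


def call_dmrs(
    bins_a: pd.DataFrame,
    bins_b: pd.DataFrame,
    context: str,
    params: DMRParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call differential bins between reference sample A and sample B.

    Both inputs must come from :func:`hetkit.io.aggregate_bins` on the same
    grid. Returns ``(dmrs, audit)``: the significant bins with direction
    hypo/hyper, and an audit table covering every bin with its filter
    status, p, q and delta.
    """
    params = params or DMRParams()
    if context not in params.delta_min:
        raise ValueError(f"no delta_min configured for context {context!r}")
    _check_same_grid(bins_a, bins_b)

    audit = bins_a[["chrom", "start", "end"]].copy()
    audit["meth_a"] = bins_a["meth_reads"].values
    audit["total_a"] = bins_a["total_reads"].values
    audit["ncov_a"] = bins_a["n_cytosines_covered"].values
    audit["meth_b"] = bins_b["meth_reads"].values
    audit["total_b"] = bins_b["total_reads"].values
    audit["ncov_b"] = bins_b["n_cytosines_covered"].values
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = np.where(audit["total_a"] > 0, audit["meth_a"] / audit["total_a"], np.nan)
        level_b = np.where(audit["total_b"] > 0, audit["meth_b"] / audit["total_b"], np.nan)
    audit["level_a"] = level_a
    audit["level_b"] = level_b
    audit["delta"] = level_b - level_a

    tested = (
        (audit["ncov_a"].values >= params.min_cytosines)
        & (audit["ncov_b"].values >= params.min_cytosines)
        & (audit["total_a"].values > 0)
        & (audit["total_b"].values > 0)
    )
    audit["tested"] = tested

    p = np.full(len(audit), np.nan)
    idx = np.flatnonzero(tested)
    ma = audit["meth_a"].values
    ta = audit["total_a"].values
    mb = audit["meth_b"].values
    tb = audit["total_b"].values
    for i in idx:
        p[i] = fisher_bin(int(ma[i]), int(ta[i]), int(mb[i]), int(tb[i]))
    audit["p_value"] = p

    q = np.full(len(audit), np.nan)
    if len(idx):
        q[idx] = bh_adjust(p[idx])
    audit["q_value"] = q

    delta = audit["delta"].values
    sig = tested & (q < params.fdr_max) & (np.abs(delta) >= params.delta_min[context])
    audit["significant"] = sig
    direction = np.where(delta < 0, "hypo", "hyper")
    audit["direction"] = np.where(sig, direction, "")

    dmrs = audit.loc[sig, [
        "chrom", "start", "end", "delta", "p_value", "q_value",
        "meth_a", "total_a", "meth_b", "total_b", "level_a", "level_b",
    ]].copy()
    dmrs["direction"] = direction[sig]
    dmrs["context"] = context
    dmrs = dmrs.reset_index(drop=True)
    audit["context"] = context
    return dmrs, audit


def merge_adjacent(dmrs: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Union runs of same-direction, same-context bins whose gap <= max_gap.

    The merged delta is recomputed from the pooled read counts of the
    constituent bins.
    """
    cols = ["chrom", "start", "end", "context", "direction",
            "meth_a", "total_a", "meth_b", "total_b", "delta", "n_bins"]
    if len(dmrs) == 0:
        return pd.DataFrame(columns=cols)
    d = dmrs.sort_values(["context", "direction", "chrom", "start"]).reset_index(drop=True)
    out = []
    cur = None
    for row in d.itertuples(index=False):
        if (
            cur is not None
            and row.context == cur["context"]
            and row.direction == cur["direction"]
            and row.chrom == cur["chrom"]
            and row.start - cur["end"] <= max_gap
        ):
            cur["end"] = max(cur["end"], row.end)
            for k, v in (("meth_a", row.meth_a), ("total_a", row.total_a),
                         ("meth_b", row.meth_b), ("total_b", row.total_b)):
                cur[k] += v
            cur["n_bins"] += 1
        else:
            if cur is not None:
                out.append(cur)
            cur = {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "context": row.context, "direction": row.direction,
                "meth_a": row.meth_a, "total_a": row.total_a,
                "meth_b": row.meth_b, "total_b": row.total_b, "n_bins": 1,
            }
    out.append(cur)
    merged = pd.DataFrame(out)
    merged["delta"] = (
        merged["meth_b"] / merged["total_b"] - merged["meth_a"] / merged["total_a"]
    )
    return merged[cols].sort_values(["chrom", "start"]).reset_index(drop=True)
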
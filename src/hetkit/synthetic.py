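"""Synthetic genome, methylome, ChIP, and calorimetry generators.

Produces a toy genome with pericentromere-concentrated long TEs, two
genotype methylomes with planted non-CG methylation losses, correlated
ChIP tracks with peak calls over bound TEs, and noisy binding isotherms —
everything needed to exercise the downstream analyses end to end, with the
ground truth recorded alongside.

Randomness: every generator derives its streams from one integer seed via
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed, documented
key per purpose, so identical seeds give byte-identical outputs and the
cytosine positions are shared between genotypes while the read counts are
not.

Seed keys: 0 = genome layout, 1 = cytosine positions, 2 = wildtype counts,
3 = mutant counts, 4 = ChIP noise, 5 = isotherm noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet
from .io import CONTEXTS, CoverageTrack
from .itc import BindingParams, Isotherm, default_injections, molar_ratio, predict_heats

__all__ = [
    "GenomeSpec",
    "SyntheticGenome",
    "MethylomeModel",
    "generate_genome",
    "plant_dmrs",
    "simulate_methylome",
    "simulate_chip",
    "ChipSim",
    "simulate_isotherm",
]

_SEED_GENOME = 0
_SEED_POSITIONS = 1
_SEED_COUNTS = {"wildtype": 2, "mutant": 3}
_SEED_CHIP = 4
_SEED_ITC = 5

MIN_CHROM_FACTOR = 10  # chromosomes must hold at least this many bins


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class GenomeSpec:
    """Layout of the toy genome.

    ``centromere_center`` is the centromere position as a fraction of each
    chromosome's length; the pericentromeric zone spans
    ``pericentromere_width`` of the chromosome centred there.
    """

    chromosomes: Sequence[tuple[str, int]] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    centromere_center: Sequence[float] | float = 0.5
    seed: int = 0
    bin_size: int = 100
    pericentromere_width: float = 1 / 3
    long_te_threshold: int = 4000
    tes_per_mb: int = 80
    genes_per_mb: int = 120
    long_te_fraction: float = 0.4
    long_te_peri_prob: float = 0.85

    def centers(self) -> list[float]:
        if isinstance(self.centromere_center, (int, float)):
            return [float(self.centromere_center)] * len(self.chromosomes)
        return [float(c) for c in self.centromere_center]

    def __post_init__(self) -> None:
        if len(self.chromosomes) < 2:
            raise ValueError("need at least 2 chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if length < MIN_CHROM_FACTOR * self.bin_size:
                raise ValueError(
                    f"chromosome {name} shorter than {MIN_CHROM_FACTOR}x bin size"
                )
        for c in self.centers():
            if not 0 < c < 1:
                raise ValueError("centromere_center must be in (0, 1)")


@dataclass
class SyntheticGenome:
    """A generated genome: sizes, annotation, and the pericentromeric zones."""

    spec: GenomeSpec
    chrom_sizes: dict[str, int]
    tes: RegionSet
    genes: RegionSet
    pericentromeres: RegionSet

    def long_tes(self) -> RegionSet:
        thr = self.spec.long_te_threshold
        return RegionSet([iv for iv in self.tes if iv.length > thr], label="long_tes")

    def short_tes(self) -> RegionSet:
        thr = self.spec.long_te_threshold
        return RegionSet([iv for iv in self.tes if iv.length <= thr], label="short_tes")


_LONG_FAMILIES = (("LTR/Gypsy", 0.5), ("LTR/Copia", 0.25), ("DNA/En-Spm", 0.15), ("other", 0.1))
_SHORT_FAMILIES = (("LTR/Gypsy", 0.1), ("LTR/Copia", 0.15), ("DNA/En-Spm", 0.1), ("other", 0.65))


def _pick(rng: np.random.Generator, table) -> str:
    names = [n for n, _ in table]
    probs = np.array([p for _, p in table])
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def _place_nonoverlapping(
    rng: np.random.Generator, occupied: list[tuple[int, int]],
    length: int, chrom_len: int, lo: int, hi: int, tries: int = 200,
) -> tuple[int, int] | None:
    """Try to place an interval of ``length`` with start uniform in
    [lo, hi) that avoids everything in ``occupied``."""
    hi = min(hi, chrom_len - length)
    if hi <= lo:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start, end
    return None


def generate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Build the toy genome: chromosome sizes, TE and gene annotation.

    Long TEs (> ``long_te_threshold``) are preferentially placed inside the
    pericentromeric zone; genes are placed in the arms; intervals never
    overlap within the annotation. Deterministic for a given spec.
    """
    rng = _rng(spec.seed, _SEED_GENOME)
    chrom_sizes = {name: int(length) for name, length in spec.chromosomes}
    centers = spec.centers()
    tes, genes, peris = [], [], []
    for (chrom, length), center in zip(spec.chromosomes, centers):
        half = spec.pericentromere_width / 2
        peri_lo = max(0, int((center - half) * length))
        peri_hi = min(length, int((center + half) * length))
        peris.append(GenomicInterval(chrom, peri_lo, peri_hi, name="pericentromere"))
        occupied: list[tuple[int, int]] = []

        n_tes = max(2, int(round(spec.tes_per_mb * length / 1e6)))
        n_long = max(1, int(round(n_tes * spec.long_te_fraction)))
        for i in range(n_tes):
            is_long = i < n_long
            if is_long:
                te_len = int(rng.integers(spec.long_te_threshold + 500, 12_000))
                in_peri = rng.random() < spec.long_te_peri_prob
            else:
                te_len = int(np.clip(rng.lognormal(6.3, 0.7), 150, spec.long_te_threshold))
                in_peri = rng.random() < 0.3
            lo, hi = (peri_lo, peri_hi) if in_peri else (0, length)
            placed = _place_nonoverlapping(rng, occupied, te_len, length, lo, hi)
            if placed is None:
                placed = _place_nonoverlapping(rng, occupied, te_len, length, 0, length)
            if placed is None:
                continue
            fam = _pick(rng, _LONG_FAMILIES if is_long else _SHORT_FAMILIES)
            strand = "+" if rng.random() < 0.5 else "-"
            tes.append(GenomicInterval(chrom, placed[0], placed[1], name=fam,
                                       strand=strand))

        n_genes = max(2, int(round(spec.genes_per_mb * length / 1e6)))
        for _ in range(n_genes):
            g_len = int(np.clip(rng.lognormal(7.6, 0.5), 500, 12_000))
            # genes live mostly in the arms
            if rng.random() < 0.92:
                if rng.random() < 0.5 and peri_lo > g_len:
                    lo, hi = 0, peri_lo
                else:
                    lo, hi = peri_hi, length
            else:
                lo, hi = 0, length
            placed = _place_nonoverlapping(rng, occupied, g_len, length, lo, hi)
            if placed is None:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GenomicInterval(chrom, placed[0], placed[1], name="gene",
                                         strand=strand))
    return SyntheticGenome(
        spec=spec,
        chrom_sizes=chrom_sizes,
        tes=RegionSet(tes, label="tes"),
        genes=RegionSet(genes, label="genes"),
        pericentromeres=RegionSet(peris, label="pericentromeres"),
    )


def plant_dmrs(genome: SyntheticGenome, fraction: float = 1.0,
               target: str = "long_te") -> RegionSet:
    """Choose the ground-truth regions where the mutant will lose
    methylation. ``target='long_te'`` selects (a deterministic prefix of)
    the long TEs; ``'all_te'`` selects from all TEs."""
    pool = genome.long_tes() if target == "long_te" else genome.tes
    k = int(round(len(pool) * fraction))
    return RegionSet(list(pool)[:k], label="planted_dmrs")


@dataclass
class MethylomeModel:
    """Generative parameters for per-cytosine counts.

    ``baseline`` maps context -> (heterochromatin p, arm p); a cytosine is
    heterochromatic when it lies in a pericentromeric zone or inside a TE.
    ``mutant_delta`` is the signed per-context change applied inside
    ``planted_dmrs`` for the mutant genotype (negative = hypomethylation).
    """

    baseline: dict = field(default_factory=lambda: {
        "CG": (0.85, 0.25), "CHG": (0.70, 0.05), "CHH": (0.35, 0.03)})
    mutant_delta: dict = field(default_factory=lambda: {
        "CG": 0.0, "CHG": -0.5, "CHH": -0.25})
    planted_dmrs: RegionSet = field(default_factory=lambda: RegionSet([], label="planted"))
    coverage_mean: float = 20.0
    cytosine_density: dict = field(default_factory=lambda: {"CG": 6, "CHG": 6, "CHH": 10})

    def __post_init__(self) -> None:
        for ctx, (het, arm) in self.baseline.items():
            if not (0 <= het <= 1 and 0 <= arm <= 1):
                raise ValueError(f"baseline[{ctx}] out of [0, 1]")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")


def _membership(cov_index, pos0: np.ndarray) -> np.ndarray:
    """True where 0-based positions fall inside the (merged) region set."""
    return (cov_index.overlap_bp(pos0, pos0 + 1) > 0)


def simulate_methylome(
    genome: SyntheticGenome,
    model: MethylomeModel,
    genotype: str,
    seed: int,
) -> pd.DataFrame:
    """Draw a per-cytosine count table for one genotype.

    Cytosine positions are derived from the seed alone (key 1) and are
    therefore identical for both genotypes under the same seed; read
    counts use a genotype-specific stream. total ~ Poisson(coverage_mean),
    methylated ~ Binomial(total, p) with p set by context, zone, and (for
    the mutant inside planted regions) the planted delta.
    """
    if genotype not in _SEED_COUNTS:
        raise ValueError(f"genotype must be one of {sorted(_SEED_COUNTS)}")
    pos_rng = _rng(seed, _SEED_POSITIONS)
    cnt_rng = _rng(seed, _SEED_COUNTS[genotype])

    het_zone = RegionSet(
        list(genome.pericentromeres) + list(genome.tes), label="het"
    )
    frames = []
    for chrom, length in genome.chrom_sizes.items():
        het_cov = het_zone._coverage(chrom)
        planted_cov = model.planted_dmrs._coverage(chrom)
        for context in CONTEXTS:
            density = model.cytosine_density.get(context, 0)
            n = int(round(density * length / 100))
            if n == 0:
                continue
            pos0 = np.sort(pos_rng.choice(length, size=min(n, length), replace=False))
            strand = np.where(pos_rng.random(len(pos0)) < 0.5, "+", "-")
            het = _membership(het_cov, pos0)
            het_p, arm_p = model.baseline[context]
            p = np.where(het, het_p, arm_p).astype(np.float64)
            if genotype == "mutant":
                delta = model.mutant_delta.get(context, 0.0)
                if delta != 0.0:
                    inside = _membership(planted_cov, pos0)
                    p = np.where(inside, np.clip(p + delta, 0.0, 1.0), p)
            total = cnt_rng.poisson(model.coverage_mean, size=len(pos0))
            meth = cnt_rng.binomial(total, p)
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos0 + 1, "strand": strand,
                "context": context, "count_methylated": meth, "count_total": total,
            }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "count_methylated", "count_total"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(drop=True)


@dataclass
class ChipSim:
    """Generated ChIP tracks, peak calls, and the bound-TE ground truth."""

    tracks: dict[str, CoverageTrack]
    peaks: RegionSet
    bound_tes: RegionSet


def simulate_chip(
    genome: SyntheticGenome,
    seed: int,
    window: int = 100,
    het_rate: float = 8.0,
    arm_rate: float = 1.0,
    noise_sd: float = 0.25,
    agdp_coef: float = 1.5,
    h3_rate: float = 2.0,
    h3_peak_boost: float = 1.3,
    active_gene_rate: float = 6.0,
) -> ChipSim:
    """Simulate correlated ChIP coverage tracks and peak intervals.

    * ``h3k9me2``: elevated over heterochromatin (pericentromeres + TEs)
      with multiplicative log-normal noise of sd ``noise_sd``;
    * ``agdp1``: ``agdp_coef`` x the noise-free h3k9me2 rate with its own
      log-normal noise (noise_sd = 0 gives exact proportionality);
    * ``h3``: near-flat, mildly boosted at bound TEs;
    * ``input``: flat;
    * ``active``: a genes-elevated mark, for negative-association checks.

    Peaks are the bound TEs (all long TEs), so every peak overlaps a TE by
    construction; the bound-TE list is returned as ground truth.
    """
    rng = _rng(seed, _SEED_CHIP)
    het_zone = RegionSet(list(genome.pericentromeres) + list(genome.tes), label="het")
    bound = genome.long_tes()
    frames: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ("h3k9me2", "agdp1", "h3", "input", "active")
    }

    def lognoise(size):
        if noise_sd <= 0:
            return np.ones(size)
        return np.exp(rng.normal(-noise_sd**2 / 2, noise_sd, size))

    for chrom, length in genome.chrom_sizes.items():
        starts = np.arange(0, length, window, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        het_frac = het_zone._coverage(chrom).overlap_bp(starts, ends) / (ends - starts)
        bound_frac = bound._coverage(chrom).overlap_bp(starts, ends) / (ends - starts)
        gene_frac = genome.genes._coverage(chrom).overlap_bp(starts, ends) / (ends - starts)

        base = arm_rate + (het_rate - arm_rate) * het_frac
        h3k9 = base * lognoise(len(starts))
        agdp = agdp_coef * h3k9 * lognoise(len(starts))
        h3 = h3_rate * (1 + (h3_peak_boost - 1) * bound_frac) * lognoise(len(starts))
        inp = np.full(len(starts), 1.0)
        active = (arm_rate + (active_gene_rate - arm_rate) * gene_frac) * lognoise(len(starts))

        for name, vals in (("h3k9me2", h3k9), ("agdp1", agdp), ("h3", h3),
                           ("input", inp), ("active", active)):
            frames[name].append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": vals}
            ))

    tracks = {}
    for name, parts in frames.items():
        df = pd.concat(parts, ignore_index=True)
        total = float((df["value"] * (df["end"] - df["start"])).sum())
        tracks[name] = CoverageTrack(df, total_mapped=total)
    peaks = RegionSet(
        [GenomicInterval(iv.chrom, iv.start, iv.end, name="peak") for iv in bound],
        label="peaks",
    )
    return ChipSim(tracks=tracks, peaks=peaks, bound_tes=bound)


def simulate_isotherm(
    params: BindingParams,
    volumes_uL: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Isotherm:
    """Forward-model an injection series with optional Gaussian noise of
    sd ``noise_sd * max|heat|``. Flags a saturation warning when the final
    molar ratio stays below twice the stoichiometry."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    volumes = default_injections() if volumes_uL is None else np.asarray(volumes_uL, float)
    heats = predict_heats(params, volumes)
    if noise_sd > 0:
        rng = _rng(seed, _SEED_ITC)
        heats = heats + rng.normal(0.0, noise_sd * np.max(np.abs(heats)), len(heats))
    ratio = molar_ratio(params, volumes)
    warn = bool(ratio[-1] < 2.0 * params.n_sites)
    return Isotherm(volumes_uL=volumes, heats_ucal=heats, molar_ratio=ratio,
                    saturation_warning=warn)


# ---------------------------------------------------------------------------
# one-call dataset emitter used by the CLI


def write_dataset(outdir, spec: GenomeSpec, model: MethylomeModel | None = None,
                  seed: int | None = None) -> dict:
    """Generate and write a complete synthetic dataset plus its ground
    truth sidecar. Returns the ground-truth dict."""
    from pathlib import Path

    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = spec.seed if seed is None else seed
    genome = generate_genome(spec)
    if model is None:
        model = MethylomeModel(planted_dmrs=plant_dmrs(genome))

    hio.write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    hio.write_bed(genome.tes, outdir / "tes.bed")
    hio.write_bed(genome.genes, outdir / "genes.bed")
    hio.write_bed(genome.pericentromeres, outdir / "pericentromeres.bed")
    hio.write_bed(model.planted_dmrs, outdir / "planted_dmrs.bed")

    for genotype in ("wildtype", "mutant"):
        table = simulate_methylome(genome, model, genotype, seed)
        hio.write_cytosine_report(table, outdir / f"{genotype}.cx.tsv")

    chip = simulate_chip(genome, seed)
    for name, track in chip.tracks.items():
        hio.write_bedgraph(track, outdir / f"{name}.bedgraph")
    hio.write_bed(chip.peaks, outdir / "peaks.bed")
    hio.write_bed(chip.bound_tes, outdir / "bound_tes.bed")

    itc_params = BindingParams(kd_uM=3.8, dh_kcal=-10.0, n_sites=3.0)
    iso = simulate_isotherm(itc_params, noise_sd=0.01, seed=seed)
    pd.DataFrame({
        "injection_index": np.arange(1, len(iso.volumes_uL) + 1),
        "volume_uL": iso.volumes_uL,
        "heat_ucal": iso.heats_ucal,
    }).to_csv(outdir / "isotherm.csv", index=False)

    truth = {
        "seed": seed,
        "chromosomes": genome.chrom_sizes,
        "n_tes": len(genome.tes),
        "n_long_tes": len(genome.long_tes()),
        "n_planted_dmrs": len(model.planted_dmrs),
        "mutant_delta": model.mutant_delta,
        "baseline": {k: list(v) for k, v in model.baseline.items()},
        "coverage_mean": model.coverage_mean,
        "n_bound_tes": len(chip.bound_tes),
        "itc_truth": {"kd_uM": itc_params.kd_uM, "dh_kcal": itc_params.dh_kcal,
                      "n_sites": itc_params.n_sites},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
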
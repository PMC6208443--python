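# hetkit

A desk-scale toolkit for heterochromatin genomics and binding calorimetry.
It re-implements, as tested and reusable components, a downstream analysis
stack for plant heterochromatin studies:

* **`hetkit.synthetic`** — generators for a toy genome (pericentromere-
  concentrated long TEs, genes in the arms), two-genotype methylomes with
  planted non-CG methylation losses, correlated ChIP coverage tracks with
  peak calls over bound TEs, and noisy binding isotherms. Ground truth
  (planted DMR BED, bound-TE list, true isotherm parameters) is always
  emitted alongside the data.
* **`hetkit.io`** — readers/writers for chrom.sizes, BED6, bedGraph, and
  per-cytosine methylation count reports (1-based positions, CG/CHG/CHH
  contexts), plus 100-bp genome binning and per-bin count pooling.
* **`hetkit.dmr`** — binwise differential-methylation calling: two-sided
  Fisher exact test on pooled methylated/unmethylated read counts per bin,
  Benjamini–Hochberg FDR over the tested set, context-specific
  absolute-difference thresholds (CG 0.4, CHG 0.2, CHH 0.1) at FDR < 0.01,
  a coverage filter (≥ 4 cytosines covered by ≥ 4 reads in both samples),
  and optional merging of adjacent significant bins.
* **`hetkit.regions`** — region-set overlap summaries, genomic-context
  composition, TE-family enrichment, bound-TE classification (> 80%
  fractional peak coverage), length-matched shuffled control sets, and
  chromosome-wide density profiles.
* **`hetkit.profiles`** — per-million track normalization, scale-region
  metaplots with fixed 2-kb flanks, per-region statistics, H3-normalized
  mark density, mark association at peaks versus shuffled controls, and
  track–track correlation.
* **`hetkit.itc`** — forward model and nonlinear least-squares fitting of
  the single-site-class (N identical independent sites) binding isotherm,
  with the Wiseman c-value diagnostic and affinity fold-ratio comparison.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, property tests (hypothesis), and
`tests/test_acceptance.py`, which checks the oracle-equivalence,
parameter-recovery, and planted-signal-recovery criteria at their stated
tolerances. The full run takes a few minutes; the Fisher-test enumeration
oracle dominates.

## CLI walkthrough

```sh
# 1. generate a synthetic dataset (2 x 1 Mb genome) with ground truth
hetkit simulate --outdir data --seed 5

# 2. call CHG differential methylation, mutant vs wild-type
hetkit dmr --wt data/wildtype.cx.tsv --mut data/mutant.cx.tsv \
    --genome data/chrom.sizes --context CHG --out-prefix chg

# 3. compare the calls with the planted truth
hetkit regions overlap --a chg.CHG.hypo.bed --b data/planted_dmrs.bed

# 4. classify peak-bound TEs and summarize their lengths
hetkit regions bind --tes data/tes.bed --peaks data/peaks.bed

# 5. correlate two ChIP tracks on 10-kb bins
hetkit profile corr --a data/agdp1.bedgraph --b data/h3k9me2.bedgraph \
    --genome data/chrom.sizes

# 6. simulate and fit a 3-site titration
hetkit itc simulate --kd 3.8 --n 3 --noise-sd 0.01 --out iso.csv
hetkit itc fit --data iso.csv
```

Other subcommands: `hetkit regions compose|enrich|shuffle|density`,
`hetkit profile metaplot|stats|assoc`, `hetkit itc compare`.

## Conventions

* BED/bedGraph intervals are 0-based half-open; cytosine report positions
  are 1-based (a cytosine at position 100 falls in bin [0, 100)).
* DMR direction is the sign of (sample B − sample A); with A = wild-type,
  "hypo" means the mutant lost methylation.
* Under-covered cytosines still contribute reads to pooled bin counts; the
  ≥4-cytosines/≥4-reads rule is a bin-eligibility filter only.
* Overlap percentages are reported at full precision and truncated to the
  integer part (11 of 12 → 91%).
* All generator randomness derives from one integer seed via
  `numpy.random.SeedSequence(seed, spawn_key=(k,))` with fixed per-purpose
  keys; identical seeds give byte-identical output files.
* ITC units: concentrations in µM, cell volume in mL, injections in µL,
  heats in µcal, dH in kcal per mole of sites. Dilution uses the
  exponential perfusion convention with the displaced-volume heat
  correction.
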
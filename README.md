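# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics.

The package covers the complete analysis chain used in summary-level MR
studies of a continuous exposure on blood-pressure-style outcomes:

- **`mrkit.io`** — read/write tab-separated summary-statistic tables
  (rsid, alleles, EAF, beta, SE, p, N) and labelled LD r² matrices, with
  hard-invariant validation and full-precision round-trips.
- **`mrkit.instruments`** — instrument selection (p ≤ 5e-8, MAF > 0.01,
  greedy LD clumping at r² < 0.1) and strength diagnostics
  (R² = 2·MAF·(1−MAF)·β², F = ((n−k−1)/k)·R²/(1−R²), mean F).
- **`mrkit.harmonize`** — align exposure and outcome effects onto a
  shared effect allele, resolving swaps, strand flips, and palindromic
  SNPs by allele-frequency concordance (ambiguous ones dropped).
- **`mrkit.estimators`** — Wald ratios, fixed/multiplicative-random IVW,
  Cochran's Q, MR-Egger (slope + intercept pleiotropy test), bootstrap
  weighted median, leave-one-out, odds-ratio/CI conversion, tail-stable
  two-sided p-values.
- **`mrkit.presso`** — pleiotropy residual-sum-and-outlier resampling:
  global RSS test, Bonferroni per-SNP outlier test with corrected
  estimate, and distortion test.
- **`mrkit.power`** — asymptotic post-hoc power for continuous and
  binary outcomes.
- **`mrkit.simulate`** — synthetic two-sample generator with known causal
  effect, optional directional/balanced pleiotropy, palindromic alleles,
  strand/allele flips, and EAF noise; plus bundled SYNTHETIC demo panels.
- **`mrkit.pipeline` / `mrkit.cli`** — end-to-end orchestration with
  method routing by instrument count (< 3 SNPs: IVW only; ≥ 3: IVW +
  MR-Egger + weighted median; ≥ 4: + PRESSO) and TSV/YAML reports.

## CLI

```sh
# generate a synthetic pair with a true effect of 0.05
mrkit simulate --j-snps 15 --theta 0.05 --seed 7 --out-prefix scratch/demo

# instrument selection (no LD matrix -> declare independence explicitly)
mrkit select scratch/demo.exposure.tsv --assume-independent --out scratch/selection.tsv

# harmonize and estimate
mrkit harmonize scratch/demo.exposure.tsv scratch/demo.outcome.tsv --out scratch/harm.tsv
mrkit estimate scratch/demo.exposure.tsv scratch/demo.outcome.tsv --seed 7

# outlier diagnostics and power
mrkit presso scratch/demo.exposure.tsv scratch/demo.outcome.tsv --seed 7
mrkit power --n-outcome 50000 --r2 0.02 --effect 0.05

# full pipeline from a YAML config (see mrkit.pipeline.AnalysisConfig)
mrkit run config.yaml
```

Every stochastic stage (weighted-median bootstrap, PRESSO, simulation)
requires an explicit seed; re-running a pipeline with the same config
produces byte-identical outputs.

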
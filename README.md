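# polyassoc

Genetic mapping in autopolyploids from **low-coverage** NGS genotyping data.

Calling exact allele dosages in an autohexaploid (dosage 0–6 per SNP)
requires on the order of 100 reads per genotype; reduced-representation
libraries (ddRAD-seq, GBS) sequenced at diploid-style depths typically yield
20–40×. `polyassoc` implements a strategy for mapping marker–trait
associations anyway: instead of hard dosage calls, every marker is carried
through the analysis as a per-individual **dosage-probability vector**
computed directly from read counts, and association is tested with GLM
likelihood-ratio scans whose genome-wide significance is calibrated by
permutation. A built-in polysomic simulator reproduces the validation
experiments (dosage-call accuracy, detection power) that motivate the
approach. The intended users are plant geneticists running preliminary,
cost-constrained QTL/association screens in autopolyploid crops (the
motivating system is autohexaploid sweet potato, 2n = 6x = 90).

## Model

For a K-ploid genotype with total depth DP and reference-allele depth RD,
each dosage d ∈ {0, …, K} has expected reference-read fraction

    r_d ∈ { 0/K + e, 1/K, …, (K−1)/K, K/K − e },

with a small ad hoc error probability e = 0.001 shielding the homozygous
classes. The relative dosage probability is the normalized binomial
likelihood

    RPr(d) = Pr(RD | DP, r_d) / Σ_i Pr(RD | DP, r_i),

computed in log space (the binomial coefficient cancels). Per marker this
gives an n × (K+1) matrix **M** whose rows sum to 1. Markers enter a GLM
(`y = β₀ + β₁x` for continuous traits, logistic for binary) under one of
two encodings:

* **Continuous** — `x = M·v` with `v = (0, 1, …, K)`: the expected dosage,
  one regressor;
* **Dogmat** — the matrix M itself as a multi-column regressor block
  (absent dosage classes dropped, reference class dropped against the
  intercept).

Each marker is scored by the likelihood-ratio χ² of β₁ = 0. Genome-wide
thresholds come from permuting the phenotype (1000 replicates by default),
recording the maximum −log₁₀(p) per replicate, and fitting a generalized
extreme-value distribution by maximum likelihood; the 1−α GEV quantile is
the threshold. A *noise-aware* alternative estimator (segregation prior ×
beta-binomial likelihood with allelic bias, overdispersion and sequencing
error; noise parameters fitted by grid marginal likelihood) is provided for
estimator comparisons.

Standard VarScan-style VCFs (FORMAT `DP` and `RD`, or `AD`) are read via
cyvcf2, with the usual filters: genotypes with DP < 10 or DP > 300 masked,
markers with > 50 % missing genotypes or major-genotype frequency > 0.95
removed.

## Worked example

Simulate an S1 autohexaploid population of 250 individuals with one
simplex (SS) causal locus acting simplex-dominantly at PVE 0.3, read depth
40, plus 300 unlinked background markers, then scan it:

```sh
cat > config.yaml <<EOF
n_individuals: 250
marker_type: SS
effect_model: SimDom
pve: 0.3
depth: 40
n_background_markers: 300
EOF
polyassoc simulate --seed 42 --config config.yaml --out-dir simdata
polyassoc scan simdata/simulated.vcf simdata/phenotype.tsv \
    --encoding continuous --n-perm 200 --seed 42 --out-dir scanout
```

which prints

```
scan written to scanout/scan.tsv
alpha=0.05 threshold: 2.246
```

and `scanout/scan.tsv` begins

```
marker_id   chrom     pos  ...  n_used  lrt_stat  df  pvalue       neglog10p
simFocal_1  simFocal  1    ...  250     21.0765   1   4.41303e-06  5.35526
simBg_1     simBg     1    ...  250     0.0137525 1   0.906645     0.0425626
```

The planted marker (`simFocal_1`) reaches −log₁₀(p) = 5.36, far above the
permutation-GEV 5 % genome-wide threshold of 2.25, while the strongest of
the 300 null background markers reaches only 1.55. (The χ² p-values use
the unscaled Gaussian deviance difference, so their absolute scale depends
on the phenotype's variance — that is why significance is judged against
the permutation threshold, which is calibrated on the same scale.)
`scanout/thresholds.tsv` records the fitted GEV (loc 1.49, scale 0.25,
shape 0.01) and the 10/5/1 % thresholds; `scanout/manhattan.png` plots the
scan. The simulator also writes `simdata/truth.tsv` with the true dosages,
genetic values and crossover counts for evaluation.

The library surface mirrors the CLI: `polyassoc.vcf_io` (VCF → count
matrices, filters), `polyassoc.dosage` (probability matrices, MGF,
noise-aware posterior), `polyassoc.association` (encodings, LRT scans),
`polyassoc.thresholds` (permutation + GEV), `polyassoc.simulate`
(populations, reads, phenotypes), `polyassoc.experiments`
(accuracy/power studies, end-to-end pipeline).

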
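# Methods

This note documents the statistical model, the simulator, the numerical
choices, and the design decisions behind `polyassoc`, in the spirit of a
package methods vignette. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Dosage-probability genotyping

A biallelic SNP in a K-ploid (default K = 6) individual has reference
dosage d ∈ {0..K}. Given total depth DP and reference depth RD, the naive
estimator scores dosages by binomial likelihoods at expected reference
fractions r = {0/K+e, 1/K, …, (K−1)/K, K/K−e} and normalizes across
dosages (`dosage.naive_dosage_probs`). Parameters:

* **e** (`error_prob`, default 0.001) — an ad hoc error probability that
  keeps the homozygous classes from having zero likelihood at any nonzero
  discordant read. Only the endpoints of r are adjusted; interior dosages
  use the exact fractions. Configurable.
* All likelihood math is in log space; the binomial coefficient is common
  to all dosages and omitted. r is symmetric about 1/2 including the
  e-adjusted endpoints, so reversing a probability vector equals swapping
  RD with DP−RD exactly (property-tested).

The **major genotype frequency** (MGF) of a marker is the largest column
mean of its probability matrix over non-missing individuals — i.e. the
dosage-class frequencies are aggregated from the probabilities, not from
hard calls, so low-confidence genotypes contribute fractionally. A
hard-call mode exists (`method="call"`) for sensitivity checks. Markers
with MGF > 0.95 are treated as potentially monomorphic and dropped; the
boundary itself is retained (strict inequality, as for the DP < 10,
DP > 300 and missingness > 0.5 filters).

### Noise-aware posterior

`dosage.noise_aware_posterior` is a deliberately simple stand-in for
EM-based polyploid genotypers: posterior[d] ∝ prior[d] ·
BetaBinomial(RD | DP, ξ(d/K), od), where the expected reference fraction
is warped by sequencing error ε and allelic bias h:

    f = p(1−ε) + (1−p)ε,      ξ = f / (h(1−f) + f).

h < 1 means alternative reads are under-detected (h = 0.5 at p = 1/2
gives ξ = 2/3). The beta-binomial is parameterized by mean ξ and
overdispersion od through α = ξ(1−od)/od, β = (1−ξ)(1−od)/od; od = 0
degenerates to the binomial. This formula lives once, in
`polyassoc.noise`, and is shared verbatim by the read-count simulator, so
the estimator and generator cannot drift apart. The prior is the exact
polysomic segregation distribution for the declared population and marker
type (S1/F1 × SS/DD/TT), or uniform. (bias, od) are estimated per marker
by maximizing the marginal likelihood over a fixed grid — bias log-spaced
0.25–2.0 (15 points), od = {0} ∪ log-spaced 0.001–0.2 (11 points) — with
ε fixed at 0.001; degenerate markers (all-reference or all-alternative
reads) return (1, 0) with a warning. This estimator knows the true
segregation prior exactly, which makes it *sharper* than a real EM
genotyper fit to data of unknown provenance; see "Known limitations".

## Association scans

Continuous traits use a Gaussian identity-link GLM, binary traits a
logistic GLM (IRLS, iteration cap 100, tolerance 1e−8; hitting the cap —
e.g. perfect separation — flags the marker rather than failing). The test
statistic is the deviance difference between the intercept-only and
intercept+marker models referred to χ² with df = rank(full design) − 1.

* **Paper mode (default).** The Gaussian deviance difference is left
  *unscaled* (RSS₀ − RSS₁), making the statistic proportional to the
  phenotype's variance. The resulting χ² p-values are therefore not
  uniformly distributed under the null at arbitrary phenotype scales —
  which is immaterial for inference because genome-wide significance is
  decided against a permutation threshold computed on the same scale.
  A `"scaled"` mode dividing by the full-model dispersion estimate is
  provided for conventional, scale-invariant p-values.
* **Encodings.** Continuous: expected dosage, one column. Dogmat: the
  probability-matrix columns, dropping classes with negligible total mass
  (< 1e−8) and then the largest-mass (reference) column to break the
  rows-sum-to-one collinearity with the intercept; df is the number of
  retained columns. Markers with fewer than two populated classes are
  untestable and flagged.
* Missing genotypes are handled by pairwise deletion per marker; `n_used`
  is recorded. Untestable markers are excluded from both observed and
  permuted maxima, consistently. No kinship or structure covariates are
  fitted.
* Hard calls break probability ties toward the lower dosage and count
  them.

## Permutation + GEV thresholds

The phenotype vector is permuted as a whole against the genotype rows —
with no covariates this is the only exchangeable unit. Per replicate the
full scan is re-run and the maximum −log₁₀(p) recorded; a GEV is fitted
to the maxima by maximum likelihood (scipy's `genextreme`; our shape
convention is Fréchet-positive, the negative of scipy's `c`) and the
threshold is the closed-form 1−α quantile, with the Gumbel limit at
shape = 0. If the ML fit fails (degenerate maxima), empirical quantiles
are used with a prominent warning. The default is 1000 permutations; a
reduced 200-replicate mode is used for desk-scale experiments with the
caveat that few replicates tend to underestimate thresholds. Per-replicate
seeds derive from one master seed via `SeedSequence` spawning, so results
are reproducible and order-independent. For continuous traits in paper
mode the permutation scan runs through a vectorized orthogonal-projection
path (per-marker QR once, all permutations as one matrix product), which
is tested for exact agreement with the per-marker GLM route.

## Simulator

The generator emulates an S1 (selfed) or F1 mapping population of an
autohexaploid under strict polysomic inheritance:

* **Gametes** receive K/2 of the K homologs by hypergeometric sampling
  (random bivalent-equivalent chromosome segregation, no double
  reduction, no preferential pairing). Offspring dosage distributions are
  the convolution of two gamete distributions — e.g. S1 simplex segregates
  1:2:1; triplex gametes are {1,9,9,1}/20.
* **Linkage.** The focal marker-gene pair is phased explicitly on the
  parent's homologs in *maximal coupling*: gene reference alleles occupy
  homologs 1..g and marker reference alleles homologs 1..m, so every gene
  allele is marker-tagged whenever counts permit. This is the most
  linkage-favorable phase; power losses observed under mismatched
  segregation types are therefore attributable to the segregation
  incompatibility itself, not adverse phase. Per meiosis a Poisson number
  of crossovers is drawn and each crossover exchanges the gene-side
  allele between two homologs chosen uniformly without replacement; the
  gamete is then sampled. This realization preserves both marginal
  segregation ratios exactly at any rate (goodness-of-fit tested) and
  decays the marker-gene correlation smoothly toward independence.
* **Crossover rate units.** `crossover_mode="literal"` (default) takes
  the Poisson mean λ equal to the map distance in cM — the benchmark's
  stated rule; `"morgan"` takes λ = cM/100, the conventional genetic
  rate. Under the literal mode with this crossover mechanism the
  within-gamete marker-gene correlation decays approximately as
  exp(−λ/3) (each of Poisson(λ) exchanges touches a given homolog with
  probability 1/3), so 5 cM already leaves only ≈ 0.19 correlation,
  while the morgan mode at 5 cM is near-complete linkage. Power studies
  in this package therefore place their PVE series at 1 cM (mid-range
  power for all PVE levels at n = 248) and their distance series at
  {0, 1, 5} cM; both modes are available to the user and logged.
* **Reads** come from the shared beta-binomial noise model at the
  configured depth (fixed DP per experiment — 20/40/100 — or resampled
  from a supplied empirical depth distribution). The benchmark's noisy
  condition is bias = 0.5, od = 0.05.
* **Phenotypes.** Genetic values g(d) on a [0,1] scale: additive
  g = d/K; simplex dominant g = 1[d ≥ 1]; diploidized additive
  g ∈ {0, 1/2, 1}. PVE is imposed analytically: ε ~ N(0, σ²) with
  σ² = Var(g)·(1−PVE)/PVE computed from the realized sample variance of
  g (closed-form counterpart of tuning the noise numerically; the
  normalization of g is harmless because PVE is scale-free). Binary
  traits are a clearly-labeled extension: y ~ Bernoulli(logistic(a+bg))
  with b = sqrt((π²/3)·PVE/((1−PVE)Var(g))) so g explains PVE of the
  latent-logistic variance, and a centering prevalence near 1/2.
* **Background markers** are unlinked, i.i.d. draws with types from a
  configurable SS/DD/TT mixture (default 0.6/0.3/0.1), passed through
  the same read model; they stand in for the real genome-wide marker
  panel used to calibrate permutation thresholds.
* Population size defaults to n = 248, a realistic selfed-population
  scale for this crop system (the accuracy panels use n = 100 per
  replicate, matching the benchmark's panel design).

### What the simulator does not emulate

Real ddRAD-seq data have locus-specific depth distributions, correlated
missingness, mapping artifacts, multi-allelic sites, linkage between
background markers, and multi-QTL architectures; the generator has none of
these. Passing tests therefore demonstrate the statistical machinery under
the stated polysomic model, not robustness to real-data pathologies.
Degenerate draws — e.g. a diploidized-additive triplex gene whose rare
homozygote classes (probability 1/400 each) are absent from a finite
sample, leaving genetic values constant — are rejected and redrawn by the
power experiment, with the PVE-undefined error surfaced to direct callers.

## Experiment design choices

* **Accuracy** is the proportion of individuals whose argmax-called
  dosage matches the truth, averaged over replicates, with across-replicate
  SE. Each sequencing condition is scored with the estimator built for
  it: the naive caller on clean reads; the noise-aware posterior on noisy
  reads. Two model facts matter for interpreting depth trends: under
  allelic bias the naive argmax converges with depth to a *fixed, wrong*
  dosage mapping (accuracy plateaus low regardless of coverage), and
  under overdispersion the per-sample beta draw imposes a
  depth-independent accuracy ceiling that triplex markers approach
  between 40× and 100×. The validation suite asserts per-step depth
  monotonicity on clean data and endpoint (20× vs 100×) gains under
  noise.
* **Power** is the fraction of replicates whose focal-marker −log₁₀(p)
  exceeds the genome-wide threshold. Thresholds are calibrated once per
  panel condition (depth, noise, trait type, n) and encoding, on 500
  naive-genotyped background markers with 200 permutations in desk-scale
  mode, and shared across estimator arms and across PVE/effect-model
  scenarios of the same panel — the analogue of calibrating one threshold
  per trait on the real marker panel. To make that sharing valid under
  the scale-dependent paper-mode statistic, continuous phenotypes are
  z-scored before scanning (an affine change; the scan's information
  content is untouched). Arms (estimator × encoding) are evaluated on the
  same simulated replicates, so arm contrasts are paired and their
  Monte-Carlo error is assessed on the within-replicate differences.

## Known limitations

* The noise-aware estimator is not an EM genotyper: it conditions on the
  declared population type and a fixed ε, and estimates only (bias, od)
  on a grid. Because its segregation prior is exact in simulations, it
  is an upper-bound-ish proxy: under the dogmat encoding its
  near-one-hot probability matrices yield systematically *higher*
  detection power than the naive matrices, whereas under the continuous
  encoding the two estimators are statistically indistinguishable —
  allelic bias shifts expected dosages nearly monotonically, leaving the
  information content of a single-regressor encoding unchanged. The
  estimator-equivalence validation is therefore stated for the
  continuous encoding.
* Unscaled paper-mode p-values are only interpretable against their
  permutation threshold; use `mode="scaled"` for standalone p-values.
* No interval mapping, no linkage-map construction, no kinship
  correction, no multi-allelic or indel support, no double reduction.
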
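"""Synthetic autopolyploid populations for method validation.

Models an S1 (selfed) or F1 (biparental) population of an autohexaploid
under strict polysomic inheritance: gametes receive a hypergeometric sample
of K/2 homologs (random bivalent-equivalent chromosome segregation, no
double reduction).  A focal marker-gene pair is linked through an explicit
parental phase; per meiosis, a Poisson number of crossovers exchanges
gene-side alleles between homolog pairs before gamete sampling, so the
marker-gene association decays with map distance while both marginal
segregation ratios are preserved exactly.

Read counts follow the shared beta-binomial noise model (allelic bias,
overdispersion, sequencing error; :mod:`polyassoc.noise`).  Phenotypes are
generated under three genetic-effect models (additive, simplex dominant,
diploidized additive) with the environmental variance set analytically so
the causal locus explains a prescribed proportion of phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import hypergeom

from .noise import expected_ref_fraction, sample_read_counts

__all__ = [
    "SimConfig",
    "ParentPhase",
    "BackgroundMarker",
    "SimulatedPopulation",
    "PARENT_DOSAGE",
    "gamete_dosage_distribution",
    "offspring_dosage_distribution",
    "simulate_linked_pair",
    "simulate_dosages",
    "simulate_read_counts",
    "genetic_effect",
    "genetic_values",
    "simulate_phenotype",
    "simulate_background_markers",
    "simulate_population",
    "write_vcf",
    "write_phenotype_tsv",
    "write_truth_tsv",
]

# Marker nomenclature: Simplex x Simplex, Duplex x Duplex, Triplex x Triplex
# (both parents carry the stated reference-allele dosage).
PARENT_DOSAGE = {"SS": 1, "DD": 2, "TT": 3}

EFFECT_MODELS = ("Add", "SimDom", "DipAdd")


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario; defaults mirror the benchmark study conditions.

    n_individuals defaults to 248, the size of the selfed autohexaploid
    mapping population the simulations emulate.  ``crossover_mode`` selects
    the Poisson rate unit: "literal" uses lambda = distance in cM per
    meiosis; "morgan" uses lambda = cM/100 (the conventional genetic rate).
    """

    ploidy: int = 6
    population: str = "S1"
    n_individuals: int = 248
    marker_type: str = "SS"
    gene_type: str | None = None
    distance_cM: float = 0.0
    depth: int = 40
    depth_empirical: tuple | None = None
    bias: float = 1.0
    od: float = 0.0
    seq_error: float = 0.001
    effect_model: str = "Add"
    pve: float = 0.2
    trait_type: str = "continuous"
    n_background_markers: int = 500
    background_type_mixture: tuple = (0.6, 0.3, 0.1)
    crossover_mode: str = "literal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ploidy % 2 or self.ploidy < 2:
            raise ValueError("ploidy must be a positive even integer")
        if self.population not in ("S1", "F1"):
            raise ValueError(f"population must be S1|F1, got {self.population!r}")
        if self.marker_type not in PARENT_DOSAGE:
            raise ValueError(f"marker_type must be one of {sorted(PARENT_DOSAGE)}")
        if self.gene_type is not None and self.gene_type not in PARENT_DOSAGE:
            raise ValueError(f"gene_type must be one of {sorted(PARENT_DOSAGE)}")
        if self.distance_cM < 0:
            raise ValueError("distance_cM must be >= 0")
        if not 0 < self.pve < 1:
            raise ValueError(f"pve must be in (0, 1), got {self.pve}")
        if not 0 <= self.od < 1:
            raise ValueError(f"od must be in [0, 1), got {self.od}")
        if self.bias <= 0:
            raise ValueError("bias must be > 0")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")
        if self.crossover_mode not in ("literal", "morgan"):
            raise ValueError("crossover_mode must be literal|morgan")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError("trait_type must be continuous|binary")

    @property
    def effective_gene_type(self) -> str:
        return self.gene_type or self.marker_type

    @property
    def crossover_lambda(self) -> float:
        d = self.distance_cM
        return d if self.crossover_mode == "literal" else d / 100.0


@dataclass(frozen=True)
class ParentPhase:
    """Homolog-level allele placement of a marker-gene pair in one parent.

    Built in maximal coupling: reference alleles of the marker are placed so
    that every gene reference-allele homolog also carries a marker reference
    allele whenever the counts permit.  This is the most linkage-favorable
    phase, so any power loss observed under mismatched segregation types is
    attributable to the segregation incompatibility itself.
    """

    marker_alleles: tuple
    gene_alleles: tuple

    @classmethod
    def maximal_coupling(cls, ploidy: int, marker_dosage: int, gene_dosage: int):
        m = np.zeros(ploidy, dtype=np.int8)
        g = np.zeros(ploidy, dtype=np.int8)
        m[:marker_dosage] = 1
        g[:gene_dosage] = 1
        return cls(marker_alleles=tuple(m), gene_alleles=tuple(g))


@dataclass
class BackgroundMarker:
    marker_type: str
    dosages: np.ndarray
    DP: np.ndarray
    RD: np.ndarray


@dataclass
class SimulatedPopulation:
    """Truth and observables for one simulated scenario."""

    config: SimConfig
    individual_ids: list[str]
    gene_dosages: np.ndarray
    marker_dosages: np.ndarray
    DP: np.ndarray
    RD: np.ndarray
    phenotype: np.ndarray
    g: np.ndarray
    sigma2: float
    crossovers: np.ndarray
    background: list[BackgroundMarker] = field(default_factory=list)


def gamete_dosage_distribution(ploidy: int, parent_dosage: int) -> np.ndarray:
    """P(gamete carries k reference alleles), k = 0..K/2, under polysomy.

    Hypergeometric: K/2 homologs drawn without replacement from K, of which
    ``parent_dosage`` carry the reference allele.  No double reduction.
    """
    if ploidy % 2 or ploidy < 2:
        raise ValueError("ploidy must be a positive even integer")
    if not 0 <= parent_dosage <= ploidy:
        raise ValueError(f"parent_dosage must be in 0..{ploidy}")
    k = np.arange(ploidy // 2 + 1)
    return hypergeom.pmf(k, ploidy, parent_dosage, ploidy // 2)


def offspring_dosage_distribution(
    ploidy: int, parent1_dosage: int, parent2_dosage: int | None = None
) -> np.ndarray:
    """Offspring dosage distribution over 0..K: convolution of two gametes.

    Selfing (S1) corresponds to parent2_dosage = parent1_dosage (default).
    """
    if parent2_dosage is None:
        parent2_dosage = parent1_dosage
    g1 = gamete_dosage_distribution(ploidy, parent1_dosage)
    g2 = gamete_dosage_distribution(ploidy, parent2_dosage)
    return np.convolve(g1, g2)


def _meioses(phase: ParentPhase, n_meioses: int, lam: float, rng: np.random.Generator):
    """Gamete marker/gene dosages and crossover counts for n meioses of one parent."""
    marker = np.asarray(phase.marker_alleles, dtype=np.int8)
    K = marker.size
    G = np.tile(np.asarray(phase.gene_alleles, dtype=np.int8), (n_meioses, 1))
    xovers = rng.poisson(lam, n_meioses) if lam > 0 else np.zeros(n_meioses, dtype=np.int64)
    # apply crossover t to every meiosis that has at least t+1 events;
    # each event exchanges the gene-side allele between two distinct homologs
    for t in range(int(xovers.max()) if n_meioses else 0):
        active = np.flatnonzero(xovers > t)
        i = rng.integers(0, K, active.size)
        j = (i + rng.integers(1, K, active.size)) % K
        gi = G[active, i].copy()
        G[active, i] = G[active, j]
        G[active, j] = gi
    picks = np.argsort(rng.random((n_meioses, K)), axis=1)[:, : K // 2]
    marker_d = marker[picks].sum(axis=1)
    gene_d = np.take_along_axis(G, picks, axis=1).sum(axis=1)
    return marker_d.astype(np.int64), gene_d.astype(np.int64), xovers


def simulate_linked_pair(config: SimConfig, rng: np.random.Generator):
    """True (gene, marker) dosages for n offspring, plus crossover counts.

    At distance 0 with matching types and maximal coupling the marker
    dosage vector equals the gene dosage vector exactly.
    """
    K, n = config.ploidy, config.n_individuals
    lam = config.crossover_lambda
    md = PARENT_DOSAGE[config.marker_type]
    gd = PARENT_DOSAGE[config.effective_gene_type]
    phase = ParentPhase.maximal_coupling(K, md, gd)
    if config.population == "S1":
        m_all, g_all, x_all = _meioses(phase, 2 * n, lam, rng)
        marker = m_all[:n] + m_all[n:]
        gene = g_all[:n] + g_all[n:]
        xov = x_all[:n] + x_all[n:]
    else:  # F1: two parents, phases drawn independently (same types here)
        m1, g1, x1 = _meioses(phase, n, lam, rng)
        m2, g2, x2 = _meioses(phase, n, lam, rng)
        marker, gene, xov = m1 + m2, g1 + g2, x1 + x2
    return gene, marker, xov


def simulate_dosages(config: SimConfig, rng: np.random.Generator, marker_type=None) -> np.ndarray:
    """Marginal offspring dosages for an unlinked marker of the given type."""
    mt = marker_type or config.marker_type
    dist = offspring_dosage_distribution(config.ploidy, PARENT_DOSAGE[mt])
    return rng.choice(config.ploidy + 1, size=config.n_individuals, p=dist)


def simulate_read_counts(dosages, config: SimConfig, rng: np.random.Generator):
    """(DP, RD) read counts for true dosages under the configured noise model."""
    dosages = np.asarray(dosages)
    if config.depth_empirical is not None:
        dp = rng.choice(np.asarray(config.depth_empirical, dtype=np.int64), size=dosages.shape)
    else:
        dp = np.full(dosages.shape, config.depth, dtype=np.int64)
    xi = expected_ref_fraction(dosages / config.ploidy, config.bias, config.seq_error)
    rd = sample_read_counts(rng, dp, xi, config.od)
    return dp, rd


def genetic_effect(d, model: str, ploidy: int = 6):
    """Genetic value g(d) on a [0, 1] scale for dosage d.

    Add: g = d/K (proportional to dosage).  SimDom: every carrier of the
    reference allele equals the reference homozygote (g = 1 for d >= 1).
    DipAdd: all heterozygotes are equivalent and exactly halfway between the
    homozygotes (g = 1/2 for 0 < d < K).
    """
    d = np.asarray(d)
    if np.any((d < 0) | (d > ploidy)):
        raise ValueError(f"dosage outside 0..{ploidy}")
    if model == "Add":
        return d / ploidy
    if model == "SimDom":
        return (d >= 1).astype(float)
    if model == "DipAdd":
        return np.where(d == 0, 0.0, np.where(d == ploidy, 1.0, 0.5))
    raise ValueError(f"unknown effect model {model!r}")


def genetic_values(gene_dosages, config: SimConfig) -> np.ndarray:
    return np.asarray(genetic_effect(gene_dosages, config.effect_model, config.ploidy), dtype=float)


def simulate_phenotype(gene_dosages, config: SimConfig, rng: np.random.Generator):
    """Phenotypes with the causal locus explaining the configured PVE.

    Continuous: y = g + e, e ~ N(0, s2) with s2 = Var(g)(1-PVE)/PVE from the
    realized sample variance of g (closed-form counterpart of tuning the
    noise numerically).  Binary: y ~ Bernoulli(logistic(a + b g)) with b set
    so g explains PVE of the latent logistic variance, b = sqrt((pi^2/3) *
    PVE / ((1-PVE) Var(g))), and a centering the prevalence near 1/2; the
    binary generator is an extension beyond the benchmark design.

    Returns (y, g, sigma2); sigma2 is NaN for binary traits.
    """
    g = genetic_values(gene_dosages, config)
    var_g = float(np.var(g))
    if var_g < 1e-12:
        raise ValueError("PVE undefined: genetic values are constant in this sample")
    if config.trait_type == "continuous":
        sigma2 = var_g * (1.0 - config.pve) / config.pve
        y = g + rng.normal(0.0, np.sqrt(sigma2), size=g.shape)
        return y, g, sigma2
    b = np.sqrt((np.pi**2 / 3.0) * config.pve / ((1.0 - config.pve) * var_g))
    a = -b * g.mean()
    y = rng.binomial(1, expit(a + b * g)).astype(float)
    return y, g, float("nan")


def simulate_background_markers(
    config: SimConfig, rng: np.random.Generator
) -> list[BackgroundMarker]:
    """Unlinked markers (types drawn from the SS/DD/TT mixture) with read counts.

    These stand in for the genome-wide marker set used to calibrate
    permutation thresholds in the simulation studies.
    """
    if config.n_background_markers < 1:
        raise ValueError("n_background_markers must be >= 1")
    types = list(PARENT_DOSAGE)
    mix = np.asarray(config.background_type_mixture, dtype=float)
    mix = mix / mix.sum()
    drawn = rng.choice(len(types), size=config.n_background_markers, p=mix)
    out = []
    for t_idx in drawn:
        mt = types[t_idx]
        dosages = simulate_dosages(config, rng, marker_type=mt)
        dp, rd = simulate_read_counts(dosages, config, rng)
        out.append(BackgroundMarker(marker_type=mt, dosages=dosages, DP=dp, RD=rd))
    return out


def simulate_population(
    config: SimConfig, rng=None, with_background: bool = False
) -> SimulatedPopulation:
    """Full scenario draw: linked pair, reads, phenotype, optional background."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    gene, marker, xov = simulate_linked_pair(config, rng)
    dp, rd = simulate_read_counts(marker, config, rng)
    y, g, sigma2 = simulate_phenotype(gene, config, rng)
    background = simulate_background_markers(config, rng) if with_background else []
    ids = [f"sim{i + 1:04d}" for i in range(config.n_individuals)]
    return SimulatedPopulation(
        config=config,
        individual_ids=ids,
        gene_dosages=gene,
        marker_dosages=marker,
        DP=dp,
        RD=rd,
        phenotype=y,
        g=g,
        sigma2=sigma2,
        crossovers=xov,
        background=background,
    )


def _gt_string(dosage: int, ploidy: int) -> str:
    return "/".join(["0"] * dosage + ["1"] * (ploidy - dosage))


def write_vcf(pop: SimulatedPopulation, path) -> None:
    """Emit the focal marker and background markers as a minimal VCF.

    FORMAT carries GT:DP:RD (VarScan-style scalar reference depth); the
    focal marker is the first record, on contig ``simFocal``.
    """
    K = pop.config.ploidy
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pop.individual_ids)
            + "\n"
        )

        def record(chrom, pos, mid, dosages, dp, rd):
            cells = "\t".join(
                f"{_gt_string(int(d), K)}:{int(t)}:{int(r)}"
                for d, t, r in zip(dosages, dp, rd)
            )
            fh.write(f"{chrom}\t{pos}\t{mid}\tA\tT\t.\tPASS\t.\tGT:DP:RD\t{cells}\n")

        record("simFocal", 1, "simFocal_1", pop.marker_dosages, pop.DP, pop.RD)
        for k, bg in enumerate(pop.background, start=1):
            record("simBg", k, f"simBg_{k}", bg.dosages, bg.DP, bg.RD)


def write_phenotype_tsv(pop: SimulatedPopulation, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tvalue\n")
        for ind, val in zip(pop.individual_ids, pop.phenotype):
            fh.write(f"{ind}\t{val:.6g}\n")


def write_truth_tsv(pop: SimulatedPopulation, path) -> None:
    """True dosages, genetic values and crossover counts, for evaluation."""
    with open(path, "w") as fh:
        fh.write("id\tgene_dosage\tmarker_dosage\tg\tcrossovers\tsigma2\n")
        for i, ind in enumerate(pop.individual_ids):
            fh.write(
                f"{ind}\t{pop.gene_dosages[i]}\t{pop.marker_dosages[i]}\t"
                f"{pop.g[i]:.6g}\t{pop.crossovers[i]}\t{pop.sigma2:.6g}\n"
            )


def config_with(config: SimConfig, **updates) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **updates)
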
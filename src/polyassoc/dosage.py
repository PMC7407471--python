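"""Allele-dosage probability estimation from read counts.

For a K-ploid genotype the reference-allele dosage d takes values 0..K. The
naive estimator scores each dosage by a binomial likelihood of the observed
reference read count RD out of total depth DP at expected reference fraction
r_d, where r = {0/K+e, 1/K, ..., (K-1)/K, K/K-e} and e is a small ad hoc
error probability shielding the boundary dosages from zero likelihoods. The
relative probabilities RPr(d) (normalized across dosages, so the binomial
coefficient cancels) form a per-marker matrix with one row per individual —
the genotype representation carried through association scans in place of
hard dosage calls.

A noise-aware alternative combines a segregation prior with a beta-binomial
read model (allelic bias, overdispersion, sequencing error; see
:mod:`polyassoc.noise`), with the noise parameters estimated by maximizing
the marginal likelihood over a fixed grid. It is a deliberately simple
posterior estimator in the spirit of EM-based polyploid genotypers, used
here for estimator comparisons in simulation studies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .noise import betabinom_logpmf, expected_ref_fraction
from .vcf_io import ReadCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "DosageModelParams",
    "DosageProbabilityMatrix",
    "naive_dosage_probs",
    "dosage_matrix",
    "continuous_dosage",
    "call_dosage",
    "major_genotype_frequency",
    "filter_mgf",
    "noise_aware_posterior",
    "estimate_noise_params",
    "write_dosage_tsv",
]

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DosageModelParams:
    """Naive binomial dosage model: ploidy K and boundary error probability e."""

    ploidy: int = 6
    error_prob: float = 0.001

    def __post_init__(self) -> None:
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError(f"ploidy must be a positive even integer, got {self.ploidy}")
        if not 0 < self.error_prob < 0.5:
            raise ValueError(f"error_prob must be in (0, 0.5), got {self.error_prob}")

    @property
    def r(self) -> np.ndarray:
        """Expected reference-read fractions per dosage, endpoints pulled in by e."""
        r = np.arange(self.ploidy + 1, dtype=float) / self.ploidy
        r[0] += self.error_prob
        r[-1] -= self.error_prob
        return r


@dataclass
class DosageProbabilityMatrix:
    """Relative dosage probabilities for one marker: individuals x (K+1).

    Unmasked rows sum to 1; ``mask[i]`` is True where the genotype is missing.
    """

    probs: np.ndarray
    mask: np.ndarray
    marker_id: str = ""
    ploidy: int = 6
    individual_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.probs.ndim != 2 or self.probs.shape[1] != self.ploidy + 1:
            raise ValueError(
                f"probs must be (n, {self.ploidy + 1}), got {self.probs.shape}"
            )
        if self.mask.shape != (self.probs.shape[0],):
            raise ValueError("mask must be one flag per individual")
        ok = ~self.mask
        if np.any(self.probs[ok] < -ROW_SUM_TOL) or np.any(self.probs[ok] > 1 + ROW_SUM_TOL):
            raise ValueError("probabilities outside [0, 1]")
        if ok.any() and not np.allclose(self.probs[ok].sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("unmasked rows must sum to 1")

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def all_masked(self) -> bool:
        return bool(self.mask.all())


def _naive_log_scores(dp, rd, params: DosageModelParams) -> np.ndarray:
    """Unnormalized log scores RD*log(r_d) + (DP-RD)*log(1-r_d), broadcast over cells."""
    dp = np.asarray(dp, dtype=float)[..., None]
    rd = np.asarray(rd, dtype=float)[..., None]
    r = params.r
    return rd * np.log(r) + (dp - rd) * np.log1p(-r)


def naive_dosage_probs(DP: int, RD: int, params: DosageModelParams | None = None) -> np.ndarray:
    """Relative dosage probability vector for one genotype cell.

    Computed in log space; the binomial coefficient is common to all dosages
    and cancels in the normalization, so it is omitted.
    """
    params = params or DosageModelParams()
    if DP < 1:
        raise ValueError(f"DP must be >= 1, got {DP}")
    if not 0 <= RD <= DP:
        raise ValueError(f"need 0 <= RD <= DP, got RD={RD}, DP={DP}")
    log_scores = _naive_log_scores(DP, RD, params)
    return np.exp(log_scores - logsumexp(log_scores))


def dosage_matrix(
    table: ReadCountTable, params: DosageModelParams | None = None
) -> list[DosageProbabilityMatrix]:
    """Naive dosage-probability matrices, one per marker of a count table.

    Masked cells become masked rows; fully masked markers are flagged via
    ``all_masked`` and skipped by downstream scans.
    """
    params = params or DosageModelParams()
    out = []
    for j in range(table.n_markers):
        mask = table.mask[:, j].copy()
        probs = np.zeros((table.n_individuals, params.ploidy + 1))
        ok = ~mask
        if ok.any():
            log_scores = _naive_log_scores(table.DP[ok, j], table.RD[ok, j], params)
            probs[ok] = np.exp(log_scores - logsumexp(log_scores, axis=1, keepdims=True))
        out.append(
            DosageProbabilityMatrix(
                probs=probs,
                mask=mask,
                marker_id=table.marker_ids[j],
                ploidy=params.ploidy,
                individual_ids=list(table.individual_ids),
            )
        )
    return out


def continuous_dosage(M: DosageProbabilityMatrix) -> np.ndarray:
    """Expected dosage per individual, sum_d RPr[i,d]*d; NaN for masked rows."""
    x = M.probs @ np.arange(M.ploidy + 1, dtype=float)
    x[M.mask] = np.nan
    return x


def call_dosage(M: DosageProbabilityMatrix, return_ties: bool = False):
    """Hard calls: per-row argmax dosage; masked rows get -1.

    Exact ties break toward the lower dosage (numpy argmax convention) and
    are counted; pass ``return_ties=True`` to receive the tie count.
    """
    calls = np.argmax(M.probs, axis=1).astype(np.int64)
    row_max = M.probs.max(axis=1)
    n_ties = int(((M.probs == row_max[:, None]).sum(axis=1) > 1)[~M.mask].sum())
    calls[M.mask] = -1
    if n_ties:
        logger.debug("%s: %d tied argmax row(s), lower dosage kept", M.marker_id, n_ties)
    return (calls, n_ties) if return_ties else calls


def major_genotype_frequency(M: DosageProbabilityMatrix, method: str = "probability") -> float:
    """Largest dosage-class frequency (MGF) of a marker.

    Default aggregates the probability matrix column-wise (largest column
    mean over unmasked rows); ``method="call"`` uses hard-call class
    frequencies instead, for sensitivity checks.  NaN if fully masked.
    """
    ok = ~M.mask
    if not ok.any():
        return float("nan")
    if method == "probability":
        return float(M.probs[ok].mean(axis=0).max())
    if method == "call":
        calls = np.argmax(M.probs[ok], axis=1)
        return float(np.bincount(calls, minlength=M.ploidy + 1).max() / ok.sum())
    raise ValueError(f"unknown MGF method {method!r}")


def filter_mgf(
    matrices: list[DosageProbabilityMatrix],
    threshold: float = 0.95,
    method: str = "probability",
) -> list[DosageProbabilityMatrix]:
    """Drop near-monomorphic markers with MGF strictly above ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept = [
        M
        for M in matrices
        if not M.all_masked and major_genotype_frequency(M, method=method) <= threshold
    ]
    n_dropped = len(matrices) - len(kept)
    if n_dropped:
        logger.info("filter_mgf: dropped %d marker(s) with MGF > %g", n_dropped, threshold)
    return kept


def _posterior_log_lik(dp, rd, prior, ploidy, bias, od, seq_error):
    """Per-individual per-dosage log prior + beta-binomial log likelihood."""
    p = np.arange(ploidy + 1, dtype=float) / ploidy
    xi = expected_ref_fraction(p, bias, seq_error)
    ll = betabinom_logpmf(
        np.asarray(rd, dtype=float)[..., None],
        np.asarray(dp, dtype=float)[..., None],
        xi,
        od,
        include_binom_coef=False,
    )
    with np.errstate(divide="ignore"):
        log_prior = np.log(np.asarray(prior, dtype=float))
    return log_prior + ll


def noise_aware_posterior(
    DP_vec,
    RD_vec,
    prior,
    bias: float = 1.0,
    od: float = 0.0,
    seq_error: float = 0.001,
    ploidy: int = 6,
    mask=None,
    marker_id: str = "",
) -> DosageProbabilityMatrix:
    """Posterior dosage probabilities under a segregation prior and noise model.

    posterior[d] ∝ prior[d] * BetaBinomial(RD | DP, xi(d/K), od) with the
    bias/sequencing-error warp xi from :mod:`polyassoc.noise`.  With od=0,
    bias=1, seq_error=0 and a uniform prior this reduces to the naive
    binomial estimator (up to its boundary-e adjustment).
    """
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (ploidy + 1,):
        raise ValueError(f"prior must have length {ploidy + 1}")
    if not np.isclose(prior.sum(), 1.0, atol=1e-6):
        raise ValueError("prior must sum to 1")
    dp = np.asarray(DP_vec, dtype=np.int64)
    rd = np.asarray(RD_vec, dtype=np.int64)
    mask = (
        np.zeros(dp.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    ).copy()
    mask |= dp < 1
    log_post = _posterior_log_lik(dp, rd, prior, ploidy, bias, od, seq_error)
    probs = np.zeros_like(log_post)
    ok = ~mask
    if ok.any():
        probs[ok] = np.exp(
            log_post[ok] - logsumexp(log_post[ok], axis=1, keepdims=True)
        )
    probs[mask] = 0.0
    return DosageProbabilityMatrix(
        probs=probs, mask=mask, marker_id=marker_id, ploidy=ploidy
    )


# Grids for the marginal-likelihood search: bias log-spaced 0.25..2.0,
# od = 0 plus log-spaced 0.001..0.2.
BIAS_GRID = np.geomspace(0.25, 2.0, 15)
OD_GRID = np.concatenate([[0.0], np.geomspace(0.001, 0.2, 11)])


def estimate_noise_params(
    DP_vec,
    RD_vec,
    prior,
    seq_error: float = 0.001,
    ploidy: int = 6,
    mask=None,
    bias_grid=None,
    od_grid=None,
) -> tuple[float, float]:
    """Grid maximum-marginal-likelihood estimate of (bias, od) for one marker.

    Maximizes sum_i log sum_d prior[d] * BetaBinomial(RD_i | DP_i, xi(d/K), od)
    over the fixed (bias, od) grid.  Degenerate markers (all reads reference
    or all alternative) return (1, 0) with a warning.
    """
    bias_grid = BIAS_GRID if bias_grid is None else np.asarray(bias_grid, dtype=float)
    od_grid = OD_GRID if od_grid is None else np.asarray(od_grid, dtype=float)
    dp = np.asarray(DP_vec, dtype=np.int64)
    rd = np.asarray(RD_vec, dtype=np.int64)
    ok = (dp >= 1) if mask is None else (~np.asarray(mask, dtype=bool)) & (dp >= 1)
    if ok.sum() < 20:
        raise ValueError(f"need >= 20 unmasked individuals, got {int(ok.sum())}")
    dp, rd = dp[ok], rd[ok]
    if np.all(rd == 0) or np.all(rd == dp):
        warnings.warn(
            "degenerate read counts (all-reference or all-alternative); "
            "returning bias=1, od=0",
            stacklevel=2,
        )
        return 1.0, 0.0
    # collapse to unique (DP, RD) cells: the likelihood only depends on counts
    pairs, counts = np.unique(np.column_stack([dp, rd]), axis=0, return_counts=True)
    dp_u = pairs[:, 0][:, None, None].astype(float)
    rd_u = pairs[:, 1][:, None, None].astype(float)
    p = np.arange(ploidy + 1, dtype=float) / ploidy
    xi = np.stack([expected_ref_fraction(p, b, seq_error) for b in bias_grid])  # (B, K+1)
    with np.errstate(divide="ignore"):
        log_prior = np.log(np.asarray(prior, dtype=float))
    best = (-np.inf, 1.0, 0.0)
    for od in od_grid:
        ll_cell = betabinom_logpmf(rd_u, dp_u, xi[None], od, include_binom_coef=False)
        marg = logsumexp(ll_cell + log_prior, axis=-1)  # (U, B)
        totals = counts @ marg  # (B,)
        b_idx = int(np.argmax(totals))
        if totals[b_idx] > best[0]:
            best = (float(totals[b_idx]), float(bias_grid[b_idx]), float(od))
    return best[1], best[2]


def write_dosage_tsv(M: DosageProbabilityMatrix, table: ReadCountTable, path) -> None:
    """Export one marker's dosage matrix: ID, DP, RD, RPr(0..K) per individual."""
    j = table.marker_ids.index(M.marker_id)
    cols = {
        "ID": table.individual_ids,
        "DP": np.where(M.mask, np.nan, table.DP[:, j]),
        "RD": np.where(M.mask, np.nan, table.RD[:, j]),
    }
    for d in range(M.ploidy + 1):
        cols[f"RPr{d}"] = np.where(M.mask, np.nan, M.probs[:, d])
    pd.DataFrame(cols).to_csv(path, sep="\t", na_rep="NA", index=False, float_format="%.6g")
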
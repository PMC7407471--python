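"""Shared read-count noise model.

Low-coverage sequencing of a polyploid genotype with reference-allele dosage
``d`` (out of ploidy ``K``) yields reference reads whose expected fraction is
not simply ``p = d/K``: base-calling error mixes the two alleles and allelic
bias warps the detectability of the reference versus the alternative allele.
Extra-binomial variation between samples (library effects) is captured by a
beta-binomial overdispersion parameter.

This module is the single source of truth for that model. Both the
noise-aware dosage posterior (:mod:`polyassoc.dosage`) and the read-count
simulator (:mod:`polyassoc.simulate`) call into it, so the estimator and the
generator can never drift apart.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln

__all__ = ["expected_ref_fraction", "betabinom_logpmf", "sample_read_counts"]

# Below this, overdispersion is numerically indistinguishable from binomial.
_OD_EPS = 1e-12


def expected_ref_fraction(p, bias: float, seq_error: float):
    """Expected reference-read fraction xi for allele frequency ``p``.

    Sequencing error first mixes the alleles, ``f = p(1-eps) + (1-p)eps``,
    then allelic bias ``h`` warps the odds of observing a reference read:
    ``xi = f / (h(1-f) + f)``.  ``h < 1`` means alternative reads are
    under-detected, inflating the reference fraction (h=0.5, p=1/2 gives
    xi = 2/3); ``h = 1`` and ``eps = 0`` recover ``xi = p``.
    """
    if bias <= 0:
        raise ValueError(f"bias must be > 0, got {bias}")
    if not 0 <= seq_error < 0.5:
        raise ValueError(f"seq_error must be in [0, 0.5), got {seq_error}")
    p = np.asarray(p, dtype=float)
    f = p * (1.0 - seq_error) + (1.0 - p) * seq_error
    return f / (bias * (1.0 - f) + f)


def betabinom_logpmf(rd, dp, xi, od, include_binom_coef: bool = True):
    """Log pmf of reference read count RD given total depth DP.

    Beta-binomial parameterized by mean ``xi`` and overdispersion ``od``
    via ``alpha = xi(1-od)/od``, ``beta = (1-xi)(1-od)/od``; ``od = 0``
    degenerates to Binomial(DP, xi).  Arguments broadcast.
    """
    if not 0 <= od < 1:
        raise ValueError(f"od must be in [0, 1), got {od}")
    rd = np.asarray(rd, dtype=float)
    dp = np.asarray(dp, dtype=float)
    xi = np.asarray(xi, dtype=float)
    coef = (
        gammaln(dp + 1) - gammaln(rd + 1) - gammaln(dp - rd + 1)
        if include_binom_coef
        else 0.0
    )
    if od < _OD_EPS:
        # log xi / log(1-xi) guarded for xi in {0,1}: 0*log(0) := 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(rd > 0, rd * np.log(xi), 0.0)
            t2 = np.where(dp - rd > 0, (dp - rd) * np.log1p(-xi), 0.0)
        return coef + t1 + t2
    alpha = xi * (1.0 - od) / od
    beta = (1.0 - xi) * (1.0 - od) / od
    return coef + betaln(rd + alpha, dp - rd + beta) - betaln(alpha, beta)


def sample_read_counts(rng: np.random.Generator, dp, xi, od: float):
    """Draw reference read counts RD ~ BetaBinomial(DP, xi, od) elementwise."""
    if not 0 <= od < 1:
        raise ValueError(f"od must be in [0, 1), got {od}")
    dp = np.asarray(dp)
    xi = np.broadcast_to(np.asarray(xi, dtype=float), dp.shape)
    if od < _OD_EPS:
        return rng.binomial(dp, xi)
    alpha = xi * (1.0 - od) / od
    beta = (1.0 - xi) * (1.0 - od) / od
    # guard exact xi in {0,1}: beta() rejects zero shape parameters
    p = np.empty(dp.shape, dtype=float)
    interior = (xi > 0) & (xi < 1)
    p[~interior] = xi[~interior]
    if np.any(interior):
        p[interior] = rng.beta(alpha[interior], beta[interior])
    return rng.binomial(dp, p)
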
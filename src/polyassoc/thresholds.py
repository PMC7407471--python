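"""Genome-wide significance thresholds by permutation and GEV tail modeling.

The phenotype vector is permuted as a whole against the genotype rows (the
standard genome-wide max-T scheme; with no covariates this is the only
exchangeable unit), the full scan is re-run per replicate, and the maximum
-log10(p) is recorded.  A generalized extreme-value distribution is fitted
to the permutation maxima by maximum likelihood and its upper quantiles give
the genome-wide thresholds; modeling the tail is more efficient than taking
empirical quantiles when the number of permutations is modest, though a low
replicate count still tends to underestimate the threshold.

Shape-parameter sign convention: shape > 0 is the heavy-tailed Frechet
domain (this is the negative of scipy's ``genextreme`` shape ``c``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, genextreme

from .association import LN10, Phenotype, _align_rows, build_design, scan
from .dosage import DosageProbabilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GevThreshold",
    "GevFitError",
    "permutation_maxima",
    "fit_gev",
    "gev_threshold",
    "compute_threshold",
    "write_threshold_tsv",
]

DEFAULT_ALPHAS = (0.10, 0.05, 0.01)


class GevFitError(RuntimeError):
    """Maximum-likelihood GEV fit failed to produce usable parameters."""


@dataclass
class GevThreshold:
    """Fitted permutation-maxima model and its -log10(p) quantiles."""

    n_perm: int
    maxima: np.ndarray
    loc: float
    scale: float
    shape: float
    thresholds: dict[float, float]
    seed: int | None = None
    method: str = "gev"
    encoding: str = ""
    trait_type: str = ""
    flags: str = field(default="")

    def threshold(self, alpha: float = 0.05) -> float:
        if alpha in self.thresholds:
            return self.thresholds[alpha]
        if self.method == "empirical":
            return float(np.quantile(self.maxima, 1 - alpha))
        return gev_threshold((self.loc, self.scale, self.shape), alpha)


def _permutation_matrix(n: int, n_perm: int, seed) -> np.ndarray:
    """Column i = the i-th permutation of range(n); per-replicate child seeds."""
    children = np.random.SeedSequence(seed).spawn(n_perm)
    out = np.empty((n, n_perm), dtype=np.intp)
    for i, child in enumerate(children):
        out[:, i] = np.random.default_rng(child).permutation(n)
    return out


def _gaussian_fast_maxima(matrices, rows_all, y, encoding, perms) -> np.ndarray | None:
    """Vectorized paper-mode Gaussian max -log10(p) per permutation.

    For each marker with orthonormal full-design basis Q (intercept
    included) over its used rows, the unscaled deviance difference for a
    permuted response y_p is ||Q^T y_p||^2 - (sum y_p)^2 / n.  Returns None
    when no marker is testable.
    """
    n_perm = perms.shape[1]
    Yp = y[perms]  # (n, n_perm)
    best = np.full(n_perm, -np.inf)
    any_testable = False
    for M in matrices:
        use = (~M.mask[rows_all]) & np.isfinite(y)
        rows = rows_all[use]
        if rows.size == 0:
            continue
        X = build_design(M, rows, encoding)
        if X is None:
            continue
        X = X[:, X.std(axis=0) > 1e-12]
        if X.shape[1] == 0:
            continue
        n_used = rows.size
        X1 = np.column_stack([np.ones(n_used), X])
        Q, R = np.linalg.qr(X1)
        diag = np.abs(np.diag(R))
        rank_keep = diag > 1e-10 * max(diag.max(), 1.0)
        Q = Q[:, rank_keep]
        df = int(rank_keep.sum()) - 1
        if df < 1 or n_used < Q.shape[1] + 2:
            continue
        any_testable = True
        Ym = Yp[use]  # rows of the permuted responses used by this marker
        proj = Q.T @ Ym
        stat = np.einsum("ij,ij->j", proj, proj) - Ym.sum(axis=0) ** 2 / n_used
        np.maximum(best, -chi2.logsf(np.maximum(stat, 0.0), df) / LN10, out=best)
    return best if any_testable else None


def permutation_maxima(
    matrices: list[DosageProbabilityMatrix],
    phenotype: Phenotype,
    encoding: str = "continuous",
    n_perm: int = 1000,
    seed=None,
    mode: str = "paper",
) -> np.ndarray:
    """Max -log10(p) of the genome-wide scan under each of n_perm permutations.

    Genotypes are untouched; the phenotype is permuted uniformly at random.
    Reproducible given ``seed`` (per-replicate seeds are derived from it by
    counter, so the replicate stream does not depend on n_perm order).
    """
    if n_perm < 50:
        warnings.warn(
            f"n_perm={n_perm} < 50: GEV fit to so few maxima is unstable", stacklevel=2
        )
    rows_all, y = _align_rows(matrices[0], phenotype)
    finite = np.isfinite(y)
    if np.nanstd(y[finite]) < 1e-12:
        warnings.warn("constant phenotype: permutation maxima are degenerate", stacklevel=2)
    perms = _permutation_matrix(y.size, n_perm, seed)
    if phenotype.trait_type == "continuous" and mode == "paper":
        fast = _gaussian_fast_maxima(matrices, rows_all, y, encoding, perms)
        if fast is not None:
            return fast
        return np.zeros(n_perm)
    # generic path (binary traits / scaled mode): full scan per replicate
    maxima = np.empty(n_perm)
    ids = phenotype.individual_ids
    for i in range(n_perm):
        perm_ph = Phenotype(ids, y[perms[:, i]], phenotype.trait_type)
        res = scan(matrices, perm_ph, encoding=encoding, mode=mode)
        ok = res["flags"] == ""
        maxima[i] = res.loc[ok, "neglog10p"].max() if ok.any() else 0.0
    return maxima


def fit_gev(maxima) -> tuple[float, float, float]:
    """Maximum-likelihood GEV fit; returns (loc, scale, shape).

    shape > 0 denotes the heavy-tailed Frechet domain (= -scipy c).
    """
    x = np.asarray(maxima, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise GevFitError(f"need >= 50 finite maxima, got {x.size}")
    if x.std() < 1e-12:
        raise GevFitError("maxima have zero variance")
    with np.errstate(all="ignore"):
        c, loc, scale = genextreme.fit(x)
        ll = genextreme.logpdf(x, c, loc, scale).sum()
    if not (np.isfinite([c, loc, scale]).all() and scale > 0 and np.isfinite(ll)):
        raise GevFitError("GEV ML fit did not converge to finite parameters")
    logger.debug("GEV fit: loc=%.4f scale=%.4f shape=%.4f loglik=%.2f", loc, scale, -c, ll)
    return float(loc), float(scale), float(-c)


def gev_threshold(params, alpha: float) -> float:
    """1-alpha quantile of a GEV given (loc, scale, shape).

    loc + (scale/shape) * ((-ln(1-alpha))^(-shape) - 1) for shape != 0,
    with the Gumbel limit loc - scale*ln(-ln(1-alpha)) at shape = 0.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    loc, scale, shape = params
    t = -np.log1p(-alpha)
    if shape == 0:
        return float(loc - scale * np.log(t))
    return float(loc + (scale / shape) * (t ** (-shape) - 1.0))


def compute_threshold(
    maxima,
    alphas=DEFAULT_ALPHAS,
    n_perm: int | None = None,
    seed=None,
    encoding: str = "",
    trait_type: str = "",
) -> GevThreshold:
    """Fit a GEV to permutation maxima and extract the threshold quantiles.

    Falls back to empirical quantiles with a prominent warning when the ML
    fit fails (e.g. degenerate maxima).
    """
    x = np.asarray(maxima, dtype=float)
    common = dict(
        n_perm=n_perm if n_perm is not None else x.size,
        maxima=x,
        seed=seed,
        encoding=encoding,
        trait_type=trait_type,
    )
    try:
        loc, scale, shape = fit_gev(x)
    except GevFitError as exc:
        warnings.warn(
            f"GEV fit failed ({exc}); falling back to EMPIRICAL quantiles, "
            "which underestimate extreme thresholds at low replicate counts",
            stacklevel=2,
        )
        finite = x[np.isfinite(x)]
        thr = {a: float(np.quantile(finite, 1 - a)) for a in alphas}
        return GevThreshold(
            loc=np.nan, scale=np.nan, shape=np.nan, thresholds=thr,
            method="empirical", flags="gev_fallback", **common,
        )
    thr = {a: gev_threshold((loc, scale, shape), a) for a in alphas}
    return GevThreshold(loc=loc, scale=scale, shape=shape, thresholds=thr, **common)


def write_threshold_tsv(thresholds: list[GevThreshold], path) -> None:
    """Threshold report: one row per (encoding, trait) with 10/5/1% quantiles."""
    rows = []
    for t in thresholds:
        row = {
            "encoding": t.encoding,
            "trait_type": t.trait_type,
            "n_perm": t.n_perm,
            "method": t.method,
            "loc": t.loc,
            "scale": t.scale,
            "shape": t.shape,
            "seed": t.seed,
        }
        for a in sorted(t.thresholds, reverse=True):
            row[f"alpha_{int(round(a * 100))}pct"] = t.thresholds[a]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", na_rep="NA", index=False, float_format="%.6g")
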
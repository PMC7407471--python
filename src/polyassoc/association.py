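"""Marker-phenotype association by GLM likelihood-ratio tests.

Each marker's dosage-probability matrix enters the model under one of two
encodings: *continuous* (the expected dosage, probability matrix times the
dosage vector v = {0..K}, a single regressor) or *dogmat* (the probability
matrix itself as a multi-column regressor block, one column per segregating
dosage class with the reference class dropped).  Continuous traits use a
Gaussian identity-link GLM, binary traits a logistic GLM; significance is
the likelihood-ratio chi-square of the marker block against the
intercept-only null.

In the default "paper" mode the Gaussian statistic is the unscaled deviance
difference (residual sum of squares difference) referred to chi-square,
which is scale-dependent; genome-wide significance is calibrated by
permutation (see :mod:`polyassoc.thresholds`) so this remains valid.  A
"scaled" mode dividing by the full-model dispersion estimate is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .dosage import DosageProbabilityMatrix, continuous_dosage

logger = logging.getLogger(__name__)

__all__ = [
    "Phenotype",
    "LrtResult",
    "fit_glm_lrt",
    "encode_continuous",
    "encode_dogmat",
    "build_design",
    "scan",
    "write_scan_tsv",
    "manhattan_plot",
]

LN10 = np.log(10.0)
_COL_SUM_TOL = 1e-8


@dataclass
class Phenotype:
    """Trait values keyed by individual ID; trait_type is declared, not inferred."""

    individual_ids: list[str]
    values: np.ndarray
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individual_ids),):
            raise ValueError("one value per individual required")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.trait_type == "binary":
            finite = self.values[np.isfinite(self.values)]
            if not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError("binary traits must take values in {0, 1}")


class LrtResult(NamedTuple):
    lrt_stat: float
    df: int
    pvalue: float
    neglog10p: float
    flags: str


def _untestable(flag: str = "untestable") -> LrtResult:
    return LrtResult(0.0, 0, 1.0, 0.0, flag)


def _prune_constant_columns(X: np.ndarray) -> np.ndarray:
    keep = X.std(axis=0) > 1e-12
    return X[:, keep]


def _chi2_tail(stat: float, df: int) -> tuple[float, float]:
    """(pvalue, -log10 p) via the log survival function for small-p resolution."""
    logsf = chi2.logsf(stat, df)
    return float(np.exp(logsf)), float(-logsf / LN10)


def _gaussian_lrt(y: np.ndarray, X: np.ndarray, mode: str) -> LrtResult:
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 <= 1e-12:
        return _untestable("constant_phenotype")
    X1 = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    df = int(rank) - 1
    if df < 1:
        return _untestable()
    rss1 = float(np.sum((y - X1 @ beta) ** 2))
    stat = max(rss0 - rss1, 0.0)
    if mode == "scaled":
        if n <= rank:
            return _untestable("saturated")
        dispersion = rss1 / (n - rank)
        stat = stat / dispersion if dispersion > 1e-300 else np.inf
    p, nlp = _chi2_tail(stat, df)
    return LrtResult(stat, df, p, nlp, "")


def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def _logistic_fit(y: np.ndarray, X1: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """IRLS logistic regression; returns (deviance, rank, converged)."""
    n, p = X1.shape
    beta = np.zeros(p)
    rank = p
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X1 @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        sw = np.sqrt(w)
        z = eta + (y - mu) / w
        new_beta, _, rank, _ = np.linalg.lstsq(X1 * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if step < tol:
            converged = True
            break
    mu = expit(np.clip(X1 @ beta, -30, 30))
    return _bernoulli_deviance(y, mu), int(rank), converged


def _binary_lrt(y: np.ndarray, X: np.ndarray, mode: str) -> LrtResult:
    if np.all(y == y[0]):
        return _untestable("constant_phenotype")
    n = y.size
    pbar = y.mean()
    dev0 = _bernoulli_deviance(y, np.full(n, pbar))
    X1 = np.column_stack([np.ones(n), X])
    dev1, rank, converged = _logistic_fit(y, X1)
    df = rank - 1
    if df < 1:
        return _untestable()
    stat = max(dev0 - dev1, 0.0)
    flags = ""
    if not converged:
        flags = "separation"
        logger.warning("logistic fit hit the iteration cap (possible separation)")
    p, nlp = _chi2_tail(stat, df)
    return LrtResult(stat, df, p, nlp, flags)


def fit_glm_lrt(y, X, trait_type: str = "continuous", mode: str = "paper") -> LrtResult:
    """Likelihood-ratio test of a marker regressor block against the null.

    Fits the intercept-only and intercept+X GLMs (Gaussian/identity for
    continuous traits, binomial/logit for binary), takes the deviance
    difference, and refers it to chi-square with df = rank(full) - 1.
    Constant columns are pruned; a design with nothing left is reported
    untestable (p = 1, df = 0).
    """
    if mode not in ("paper", "scaled"):
        raise ValueError(f"mode must be paper|scaled, got {mode!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X must have matching length")
    X = _prune_constant_columns(X)
    if X.shape[1] == 0:
        return _untestable()
    if y.size < X.shape[1] + 2:
        return _untestable("too_few_observations")
    if trait_type == "continuous":
        return _gaussian_lrt(y, X, mode)
    if trait_type == "binary":
        return _binary_lrt(y, X, mode)
    raise ValueError(f"unknown trait_type {trait_type!r}")


def encode_continuous(M: DosageProbabilityMatrix, rows=None) -> np.ndarray:
    """One-column design: expected dosage per (selected) individual."""
    x = continuous_dosage(M)
    if rows is not None:
        x = x[rows]
    return x[:, None]


def encode_dogmat(M: DosageProbabilityMatrix, rows=None) -> np.ndarray | None:
    """Dosage-probability columns as a multi-column design.

    Columns whose total mass is below 1e-8 (dosage classes absent from the
    marker) are dropped, then the largest-mass column (the reference class)
    is dropped to break the rows-sum-to-one collinearity with the intercept.
    Returns None (untestable) when fewer than two classes are present.
    """
    P = M.probs if rows is None else M.probs[rows]
    col_mass = P.sum(axis=0)
    present = col_mass >= _COL_SUM_TOL
    if present.sum() < 2:
        return None
    drop = np.argmax(np.where(present, col_mass, -np.inf))
    present[drop] = False
    return P[:, present]


def build_design(M: DosageProbabilityMatrix, rows, encoding: str) -> np.ndarray | None:
    if encoding == "continuous":
        return encode_continuous(M, rows)
    if encoding == "dogmat":
        return encode_dogmat(M, rows)
    raise ValueError(f"unknown encoding {encoding!r}")


def _align_rows(M: DosageProbabilityMatrix, phenotype: Phenotype) -> tuple[np.ndarray, np.ndarray]:
    """Indices into M's rows and matching phenotype values, by exact ID match."""
    if M.individual_ids is None:
        if M.n_individuals != len(phenotype.individual_ids):
            raise ValueError("matrices carry no individual IDs and lengths differ")
        return np.arange(M.n_individuals), phenotype.values
    pos = {gid: i for i, gid in enumerate(phenotype.individual_ids)}
    g_idx, y = [], []
    for i, gid in enumerate(M.individual_ids):
        if gid in pos:
            g_idx.append(i)
            y.append(phenotype.values[pos[gid]])
    if not g_idx:
        raise ValueError("no overlapping individual IDs between genotypes and phenotype")
    return np.asarray(g_idx), np.asarray(y)


def scan(
    matrices: list[DosageProbabilityMatrix],
    phenotype: Phenotype,
    encoding: str = "continuous",
    mode: str = "paper",
    marker_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genome-wide LRT scan: one result row per marker.

    Missing genotypes are handled by pairwise deletion per marker
    (``n_used`` records the sample actually fitted); untestable markers are
    flagged and carried with p = 1 so downstream threshold computations can
    exclude them consistently.
    """
    rows_all, y_all = _align_rows(matrices[0], phenotype) if matrices else (None, None)
    records = []
    for j, M in enumerate(matrices):
        rows, y = (rows_all, y_all)
        use = (~M.mask[rows]) & np.isfinite(y)
        sub_rows, sub_y = rows[use], y[use]
        if sub_rows.size == 0:
            res = _untestable("all_missing")
        else:
            X = build_design(M, sub_rows, encoding)
            res = _untestable() if X is None else fit_glm_lrt(sub_y, X, phenotype.trait_type, mode)
        rec = {
            "marker_id": M.marker_id,
            "chrom": ".",
            "pos": 0,
            "homologous_group": pd.NA,
            "encoding": encoding,
            "n_used": int(sub_rows.size),
            "lrt_stat": res.lrt_stat,
            "df": res.df,
            "pvalue": res.pvalue,
            "neglog10p": res.neglog10p,
            "flags": res.flags,
        }
        if marker_meta is not None:
            meta = marker_meta.iloc[j]
            rec["chrom"] = meta["chrom"]
            rec["pos"] = int(meta["pos"])
            rec["homologous_group"] = meta.get("homologous_group", pd.NA)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df.astype({"homologous_group": "Int64"}) if len(df) else df


def write_scan_tsv(scan_df: pd.DataFrame, path) -> None:
    scan_df.to_csv(path, sep="\t", na_rep="NA", index=False, float_format="%.6g")


def manhattan_plot(scan_df: pd.DataFrame, threshold: float | None = None, path=None):
    """Manhattan-style plot of -log10(p), colored by homologous group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan_df[scan_df["flags"] == ""].reset_index(drop=True)
    groups = df["homologous_group"].astype("Int64")
    key = groups.fillna(-1).to_numpy()
    order = np.argsort(key, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    key = key[order]
    fig, ax = plt.subplots(figsize=(9, 3.2))
    x = np.arange(len(df))
    for k, grp in enumerate(np.unique(key)):
        sel = key == grp
        label = "NA" if grp < 0 else str(int(grp))
        ax.scatter(x[sel], df["neglog10p"][sel], s=6, color=f"C{k % 10}", label=label)
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1)
    ax.set_xlabel("marker (by homologous group)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.legend(fontsize=6, ncol=8, title="group", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
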
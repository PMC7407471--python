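"""VCF ingestion and genotype-level read-count filtering.

Reads per-genotype total depth (DP) and reference-allele depth (RD, or the
first element of AD for callers that emit allele-depth lists) from a VCF into
paired count matrices, and applies the standard low-coverage GBS filters:
per-genotype depth bounds, per-marker missingness, and (downstream, via the
dosage module) major-genotype-frequency screening of near-monomorphic sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReadCountTable",
    "FormatFieldError",
    "read_vcf_counts",
    "filter_depth",
    "filter_missing",
    "read_phenotype_tsv",
    "attach_homologous_groups",
    "write_counts_tsv",
]


class FormatFieldError(ValueError):
    """A required FORMAT field is absent from every record of a VCF."""


@dataclass
class ReadCountTable:
    """Paired DP/RD count matrices (individuals x markers) with a missing mask.

    ``mask[i, j]`` is True where the genotype cell is missing; DP and RD share
    the mask.  Marker metadata (chrom, 1-based pos, optional homologous group)
    lives in a DataFrame aligned with ``marker_ids``.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    DP: np.ndarray
    RD: np.ndarray
    mask: np.ndarray
    marker_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.DP = np.asarray(self.DP, dtype=np.int64)
        self.RD = np.asarray(self.RD, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, m = len(self.individual_ids), len(self.marker_ids)
        if self.DP.shape != (n, m) or self.RD.shape != (n, m) or self.mask.shape != (n, m):
            raise ValueError(
                f"shape mismatch: expected {(n, m)}, got DP {self.DP.shape}, "
                f"RD {self.RD.shape}, mask {self.mask.shape}"
            )
        if self.marker_meta is None:
            self.marker_meta = pd.DataFrame(
                {
                    "chrom": ["."] * m,
                    "pos": np.zeros(m, dtype=np.int64),
                    "homologous_group": pd.array([pd.NA] * m, dtype="Int64"),
                }
            )
        valid = ~self.mask
        if np.any(self.DP[valid] < 0) or np.any(self.RD[valid] < 0):
            raise ValueError("negative read counts in unmasked cells")
        if np.any(self.RD[valid] > self.DP[valid]):
            raise ValueError("RD > DP in unmasked cells")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of masked genotype cells."""
        return self.mask.mean(axis=0)

    def select_markers(self, idx) -> "ReadCountTable":
        idx = np.asarray(idx)
        return ReadCountTable(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[j] for j in idx],
            DP=self.DP[:, idx],
            RD=self.RD[:, idx],
            mask=self.mask[:, idx],
            marker_meta=self.marker_meta.iloc[idx].reset_index(drop=True),
        )


def _extract_int_field(variant, field_name: str, n: int):
    """Return an int vector for a FORMAT field, or None if absent.

    Negative values (htslib missing sentinels) are reported as missing.
    """
    try:
        arr = variant.format(field_name)
    except KeyError:
        return None
    if arr is None:
        return None
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, 0]  # AD-style list field: first element = reference depth
    vals = arr.astype(np.int64, copy=False).reshape(n)
    missing = vals < 0
    return np.where(missing, 0, vals), missing


def read_vcf_counts(path, dp_field: str = "DP", rd_field: str = "RD") -> ReadCountTable:
    """Read per-genotype DP/RD counts for biallelic SNPs from a VCF.

    ``rd_field`` may be a scalar integer FORMAT field (VarScan-style ``RD``)
    or an allele-depth list field (``AD``), in which case the first element
    (reference depth) is used.  When the requested ``rd_field`` is absent
    from the file but ``AD`` is present, the reader falls back to ``AD[0]``
    and logs which path was taken.  Multi-allelic and indel records are
    skipped with a warning; cells lacking either field are masked missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dp_cols, rd_cols, mask_cols = [], [], []
    marker_ids, chroms, positions = [], [], []
    n_skipped = 0
    rd_seen = ad_fallback = False

    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        dp = _extract_int_field(variant, dp_field, n)
        rd = _extract_int_field(variant, rd_field, n)
        if rd is None and rd_field != "AD":
            rd = _extract_int_field(variant, "AD", n)
            if rd is not None:
                ad_fallback = True
        if rd is not None:
            rd_seen = True
        if dp is None or rd is None:
            # whole record lacks a field: fully masked column
            dp_vals = np.zeros(n, dtype=np.int64)
            rd_vals = np.zeros(n, dtype=np.int64)
            miss = np.ones(n, dtype=bool)
        else:
            dp_vals, dp_miss = dp
            rd_vals, rd_miss = rd
            miss = dp_miss | rd_miss
            # inconsistent caller output (RD > DP) is treated as missing
            bad = (~miss) & (rd_vals > dp_vals)
            miss |= bad
            dp_vals = np.where(miss, 0, dp_vals)
            rd_vals = np.where(miss, 0, rd_vals)
        dp_cols.append(dp_vals)
        rd_cols.append(rd_vals)
        mask_cols.append(miss)
        marker_ids.append(f"{variant.CHROM}_{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
    vcf.close()

    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP record(s) in %s", n_skipped, path)
    if marker_ids and not rd_seen:
        raise FormatFieldError(
            f"FORMAT field {rd_field!r} (and AD fallback) absent from every record of {path}"
        )
    if ad_fallback:
        logger.info("%s: field %r absent, reference depths taken from AD[0]", path, rd_field)
    else:
        logger.info("%s: reference depths taken from FORMAT/%s", path, rd_field)

    m = len(marker_ids)
    shape = (n, m)
    meta = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "homologous_group": pd.array([pd.NA] * m, dtype="Int64"),
        }
    )
    return ReadCountTable(
        individual_ids=samples,
        marker_ids=marker_ids,
        DP=np.column_stack(dp_cols) if m else np.zeros(shape, dtype=np.int64),
        RD=np.column_stack(rd_cols) if m else np.zeros(shape, dtype=np.int64),
        mask=np.column_stack(mask_cols) if m else np.ones(shape, dtype=bool),
        marker_meta=meta,
    )


def filter_depth(table: ReadCountTable, min_dp: int = 10, max_dp: int = 300) -> ReadCountTable:
    """Mask genotype cells with DP below ``min_dp`` or above ``max_dp``.

    Boundaries are inclusive for retention (strict inequalities for removal):
    DP = min_dp and DP = max_dp survive.  Mask-only; shape unchanged.
    """
    if min_dp > max_dp:
        raise ValueError(f"min_dp ({min_dp}) > max_dp ({max_dp})")
    out_of_range = (table.DP < min_dp) | (table.DP > max_dp)
    new_mask = table.mask | out_of_range
    dp = np.where(new_mask, 0, table.DP)
    rd = np.where(new_mask, 0, table.RD)
    return replace(table, DP=dp, RD=rd, mask=new_mask, marker_meta=table.marker_meta.copy())


def filter_missing(table: ReadCountTable, max_missing: float = 0.5) -> ReadCountTable:
    """Drop markers whose missing fraction strictly exceeds ``max_missing``."""
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    keep = np.flatnonzero(table.missing_fraction() <= max_missing)
    return table.select_markers(keep)


def read_phenotype_tsv(path, trait_type: str):
    """Read a two-column ``id<TAB>value`` phenotype TSV into a Phenotype."""
    from .association import Phenotype

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"phenotype file {path} needs columns id<TAB>value")
    ids = df.iloc[:, 0].astype(str).tolist()
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    return Phenotype(individual_ids=ids, values=values, trait_type=trait_type)


def attach_homologous_groups(table: ReadCountTable, groups) -> ReadCountTable:
    """Join a marker_id -> homologous group (1-15) annotation onto the table.

    ``groups`` is a mapping or a TSV path with columns marker_id, group.
    Unmatched markers keep group NA and still appear in scans.
    """
    if not isinstance(groups, dict):
        gdf = pd.read_csv(groups, sep="\t", dtype={0: str})
        groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    meta = table.marker_meta.copy()
    meta["homologous_group"] = pd.array(
        [groups.get(mid, pd.NA) for mid in table.marker_ids], dtype="Int64"
    )
    return replace(table, marker_meta=meta)


def write_counts_tsv(table: ReadCountTable, dp_path, rd_path) -> None:
    """Debug dump of the DP and RD matrices (missing cells as NA)."""
    for mat, path in ((table.DP, dp_path), (table.RD, rd_path)):
        df = pd.DataFrame(
            np.where(table.mask, np.nan, mat),
            index=table.individual_ids,
            columns=table.marker_ids,
        )
        df.to_csv(path, sep="\t", na_rep="NA", index_label="id")
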
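"""Cell-level QC with chemistry-dependent thresholds, TP10K normalization,
and pseudo-bulk aggregation (sum and mean variants)."""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "filter_cells",
    "lognorm",
    "pseudobulk_sum",
    "pseudobulk_mean",
]

MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QCThresholds:
    """Droplet QC cutoffs.

    A cell is retained iff total UMIs > ``min_umis`` (strict) and its
    mitochondrial UMI fraction is strictly below the threshold for its
    sample's chemistry: v2 libraries use ``max_mito_fraction_v2`` and v3
    (including dual-index) libraries, which typically carry a higher
    mitochondrial load, use ``max_mito_fraction_v3``.
    """

    min_umis: int = 500
    max_mito_fraction_v2: float = 0.25
    max_mito_fraction_v3: float = 0.40

    def for_chemistry(self, chemistry: str) -> float:
        if chemistry == "v2":
            return self.max_mito_fraction_v2
        if chemistry in ("v3", "v3-dual"):
            return self.max_mito_fraction_v3
        raise ValueError(f"unknown chemistry {chemistry!r}")


def _totals(data: ad.AnnData) -> np.ndarray:
    return np.asarray(sp.csr_matrix(data.X).sum(axis=1)).ravel()


def mito_fraction(data: ad.AnnData, prefix: str = MITO_PREFIX) -> np.ndarray:
    """Per-cell fraction of UMIs from genes whose name starts with ``prefix``."""
    is_mito = data.var_names.str.startswith(prefix)
    total = _totals(data)
    mito = np.asarray(sp.csr_matrix(data.X)[:, np.asarray(is_mito)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def filter_cells(
    data: ad.AnnData,
    samples: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = MITO_PREFIX,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply UMI and mitochondrial-fraction QC; returns (filtered, log).

    The retention log has one row per sample: cells in, cells kept, and the
    two rejection counts. Idempotent: filtering a filtered atlas is a no-op.
    """
    if data.n_obs == 0:
        return data.copy(), pd.DataFrame(
            columns=["sample_id", "n_in", "n_kept", "n_low_umi", "n_high_mito"]
        )
    chem = samples["chemistry"]
    unknown = set(data.obs["sample_id"]) - set(samples.index)
    if unknown:
        raise ValueError(f"cells reference samples with no covariates: {sorted(unknown)}")
    cell_chem = data.obs["sample_id"].map(chem)
    bad_chem = ~cell_chem.isin(["v2", "v3", "v3-dual"])
    if bad_chem.any():
        raise ValueError(
            f"unknown chemistry labels: {sorted(cell_chem[bad_chem].unique())}"
        )
    total = _totals(data)
    mfrac = mito_fraction(data, mito_prefix)
    limit = cell_chem.map(thresholds.for_chemistry).to_numpy(dtype=float)
    keep_umi = total > thresholds.min_umis
    keep_mito = mfrac < limit
    keep = keep_umi & keep_mito

    log = (
        pd.DataFrame(
            {
                "sample_id": data.obs["sample_id"].values,
                "kept": keep,
                "low_umi": ~keep_umi,
                "high_mito": keep_umi & ~keep_mito,
            }
        )
        .groupby("sample_id", sort=True)
        .agg(n_in=("kept", "size"), n_kept=("kept", "sum"),
             n_low_umi=("low_umi", "sum"), n_high_mito=("high_mito", "sum"))
        .reset_index()
    )
    return data[keep].copy(), log


def lognorm(data: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log(TP10K + 1): value = ln(1 + scale * count / cell_total).

    Cells with zero total UMIs are rejected — they should not have survived QC.
    """
    total = _totals(data)
    if np.any(total == 0):
        raise ValueError("cells with zero total UMIs; run filter_cells first")
    X = sp.csr_matrix(data.X, dtype=np.float64)
    inv = scale / total
    X = sp.diags(inv) @ X
    X.data = np.log1p(X.data)
    out = data.copy()
    out.X = X
    return out


def _subset(data: ad.AnnData, cell_set) -> ad.AnnData:
    sub = data if cell_set is None else data[cell_set]
    if sub.n_obs == 0:
        raise ValueError("empty cell set")
    return sub


def pseudobulk_sum(data: ad.AnnData, cell_set=None, scale: float = 1e4) -> pd.Series:
    """Sum-variant pseudo-bulk of raw counts.

    Per gene g: ln(1 + scale * sum_cells count_g / sum_cells total), i.e. the
    cells' count vectors are summed, normalized by the pooled library size,
    scaled, and shifted by one before the natural log so every entry is
    positive-logged (>= 0).
    """
    sub = _subset(data, cell_set)
    counts = np.asarray(sp.csr_matrix(sub.X).sum(axis=0)).ravel()
    total = counts.sum()
    if total == 0:
        raise ValueError("cell set has zero total UMIs")
    return pd.Series(np.log1p(scale * counts / total), index=sub.var_names)


def pseudobulk_mean(data: ad.AnnData, cell_set=None) -> pd.Series:
    """Mean-variant pseudo-bulk: per-gene mean of raw counts across the set."""
    sub = _subset(data, cell_set)
    return pd.Series(
        np.asarray(sp.csr_matrix(sub.X).mean(axis=0)).ravel(), index=sub.var_names
    )
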
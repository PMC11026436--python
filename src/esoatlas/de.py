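"""Covariate-adjusted differential expression with an ambient-RNA filter.

Per cell type, group membership (e.g. active vs healthy cells) is modeled by
logistic regression on each gene's log-normalized expression plus nuisance
covariates (log2 detected genes per cell, steroid treatment, biopsy region,
10x chemistry); the gene term is assessed by a two-tailed likelihood-ratio
test. Upregulated hits are then screened against ambient-RNA artifacts: a
gene truly induced in a cell type should be up in most individual samples of
the focal condition, whereas a gene that merely leaks in from the ambient
pool of another abundant cell type tracks that pool and is typically *down*
per sample — such majority-downregulated genes are flagged for removal.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .qc import lognorm

__all__ = ["de_logistic", "ambient_filter", "lfc_concordance"]

LOG2FC_PSEUDOCOUNT = 1e-9
SIGNIFICANT_ADJ_P = 1e-3
SIGNIFICANT_FOLD = 1.5


def _covariate_matrix(
    data: ad.AnnData, samples: pd.DataFrame, covariates
) -> np.ndarray:
    cols = []
    detected = np.asarray((sp.csr_matrix(data.X) > 0).sum(axis=1)).ravel()
    cols.append(np.log2(np.maximum(detected, 1)))
    per_cell = samples.reindex(data.obs["sample_id"])
    for cov in covariates:
        v = per_cell[cov]
        if v.dtype == bool or np.issubdtype(v.dtype, np.number):
            cols.append(v.to_numpy(dtype=float))
        else:
            levels = sorted(v.astype(str).unique())
            for lev in levels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(dtype=float))
    Z = np.column_stack(cols)
    keep = np.array([len(np.unique(Z[:, j])) > 1 for j in range(Z.shape[1])])
    return Z[:, keep]


def de_logistic(
    data: ad.AnnData,
    samples: pd.DataFrame,
    cell_type: str | None,
    group_a: str,
    group_b: str,
    group_key: str = "condition",
    covariates=("steroid", "region", "chemistry"),
    min_cells: int = 20,
    min_expressing_fraction: float = 0.10,
    is_lognorm: bool = False,
) -> pd.DataFrame:
    """Logistic-regression differential expression of group A vs group B.

    Per tested gene, the likelihood-ratio test compares a logistic model of
    group membership on expression + covariates against the covariate-only
    null (two-tailed chi-square, 1 df). Both Bonferroni- and BH-adjusted
    p-values are reported. log2 fold change is the ratio of group means of
    expm1(lognorm) with a small pseudocount. A gene is called ``significant``
    at adjusted (Bonferroni) p < 0.001 and fold change > 1.5. Genes are
    prefiltered to those expressed in >= ``min_expressing_fraction`` of
    either group.
    """
    if cell_type is not None:
        data = data[np.asarray(data.obs["cell_type"] == cell_type)]
    cond = samples.reindex(data.obs["sample_id"])[group_key].to_numpy()
    in_a, in_b = cond == group_a, cond == group_b
    if in_a.sum() < min_cells or in_b.sum() < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per group "
            f"(got {int(in_a.sum())} vs {int(in_b.sum())})"
        )
    sub = data[in_a | in_b].copy()
    y = (samples.reindex(sub.obs["sample_id"])[group_key] == group_a).to_numpy(float)

    raw = sub if not is_lognorm else None
    ln = sub if is_lognorm else lognorm(sub)
    Xe = sp.csr_matrix(ln.X)
    expressed = np.asarray((Xe > 0).todense())
    frac_a = expressed[y == 1].mean(axis=0)
    frac_b = expressed[y == 0].mean(axis=0)
    tested = (frac_a >= min_expressing_fraction) | (frac_b >= min_expressing_fraction)

    Z = _covariate_matrix(raw if raw is not None else sub, samples, covariates)
    Z = np.column_stack([np.ones(len(y)), Z])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_fit = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
    ll_null = null_fit.llf

    dense = np.asarray(Xe.todense())
    mean_expm1_a = np.expm1(dense[y == 1]).mean(axis=0)
    mean_expm1_b = np.expm1(dense[y == 0]).mean(axis=0)
    log2fc = np.log2(
        (mean_expm1_a + LOG2FC_PSEUDOCOUNT) / (mean_expm1_b + LOG2FC_PSEUDOCOUNT)
    )

    rows = []
    for j in np.flatnonzero(tested):
        Xj = np.column_stack([Z, dense[:, j]])
        flag = ""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.GLM(y, Xj, family=sm.families.Binomial()).fit(maxiter=100)
                if not np.all(np.isfinite(fit.bse)):
                    flag = "separation"
                ll_alt = fit.llf
            except Exception:
                try:  # ridge-stabilized refit
                    fit = sm.GLM(y, Xj, family=sm.families.Binomial()).fit_regularized(
                        alpha=1e-4, L1_wt=0.0
                    )
                    mu = 1 / (1 + np.exp(-(Xj @ fit.params)))
                    mu = np.clip(mu, 1e-12, 1 - 1e-12)
                    ll_alt = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
                    flag = "ridge"
                except Exception:
                    ll_alt, flag = np.nan, "failed"
        if np.isnan(ll_alt):
            p = np.nan
        else:
            lrt = max(2.0 * (ll_alt - ll_null), 0.0)
            p = st.chi2.sf(lrt, df=1)
        rows.append(
            {
                "gene": ln.var_names[j],
                "log2fc": log2fc[j],
                "p": p,
                "frac_a": frac_a[j],
                "frac_b": frac_b[j],
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    m = out["p"].notna()
    out["p_bonferroni"] = np.nan
    out.loc[m, "p_bonferroni"] = np.minimum(out.loc[m, "p"] * m.sum(), 1.0)
    out["p_bh"] = np.nan
    out.loc[m, "p_bh"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    out["significant"] = (out["p_bonferroni"] < SIGNIFICANT_ADJ_P) & (
        np.abs(out["log2fc"]) > np.log2(SIGNIFICANT_FOLD)
    )
    out["ambient_filtered"] = False
    out.attrs["group_a"], out.attrs["group_b"] = group_a, group_b
    out.attrs["cell_type"] = cell_type
    return out


def ambient_filter(
    de: pd.DataFrame,
    data: ad.AnnData,
    samples: pd.DataFrame,
    cell_type: str | None,
    focal_condition: str | None = None,
    comparison_condition: str | None = None,
    group_key: str = "condition",
    majority: float = 0.5,
    is_lognorm: bool = False,
) -> pd.DataFrame:
    """Flag upregulated genes that are downregulated in most focal samples.

    For each gene upregulated overall (log2fc > 0), compute per focal-
    condition sample s the sign of mean(lognorm in type-c cells of s) minus
    mean(lognorm in all comparison-condition type-c cells pooled). If
    strictly more than ``majority * M`` of the M focal samples are negative,
    the gene is flagged ``ambient_filtered`` — the hallmark of an ambient-RNA
    artifact. Samples with zero type-c cells are excluded from M with a
    warning. Ties (exactly the threshold) retain the gene.
    """
    focal_condition = focal_condition or de.attrs.get("group_a")
    comparison_condition = comparison_condition or de.attrs.get("group_b")
    if cell_type is not None:
        data = data[np.asarray(data.obs["cell_type"] == cell_type)]
    ln = data if is_lognorm else lognorm(data)
    cond = samples.reindex(ln.obs["sample_id"])[group_key].to_numpy()
    dense = np.asarray(sp.csr_matrix(ln.X).todense())
    genes = list(ln.var_names)
    gi = {g: i for i, g in enumerate(genes)}

    comp_cells = cond == comparison_condition
    if comp_cells.sum() == 0:
        raise ValueError(f"no cells in comparison condition {comparison_condition!r}")
    baseline = dense[comp_cells].mean(axis=0)

    focal_samples = [
        s for s in samples.index[samples[group_key] == focal_condition]
        if (ln.obs["sample_id"] == s).any()
    ]
    skipped = set(samples.index[samples[group_key] == focal_condition]) - set(focal_samples)
    if skipped:
        warnings.warn(
            f"focal samples with zero {cell_type!r} cells excluded: {sorted(skipped)}"
        )
    M = len(focal_samples)
    if M == 0:
        raise ValueError("no focal samples with cells of this type")

    out = de.copy()
    out["n_focal_samples"] = M
    out["n_down_samples"] = 0
    for g in out.index:
        if g not in gi or out.loc[g, "log2fc"] <= 0:
            continue
        j = gi[g]
        n_down = 0
        for s in focal_samples:
            cells_s = (ln.obs["sample_id"] == s).to_numpy()
            if dense[cells_s, j].mean() - baseline[j] < 0:
                n_down += 1
        out.loc[g, "n_down_samples"] = n_down
        if n_down > majority * M:
            out.loc[g, "ambient_filtered"] = True
    out.loc[out["ambient_filtered"], "significant"] = False
    return out


def lfc_concordance(
    de_ab: pd.DataFrame, de_cd: pd.DataFrame, min_shared: int = 3
) -> dict:
    """Concordance of log2 fold changes between two comparisons.

    Matches genes significant in either table, and reports Pearson R, the
    regression slope with its two-tailed p, and overlap fractions (what
    share of one comparison's significant genes is also significant, with
    the same sign, in the other).
    """
    sig_ab = set(de_ab.index[de_ab["significant"]])
    sig_cd = set(de_cd.index[de_cd["significant"]])
    union = sorted((sig_ab | sig_cd) & set(de_ab.index) & set(de_cd.index))
    if len(union) < min_shared:
        warnings.warn(f"only {len(union)} shared genes; concordance undefined")
        return {"n": len(union), "pearson_r": np.nan, "slope": np.nan, "p": np.nan,
                "overlap_ab_in_cd": np.nan, "overlap_cd_in_ab": np.nan}
    x = de_ab.loc[union, "log2fc"].to_numpy()
    y = de_cd.loc[union, "log2fc"].to_numpy()
    r, _ = st.pearsonr(x, y)
    lr = st.linregress(x, y)

    def _same_call(g):
        return (
            g in sig_ab and g in sig_cd
            and np.sign(de_ab.loc[g, "log2fc"]) == np.sign(de_cd.loc[g, "log2fc"])
        )

    both = [g for g in union if _same_call(g)]
    return {
        "n": len(union),
        "pearson_r": r,
        "slope": lr.slope,
        "p": lr.pvalue,
        "overlap_ab_in_cd": len(both) / len(sig_ab) if sig_ab else np.nan,
        "overlap_cd_in_ab": len(both) / len(sig_cd) if sig_cd else np.nan,
    }
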
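"""Cell-composition statistics for multi-sample single-cell atlases.

The sample x cell-type count table is the substrate for every analysis here:

* negative-binomial differential abundance with a log-total-cells offset and
  clinical covariates (condition, chemistry, steroid treatment, region);
* centered log-ratio (CLR) transform and PCA of compositions;
* a quantile-normalized rank-regression alternative to the NB model;
* multi-term sequential PERMANOVA on Euclidean distances;
* Spearman correlation of per-type abundance with a clinical activity score
  (eosinophils/HPF, EREFS);
* pairwise proportion-correlation hierarchical clustering (WPGMA/Mcquitty);
* Fisher exact tests of subset membership x condition;
* Lasso selection of composition features predicting a target cell fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.linear_model import Lasso
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CompositionTable",
    "composition_table",
    "nb_abundance",
    "clr_transform",
    "composition_pca",
    "quantile_normalize",
    "quantile_rank_regression",
    "permanova",
    "activity_correlation",
    "proportion_correlation_clusters",
    "condition_proportion_fisher",
    "fisher_tests",
    "lasso_fraction_predictor",
]

DEFAULT_COVARIATES = ("condition", "chemistry", "steroid", "region")


@dataclass
class CompositionTable:
    """Sample x cell-type cell counts plus per-sample covariates."""

    counts: pd.DataFrame  # samples x cell types, nonnegative integers
    samples: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative cell counts")
        missing = set(self.counts.index) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without covariates: {sorted(missing)}")
        self.samples = self.samples.loc[self.counts.index]

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)


def composition_table(obs: pd.DataFrame, samples: pd.DataFrame) -> CompositionTable:
    """Tabulate per-sample cell-type counts from per-cell metadata."""
    counts = (
        obs.groupby(["sample_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(samples.index, fill_value=0)
    )
    counts.columns.name = None
    return CompositionTable(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _design_matrix(
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    condition_reference: str = "healthy",
) -> pd.DataFrame:
    """Treatment-coded design with intercept; constant columns dropped."""
    cols = {}
    for cov in covariates:
        if cov not in samples.columns:
            warnings.warn(f"covariate {cov!r} absent from sample table; skipped")
            continue
        v = samples[cov]
        if v.dtype == bool or np.issubdtype(v.dtype, np.number):
            cols[cov] = v.astype(float)
        else:
            levels = sorted(v.astype(str).unique())
            if cov == "condition" and condition_reference in levels:
                levels = [condition_reference] + [
                    l for l in levels if l != condition_reference
                ]
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (v.astype(str) == lev).astype(float)
    X = pd.DataFrame(cols, index=samples.index)
    const = X.columns[X.nunique() <= 1]
    if len(const):
        warnings.warn(f"dropping constant design columns: {list(const)}")
        X = X.drop(columns=const)
    X.insert(0, "Intercept", 1.0)
    # drop linearly dependent columns (keep earliest), e.g. confounded covariates
    keep, dropped = [0], []
    for j in range(1, X.shape[1]):
        trial = X.iloc[:, keep + [j]].to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
        else:
            dropped.append(X.columns[j])
    if dropped:
        warnings.warn(f"dropping collinear design columns: {dropped}")
        X = X.iloc[:, keep]
    return X


# ---------------------------------------------------------------------------
# negative-binomial differential abundance
# ---------------------------------------------------------------------------

def nb_abundance(
    comp: CompositionTable,
    covariates=DEFAULT_COVARIATES,
    condition_reference: str = "healthy",
    contrast: str = "active",
) -> pd.DataFrame:
    """Per-cell-type NB regression of counts with a log-total-cells offset.

    Fits ``y[s, c] ~ NB(mu, theta)`` with ``log mu = X beta + log N_s`` by
    maximum likelihood (dispersion estimated jointly), falling back to a
    Poisson GLM when the NB fit does not converge or the dispersion
    degenerates. Reports the Wald test for the ``contrast`` condition level
    versus ``condition_reference`` and BH FDR across cell types. Remission
    (and any other non-reference) contrasts are included as extra columns.
    """
    X = _design_matrix(comp.samples, covariates, condition_reference)
    term = f"condition[{contrast}]"
    if term not in X.columns:
        raise ValueError(f"contrast level {contrast!r} not in design")
    offset = np.log(comp.totals.to_numpy(dtype=float))
    # Wald statistics referred to a t distribution on residual df rather than
    # the normal: with a few dozen samples the plug-in SE makes the normal
    # reference liberal, and the t reference restores near-nominal size.
    df_resid = len(comp.counts) - X.shape[1]
    if df_resid < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    rows = []
    for ct in comp.counts.columns:
        y = comp.counts[ct].to_numpy(dtype=float)
        if y.sum() == 0:
            warnings.warn(f"cell type {ct!r} has zero counts everywhere; excluded")
            continue
        res, model_used, converged = _fit_nb(y, X, offset)
        beta = res.params[X.columns.get_loc(term)]
        se = res.bse[X.columns.get_loc(term)]
        wald = beta / se if se > 0 else np.nan
        p = 2 * st.t.sf(abs(wald), df=df_resid)
        tcrit = st.t.ppf(0.975, df=df_resid)
        row = {
            "cell_type": ct,
            "beta": beta,
            "se": se,
            "wald": wald,
            "p": p,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "model": model_used,
            "converged": converged,
            "theta": _theta_of(res, model_used),
        }
        for col in X.columns:
            if col.startswith("condition[") and col != term:
                j = X.columns.get_loc(col)
                row[f"beta_{col}"] = res.params[j]
                row[f"p_{col}"] = 2 * st.t.sf(
                    abs(res.params[j] / res.bse[j]), df=df_resid
                )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("cell_type")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significance"] = pd.cut(
        out["fdr"], [-np.inf, 0.001, 0.01, 0.05, np.inf],
        labels=["***", "**", "*", ""],
    ).astype(str)
    return out


def _fit_nb(y: np.ndarray, X: pd.DataFrame, offset: np.ndarray):
    """NB2 regression with Cox-Reid adjusted profile-likelihood dispersion.

    The plain dispersion MLE is biased downward with a few dozen samples,
    making Wald tests liberal; the Cox-Reid adjustment (profile likelihood
    penalized by half the log-determinant of the weighted information, as in
    edgeR) restores near-nominal size. Falls back to a Poisson GLM when the
    NB fit fails or the dispersion pins at (effectively) zero.
    Returns (result, model_name, converged).
    """
    Xn = X.to_numpy()

    def neg_apl(log_alpha: float) -> float:
        alpha = np.exp(log_alpha)
        try:
            fam = sm.families.NegativeBinomial(alpha=alpha)
            res = sm.GLM(y, Xn, family=fam, offset=offset).fit()
            mu = res.fittedvalues
            ll = np.sum(st.nbinom.logpmf(y, 1.0 / alpha, 1.0 / (1.0 + alpha * mu)))
            W = mu / (1.0 + alpha * mu)
            _, logdet = np.linalg.slogdet(Xn.T @ (W[:, None] * Xn))
            return -(ll - 0.5 * logdet)
        except Exception:
            return np.inf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            opt = _minimize_scalar_bounded(neg_apl, np.log(1e-6), np.log(50.0))
            alpha = float(np.exp(opt))
            if np.isfinite(neg_apl(np.log(alpha))) and alpha > 2e-6:
                res = sm.GLM(
                    y, Xn, family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit()
                if np.all(np.isfinite(res.bse)):
                    res.alpha = alpha
                    return res, "negative_binomial", True
        except Exception:
            pass
        res = sm.GLM(y, Xn, family=sm.families.Poisson(), offset=offset).fit()
    return res, "poisson", True


def _minimize_scalar_bounded(fun, lo: float, hi: float) -> float:
    from scipy.optimize import minimize_scalar

    opt = minimize_scalar(
        fun, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
    )
    return float(opt.x)


def _theta_of(res, model_used: str) -> float:
    if model_used == "negative_binomial":
        return 1.0 / res.alpha  # size parameter: Var = mu + mu^2 / theta
    return np.inf


# ---------------------------------------------------------------------------
# CLR + PCA
# ---------------------------------------------------------------------------

def clr_transform(
    counts: pd.DataFrame | CompositionTable, zero_replace: float = 0.5
) -> pd.DataFrame:
    """Centered log-ratio transform of sample x cell-type counts.

    Zero counts are imputed with ``zero_replace`` (half-count multiplicative
    replacement by default), rows are closed to proportions, and each entry
    becomes ln(p) minus the row mean of ln(p); rows therefore sum to zero and
    the transform is invariant to scaling a sample's counts.
    """
    if isinstance(counts, CompositionTable):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    if np.any(y.sum(axis=1) == 0):
        raise ValueError("sample with all-zero counts")
    y = np.where(y == 0, zero_replace, y)
    p = y / y.sum(axis=1, keepdims=True)
    logp = np.log(p)
    clr = logp - logp.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # cell types x PCs
    explained_variance_ratio: np.ndarray


def composition_pca(clr: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Centered PCA of a CLR matrix with a fixed sign convention.

    Each component is oriented so that its largest-|loading| cell type has a
    positive loading, making scores reproducible across SVD implementations.
    """
    X = clr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    nz = int((s > s.max() * 1e-12).sum()) if s.size and s.max() > 0 else 0
    k = nz if n_components is None else min(n_components, nz)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for j in range(k):  # sign convention
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    evr = (s ** 2) / (Xc ** 2).sum() if (Xc ** 2).sum() > 0 else np.zeros(k)
    scores = pd.DataFrame(
        U * s, index=clr.index, columns=[f"PC{j + 1}" for j in range(k)]
    )
    if k == 0:
        scores = pd.DataFrame(
            np.zeros((len(clr), 1)), index=clr.index, columns=["PC1"]
        )
        loadings = pd.DataFrame(
            np.zeros((clr.shape[1], 1)), index=clr.columns, columns=["PC1"]
        )
        return PCAResult(scores, loadings, np.zeros(1))
    loadings = pd.DataFrame(
        Vt.T, index=clr.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return PCAResult(scores, loadings, evr)


# ---------------------------------------------------------------------------
# quantile-normalized rank regression
# ---------------------------------------------------------------------------

def quantile_normalize(props: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize each cell type's across-sample proportion vector.

    The common reference distribution is the mean of the order statistics
    across cell types; tied proportions receive the mean of the reference
    values their (average) ranks span, so every column has an identical
    multiset of values afterwards (up to ties).
    """
    X = props.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = st.rankdata(X[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=props.index, columns=props.columns)


def quantile_rank_regression(
    comp: CompositionTable,
    covariates=DEFAULT_COVARIATES,
    condition_reference: str = "healthy",
    contrast: str = "active",
) -> pd.DataFrame:
    """OLS of quantile-normalized cell-type proportions on covariates.

    A rank-based alternative to :func:`nb_abundance`: proportions are
    quantile-normalized across samples (so all cell types share one value
    distribution), then each cell type's normalized values are regressed on
    the covariates and the contrast coefficient is tested with a two-tailed
    t-test; BH FDR across cell types.
    """
    X = _design_matrix(comp.samples, covariates, condition_reference)
    term = f"condition[{contrast}]"
    if term not in X.columns:
        raise ValueError(f"contrast level {contrast!r} not in design")
    qn = quantile_normalize(comp.proportions)
    rows = []
    for ct in qn.columns:
        res = sm.OLS(qn[ct].to_numpy(), X.to_numpy()).fit()
        j = X.columns.get_loc(term)
        rows.append(
            {
                "cell_type": ct,
                "beta": res.params[j],
                "se": res.bse[j],
                "t": res.tvalues[j],
                "p": res.pvalues[j],
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(
    comp: CompositionTable,
    terms=("condition",),
    n_perm: int = 9999,
    seed: int = 0,
    quantile_norm: bool = True,
) -> pd.DataFrame:
    """Sequential (Type I) multi-term PERMANOVA on Euclidean distances.

    Samples are represented by their (optionally quantile-normalized)
    cell-type proportions; the Euclidean distance matrix is Gower-centered
    and its total sum of squares partitioned sequentially over the model
    terms via projection (hat) matrices, exactly as in distance-based
    redundancy analysis. Per term, pseudo-F is tested by permuting samples,
    with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    props = comp.proportions
    data = quantile_normalize(props) if quantile_norm else props
    Y = data.to_numpy(dtype=float)
    n = Y.shape[0]

    kept_terms = []
    for t in terms:
        v = comp.samples[t]
        if v.nunique() <= 1:
            warnings.warn(f"term {t!r} has a single level; dropped")
        else:
            kept_terms.append(t)
    if not kept_terms:
        raise ValueError("no term with >= 2 levels")

    D2 = ssd.squareform(ssd.pdist(Y, metric="euclidean")) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J

    # cumulative hat matrices (with intercept)
    hats, dfs = [], []
    X_cum = np.ones((n, 1))
    rank_prev = 1
    for t in kept_terms:
        Xt = _design_matrix(comp.samples, (t,)).drop(columns="Intercept").to_numpy()
        X_cum = np.hstack([X_cum, Xt])
        Q, _ = np.linalg.qr(X_cum)
        rank = np.linalg.matrix_rank(X_cum)
        H = Q[:, :rank] @ Q[:, :rank].T
        hats.append(H)
        dfs.append(rank - rank_prev)
        rank_prev = rank
    H_full = hats[-1]
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def f_stats(Gm: np.ndarray) -> np.ndarray:
        ss_res = np.trace((np.eye(n) - H_full) @ Gm)
        ss_prev = np.trace(np.ones((n, n)) / n @ Gm)  # == 0 after centering
        out = np.empty(len(hats))
        prev = ss_prev
        for k, H in enumerate(hats):
            ss_k = np.trace(H @ Gm) - prev
            prev = np.trace(H @ Gm)
            out[k] = (ss_k / dfs[k]) / (ss_res / df_res)
        return out

    F_obs = f_stats(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += f_stats(G[np.ix_(perm, perm)]) >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    ss_total = np.trace(G)
    ss_terms, prev = [], 0.0
    for H in hats:
        cur = np.trace(H @ G)
        ss_terms.append(cur - prev)
        prev = cur
    return pd.DataFrame(
        {
            "term": kept_terms,
            "df": dfs,
            "ss": ss_terms,
            "r2": np.array(ss_terms) / ss_total,
            "pseudo_F": F_obs,
            "p": pvals,
        }
    ).set_index("term")


# ---------------------------------------------------------------------------
# activity correlation
# ---------------------------------------------------------------------------

def activity_correlation(
    comp: CompositionTable,
    activity: str | pd.Series = "eos_per_hpf",
    use_proportions: bool = False,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Spearman correlation of per-type cell numbers with a disease-activity
    scalar (eosinophils/HPF or EREFS), with the t-based two-tailed p-value
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 df, and BH FDR.
    """
    a = comp.samples[activity] if isinstance(activity, str) else activity
    a = pd.Series(a).reindex(comp.counts.index).astype(float)
    mask = a.notna()
    if mask.sum() < 4:
        raise ValueError("need >= 4 samples with non-missing activity")
    a = a[mask]
    if a.nunique() == 1:
        raise ValueError("activity vector is constant; Spearman undefined")
    mat = comp.proportions if use_proportions else comp.counts
    mat = mat.loc[a.index]
    n = len(a)
    rows = []
    for ct in mat.columns:
        rho = st.spearmanr(mat[ct], a).statistic
        if np.isclose(abs(rho), 1.0):
            t, p = np.inf * np.sign(rho), 0.0
        elif np.isnan(rho):
            t, p = np.nan, 1.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = 2 * st.t.sf(abs(t), df=n - 2)
        rows.append({"cell_type": ct, "rho": rho, "t": t, "p": p})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["reported"] = out["fdr"] < fdr_threshold
    return out


# ---------------------------------------------------------------------------
# proportion-correlation clustering
# ---------------------------------------------------------------------------

@dataclass
class CorrelationClustering:
    correlation: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def proportion_correlation_clusters(comp: CompositionTable) -> CorrelationClustering:
    """Pearson correlation of cell-type proportions across samples, clustered
    hierarchically with the Mcquitty (WPGMA) linkage on distance 1 - r."""
    if len(comp.counts) < 3:
        raise ValueError("need >= 3 samples")
    props = comp.proportions
    sd = props.std(axis=0)
    excluded = list(props.columns[sd == 0])
    if excluded:
        warnings.warn(f"zero-variance cell types excluded: {excluded}")
    props = props.drop(columns=excluded)
    corr = props.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="weighted")
    order = [corr.columns[i] for i in sch.leaves_list(Z)]
    return CorrelationClustering(corr, Z, order, excluded)


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------

def condition_proportion_fisher(table: np.ndarray) -> tuple[float, float, bool]:
    """Two-tailed Fisher exact test of a 2x2 membership x condition table.

    Returns (odds_ratio, p, degenerate); an empty margin yields p = 1 by
    convention with the degenerate flag raised.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return np.nan, 1.0, True
    odds, p = st.fisher_exact(t, alternative="two-sided")
    return odds, p, False


def fisher_tests(tables: dict[str, np.ndarray]) -> pd.DataFrame:
    """Vectorized :func:`condition_proportion_fisher` with BH FDR across subsets."""
    rows = []
    for name, t in tables.items():
        odds, p, flag = condition_proportion_fisher(t)
        rows.append({"subset": name, "odds_ratio": odds, "p": p, "degenerate": flag})
    out = pd.DataFrame(rows).set_index("subset")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Lasso feature selection
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    alpha: float
    coefficients: pd.Series  # nonzero only
    intercept: float
    loocv_predictions: pd.Series
    slope: float
    slope_p: float
    r2: float


def lasso_fraction_predictor(
    target: pd.Series,
    features: pd.DataFrame,
    alphas: np.ndarray | None = None,
) -> LassoFit:
    """L1-regularized regression of a per-sample cell fraction on cell-type
    composition features, with leave-one-out CV for the penalty.

    Features are column-standardized; the penalty grid is log-spaced; the
    penalty minimizing LOOCV squared error is refit on all samples. Reported:
    nonzero coefficients (on the standardized scale), LOOCV predictions at
    the chosen penalty, and the slope t-test of observed ~ predicted.
    """
    y = target.to_numpy(dtype=float)
    if len(y) < 5:
        raise ValueError("need >= 5 samples")
    if np.allclose(y, 0):
        raise ValueError("all-zero target")
    X = features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if alphas is None:
        amax = np.abs(Xs.T @ (y - y.mean())).max() / len(y)
        alphas = np.logspace(np.log10(max(amax, 1e-8)), np.log10(max(amax, 1e-8)) - 4, 40)

    n = len(y)
    cv_err = np.zeros(len(alphas))
    preds = np.zeros((len(alphas), n))
    for i in range(n):
        tr = np.arange(n) != i
        for a_i, a in enumerate(alphas):
            m = Lasso(alpha=a, max_iter=50_000)
            m.fit(Xs[tr], y[tr])
            preds[a_i, i] = m.predict(Xs[i][None, :])[0]
    cv_err = ((preds - y[None, :]) ** 2).mean(axis=1)
    best = int(np.argmin(cv_err))
    alpha = float(alphas[best])
    final = Lasso(alpha=alpha, max_iter=50_000).fit(Xs, y)
    coefs = pd.Series(final.coef_, index=features.columns)
    loocv = pd.Series(preds[best], index=target.index)
    if np.std(preds[best]) == 0:
        slope, slope_p, r2 = np.nan, 1.0, 0.0
    else:
        lr = st.linregress(preds[best], y)
        slope, slope_p, r2 = lr.slope, lr.pvalue, lr.rvalue ** 2
    return LassoFit(
        alpha=alpha,
        coefficients=coefs[coefs.abs() > 1e-10],
        intercept=float(final.intercept_),
        loocv_predictions=loocv,
        slope=slope,
        slope_p=slope_p,
        r2=r2,
    )
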
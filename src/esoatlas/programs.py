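"""Gene signatures, NMF expression programs, and risk-gene modules.

Signature scoring follows the binned-control scheme: genes are binned by
dataset-average expression, each signature gene draws control genes from its
bin, and a cell's score is its mean signature expression minus its mean
control expression — removing depth and overall-expression effects. NMF
discovers additive gene programs within a cell family (e.g. macrophages).
The risk-gene screen keeps genes detected in at least 25% of cells of some
subset; modules are then found by Ward.D2 clustering of square-root
mean-pseudo-bulk profiles across subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
import scipy.stats as st
from sklearn.decomposition import NMF

from .qc import pseudobulk_mean

__all__ = [
    "GeneSignature",
    "score_signature",
    "ProgramDecomposition",
    "nmf_programs",
    "expressed_gene_screen",
    "risk_modules",
    "signature_correlation",
]


@dataclass
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty signature")
        seen, dedup = set(), []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                dedup.append(g)
        self.genes = tuple(dedup)


def score_signature(
    data: ad.AnnData,
    signature: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control signature score per cell on log-normalized data.

    Genes are ranked by their dataset-average expression and cut into
    ``n_bins`` equal-size bins; for each signature gene, ``n_ctrl`` control
    genes are sampled (with replacement if the bin is smaller) from its bin.
    Score = mean(signature expression) - mean(control expression) per cell.
    Reproducible from ``seed``. Shift-invariant: adding a constant to all
    values leaves scores unchanged.
    """
    if data.n_vars < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} bins")
    present = [g for g in signature.genes if g in set(data.var_names)]
    if not present:
        raise ValueError(f"signature {signature.name!r} entirely absent from matrix")
    X = np.asarray(sp.csr_matrix(data.X).todense())
    gene_mean = X.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(data.n_vars, dtype=int)
    bin_of[order] = np.floor(
        np.arange(data.n_vars) * n_bins / data.n_vars
    ).astype(int)
    gi = {g: i for i, g in enumerate(data.var_names)}
    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for g in present:
        b = bin_of[gi[g]]
        pool = np.flatnonzero(bin_of == b)
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl))
    ctrl_idx = np.unique(np.concatenate(ctrl_idx))
    sig_idx = np.array([gi[g] for g in present])
    scores = X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(scores, index=data.obs_names, name=signature.name)


@dataclass
class ProgramDecomposition:
    gene_loadings: pd.DataFrame  # genes x programs, >= 0
    cell_scores: pd.DataFrame  # cells x programs, >= 0
    rank: int
    reconstruction_error: float

    def top_genes(self, program: int, n: int = 10) -> list[str]:
        col = self.gene_loadings.iloc[:, program]
        return list(col.sort_values(ascending=False).index[:n])


def nmf_programs(
    data: ad.AnnData, rank: int, seed: int = 0, max_iter: int = 500
) -> ProgramDecomposition:
    """Non-negative matrix factorization of log-normalized profiles of one
    cell family into ``rank`` additive gene programs.

    Coordinate-descent NMF from a seeded random initialization; the per-cell
    program score is the cell's coefficient on that program.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    X = np.asarray(sp.csr_matrix(data.X).todense())
    if rank > min(X.shape):
        raise ValueError(f"rank {rank} exceeds matrix dimensions {X.shape}")
    if (X < 0).any():
        raise ValueError("NMF requires nonnegative input")
    model = NMF(
        n_components=rank, init="random", random_state=seed, max_iter=max_iter
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(X)  # cells x rank
    H = model.components_  # rank x genes
    cols = [f"program{j + 1}" for j in range(rank)]
    return ProgramDecomposition(
        gene_loadings=pd.DataFrame(H.T, index=data.var_names, columns=cols),
        cell_scores=pd.DataFrame(W, index=data.obs_names, columns=cols),
        rank=rank,
        reconstruction_error=float(model.reconstruction_err_),
    )


def rank_sweep(
    data: ad.AnnData, ranks, seed: int = 0, max_iter: int = 300
) -> pd.DataFrame:
    """Reconstruction error per candidate rank (elbow report)."""
    rows = [
        {"rank": r, "reconstruction_error": nmf_programs(
            data, r, seed=seed, max_iter=max_iter).reconstruction_error}
        for r in ranks
    ]
    return pd.DataFrame(rows).set_index("rank")


def expressed_gene_screen(
    data: ad.AnnData,
    genes,
    threshold: float = 0.25,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Fraction of cells with count > 0 per (gene, subset); pass iff >= threshold."""
    labels = data.obs["cell_type"] if labels is None else labels
    labels = pd.Series(np.asarray(labels, dtype=object), index=data.obs_names)
    present = [g for g in genes if g in set(data.var_names)]
    absent = [g for g in genes if g not in set(data.var_names)]
    X = sp.csr_matrix(data.X)
    gi = {g: i for i, g in enumerate(data.var_names)}
    subsets = sorted(labels.unique())
    rows = []
    for g in present:
        col = np.asarray((X[:, gi[g]] > 0).todense()).ravel()
        for s in subsets:
            frac = float(col[(labels == s).to_numpy()].mean())
            rows.append({"gene": g, "subset": s, "fraction": frac,
                         "passes": frac >= threshold})
    for g in absent:
        for s in subsets:
            rows.append({"gene": g, "subset": s, "fraction": 0.0, "passes": False})
    return pd.DataFrame(rows)


@dataclass
class RiskModules:
    linkage: np.ndarray
    modules: pd.Series  # gene -> module label
    profiles: pd.DataFrame  # genes x subsets, sqrt mean pseudo-bulk
    genes: list[str]


def risk_modules(
    data: ad.AnnData,
    genes,
    labels: pd.Series | None = None,
    screen_threshold: float = 0.25,
    n_modules: int | None = None,
    height_fraction: float = 0.5,
) -> RiskModules:
    """Risk-gene modules from subset-specific expression profiles.

    Genes passing the >= ``screen_threshold`` expressing-fraction screen in
    at least one subset are profiled by mean-variant pseudo-bulk per subset,
    square-root transformed, and clustered with Ward.D2 on Euclidean
    distances. Modules come from cutting the tree into ``n_modules`` (if
    given) or at ``height_fraction`` of the maximum merge height. Output is
    invariant to the order genes are supplied in.
    """
    labels = data.obs["cell_type"] if labels is None else labels
    labels = pd.Series(np.asarray(labels, dtype=object), index=data.obs_names)
    screen = expressed_gene_screen(data, genes, screen_threshold, labels)
    passing = sorted(screen.loc[screen["passes"], "gene"].unique())
    if len(passing) < 1:
        raise ValueError("no genes pass the expressing-fraction screen")
    subsets = sorted(labels.unique())
    prof = pd.DataFrame(index=passing, columns=subsets, dtype=float)
    for s in subsets:
        pb = pseudobulk_mean(data, (labels == s).to_numpy())
        prof[s] = pb.reindex(passing).to_numpy()
    prof = np.sqrt(prof)
    if len(passing) == 1:
        return RiskModules(
            linkage=np.zeros((0, 4)),
            modules=pd.Series({passing[0]: 1}),
            profiles=prof,
            genes=passing,
        )
    if (prof.std(axis=1) == 0).any():
        warnings.warn("constant gene profiles present; they merge at height 0")
    Z = sch.linkage(prof.to_numpy(), method="ward")
    if n_modules is not None:
        assign = sch.fcluster(Z, t=n_modules, criterion="maxclust")
    else:
        cut = height_fraction * Z[:, 2].max()
        assign = sch.fcluster(Z, t=cut, criterion="distance")
    return RiskModules(
        linkage=Z,
        modules=pd.Series(assign, index=passing),
        profiles=prof,
        genes=passing,
    )


def signature_correlation(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Spearman correlation (average-rank ties) of paired per-sample summaries
    with the t-based two-tailed p-value; requires n >= 4 paired values."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 4:
        raise ValueError("need >= 4 paired samples")
    rho = st.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
    if np.isclose(abs(rho), 1.0):
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return float(rho), float(2 * st.t.sf(abs(t), df=n - 2))
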
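"""Reference-based cell annotation via supervised metric learning.

A labeled reference atlas is mapped to a low-dimensional latent space with
neighborhood component analysis (NCA, a supervised linear projection that
maximizes stochastic nearest-neighbor label agreement), and query cells are
projected with the *same* learned transform and classified by k-nearest
neighbors (k = 11 by default) in that space. The preprocessing recipe
(log normalization, gene selection, per-gene standardization statistics) is
frozen on the reference and re-applied unchanged to queries, so the mapping
is deterministic and leakage-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors
from sklearn.neighbors import NeighborhoodComponentsAnalysis

from .qc import lognorm

__all__ = ["LatentModel", "fit_latent", "classify_knn"]

DEFAULT_DIM = 50
DEFAULT_K = 11
DEFAULT_HVG = 2000
MIN_GENE_OVERLAP = 0.5


@dataclass
class LatentModel:
    """A fitted NCA projection plus its frozen preprocessing recipe."""

    projection: np.ndarray  # genes x dim
    genes: list[str]
    gene_mean: np.ndarray  # reference lognorm means (standardization)
    gene_sd: np.ndarray
    latent_reference: np.ndarray  # reference cells x dim
    reference_labels: np.ndarray
    dim: int
    converged: bool

    def preprocess(self, data: ad.AnnData, is_lognorm: bool = False) -> np.ndarray:
        """lognorm -> restrict to model genes -> standardize with REFERENCE stats."""
        overlap = [g for g in self.genes if g in set(data.var_names)]
        if len(overlap) < MIN_GENE_OVERLAP * len(self.genes):
            missing = sorted(set(self.genes) - set(data.var_names))
            raise ValueError(
                f"query shares only {len(overlap)}/{len(self.genes)} model genes "
                f"(< {MIN_GENE_OVERLAP:.0%}); missing e.g. {missing[:10]}"
            )
        ln = data if is_lognorm else lognorm(data)
        X = np.zeros((data.n_obs, len(self.genes)))
        idx = {g: i for i, g in enumerate(ln.var_names)}
        dense = np.asarray(sp.csr_matrix(ln.X).todense())
        for j, g in enumerate(self.genes):
            if g in idx:
                X[:, j] = dense[:, idx[g]]
        return (X - self.gene_mean) / self.gene_sd

    def project(self, data: ad.AnnData, is_lognorm: bool = False) -> np.ndarray:
        return self.preprocess(data, is_lognorm) @ self.projection

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            projection=self.projection,
            gene_mean=self.gene_mean,
            gene_sd=self.gene_sd,
            latent_reference=self.latent_reference,
            reference_labels=self.reference_labels.astype(str),
        )
        path.with_suffix(".json").write_text(
            json.dumps({"genes": self.genes, "dim": self.dim, "converged": self.converged})
        )

    @classmethod
    def load(cls, path: str | Path) -> "LatentModel":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"), allow_pickle=False)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            projection=arrs["projection"],
            genes=meta["genes"],
            gene_mean=arrs["gene_mean"],
            gene_sd=arrs["gene_sd"],
            latent_reference=arrs["latent_reference"],
            reference_labels=arrs["reference_labels"],
            dim=meta["dim"],
            converged=meta["converged"],
        )


def _select_hvg(X: np.ndarray, n_top: int) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes of a lognorm matrix."""
    var = X.var(axis=0)
    if n_top >= X.shape[1]:
        return np.arange(X.shape[1])
    return np.sort(np.argsort(-var)[:n_top])


def fit_latent(
    reference: ad.AnnData,
    labels: pd.Series | None = None,
    dim: int = DEFAULT_DIM,
    n_hvg: int | None = DEFAULT_HVG,
    max_cells_per_class: int | None = 150,
    max_iter: int = 200,
    seed: int = 0,
    is_lognorm: bool = False,
) -> LatentModel:
    """Fit the NCA latent space on a labeled reference.

    NCA is initialized from PCA with a fixed seed (deterministic) and
    optimized for at most ``max_iter`` iterations. For tractability the NCA
    objective is optimized on a per-class subsample of at most
    ``max_cells_per_class`` cells (the learned projection is then applied to
    everything); ``None`` disables subsampling. The latent model keeps the
    full reference embedding for kNN classification.
    """
    labels = reference.obs["cell_type"] if labels is None else labels
    labels = np.asarray(labels, dtype=object)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 reference labels")
    ln = reference if is_lognorm else lognorm(reference)
    dense = np.asarray(sp.csr_matrix(ln.X).todense())
    hvg_idx = _select_hvg(dense, n_hvg) if n_hvg else np.arange(dense.shape[1])
    genes = [ln.var_names[i] for i in hvg_idx]
    if dim > len(genes):
        raise ValueError(f"dim={dim} exceeds the {len(genes)} selected genes")
    X = dense[:, hvg_idx]
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    rng = np.random.default_rng(seed)
    if max_cells_per_class is not None:
        take = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if len(idx) > max_cells_per_class:
                idx = rng.choice(idx, max_cells_per_class, replace=False)
            take.append(idx)
        train_idx = np.sort(np.concatenate(take))
    else:
        train_idx = np.arange(len(labels))

    nca = NeighborhoodComponentsAnalysis(
        n_components=dim, init="pca", max_iter=max_iter, random_state=seed
    )
    nca.fit(Xs[train_idx], labels[train_idx])
    converged = nca.n_iter_ < max_iter
    projection = nca.components_.T  # genes x dim
    return LatentModel(
        projection=projection,
        genes=genes,
        gene_mean=mean,
        gene_sd=sd,
        latent_reference=Xs @ projection,
        reference_labels=labels,
        dim=dim,
        converged=converged,
    )


def classify_knn(
    model: LatentModel,
    query: ad.AnnData,
    k: int = DEFAULT_K,
    uncertain_below: float = 0.5,
    is_lognorm: bool = False,
) -> pd.DataFrame:
    """kNN label transfer in the latent space.

    Each query cell receives the majority label of its k Euclidean nearest
    reference cells; ties are broken by the larger summed inverse distance.
    The vote fraction is reported as confidence, with votes below
    ``uncertain_below`` flagged uncertain.
    """
    Z = model.project(query, is_lognorm=is_lognorm)
    nn = NearestNeighbors(n_neighbors=k).fit(model.latent_reference)
    dist, idx = nn.kneighbors(Z)
    labels, votes = [], []
    inv = 1.0 / np.maximum(dist, 1e-12)
    for i in range(len(Z)):
        neigh = model.reference_labels[idx[i]]
        uniq, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        cands = uniq[counts == top]
        if len(cands) == 1:
            lab = cands[0]
        else:  # tie: summed inverse distance
            weight = {c: inv[i][neigh == c].sum() for c in cands}
            lab = max(sorted(weight), key=lambda c: weight[c])
        labels.append(lab)
        votes.append(top / k)
    out = pd.DataFrame(
        {"label": labels, "vote_fraction": votes}, index=query.obs_names
    )
    out["uncertain"] = out["vote_fraction"] < uncertain_below
    return out
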
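"""Ligand-receptor interaction scoring between cell subsets.

The score of a gene g in cell subset s is the share of g's UMIs that fall in
s (total UMIs of g in s over total UMIs of g across all subsets). A
multi-subunit complex's weight in a subset is the geometric mean of its
subunits' shares. The interaction score of a directed ligand->receptor pair
between subsets (i, j) is the ligand complex's weight in i times the
receptor complex's weight in j, and the interaction strength between (i, j)
is the sum of the top k pair scores (k = 10 by default, damping background
noise from the long tail of weakly-scored pairs). Strengths rank each
subset's interaction partners; conditions are analyzed separately by
recomputing shares within each condition's cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LigandReceptorCatalog",
    "load_catalog",
    "demo_catalog",
    "subset_shares",
    "complex_weight",
    "pair_scores",
    "interaction_strength",
    "rank_partners",
    "per_condition_interactions",
]

DEFAULT_K = 10
MIN_CELLS_PER_SUBSET = 10


@dataclass
class LigandReceptorCatalog:
    """Directed ligand->receptor pairs; either side may be a multi-subunit
    complex (e.g. an integrin heterodimer)."""

    pairs: list[tuple[str, tuple[str, ...], tuple[str, ...]]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for pid, lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError(f"pair {pid!r} has an empty subunit set")

    def __len__(self) -> int:
        return len(self.pairs)

    def resolve(self, genes) -> tuple["LigandReceptorCatalog", list[str]]:
        """Drop pairs with subunits absent from ``genes``; returns (kept, log)."""
        gene_set = set(genes)
        kept, dropped = [], []
        for pid, lig, rec in self.pairs:
            missing = [g for g in lig + rec if g not in gene_set]
            if missing:
                dropped.append(f"{pid}: missing {','.join(missing)}")
            else:
                kept.append((pid, lig, rec))
        return LigandReceptorCatalog(kept, self.provenance), dropped


def load_catalog(path: str | Path) -> LigandReceptorCatalog:
    """Read a catalog CSV: pair_id, ligand_subunits, receptor_subunits
    with '|'-delimited subunit genes."""
    df = pd.read_csv(path)
    required = {"pair_id", "ligand_subunits", "receptor_subunits"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: catalog must have columns {sorted(required)}")
    pairs = [
        (
            str(r.pair_id),
            tuple(str(r.ligand_subunits).split("|")),
            tuple(str(r.receptor_subunits).split("|")),
        )
        for r in df.itertuples()
    ]
    return LigandReceptorCatalog(pairs, provenance=str(path))


def demo_catalog() -> LigandReceptorCatalog:
    """The 30-pair demonstration catalog shipped with the package."""
    with resources.as_file(
        resources.files("esoatlas.data") / "lr_catalog_demo.csv"
    ) as p:
        cat = load_catalog(p)
    cat.provenance = "esoatlas demo catalog"
    return cat


def subset_shares(
    data: ad.AnnData,
    labels: pd.Series | None = None,
    min_cells: int = MIN_CELLS_PER_SUBSET,
) -> pd.DataFrame:
    """Per-gene UMI shares across cell subsets (genes x subsets).

    Shares are computed from raw UMI sums (cells are the aggregation unit).
    Rows of genes with any detected UMIs sum to 1; undetected genes are
    all-zero. Subsets with fewer than ``min_cells`` cells are excluded, as
    their shares are dominated by sampling noise.
    """
    labels = data.obs["cell_type"] if labels is None else labels
    labels = pd.Series(np.asarray(labels, dtype=object), index=data.obs_names)
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    counts = labels.value_counts()
    keep = sorted(counts.index[counts >= min_cells])
    if not keep:
        raise ValueError(f"no subset with >= {min_cells} cells")
    X = sp.csr_matrix(data.X)
    sums = np.zeros((data.n_vars, len(keep)))
    for j, subset in enumerate(keep):
        mask = (labels == subset).to_numpy()
        sums[:, j] = np.asarray(X[mask].sum(axis=0)).ravel()
    totals = sums.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        shares = np.where(totals > 0, sums / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(shares, index=data.var_names, columns=keep)


def complex_weight(shares: pd.DataFrame, subunits, subset: str) -> float:
    """Geometric mean of the subunit shares in ``subset``; 0 if any is 0."""
    vals = shares.loc[list(subunits), subset].to_numpy(dtype=float)
    if np.any(vals <= 0):
        return 0.0
    return float(np.exp(np.log(vals).mean()))


def pair_scores(
    shares: pd.DataFrame, catalog: LigandReceptorCatalog, i: str, j: str
) -> pd.Series:
    """Score of each catalog pair for ordered subsets (ligand in i,
    receptor in j): ligand complex weight in i times receptor weight in j."""
    resolved, dropped = catalog.resolve(shares.index)
    if dropped:
        warnings.warn(f"excluded pairs with unresolvable subunits: {dropped}")
    scores = {
        pid: complex_weight(shares, lig, i) * complex_weight(shares, rec, j)
        for pid, lig, rec in resolved.pairs
    }
    return pd.Series(scores, dtype=float)


@dataclass
class InteractionStrengthMatrix:
    strength: pd.DataFrame  # ordered (ligand subset i rows, receptor subset j cols)
    k: int
    ledger: pd.DataFrame  # columns: source, target, pair_id, score, in_top_k


def interaction_strength(
    shares: pd.DataFrame, catalog: LigandReceptorCatalog, k: int = DEFAULT_K
) -> InteractionStrengthMatrix:
    """Sum of the top-k pair scores for every ordered subset pair.

    Ties at the k-th score are broken by pair_id order (stable sort), and
    catalogs with fewer than k pairs simply sum everything. Autocrine pairs
    (i == j) are included.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    resolved, dropped = catalog.resolve(shares.index)
    if dropped:
        warnings.warn(f"excluded pairs with unresolvable subunits: {dropped}")
    subsets = list(shares.columns)
    # precompute complex weights: pair side x subset
    lig_w = np.array(
        [[complex_weight(shares, lig, s) for s in subsets] for _, lig, _ in resolved.pairs]
    ).reshape(len(resolved.pairs), len(subsets)) if resolved.pairs else np.zeros((0, len(subsets)))
    rec_w = np.array(
        [[complex_weight(shares, rec, s) for s in subsets] for _, _, rec in resolved.pairs]
    ).reshape(len(resolved.pairs), len(subsets)) if resolved.pairs else np.zeros((0, len(subsets)))
    pair_ids = [pid for pid, _, _ in resolved.pairs]

    strength = pd.DataFrame(0.0, index=subsets, columns=subsets)
    ledger_rows = []
    for a, i in enumerate(subsets):
        for b, j in enumerate(subsets):
            scores = lig_w[:, a] * rec_w[:, b]
            order = np.argsort(-scores, kind="stable")
            topk = set(order[:k].tolist())
            strength.loc[i, j] = float(scores[order[:k]].sum())
            for rank, idx in enumerate(order):
                ledger_rows.append(
                    {
                        "source": i,
                        "target": j,
                        "pair_id": pair_ids[idx],
                        "score": scores[idx],
                        "rank": rank + 1,
                        "in_top_k": rank < k,
                    }
                )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["source", "target", "pair_id", "score", "rank", "in_top_k"],
    )
    return InteractionStrengthMatrix(strength=strength, k=k, ledger=ledger)


def symmetrize(strengths: InteractionStrengthMatrix) -> pd.DataFrame:
    """Pooled both-direction strength: directed(i->j) + directed(j->i)."""
    S = strengths.strength
    return S + S.T


def rank_partners(
    strengths: InteractionStrengthMatrix | pd.DataFrame,
    cell_type: str,
    top_n: int = 3,
) -> pd.DataFrame:
    """Top interaction partners of ``cell_type`` with row z-scored weights.

    Partners are ordered by descending strength with lexicographic
    tie-break; z-scores use the population standard deviation over the
    returned row. A single partner (sd undefined) gets z = 0 and a flag.
    """
    S = strengths.strength if isinstance(strengths, InteractionStrengthMatrix) else strengths
    if cell_type not in S.index:
        raise KeyError(cell_type)
    row = S.loc[cell_type]
    ordered = sorted(row.index, key=lambda p: (-row[p], p))[:top_n]
    vals = row[ordered].to_numpy(dtype=float)
    sd = vals.std()  # population sd
    degenerate = len(vals) < 2 or sd == 0
    z = np.zeros_like(vals) if degenerate else (vals - vals.mean()) / sd
    return pd.DataFrame(
        {"partner": ordered, "strength": vals, "z": z, "z_degenerate": degenerate}
    )


def per_condition_interactions(
    data: ad.AnnData,
    samples: pd.DataFrame,
    catalog: LigandReceptorCatalog,
    k: int = DEFAULT_K,
    group_key: str = "condition",
    min_cells: int = MIN_CELLS_PER_SUBSET,
) -> dict[str, InteractionStrengthMatrix]:
    """Interaction strengths per condition, shares recomputed within each.

    Subsets falling below ``min_cells`` in a condition are absent from that
    condition's matrix (logged via warning in :func:`subset_shares`).
    """
    cond = samples.reindex(data.obs["sample_id"])[group_key].to_numpy()
    out = {}
    for level in pd.unique(cond):
        sub = data[cond == level]
        shares = subset_shares(sub, min_cells=min_cells)
        out[str(level)] = interaction_strength(shares, catalog, k=k)
    return out
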
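"""Synthetic multi-sample esophageal atlas generator with known ground truth.

Emulates the structure of a droplet scRNA-seq atlas of esophageal biopsies:
multiple donors per condition (healthy / remission / active EoE), paired
distal+proximal biopsies for a subset of donors, three 10x chemistry batches
with chemistry-dependent mitochondrial load, condition-dependent shifts in
cell-type composition, cell-type-specific differential expression, ambient
RNA contamination mixed at the UMI level, and planted ligand-receptor axes.

Every downstream statistic in this package can be validated against the
planted parameters returned in :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "AtlasConfig",
    "SyntheticTruth",
    "AtlasConfigError",
    "AtlasIOError",
    "generate_atlas",
    "simulate_composition",
    "write_atlas",
    "read_atlas",
]

CONDITIONS = ("healthy", "remission", "active")
CHEMISTRIES = ("v2", "v3", "v3-dual")


class AtlasConfigError(ValueError):
    """Raised when an :class:`AtlasConfig` is internally inconsistent."""


class AtlasIOError(ValueError):
    """Raised when an on-disk atlas is malformed; names the offending file."""


@dataclass
class LRPlant:
    """A planted directed ligand->receptor axis between two cell types."""

    ligand_genes: tuple[str, ...]
    receptor_genes: tuple[str, ...]
    source_type: str
    target_type: str
    intensity: float = 20.0


@dataclass
class AtlasConfig:
    """Parameters of the synthetic atlas.

    Defaults mirror the design of the study being emulated — 22 donors
    (8 active EoE, 7 remission, 7 healthy), 15 donors contributing paired
    distal+proximal biopsies (37 samples: 14 active / 11 remission / 12
    healthy), and chemistry batches of 7 v2 / 9 v3 / 6 v3-dual donors —
    at desk scale in cells, genes, and cell types.
    """

    donors_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 7, "remission": 7, "active": 8}
    )
    # donors with both distal and proximal biopsies, per condition;
    # defaults yield 12 healthy / 11 remission / 14 active biopsies
    paired_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 5, "remission": 4, "active": 6}
    )
    chemistry_batches: Mapping[str, int] = field(
        default_factory=lambda: {"v2": 7, "v3": 9, "v3-dual": 6}
    )
    n_cell_types: int = 15
    n_genes: int = 300
    cells_per_sample: int | tuple[int, int] = 400
    composition_base: np.ndarray | None = None  # Dirichlet concentrations
    composition_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    de_effects: Sequence[tuple[str, str, str, float]] = field(default_factory=tuple)
    ambient_fraction: float = 0.05
    # optional per-condition Beta(a, b) distribution of per-sample ambient
    # load; samples of unlisted conditions use the scalar ambient_fraction.
    # A right-skewed Beta plants the classic artifact regime: a few heavily
    # contaminated samples against a quiet majority.
    ambient_fraction_by_condition: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    mito_gene_count: int = 10
    mito_fraction_by_chemistry: Mapping[str, float] = field(
        default_factory=lambda: {"v2": 0.08, "v3": 0.16, "v3-dual": 0.16}
    )
    mito_concentration: float = 60.0  # Beta concentration of per-cell mito load
    lr_plants: Sequence[LRPlant] = field(default_factory=tuple)
    # genes expressed (almost) exclusively in one cell type, e.g. for planting
    # ambient-leakage scenarios: gene -> (cell type, intensity)
    exclusive_genes: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    library_size_log_mean: float = float(np.log(2500.0))
    library_size_log_sd: float = 0.35
    profile_shape: float = 0.35  # gamma shape of per-(type, gene) baseline rates
    seed: int = 0

    # -- derived label helpers ------------------------------------------------
    @property
    def cell_types(self) -> list[str]:
        return [f"ct{i:02d}" for i in range(self.n_cell_types)]

    @property
    def gene_names(self) -> list[str]:
        mito = [f"MT-G{i}" for i in range(self.mito_gene_count)]
        rest = [f"G{i:04d}" for i in range(self.n_genes - self.mito_gene_count)]
        return mito + rest

    def validate(self) -> None:
        if not 0.0 <= self.ambient_fraction < 1.0:
            raise AtlasConfigError("ambient_fraction must be in [0, 1)")
        if self.n_cell_types < 1 or self.n_genes < 2:
            raise AtlasConfigError("need at least 1 cell type and 2 genes")
        if not 0 <= self.mito_gene_count < self.n_genes:
            raise AtlasConfigError("mito_gene_count must be < n_genes")
        for cond, n_paired in self.paired_per_condition.items():
            if n_paired > self.donors_per_condition.get(cond, 0):
                raise AtlasConfigError(
                    f"paired donors for {cond!r} exceed its donor count"
                )
        if sum(self.chemistry_batches.values()) != sum(self.donors_per_condition.values()):
            raise AtlasConfigError("chemistry batch sizes must sum to the donor count")
        for cond in self.donors_per_condition:
            if cond not in CONDITIONS:
                raise AtlasConfigError(f"unknown condition {cond!r}")
        for chem, frac in self.mito_fraction_by_chemistry.items():
            if chem not in CHEMISTRIES:
                raise AtlasConfigError(f"unknown chemistry {chem!r}")
            if not 0.0 <= frac < 1.0:
                raise AtlasConfigError("mito fractions must be in [0, 1)")
        if self.composition_base is not None and len(self.composition_base) != self.n_cell_types:
            raise AtlasConfigError("composition_base length must equal n_cell_types")
        types, genes = set(self.cell_types), set(self.gene_names)
        for gene, ct, cond, _ in self.de_effects:
            if gene not in genes or ct not in types or cond not in CONDITIONS:
                raise AtlasConfigError(f"de_effect refers to unknown ({gene}, {ct}, {cond})")
        for (ct, cond) in self.composition_effects:
            if ct not in types or cond not in CONDITIONS:
                raise AtlasConfigError(f"composition_effect refers to unknown ({ct}, {cond})")
        for plant in self.lr_plants:
            if plant.source_type not in types or plant.target_type not in types:
                raise AtlasConfigError("lr_plant refers to unknown cell type")
            for g in tuple(plant.ligand_genes) + tuple(plant.receptor_genes):
                if g not in genes:
                    raise AtlasConfigError(f"lr_plant refers to unknown gene {g!r}")
        for g, (ct, _) in self.exclusive_genes.items():
            if g not in genes or ct not in types:
                raise AtlasConfigError(f"exclusive_gene refers to unknown ({g}, {ct})")
        for cond, (a, b) in self.ambient_fraction_by_condition.items():
            if cond not in CONDITIONS or a <= 0 or b <= 0:
                raise AtlasConfigError(
                    f"ambient_fraction_by_condition[{cond!r}] must be positive Beta params"
                )


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated atlas, for recovery testing."""

    sample_composition: pd.DataFrame  # samples x cell types, rows sum to 1
    composition_effects: dict[str, float]  # "ct|condition" -> log enrichment
    de_effects: list[tuple[str, str, str, float]]
    ambient_fraction: float
    ambient_profile: np.ndarray  # dataset-mean per-gene probability vector
    lr_plants: list[LRPlant]
    cell_types: list[str]
    gene_names: list[str]
    ambient_profiles: pd.DataFrame | None = None  # per-sample profiles
    ambient_fractions: pd.Series | None = None  # per-sample ambient load

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.sample_composition.equals(other.sample_composition)
            and self.composition_effects == other.composition_effects
            and [tuple(e) for e in self.de_effects] == [tuple(e) for e in other.de_effects]
            and self.ambient_fraction == other.ambient_fraction
            and np.array_equal(self.ambient_profile, other.ambient_profile)
            and (
                (self.ambient_profiles is None and other.ambient_profiles is None)
                or (
                    self.ambient_profiles is not None
                    and other.ambient_profiles is not None
                    and self.ambient_profiles.equals(other.ambient_profiles)
                )
            )
            and (
                (self.ambient_fractions is None and other.ambient_fractions is None)
                or (
                    self.ambient_fractions is not None
                    and other.ambient_fractions is not None
                    and self.ambient_fractions.equals(other.ambient_fractions)
                )
            )
            and self.lr_plants == other.lr_plants
            and self.cell_types == other.cell_types
            and self.gene_names == other.gene_names
        )


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def _design_samples(cfg: AtlasConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign donors to conditions, chemistries, regions, and clinical covariates."""
    donors, conditions, paired = [], [], []
    i = 0
    for cond in CONDITIONS:
        n_cond = cfg.donors_per_condition.get(cond, 0)
        n_paired = cfg.paired_per_condition.get(cond, 0)
        for d in range(n_cond):
            donors.append(f"D{i:02d}")
            conditions.append(cond)
            paired.append(d < n_paired)  # first donors of each condition paired
            i += 1
    n_donors = len(donors)
    paired = np.asarray(paired)
    order = rng.permutation(n_donors)
    chem_labels = [c for c, n in cfg.chemistry_batches.items() for _ in range(n)]
    chemistry = np.empty(n_donors, dtype=object)
    chemistry[order] = chem_labels

    rows = []
    for d in range(n_donors):
        cond = conditions[d]
        steroid = bool(rng.random() < 0.4) if cond != "healthy" else False
        diet = bool(rng.random() < 0.4) if cond != "healthy" else False
        if cond == "healthy":
            eos = 0.0
        elif cond == "remission":
            eos = float(rng.poisson(2.0))
        else:
            eos = float(np.round(rng.normal(45.0, 15.0)).clip(16, 150))
        erefs = {"healthy": 0.0, "remission": 1.0, "active": 5.0}[cond] + float(
            rng.poisson(1.0)
        )
        regions = ["distal", "proximal"] if paired[d] else ["distal"]
        for region in regions:
            rows.append(
                {
                    "sample_id": f"{donors[d]}_{region}",
                    "donor": donors[d],
                    "condition": cond,
                    "region": region,
                    "chemistry": chemistry[d],
                    "steroid": steroid,
                    "diet": diet,
                    "eos_per_hpf": eos,
                    "erefs": erefs,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

def _base_profiles(cfg: AtlasConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell-type mean expression over non-mito genes, and a mito profile.

    Each (type, gene) baseline rate is an independent gamma draw, so types are
    genuinely distinct transcriptional states; planted ligand/receptor genes
    are then concentrated in their source/target types.
    """
    n_body = cfg.n_genes - cfg.mito_gene_count
    profiles = rng.gamma(cfg.profile_shape, 1.0, size=(cfg.n_cell_types, n_body))
    profiles += 1e-4  # no exactly-zero rates; keeps multinomials well-defined
    mito = rng.gamma(1.0, 1.0, size=cfg.mito_gene_count) + 1e-3 if cfg.mito_gene_count else np.array([])

    gene_idx = {g: i for i, g in enumerate(cfg.gene_names)}
    type_idx = {t: i for i, t in enumerate(cfg.cell_types)}
    mean_rate = float(profiles.mean())
    concentrated = [
        (g, plant.source_type, plant.intensity)
        for plant in cfg.lr_plants for g in plant.ligand_genes
    ] + [
        (g, plant.target_type, plant.intensity)
        for plant in cfg.lr_plants for g in plant.receptor_genes
    ] + [(g, ct, inten) for g, (ct, inten) in cfg.exclusive_genes.items()]
    for g, t, intensity in concentrated:
        j = gene_idx[g] - cfg.mito_gene_count
        if j < 0:
            raise AtlasConfigError("concentrated genes may not be mitochondrial")
        profiles[:, j] *= 0.02  # background leakage only
        profiles[type_idx[t], j] = intensity * mean_rate
    profiles /= profiles.sum(axis=1, keepdims=True)
    if cfg.mito_gene_count:
        mito = mito / mito.sum()
    return profiles, mito


def _condition_profile(
    cfg: AtlasConfig, base: np.ndarray, type_name: str, cond: str
) -> np.ndarray:
    """Apply planted DE log2 fold changes of (type, condition) to a base profile."""
    prof = base.copy()
    gene_idx = {g: i - cfg.mito_gene_count for i, g in enumerate(cfg.gene_names)}
    touched = False
    for gene, ct, de_cond, log2fc in cfg.de_effects:
        if ct == type_name and de_cond == cond:
            prof[gene_idx[gene]] *= 2.0 ** log2fc
            touched = True
    if touched:
        prof = prof / prof.sum()
    return prof


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_atlas(cfg: AtlasConfig) -> tuple[ad.AnnData, pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic atlas.

    Returns ``(data, samples, truth)`` where ``data`` is an AnnData of raw UMI
    counts (cells x genes, CSR) with ``obs`` columns ``barcode``, ``sample_id``
    and ``cell_type``; ``samples`` is the per-sample covariate table; and
    ``truth`` records every planted parameter.

    Per sample, the composition is Dirichlet(base * exp(condition effects))
    and per-type cell counts are multinomial. Per cell, the library size is
    lognormal and gene counts are multinomial over the cell type's mean
    profile (with the sample's condition DE applied and a chemistry-dependent
    Beta-distributed mitochondrial share); a Binomial(library, ambient)
    number of UMIs is instead drawn from the pooled ambient profile, i.e.
    each UMI is independently Bernoulli-switched to ambient.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    design_rng = np.random.default_rng(root.spawn(1)[0])
    samples = _design_samples(cfg, design_rng)
    profiles, mito_profile = _base_profiles(cfg, design_rng)

    base = (
        np.asarray(cfg.composition_base, dtype=float)
        if cfg.composition_base is not None
        else 40.0 / np.arange(1, cfg.n_cell_types + 1)
    )
    if np.any(base <= 0):
        raise AtlasConfigError("composition_base entries must be positive")

    # condition-specific expression profiles (non-mito block), cached
    cond_profiles = {
        (t, cond): _condition_profile(cfg, profiles[i], t, cond)
        for i, t in enumerate(cfg.cell_types)
        for cond in CONDITIONS
    }

    blocks, barcodes, cell_samples, cell_types_out = [], [], [], []
    comp_rows, ambient_rows, amb_fracs = {}, {}, {}
    # one independent child stream per sample => partial regeneration is stable
    sample_seeds = root.spawn(1)[0].spawn(len(samples) + 1)[1:]
    for (sid, row), sseed in zip(samples.iterrows(), sample_seeds):
        rng = np.random.default_rng(sseed)
        cond = row["condition"]
        conc = base * np.exp(
            [cfg.composition_effects.get((t, cond), 0.0) for t in cfg.cell_types]
        )
        p_true = rng.dirichlet(conc)
        comp_rows[sid] = p_true
        if isinstance(cfg.cells_per_sample, tuple):
            n_cells = int(rng.integers(cfg.cells_per_sample[0], cfg.cells_per_sample[1] + 1))
        else:
            n_cells = int(cfg.cells_per_sample)
        n_per_type = rng.multinomial(n_cells, p_true)

        mito_mean = cfg.mito_fraction_by_chemistry.get(row["chemistry"], 0.0)
        if not cfg.mito_gene_count:
            mito_mean = 0.0
        # the sample's own ambient soup: its condition profiles mixed at its
        # true composition, with the chemistry's mean mitochondrial load
        body_mix = p_true @ np.vstack([cond_profiles[(t, cond)] for t in cfg.cell_types])
        ambient_profile_s = np.concatenate(
            [mito_mean * mito_profile, (1 - mito_mean) * body_mix]
        )
        ambient_profile_s = ambient_profile_s / ambient_profile_s.sum()
        ambient_rows[sid] = ambient_profile_s
        if cond in cfg.ambient_fraction_by_condition:
            a, b = cfg.ambient_fraction_by_condition[cond]
            amb_frac_s = float(rng.beta(a, b))
        else:
            amb_frac_s = cfg.ambient_fraction
        amb_fracs[sid] = amb_frac_s
        for t_i, (t_name, n_t) in enumerate(zip(cfg.cell_types, n_per_type)):
            if n_t == 0:
                continue
            lib = np.maximum(
                1,
                np.round(
                    rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, n_t)
                ).astype(np.int64),
            )
            body = cond_profiles[(t_name, cond)]
            if cfg.mito_gene_count and mito_mean > 0:
                f = rng.beta(
                    mito_mean * cfg.mito_concentration,
                    (1 - mito_mean) * cfg.mito_concentration,
                    size=n_t,
                )
            else:
                f = np.zeros(n_t)
            pvals = np.concatenate(
                [f[:, None] * mito_profile[None, :] if cfg.mito_gene_count else np.empty((n_t, 0)),
                 (1 - f)[:, None] * body[None, :]],
                axis=1,
            )
            n_amb = rng.binomial(lib, amb_frac_s)
            native = rng.multinomial(lib - n_amb, pvals)
            ambient = rng.multinomial(n_amb, ambient_profile_s)
            blocks.append(sp.csr_matrix(native + ambient))
            cell_samples.extend([sid] * n_t)
            cell_types_out.extend([t_name] * n_t)
        barcodes.extend(f"{sid}-{i:05d}" for i in range(n_cells))

    X = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, cfg.n_genes), dtype=np.int64)
    X = X.astype(np.int64)
    obs = pd.DataFrame(
        {"barcode": barcodes, "sample_id": cell_samples, "cell_type": cell_types_out}
    )
    obs.index = pd.Index(barcodes, name="barcode")
    data = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(cfg.gene_names, name="gene"))
    )
    ambient_profiles = pd.DataFrame.from_dict(
        ambient_rows, orient="index", columns=cfg.gene_names
    )
    truth = SyntheticTruth(
        sample_composition=pd.DataFrame.from_dict(
            comp_rows, orient="index", columns=cfg.cell_types
        ),
        composition_effects={f"{t}|{c}": v for (t, c), v in cfg.composition_effects.items()},
        de_effects=[tuple(e) for e in cfg.de_effects],
        ambient_fraction=cfg.ambient_fraction,
        ambient_profile=ambient_profiles.mean(axis=0).to_numpy(),
        ambient_profiles=ambient_profiles,
        ambient_fractions=pd.Series(amb_fracs, name="ambient_fraction"),
        lr_plants=list(cfg.lr_plants),
        cell_types=cfg.cell_types,
        gene_names=cfg.gene_names,
    )
    return data, samples, truth


def expected_profiles(cfg: AtlasConfig) -> pd.DataFrame:
    """Deterministic per-type baseline expression profiles for a config.

    Returns the cell-type x gene matrix of expected non-mitochondrial
    expression shares that :func:`generate_atlas` would use for the healthy
    condition (mitochondrial columns are zero here; the mitochondrial share
    is drawn per cell). Useful for choosing well-expressed genes to plant
    differential-expression effects on: the draw depends only on the
    config's seed and dimensions.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    _design_samples(cfg, rng)  # consume the design draws, as generation does
    profiles, _ = _base_profiles(cfg, rng)
    full = np.zeros((cfg.n_cell_types, cfg.n_genes))
    full[:, cfg.mito_gene_count:] = profiles
    return pd.DataFrame(full, index=cfg.cell_types, columns=cfg.gene_names)


def simulate_composition(
    n_samples: int = 30,
    n_cell_types: int = 10,
    effects: Mapping[tuple[str, str], float] | None = None,
    base: np.ndarray | None = None,
    total_cells: int = 3000,
    conditions: Sequence[str] = ("healthy", "active"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fast Dirichlet-multinomial composition-only simulator.

    Generates sample x cell-type count tables with the same compositional
    model as :func:`generate_atlas` but without per-cell expression — the
    workhorse for abundance-statistics calibration at many replicates.
    Returns ``(counts, samples, true_composition)``.
    """
    rng = np.random.default_rng(seed)
    cell_types = [f"ct{i:02d}" for i in range(n_cell_types)]
    if base is None:
        base = 40.0 / np.arange(1, n_cell_types + 1)
    effects = dict(effects or {})
    conds = [conditions[i % len(conditions)] for i in range(n_samples)]
    chem = [CHEMISTRIES[i % 3] for i in range(n_samples)]
    # period-4 pattern, orthogonal to the period-2 condition assignment
    region = ["distal" if i % 4 < 2 else "proximal" for i in range(n_samples)]
    steroid = [bool((i + 1) % 4 < 2) and conds[i] != "healthy" for i in range(n_samples)]
    rows, comp = [], []
    for i in range(n_samples):
        conc = base * np.exp([effects.get((t, conds[i]), 0.0) for t in cell_types])
        p = rng.dirichlet(conc)
        comp.append(p)
        rows.append(rng.multinomial(total_cells, p))
    ids = [f"S{i:03d}" for i in range(n_samples)]
    counts = pd.DataFrame(rows, index=ids, columns=cell_types)
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "donor": ids,
            "condition": conds,
            "region": region,
            "chemistry": chem,
            "steroid": steroid,
        }
    ).set_index("sample_id", drop=False)
    true_comp = pd.DataFrame(comp, index=ids, columns=cell_types)
    return counts, samples, true_comp


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_atlas(
    data: ad.AnnData, samples: pd.DataFrame, directory: str | Path,
    truth: SyntheticTruth | None = None,
) -> None:
    """Write an atlas as Matrix Market + TSV/CSV (+ ``truth.json`` if given).

    ``matrix.mtx`` holds integer counts genes x cells (the droplet-pipeline
    convention); ``genes.tsv`` / ``barcodes.tsv`` carry the axis labels;
    ``cells.csv`` the per-cell metadata and ``samples.csv`` the covariates.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(data.X).T.tocoo()  # genes x cells
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(data.var_names).to_csv(directory / "genes.tsv", index=False, header=False)
    pd.Series(data.obs["barcode"].values).to_csv(
        directory / "barcodes.tsv", index=False, header=False
    )
    data.obs[["barcode", "sample_id", "cell_type"]].to_csv(
        directory / "cells.csv", index=False
    )
    samples.to_csv(directory / "samples.csv", index=False)
    if truth is not None:
        payload = {
            "sample_composition": {
                sid: list(map(float, row))
                for sid, row in truth.sample_composition.iterrows()
            },
            "composition_effects": truth.composition_effects,
            "de_effects": [list(e) for e in truth.de_effects],
            "ambient_fraction": truth.ambient_fraction,
            "ambient_profile": [float(x) for x in truth.ambient_profile],
            "ambient_profiles": (
                None
                if truth.ambient_profiles is None
                else {
                    sid: [float(x) for x in row]
                    for sid, row in truth.ambient_profiles.iterrows()
                }
            ),
            "ambient_fractions": (
                None
                if truth.ambient_fractions is None
                else {k: float(v) for k, v in truth.ambient_fractions.items()}
            ),
            "lr_plants": [asdict(p) for p in truth.lr_plants],
            "cell_types": truth.cell_types,
            "gene_names": truth.gene_names,
        }
        (directory / "truth.json").write_text(json.dumps(payload))


def read_atlas(
    directory: str | Path,
) -> tuple[ad.AnnData, pd.DataFrame, SyntheticTruth | None]:
    """Read an atlas written by :func:`write_atlas`; bit-exact round trip."""
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise AtlasIOError(f"{mtx_path}: malformed Matrix Market file: {exc}") from exc
    genes = [
        ln for ln in (directory / "genes.tsv").read_text().splitlines() if ln
    ]
    barcodes = [
        ln for ln in (directory / "barcodes.tsv").read_text().splitlines() if ln
    ]
    if mat.shape != (len(genes), len(barcodes)):
        raise AtlasIOError(
            f"{mtx_path}: header declares {mat.shape}, but genes.tsv has "
            f"{len(genes)} rows and barcodes.tsv has {len(barcodes)}"
        )
    X = sp.csr_matrix(mat.T).astype(np.int64)
    X.resize((len(barcodes), len(genes)))
    cells = pd.read_csv(directory / "cells.csv", dtype={"barcode": str})
    for col in ("barcode", "sample_id", "cell_type"):
        if col not in cells.columns:
            raise AtlasIOError(f"{directory / 'cells.csv'}: missing column {col!r}")
    if len(cells) != len(barcodes):
        raise AtlasIOError(
            f"{directory / 'cells.csv'}: {len(cells)} rows but {len(barcodes)} barcodes"
        )
    cells.index = pd.Index(cells["barcode"].astype(str), name="barcode")
    data = ad.AnnData(
        X=X, obs=cells, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    samples = pd.read_csv(directory / "samples.csv")
    samples = samples.set_index("sample_id", drop=False)
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = SyntheticTruth(
            sample_composition=pd.DataFrame.from_dict(
                payload["sample_composition"], orient="index",
                columns=payload["cell_types"],
            ),
            composition_effects=payload["composition_effects"],
            de_effects=[tuple(e) for e in payload["de_effects"]],
            ambient_fraction=payload["ambient_fraction"],
            ambient_profile=np.asarray(payload["ambient_profile"]),
            ambient_profiles=(
                None
                if payload.get("ambient_profiles") is None
                else pd.DataFrame.from_dict(
                    payload["ambient_profiles"], orient="index",
                    columns=payload["gene_names"],
                )
            ),
            ambient_fractions=(
                None
                if payload.get("ambient_fractions") is None
                else pd.Series(payload["ambient_fractions"], name="ambient_fraction")
            ),
            lr_plants=[LRPlant(
                ligand_genes=tuple(p["ligand_genes"]),
                receptor_genes=tuple(p["receptor_genes"]),
                source_type=p["source_type"],
                target_type=p["target_type"],
                intensity=p["intensity"],
            ) for p in payload["lr_plants"]],
            cell_types=payload["cell_types"],
            gene_names=payload["gene_names"],
        )
    return data, samples, truth
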
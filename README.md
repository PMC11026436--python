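# esoatlas

Statistical toolkit for multi-sample single-cell atlases of the esophageal
mucosa, built around the comparisons that matter in eosinophilic esophagitis
(EoE): healthy vs. remission vs. active disease across donors, biopsy
regions, and 10x chemistry batches.

The package implements, as reusable and tested components:

- **Differential cell-type abundance** — per cell type a negative binomial
  regression of cell counts, `y_sc ~ NB(μ_sc, θ_c)` with
  `log μ_sc = x_s'β_c + log N_s`, where `N_s` is the total analyzed cells of
  biopsy `s` and covariates are condition, chemistry, steroid treatment, and
  region; Wald tests on the active-vs-healthy contrast with BH FDR. A
  quantile-normalized rank-regression variant, centered log-ratio (CLR)
  transform + PCA of compositions, and a multi-term sequential PERMANOVA
  complete the compositional battery.
- **Covariate-adjusted differential expression** — per gene a logistic
  regression of group membership on log(TP10K+1) expression plus log2
  detected genes, steroid, region and chemistry, tested by likelihood
  ratio, with an **ambient-RNA filter**: an upregulated gene that is
  *down* in the majority of the individual focal-condition samples is
  flagged as contamination-driven and removed.
- **Ligand–receptor interaction scoring** — the share of a gene's UMIs per
  cell subset `s_g`, geometric-mean weights for multi-subunit complexes,
  directed pair scores `w_lig(i) · w_rec(j)`, and the interaction strength
  between two subsets as the **sum of the top k = 10 pair scores** (robust
  to the long tail of background pairs; ranking stable for k in 5–15).
- **Reference-based annotation** — neighborhood component analysis maps a
  labeled reference to a 50-dimensional latent space; query cells are
  projected with the frozen transform and classified by kNN (k = 11).
- **Gene programs and risk-gene modules** — binned-control signature
  scores, NMF expression programs, a ≥25 %-expressing screen, and risk-gene
  modules from Ward.D2 clustering of square-root mean pseudo-bulk profiles.
- **A synthetic atlas generator** with full ground truth — 22 donors,
  paired distal/proximal biopsies (37 samples: 14 active / 11 remission /
  12 healthy), three chemistry batches with chemistry-dependent
  mitochondrial load, planted composition shifts, cell-type-specific DE,
  UMI-level ambient contamination, and planted ligand–receptor axes — so
  every statistic above can be validated against known parameters.

## Worked example

```python
import numpy as np
from esoatlas.synthetic import AtlasConfig, generate_atlas
from esoatlas.qc import filter_cells, QCThresholds
from esoatlas.composition import composition_table, nb_abundance

cfg = AtlasConfig(seed=0, composition_effects={("ct03", "active"): np.log(2.5)})
data, samples, truth = generate_atlas(cfg)

kept, log = filter_cells(data, samples, QCThresholds())  # >500 UMIs, <25%/40% mito
comp = composition_table(kept.obs, samples)
res = nb_abundance(comp)
print(res.loc["ct03", ["beta", "se", "fdr", "significance"]])
```

```
beta            0.8605
se              0.1028
fdr             0.0
significance    ***
```

The planted 2.5-fold concentration bump for `ct03` in active disease
corresponds to a true log proportion ratio of ≈ 0.86 after closure (raising
one type necessarily dilutes the others); the fitted coefficient recovers it
with FDR < 0.001 (`***`, the FDR < 0.001 tier). QC retained 14,796 of
14,800 simulated cells.

A shell workflow covers the file-based stages
(`matrix.mtx` / `genes.tsv` / `barcodes.tsv` / `cells.csv` / `samples.csv`):

```bash
esoatlas simulate --out raw/ --seed 1
esoatlas qc --in raw/ --out clean/
esoatlas interact --in clean/ --catalog my_pairs.csv --k 10 --out interactions/
```

The ligand–receptor catalog is a CSV with `pair_id,ligand_subunits,
receptor_subunits` and `|`-delimited subunits (e.g. `ITGA4|ITGB7`); a
30-pair demonstration catalog ships with the package
(`esoatlas.interactions.demo_catalog()`).

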
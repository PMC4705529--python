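# cocompart

3D confocal object **co-compartmentalization** analysis for puncta-forming
proteins, with a ground-truthed synthetic benchmark.

When innate-immunity sensors (NOD-like receptors, the NLRP3/NALP3
inflammasome scaffold) and autophagosome markers (LC3) are imaged as
fluorescent puncta in single cells, the biological questions are spatial:
do the puncta of one marker overlap the objects of another, do they
aggregate, do they relocate toward the nucleus, and do those patterns
shift with treatment (e.g. LPS or the NOD1 ligand iE-DAP)? `cocompart`
implements the full measurement chain for such questions, plus the
companion statistics used alongside the imaging:

* **Synthetic scenes** — a single-cell generator on an anisotropic
  confocal grid (140 nm axial / 40 nm lateral) with exact per-punctum
  ground truth and three treatment dials: aggregation, perinuclear bias,
  and a pairwise co-localization fraction f<sub>ab</sub>.
* **Preprocessing** — translational slice registration; anisotropic
  Gaussian PSF (σ<sub>lat</sub> = 0.21 λ/NA, σ<sub>ax</sub> = 0.66 λ n/NA²);
  Richardson–Lucy deconvolution with total-variation regularization.
* **Segmentation** — Otsu/fixed/quantile thresholding within the cell
  mask, 3D connected components, marching-cubes surface meshes for the
  nucleus and cell membrane with enclosed volumes.
* **Object features** — 16 attributes per object (overlap percentage and
  partner count, volume, intensities, ellipsoid axes and orientation
  angles, normalized distances to the nuclear and cell surfaces) plus
  class and treatment labels: an 18-column table.
* **Pixel colocalization** — Pearson R_total, Costes automatic
  thresholds, Manders M1/M2.
* **Multivariate analysis** — PCA with scree/loadings, declarative
  rectangular gates in score space, per-cluster summaries, one-way ANOVA
  with Holm–Šidák or Tukey post-tests.
* **Label-free proteomics** — sum normalization → log2 with
  zeros-imputed-as-1 → LOESS bias correction → per-protein ANOVA →
  Benjamini–Hochberg FDR; two-way hierarchical clustering
  (complete/median linkage on correlation distance); a synthetic LFQ
  generator with planted differential expression.
* **qPCR** — comparative-Ct (ΔΔCt) fold changes: fold = 2^(−ΔΔCt).

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate one scene in which half of the NALP3 puncta are placed overlapping
an LC3 punctum, run the default chain (RL deconvolution, Otsu within the
cell mask, 3D labelling, meshes, features, pixel colocalization):

```python
import cocompart as cc
from cocompart.pipeline import PipelineConfig, analyze_scene

cfg = cc.SceneConfig(seed=11, coloc=((("NALP3", "LC3"), 0.5),))
channels, truth = cc.generate_scene(cfg)
table, coloc = analyze_scene(channels, "iE-DAP",
                             {"NALP3": "LC3", "LC3": "NALP3"},
                             PipelineConfig())

df = table.table
print(df.groupby("cls")[["pct_voxels_coloc", "volume_nm3",
                         "dist_nucleus_norm"]].mean().round(3))
res = coloc["LC3|NALP3"]
print(f"R_total = {res.r_total:.3f}   M1 = {res.m1:.3f}   M2 = {res.m2:.3f}")
```

prints

```
       pct_voxels_coloc  volume_nm3  dist_nucleus_norm
cls
LC3              20.291  72172800.0              0.219
NALP3            25.038  61308800.0              0.222
R_total = 0.241   M1 = 0.930   M2 = 0.825
```

All 10 puncta of each class are recovered as segmented objects. With the
co-localization dial at 0.5, the mean overlap attribute sits near 25% —
half the NALP3 objects overlap an LC3 object partially, half not at all —
and the pixel-level Pearson correlation is modestly positive while the
Manders coefficients are high (above the Costes thresholds, most remaining
intensity is shared). The normalized nucleus distances (~0.22 cell
equivalent radii) reflect uniform cytoplasmic placement; raising
`perinuclear_bias` lowers them.

The ΔΔCt helper turns qPCR cycle differences into fold changes:

```python
from cocompart.qpcr import fold_change
fc = fold_change(-7.0)   # 7 cycles earlier than control
print(fc.fold, fc.log2_fold)   # 128.0  7.0
```

A command-line interface wraps the same chain
(`cocompart simulate / preprocess / features / coloc / pca / lfq /
run-all`); `cocompart run-all --seed 0 --out demo/` writes OME-TIFF
scenes, ground truth, the feature table, PCA reports, colocalization and
differential-expression reports, each with a JSON provenance block.

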
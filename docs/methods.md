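# Methods

`cocompart` re-implements, as a tested and reusable pipeline, a 3D confocal
object "co-compartmentalization" analysis together with the statistical
machinery around it: synthetic ground-truthed scenes, stack preprocessing,
3D segmentation and meshing, a 16-attribute per-object feature model, PCA
with declarative gating, pixel colocalization statistics, a label-free
proteomics differential-expression chain, and comparative-Ct qPCR
arithmetic. This note records the models, the parameter choices that
matter, and the limits of what the synthetic benchmark can show.

## Synthetic scenes

A scene is one cell: an ellipsoidal membrane (default semi-axes
1700 x 2400 x 2400 nm in z/y/x) containing a concentric ellipsoidal nucleus
(900 x 1100 x 1100 nm), rasterized on an anisotropic confocal grid of
32 x 128 x 128 voxels at 140 nm axial / 40 nm lateral pitch — the voxel
geometry of a high-NA laser-scanning acquisition. Puncta are spheres in
physical units (default radius 250 ± 40 nm, the scale of inflammasome
specks and autophagosomes; integrated intensity 30 000 ± 4 000 photons),
rasterized by voxel-centre membership. Spheres were chosen because their
volume, overlap and second moments have closed forms, so every downstream
attribute has an exact oracle.

Placement is rejection sampling in the cytoplasm with a minimum
centre-to-centre separation. Two puncta of the *same* class must clear the
sum of their radii plus a 500 nm margin, so that diffraction blur cannot
fuse neighbouring puncta into a single segmented object; puncta of
*different* classes only need to not touch (they live in different
channels, but accidental voxel overlap would corrupt the co-localization
ground truth). A punctum deliberately parked on its partner cannot always
honour the full same-class margin, so the co-localization pass relaxes it
to 150 nm (and waives it entirely rather than failing a very crowded
scene); rare same-channel merges are accepted there.

Three dials produce the treatment-dependent spatial statistics the
analysis must recover:

* **aggregation** ∈ [0,1] — that fraction of a class's puncta is drawn
  around 3 class-specific cluster sites (Gaussian dispersion 450 nm)
  instead of uniformly; raising it lowers same-class nearest-neighbour
  distances.
* **perinuclear_bias** ∈ [0,1] — that fraction is placed on the nucleus
  surface pushed radially outward by the punctum radius plus a uniform
  offset within a 250 nm shell; raising it lowers the centroid-to-nucleus
  distance.
* **coloc** (per ordered class pair, f_ab ∈ [0,1]) — round(f_ab · n_a)
  class-a puncta are repositioned onto distinct class-b partners with a
  centre offset drawn uniformly in [0, r_a] and a verified voxel-level
  overlap; partner links are recorded symmetrically in the ground truth.

Counts for each dial are rounded half-up rather than sampled, so a single
scene realizes the dialled fraction exactly. Channels are rendered as the
sum of rasterized puncta convolved with the Gaussian PSF below, plus a
constant background (20 photons), Poisson shot noise and additive Gaussian
read noise (SD 2). The nucleus and cell-mask channels emulate traced
binary masks: crisp, noise-free, scaled to a nominal intensity. The
ground truth (punctum table, masks) is never blurred.

What the generator does **not** emulate: multi-cell fields, non-spherical
or textured puncta, spatially varying background, spherical aberration,
bleaching, chromatic shifts, or stage drift between slices (drift is
exercised separately in the registration tests). Passing the recovery
tests therefore shows the chain is correct and sensitive under idealized
single-cell optics, not that it is robust to every real-world artefact.

## Preprocessing

**Registration.** Slice-to-slice translational alignment: each z-slice is
aligned to the previously registered slice by sub-pixel FFT
cross-correlation (upsampled matrix-multiply DFT, factor 20), shifts
accumulate down the stack, and out-of-frame regions are zero-filled. A
constant slice gets shift (0,0) with a logged warning.

**PSF.** The vectorial point-spread function of the real instrument is
replaced by the standard Gaussian approximation: sigma_lateral =
0.21 λ/NA, sigma_axial = 0.66 λ n / NA² (defaults NA 1.4, λ 520 nm,
n 1.515 → 78 nm lateral, 265 nm axial), truncated at ±3σ and normalized
to unit sum. This is adequate at the puncta scale and keeps the forward
model analytically known. Because the kernel is separable, convolution
runs through a separable Gaussian filter rather than a dense 3D kernel.

**Deconvolution.** Richardson-Lucy with optional total-variation
regularization: multiplicative RL update, TV entering as the factor
1/(1 − λ·div(∇u/|∇u|)) per iteration (forward differences, ε = 1e-8
regularized norm, correction clamped to [0.5, 1.5] for stability), with
reflective boundaries. Defaults: 50 iterations, λ = 0.002 (both the
standalone function and the pipeline); the dial-tracking benchmarks run
25 iterations, which suffices where only rankings, not absolute volumes,
are scored. With λ = 0, RL
conserves flux for a unit-sum PSF, never goes negative, and does not
decrease the Poisson likelihood — all three are tested.

Deconvolution before segmentation is not cosmetic here: with a 265 nm
axial sigma, the thresholded halo of a blurred punctum extends several
hundred nm beyond the true sphere, and halos of *different* channels
overlap even when the true spheres are disjoint, inflating the
object-colocalization attributes. RL at 25-50 iterations removes most of
that halo and makes the co-localization dial readable at the object
level. Absolute volumetry is harder: because the axial blur is comparable
to the object size, a partially converged RL estimate still carries a
soft edge, and the global threshold cuts it at a fraction of each
object's peak that varies with object brightness and size. Run to near
convergence (~300 iterations with TV at this blur-to-object ratio) the
median single-object volume error falls within 20%; at the default 50
iterations it sits near 30%, which is adequate for detection, counting
and overlap statistics but not for calibrated volumes.

## Segmentation and meshes

Puncta channels are thresholded by Otsu's method computed *within the
cell mask only* (background outside the cell would bias the threshold);
fixed and quantile thresholds are available. Connected components are
labelled at 26-connectivity, components under 5 voxels dropped, labels
relabelled contiguously in scan order (deterministic). A marker-based
watershed split (distance-transform maxima as seeds) is provided behind a
flag, off by default. Voxel (i,j,k) is centred at ((i+0.5)dz, (j+0.5)dy,
(k+0.5)dx); all physical coordinates follow this convention.

Nucleus and membrane masks become closed triangle meshes by marching
cubes at the 0.5 iso-level (after one-voxel padding so surfaces close at
grid borders), with vertices in nm and enclosed volume from the signed
tetrahedron sum. Meshes must be watertight for distance queries. The
point-to-mesh distance is an exact vectorized point-triangle query over
all triangles (clamped barycentric projection), checked against a scalar
per-triangle scan in the tests.

## The per-object feature model

Each segmented object is described by 16 attributes plus its molecule
class and treatment label (an 18-column table): percentage of voxels
inside any partner-channel object and the number of distinct partner
objects overlapped; volume; mean and integrated intensity; ellipsoid-
equivalent major/minor axis lengths (4·sqrt(eigenvalue) of the physical-
coordinate voxel covariance), their ratio (elongation), and the six
angles between major/minor axes and x/y/z folded into [0°, 90°]; and the
centroid distances to the nuclear and cell surfaces. Distances are
normalized by the *cell equivalent radius* — the radius of the sphere
with the cell mesh's enclosed volume — making them dimensionless and
cell-size invariant. Object-level overlap is computed voxel-wise against
the partner label volume; at the 0.5 iso-level this is equivalent to
mesh-based overlap and admits an exact brute-force oracle. Intensity
attributes are measured on the registered, non-deconvolved stack by
default (deconvolution redistributes intensity); a flag switches this.
Objects with fewer than 4 voxels or a singular covariance report NaN for
the shape attributes and are dropped (with a logged count) before PCA.

The per-class spread statistic ("average object distance" — mean over
objects of the mean centroid distance to all other same-class objects) is
a condition-level summary, not a per-object column; treating it as a
17th column would break the 16-attribute table contract.

## Pixel colocalization

R_total is the Pearson correlation of two channels over the analysed
voxels, restricted to the cell mask. Costes' automatic thresholds: an
orthogonal (total-least-squares) regression ch2 ≈ a·ch1 + b, then a
threshold descending from max(ch1) in steps of (max−min)/256 until the
correlation of the voxels *below* both thresholds reaches ≤ 0; if it
never does, the descent hits the intensity floor and every voxel counts
as colocalized. A non-positive slope flags the pair as having no positive
colocalization, with undefined thresholds. Manders M1/M2 are the
above-threshold intensity fractions of each channel residing in the other
channel's positive voxels. A block-shuffling randomization p-value is
available but off by default.

## PCA, gating, group comparison

The attribute matrix is z-scored per attribute (a constant attribute
raises, naming itself), decomposed by covariance eigendecomposition, with
a deterministic sign convention (largest-magnitude loading element
positive). All 16 attributes are used by default; any subset can be
configured. Cluster sub-selection uses declarative axis-aligned
rectangular gates on a chosen (PCi, PCj) pair, optionally filtered by
treatment — a serialized, reproducible replacement for interactive
selection. Group comparisons report mean ± SD per condition, one-way
ANOVA, and Holm-Šidák-adjusted pairwise tests (Tukey by flag), with
significance flagged at P < 0.01.

## Label-free proteomics chain

The protein × sample intensity matrix (0 = not observed) passes through:
column-sum normalization (each sample scaled to the mean raw column sum);
log2 with zeros imputed as 1 — so imputed cells sit at log2 = 0, a
faithful reproduction of the upstream convention, with an
exclude-missing alternative available through the imputed-cell mask;
optional per-sample LOESS bias correction of M = sample − reference
against A = (sample + reference)/2, reference = per-protein median over
samples, span 0.4, imputed cells excluded from the fit and left
unchanged; vectorized one-way ANOVA per protein (a protein is testable
when every group keeps ≥ 2 non-imputed observations); and
Benjamini-Hochberg adjustment across testable proteins (default
significance q < 0.001; the recovery benchmarks use q < 0.05).
Two-way hierarchical clustering uses 1 − Pearson correlation distance,
complete linkage for samples and median linkage for proteins, with
deterministic tie-breaks.

The synthetic LFQ generator plants: per-protein baselines log2 ~ N(23, 2),
sample noise SD 0.25, a DE fraction (default 5%) shifted ±2 log2 units in
one random non-control group, and intensity-dependent dropout (per-cell
missing probability decreasing linearly in intensity rank, averaging the
dialled rate). Under the default study conditions (2000 proteins, 3
groups × 3 replicates) the chain reaches ≥ 0.8 sensitivity with false
discovery proportion ≤ 0.1 at q < 0.05, and null matrices stay at the
nominal level.

## qPCR

Comparative-Ct arithmetic with amplification efficiency fixed at 2:
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control,
fold = 2^(−ΔΔCt). Efficiency-corrected variants are out of scope.

## Treatment panel used in the end-to-end checks

The default panel encodes the qualitative signatures the analysis should
detect, with magnitudes chosen for detectability at the desk-scale scene
size (no quantitative effect sizes exist to match): untreated baseline;
an endotoxin-like condition with scaffold aggregation (0.7) and particle
growth (radius 330 nm, doubled intensity); and a NOD1-ligand-like
condition with full perinuclear relocation and full co-localization of
the scaffold with the autophagosome marker. Separation is evaluated as
the silhouette of treatment labels in (PC1, PC2) restricted to the
treatment-responsive scaffold class, per seed.

## Problem sizes and determinism

All randomness flows from explicit seeds through `numpy`'s Generator;
identical configuration and seed reproduce scenes, tables and reports
bit-identically. The test suite and the acceptance script run the image
chain at the default 32 × 128 × 128 grid with 10 puncta per class and
scale replication (3-20 seeds per check, 10 for the silhouette check,
2000-protein LFQ matrices) so the full run stays within a desktop-class
time budget; these sizes are stated in each check.

## Known limitations

* The Gaussian PSF under-represents the axial side-lobe structure of a
  real high-NA PSF; axial attribute accuracy on real data will be worse
  than on the benchmark.
* Otsu within the cell mask assumes bright puncta over a homogeneous
  background; strong autofluorescence gradients would need the quantile
  or fixed thresholds.
* The zero-imputation convention maps missing LFQ values to log2 = 0,
  which biases group means for proteins with many dropouts; the testable
  flag (≥ 2 observed per group) bounds but does not remove this.
* Median linkage with correlation distance (the upstream tool's choice)
  is not guaranteed monotone; dendrograms may show inversions.
* One cell per scene: population heterogeneity and cell-to-cell contact
  effects are out of scope.
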
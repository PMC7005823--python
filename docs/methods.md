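# Methods

## Problem setting

A probe-panel imaging screen compares two cell populations — a gene
knockout (KO) and its wild-type parent (WT) — across a panel of
fluorescent chemical probes, one probe per well, each reporting on a
different cellular process (lipid trafficking, organelle morphology, ion
concentrations, stress pathways).  Each probe is imaged in two technical
replicates per condition with three fields per replicate, i.e. 12
two-channel images (DNA + probe) per probe and treatment arm.  The
analysis question is: *which probes reveal a phenotype difference between
KO and WT?*  Answering it by visual inspection is slow and biased; this
package automates it with segmentation-free whole-image profiling.

## Whole-image feature bank

Per probe-channel image the bank computes exactly 923 named features on a
grid of transform planes × feature families, in the spirit of
compound-hierarchy (CHARM/WND-CHARM-style) feature sets:

* **Planes** (each contrast-stretched to [0, 1]): raw, Fourier magnitude
  (DC removed, log-compressed), wavelet approximation+detail (single-level
  `sym5`; the two bands are tiled side by side), order-20 Chebyshev
  reconstruction, Sobel edge magnitude, and the compound paths
  wavelet∘Fourier, Fourier∘wavelet and Chebyshev∘Fourier.
* **Families**: pixel statistics (7), multiscale histograms with 2/4/6/8
  bins plus a per-scale entropy (24), the 13 classic co-occurrence
  (Haralick) features direction-averaged plus direction-range at 32 grey
  levels (26), Tamura coarseness/contrast/directionality (6), Gabor
  energies of a 7-filter bank (7), Zernike moment magnitudes to degree 15
  of the Otsu-thresholded plane (72), 32-bin histograms of 2-D Chebyshev
  coefficients and of Chebyshev coefficients of the Fourier magnitude
  (32 each), Radon projection statistics at 0/45/90/135 degrees (12),
  statistics of Otsu-thresholded objects (34), and "comb" line moments —
  mean/σ/skew/kurtosis per row, column, diagonal and anti-diagonal line,
  aggregated by mean/σ/range (48).

The four texture/statistics families run on all eight planes (504
features); the remaining assignments complete the 923 total.  The grid is
exported by `feature_manifest()` and is the single source of truth for
feature order.  Degenerate statistics (correlation of a constant
co-occurrence matrix, skewness of a constant line) are imputed as 0 so
every vector is finite.

Because every plane is contrast-stretched, the bank is invariant to
absolute intensity scaling.  Whole-image features are deliberately *not*
translation-invariant; Zernike magnitudes and direction-averaged Haralick
features are invariant to exact 90° grid rotations (asserted at 1e-6).

## Segmentation comparator

The comparator follows the classical route: Gaussian smoothing + Otsu +
hole filling + 20 px minimum area segments nuclei in the DNA channel (no
declumping — synthetic nuclei never touch); cell regions are the nuclei
expanded outward up to N pixels (default N = 10), contested pixels going
to the nearest nucleus with ties to the lower label (one exact Euclidean
distance transform per nucleus).  Within each cell region, 237 per-object
measurements are taken from the probe channel: a 16-scale opening
granularity spectrum, 5 object-neighbour features, 6-ring × 3-statistic
radial intensity distribution (nucleus-centred), 16 intensity summaries
and 7-scale × 26 co-occurrence texture features.  Rows are averaged to a
237-value per-image vector; images with zero objects are dropped from
embedding with a logged count (NaN rows would poison t-SNE).

Crucially, the comparator's intensity features are computed on the *raw*
probe signal, so — unlike the contrast-stretched whole-image bank — it is
sensitive to absolute brightness, including low-intensity speckle
artifacts on unstained probes.  This asymmetry reproduces the known
failure mode in which an unstained, artifact-carrying probe outranks real
phenotypes under segmentation-based analysis.

## Feature reduction

Variance → pairwise correlation → collinearity, in that order (cheap
filters first; the three criteria are not order-defined by the problem):

* variance: on z-scored columns (pipeline default) the variance is exactly
  0 for constants and 1 otherwise, so the 1e-8 floor removes constants;
  the standalone filter uses raw variance (ddof = 1);
* correlation: greedy in manifest column order, dropping any column with
  |Pearson r| > 0.95 against an earlier retained column (deterministic);
* collinearity: iteratively drop the largest-VIF column until all
  VIF ≤ 10, VIF taken from the diagonal of the ridge-stabilised
  (λ = 1e-8) inverse correlation matrix so exact linear dependence and
  n < p cases stay finite.

Each dropped column is recorded with its stage and statistic; the
operator is idempotent and conserving (retained + dropped = input).  An
optional supervised stage (Welch t-test against a binary class label) is
off by default because a probe screen has no control-image classes.
Retained counts are data-dependent by design; no fixed output size is
asserted.

## Embedding and Dunn ranking

The reduced matrix of the whole screen is z-scored and embedded once into
2D with t-SNE (perplexity 30 clipped to (n−1)/3, PCA initialisation,
fixed seed; all recorded).  Perplexity 30 suits full-size screens
(hundreds of images); for small screens the perplexity should be on the
order of the per-condition cluster size (≈ 5 for 12 images per probe),
otherwise neighbourhoods span several probes and within-probe condition
structure is smoothed away.  For each probe, its KO and WT images form two
point sets **in the single global embedding**, and the two-cluster Dunn
index

    D = min cross-cluster distance / max within-cluster diameter

scores their separation (single-linkage δ, complete diameter Δ,
Euclidean).  Sentinels: δ = 0 → 0; both diameters 0 with δ > 0 → +inf.
Probes are ranked by descending D, ties broken by ascending SKU.  Because
t-SNE distances are not metrically faithful, the Dunn index can
alternatively be computed in the reduced feature space
(`DunnConfig(space="reduced_features")`).

Under two treatment arms, both arms are embedded **jointly** — separate
embeddings would make Dunn ratios incomparable — and
`fold_change = dunn_treated / dunn_control` per probe (control 0 with
treated > 0 → +inf; both 0 → 1).

## Synthetic screen generator

The generator renders the full screen layout (2 conditions × 2 replicates
× 3 fields = 12 images per probe and arm) with ground truth.  Defaults
are the study conditions used throughout: 44 probes, 8 true positives,
256 px fields, ~12 cells per field (Poisson), 7 px nucleus radius,
Poisson photon noise (400 photons at unit intensity) plus Gaussian read
noise (σ = 0.01) truncated at 2.5σ — a bounded sensor-noise model, so an
unstained channel stays below 3σ everywhere.

Each probe has a deterministic probe-specific "style" (base intensity
0.25–0.5, cytoplasm extent 2.3–3.3 nuclear radii, mottle texture scale and
amplitude, cell-density factor), because distinct stains look distinct:
this makes each probe occupy its own island in the embedding, as real
screens do.  Cytoplasmic stain is the per-pixel **maximum** over cell
profiles, not the sum — cells are disjoint compartments, and summing
overlapping profiles would saturate the background of bright, extended
probes and mask their puncta.  True-positive probes add a KO-side delta of
25 Poisson-mean bright puncta (radius ≈ 2.5 px, intensity 0.85) placed in
cytoplasmic annuli; a treatment arm multiplies the KO–WT delta by a
per-arm factor (default 2 for non-control arms), emulating a synergistic
small-molecule treatment.  An "artifact" phenotype (no stain; sparse
speckles at roughly 2–4.5 % of full scale, barely above the read-noise
band) models cell-impermeant probes; an optional multiplicative
background-gain difference between condition well-groups models
plate-position illumination artifacts.  The combination — no staining in
either condition, low-intensity speckles, a pure gain skew — is the
scenario in which segmentation-based analysis produces a false-positive
top rank while the contrast-stretched whole-image bank correctly treats
the probe as null: a pure gain is removed exactly by rescaling, but raw
per-object intensity means shift by the full gain factor.

Per-image random streams are derived from the master seed plus a CRC-32
hash of the image key, so the screen is a pure function of its
configuration and adding probes never perturbs existing images.

What the generator does **not** model: optical PSFs, illumination
gradients, plate/well-edge effects, cell-cycle heterogeneity, overlapping
nuclei, or probe photochemistry.  Passing tests therefore show that the
pipeline recovers phenotype differences expressible as texture/granularity
/intensity-distribution changes under realistic noise — not that it is
robust to every artefact of real microscopes.

## Problem sizes used by the test suite and reproduction script

The end-to-end checks run the full default screen (44 probes, 528 images,
256 px).  Unit and property tests use 64–128 px fields and feature-level
simulations (Gaussian probe clouds → t-SNE → ranking, 20 seeds) so the
ranking statistics can be replicated across many seeds quickly; the
segmentation-vs-whole-image comparison uses 10 seeded 5-probe screens at
128 px.

## Known limitations

* The 923- and 237-column manifests are fixed grids chosen by this
  package; only the totals and family semantics are meaningful, not any
  correspondence to a particular historic feature list.
* Dunn indices on t-SNE coordinates inherit t-SNE's distortions; ranks
  are comparable within one embedding only, and fold changes are only
  defined on a joint embedding.
* With 6-point clusters the Dunn index degenerates easily (hence the
  explicit 0/+inf sentinels).
* The reduction thresholds (0.95, VIF 10) are conventional defaults, not
  calibrated to any particular screen.
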
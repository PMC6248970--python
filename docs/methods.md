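# Methods

`radadapt` re-implements, as a tested pipeline, a radiomic-signature
workflow for predicting whether a stage-III NSCLC patient undergoing
concurrent chemoradiation will need plan adaptation (significant tumor
shrinkage requiring a new treatment plan).  The input per patient is the
planning CT volume with a manually delineated 3D tumor ROI plus nine
clinician-scored semantic features; the output is a binary prediction
(adaptive vs non-adaptive) with a full evaluation report.

## Feature extraction

All image features are computed inside the ROI mask on the voxel grid as
stored; no resampling is performed (voxel spacing is carried as metadata
only).

**First-order statistics (12).**  Computed on raw ROI intensities: mean,
population standard deviation, skewness (m3/m2^1.5) and non-excess
kurtosis (m4/m2^2, Gaussian → 3); and on an equal-width normalized
histogram over [min, max] (default 64 bins): width between the outermost
occupied bin centers, energy Σp², base-2 entropy, the absolute maximum's
height and bin-center position (ties → lowest center), the energy in a ±2
bin window around the maximum, the count of relative maxima and their
energy.  Relative maxima are plateau-aware: a maximal run of equal values
higher than both flanking values counts once, at its left edge; boundary
runs compare only their inner neighbor.  A constant ROI is degenerate:
single-bin histogram, skewness/kurtosis reported as 0 and flagged.  64
bins is a compromise: enough resolution for the peak-count features to be
informative on ~10³-voxel ROIs, coarse enough that bins are populated.

**Quantization.**  Texture features use a discrete gray-level alphabet:
equal-width binning of the ROI's own intensity range into G levels
(default 32), `level(v) = min(G, 1 + floor(G·(v−min)/(max−min)))`, level 0
outside the ROI.  Relative (per-ROI) rather than absolute binning is the
common choice when acquisition calibration across patients is not
guaranteed; G = 32 keeps 32×32 co-occurrence matrices dense for small
ROIs.

**GLCM (130 = 13 directions × 10 statistics).**  The co-occurrence matrix
at unit displacement d counts ordered level pairs (v(x), v(x+d)) over
voxel pairs with both endpoints in the ROI, normalized by the pair count;
matrices are not symmetrized.  Only one displacement per ± pair is
computed: under the both-endpoints rule GLCM(−d) is exactly GLCM(d)ᵀ and
all ten statistics are transpose-invariant, so the 26 signed unit offsets
collapse to 13 canonical directions (the canonical set keeps (0,−1,0) and
(−1,1,−1) as the representatives of their classes).  Statistics, with
gray levels indexed 1..G and marginals (μx, μy, σx, σy): energy, base-2
entropy, inertia (contrast) Σ(i−j)²p, absolute (dissimilarity) Σ|i−j|p,
inverse difference moment Σp/(1+(i−j)²), correlation (0 when either
marginal is constant), sum average Σ(i+j)p, variance — symmetrized as
½[Σ(i−μx)²p + Σ(j−μy)²p] so it is direction-flip invariant — cluster
shade Σ(i+j−μx−μy)³p and cluster prominence Σ(i+j−μx−μy)⁴p.  An ROI too
thin along d yields a zero matrix; its statistics are emitted as 0 and
flagged.

**LBP-TOP (100 = 10 configurations × 10 statistics).**  Every in-ROI
voxel whose sampling circle fits inside the volume bounds is coded in the
three orthogonal planes through it (XY, XZ, YZ).  The 8 neighbors on a
circle of radius R are sampled by bilinear interpolation of the quantized
levels; bit k is set iff neighbor ≥ center (the comparison carries a 1e-9
tolerance so interpolation round-off cannot flip an exact tie).  Codes
may be compressed by the standard mappings: u2 (58 uniform patterns + 1
pooled bin = 59), ri (36 rotation classes), riu2 (10).  Per-plane
histograms are normalized to mass 1/3 and concatenated.  The
configuration grid is radii {1,2,3} × mappings {raw, u2, ri} plus riu2 at
R = 3 — ten configurations, chosen to realize the published family size
of 100 while covering the radius/mapping axes.  Each concatenated
histogram is summarized by: mean, std, skewness, kurtosis of the bin
index treated as a random variable; the number of occupied bins ("range",
pattern diversity); energy; entropy; the maximum bin's height and index;
and the count of relative maxima (same plateau rule as above).

**Semantic features (9).**  Age (years); sex M→0/F→1; smoking
never/former/current→0/1/2, unknown→−1; T (1–4) and N (0–3) as given;
stage IIIA→0/IIIB→1; histology adenocarcinoma/squamous/NOS/unavailable
→0/1/2/3; EGFR mutated/wild-type/unknown→1/0/−1; ALK
rearranged/negative/unknown→1/0/−1.  Integer coding (not one-hot) because
the downstream learner is tree-based; ordinal fields keep their order.
The mutation evaluation is split into EGFR and ALK — the two mutations
routinely scored in this disease — to complete the nine-feature set.

The registry fixes the order: 12 first-order, 130 GLCM, 100 LBP-TOP,
9 semantic — 251 named features.

## Signature selection

An outer leave-one-out loop wraps a per-fold wrapper search; a feature's
selection frequency is the fraction of the n folds whose subset contains
it, and the signature keeps features with frequency ≥ τ (default 10%).

The wrapper is a best-first forward search over the subset lattice.  The
objective for a candidate subset is the accuracy of a random forest under
stratified 2-fold cross-validation of the fold's training rows, averaged
over 5 independently drawn splits — a single split's accuracy on ~60 rows
has a standard error of several percent, and averaging repeated splits
keeps chance improvements from steering the search.  The search expands
the best unexpanded subset (children add one unused feature each),
accepts a new global best only when it improves the objective by at least
0.005, and stops after 5 consecutive expansions without a new global
best, returning the best subset found.  The empty subset scores the
majority-class baseline, so a table with no usable feature can yield an
empty signature.  Ties break by registry order; all randomness (splits,
forest seeds) derives from the run seed with per-fold offsets, so a rerun
reproduces the per-fold subsets exactly.

The inner forest is a compiled (numba) CART/gini bootstrap random forest
— trees grown to purity, ⌊√p⌋ split candidates per node, majority vote.
A selection run needs on the order of 10⁵ forest fits, which demands a
per-fit cost in the tens of microseconds; the compiled forest is
cross-checked against scikit-learn's RandomForestClassifier in the test
suite.  Its default size is 100 trees; the simulations below use 20.

### What the planted-signal simulations show — and a caveat

On tabular cohorts with k informative columns at effect size d, the
pipeline behaves as expected at the extremes: with d = 0 the
leave-one-out AUC is at chance level, with d = 3 it exceeds 0.9, and
informative columns receive high selection frequencies.  A stricter
property — *every* informative column's frequency above *every* noise
column's at n = 60, p = 50, k = 5, d = 1.5 — does not hold reliably, and
measurement shows why it cannot: evaluated at high precision (40 repeated
splits), a third to two-thirds of the 45 noise columns score above adding
the weakest informative column to the four stronger ones.  At n = 60 a
noise column's chance class-correlation can carry more within-sample
cross-validation value than a fifth, largely redundant, d = 1.5 signal;
and because leave-one-out training sets share all but one row, such
columns recur across folds.  This is a property of wrapper selection at
small n, not of any particular search strategy — users should read
selection frequencies as a ranking, not as a clean signal/noise
separator.

## Classification and evaluation

The final classifier is scikit-learn's random forest (default 500
bootstrapped trees, m = ⌊√p⌋ < p split candidates per node).  Evaluation
pools the out-of-fold positive-class probabilities — the fraction of
trees voting "adaptive" — of a leave-one-out cross-validation into one
ROC.  Reported metrics: trapezoidal AUC (ties at midpoint; equal to the
Mann-Whitney statistic), and at the 0.5 vote threshold accuracy,
precision, sensitivity, specificity.  Predictive values are adjusted by
Bayes' rule to an assumed prevalence π (default 0.40, the literature rate
of significant tumor shrinkage during chemoradiation):
ppv = sens·π/(sens·π+(1−spec)(1−π)), npv = spec(1−π)/(spec(1−π)+(1−sens)π).
At π equal to the sample prevalence the adjusted PPV reduces to the raw
precision.  95% intervals are Wald, p ± 1.96√(p(1−p)/n) with n the number
of pooled predictions, and Hanley–McNeil for the AUC.

The .632+ bootstrap error uses B replicates (default 200): resubstitution
error err̄ of a forest trained on the full table; leave-one-out bootstrap
error ε̂0 (per row, the mean error over replicates where the row is
out-of-bag; rows never out-of-bag are excluded); no-information rate
γ = Σ_k p̂_k(1−q̂_k); relative overfitting R = (ε̂0−err̄)/(γ−err̄) clipped to
[0,1] (0 when the denominator is ≤ 0); weight w = 0.632/(1−0.368R);
estimate (1−w)·err̄ + w·min(ε̂0, γ).

## Synthetic data

The phantom generator emulates the study's two-class cohort so the whole
pipeline is testable without clinical data.  Defaults mirror the
91-patient cohort: class sizes 50/41; semantic categories at the cohort's
frequencies (male 76%, stage IIIB 40%, histology 43/47/7/3%, age ~
N(71, 9.6²)); categories the cohort table does not report (smoking, T, N,
mutation rates) use values typical of a stage-III NSCLC population and
are identical in both classes, so phantom class signal is purely
textural.  Each phantom is a 48³ volume of Gaussian background with an
ellipsoidal ROI (semi-axes 8–14 voxels).  Tumor texture superimposes a
two-component blob mixture (Gaussian-smoothed noise field at σ = 1.5,
thresholded at its ROI median — sharp internal boundaries) on a smooth
σ = 3 drift (3–7 HU) plus 3 HU voxel noise.  The per-patient blob
strength s scales a 15 HU full contrast and is drawn from overlapping
class ranges: s ~ U(0.3, 1.3) for adaptive, s ~ U(0, 0.85) for
non-adaptive (s = 0 being the purely smooth, homogeneous tumor).  The
overlap is deliberate calibration: with ~5·10³ voxels per ROI, texture
features have tiny estimation error, so any categorical class difference
would separate phantoms perfectly; drawing the heterogeneity strength
from overlapping distributions puts the pipeline in the realistic
imperfect-separation regime (class-discrimination ceiling
P(s_adaptive > s_non-adaptive) ≈ 0.82; pooled LOO AUC on cohorts of a
few dozen phantoms scatters roughly between 0.7 and 0.95 around it).
What phantoms
do not model: CT physics (beam hardening, partial volume), inter-scanner
variation, semantic–outcome association, and feature–feature correlation
structure of real tumors — so green pipeline tests demonstrate
correctness of the computations, not clinical performance.

The tabular generator draws k informative columns at N(d, 1) vs N(0, 1)
by class and the rest N(0, 1), with names drawn from the real registry.

## Run sizes and numerical choices

Simulation-backed tests and the acceptance script use test-scale forest
settings — 20-tree wrapper forests with 5-fold split averaging, 200-tree
final forests, B = 50 bootstrap replicates, 25-phantom end-to-end cohorts
— chosen so a full run completes in minutes on one CPU; the statistical
properties they check are scale-robust.  Production defaults (100/500
trees, B = 200) live in `RunConfig`.  Degenerate inputs are defined, not
errors: constant ROIs, ROIs too thin for a GLCM direction, and volumes
too small for an LBP circle all yield flagged zero features.  Float
comparisons at decision boundaries (LBP ties, selection threshold τ)
carry explicit tolerances so results do not depend on round-off.

## Known limitations

The exact inventory of the original tool's 10 GLCM statistics and the
LBP configuration grid are reconstructions constrained by the published
family sizes (130 and 100); the original wrapper's search strategy,
stopping rule and inner metric are likewise not public, so published
per-feature frequencies are not expected to reproduce exactly.  The
published sensitivity CI is not a Wald interval at any defensible n; this
package emits Wald-at-n for all proportion metrics.  DICOM series
assembly and RT-STRUCT parsing are out of scope — convert to NIfTI/NRRD
upstream.
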
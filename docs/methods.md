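# Methods

## Problem and pipeline

The pipeline classifies image patches of H&E-stained early-stage ER+
breast cancer into Oncotype DX (ODx) risk categories from nuclear
morphology alone, then aggregates patch calls into a per-patient risk
prediction. ODx recurrence scores (0–100) are bucketed low (≤ 17),
intermediate (18–30), high (≥ 31); modified Bloom–Richardson (mBR)
grades (3–9) are bucketed low (4–5), moderate (6–7), high (8–9), with a
grade of 3 mapped to low as a below-range convention. Cases whose ODx
category and mBR bucket sit at opposite extremes (low/high or high/low)
are excluded before modeling. Four classification tasks are supported:
concordant extremes only (LLvsHH), low vs high (LvsH), low vs
intermediate+high (LvsIH), and low+intermediate vs high (LIvsH); the
positive label is always the higher-risk side, so AUC > 0.5 always
means risk-concordant scoring.

## Feature catalog

216 features per tissue compartment, computed once for epithelial and
once for stromal nuclei (432 per patch), or once over all nuclei in the
pooled ablation mode (216).

**Architecture (116).** Unless noted, each measurement set is summarized
by mean, population standard deviation, min/max ratio, and the disorder
statistic 1 − 1/(1 + σ/μ) (equal to σ/(μ+σ); 0 for perfectly regular
sets, → 1 with high relative variability; defined as 0 when μ = 0).

- *Voronoi (12):* cell area, perimeter, and chord lengths (all
  vertex-pair distances per cell) over cells lying strictly inside the
  patch. Cells touching the boundary are dropped because clipped or
  unbounded cells bias area statistics; fewer than 5 usable cells makes
  the family undefined.
- *Delaunay (8):* edge lengths and triangle areas of the triangulation.
- *MST (4):* edge lengths of the exact Euclidean minimum spanning tree
  built on the complete distance matrix.
- *Nearest neighbors (27):* neighbor counts within 10/20/30/40/50 px
  (mean, SD, disorder), distance to the 3rd/5th/7th nearest neighbor
  (mean, SD, disorder), global density, and mean/SD of the 1-NN
  distance. Radii are native 40× pixels (≈ 0.25 µm/px).
- *Cell cluster graph (39):* deterministic distance-decay rule — edge
  (u,v) iff d(u,v)^−α > r, i.e. d < r^(−1/α); defaults α = 0.5,
  r = 0.2 (25 px). Statistics: node/edge counts, density, degree
  summary, eccentricity summary with 90th-percentile variants (over the
  90 % of nodes with smallest eccentricity in the largest component),
  average and SD of shortest-path lengths, clustering coefficients
  C (global transitivity), D (mean local clustering, isolated nodes
  contributing 0), E (mean local clustering over nodes of degree ≥ 2),
  component structure (count, giant ratio, sizes, isolated/end/central
  node counts and fractions), edge-length statistics including skewness
  and kurtosis, and adjacency-spectrum measures (spectral radius,
  second-largest magnitude, graph energy, distinct eigenvalues at 1e-8
  tolerance, and the log–log slope of the top half of the magnitude
  spectrum).
- *Cell orientation co-occurrence entropy (26):* nuclear principal-axis
  orientations quantized into eight 22.5° bins on [0°, 180°); for the
  CCG edge set and for a 40 px proximity graph, the symmetric normalized
  co-occurrence matrix of bin pairs over connected nuclei yields 13
  second-order statistics (contrast energy/inverse moment/average/
  variance/entropy, intensity average/variance/entropy, entropy, energy,
  correlation, information measures 1 and 2; logs base 2, zero-edge
  graphs give all-zero statistics by convention).

**Shape (100).** 25 per-nucleus descriptors aggregated by mean, SD,
median, and min/max ratio. The boundary is resampled to 128
equal-arc-length points before any radial or Fourier computation, which
removes vertex-density dependence. Descriptors: area ratio
A/(πR²max), perimeter ratio P/(2πReq), distance ratio (mean radial
distance / Rmax), radial SD and variance, smoothness (mean absolute
deviation of each radial distance from its neighbors' average),
length/width ratio (square root of the principal second-moment ratio),
Hu invariant moments 1–7, box-counting fractal dimension of the
boundary (5 dyadic scales on a 128-px grid), and Fourier descriptor
magnitudes of harmonics 1–10 normalized by harmonic 1. Geometric
moments of the filled polygon are computed exactly by triangle
decomposition with closed-form simplex integrals, so Hu invariance
holds to machine precision; "Invariant Moment k" means Hu's k-th
invariant and "Fourier Descriptor k" the normalized magnitude of
harmonic k.

Numerical conventions: coincident centroids (< 1e-6 px) are merged
before graph construction; population (not sample) standard deviations
are used throughout for stability on small compartments; the min/max
ratio is computed on magnitudes (identical for the non-negative
architecture measurements, bounded in [0, 1] for signed descriptors)
and snaps to 1 when the set is constant up to rounding noise; families
whose preconditions fail are NaN; a compartment with fewer than 5
nuclei yields a NaN half-vector and the patch is excluded from
modeling.

## Ranking, classification, voting

Rankers operate on z-scored training-fold data only. Rank-sum orders
features by two-sided Wilcoxon p-value (exact Mann–Whitney null for
small tie-free samples, tie- and continuity-corrected normal
approximation otherwise; constant features get p = 1), with ties broken
by |z| then catalog order. PLS-VIP fits a two-component projection to
latent structures of the binary label on standardized features and
ranks by VIP_j = √(p Σk SSk (w_jk/‖wk‖)² / Σk SSk); the identity
(1/p) Σ VIP² = 1 holds by construction. MRMR discretizes each feature
at μ ± σ into three levels, then greedily selects by mutual-information
relevance minus (MID) or divided by (MIQ, ε = 1e-12) mean redundancy
against the selected set; ties resolve by catalog order.

Classifiers: random forest (50 entropy-split trees, no depth cap — the
closest scikit-learn analogue of a bagged C4.5 ensemble, which uses
gain-ratio splits not available there), a four-hidden-layer × 10-node
logistic MLP trained with L-BFGS (full-batch training is the reliable
choice at these sample sizes; "3 kernel SVM" is read as a degree-3
polynomial kernel, with margins squashed through a logistic to [0, 1]),
and LDA with the SVD solver (pseudo-inverse behavior on rank-deficient
covariance). All scores are probabilities of the positive class; a
patch is called positive at score ≥ 0.5.

Cross-validation: 100 iterations (configurable) of randomly initialized
3-fold splits made at the patient level, so no patient contributes
patches to both sides of a fold — asserted, not assumed. Per fold:
standardization fit on training patches, ranker run on training patches,
top-10 features selected (the count is unstated upstream; 10 is the
default and configurable), classifier fit, held-out patches scored.
Iteration AUC is computed on the pooled out-of-fold scores (chosen over
per-fold averaging; both conventions exist) and reported as mean ±
population SD across iterations.

Voting: a patient's fraction of positive patches is compared with a
threshold that maximizes training-patient accuracy, swept over the
midpoints of consecutive sorted unique training fractions plus {0, 1};
"surpassing" is inclusive (≥) and accuracy ties resolve to the smallest
candidate. The threshold is learned per fold on training patients only.
External validation freezes standardization, ranking, classifier, and
threshold on the full primary cohort and applies them once, without
retraining, to a cohort with disjoint patient ids.

## Synthetic cohorts

The generator emulates 40× patches (0.25 µm/px) containing epithelial
nests in stroma. Epithelial centroids follow a Thomas process (Poisson
parents, Gaussian offspring with SD `cluster_spread`); the epithelium
mask is the union of nest hulls dilated by the nuclear radius plus a
spread margin; stromal centroids are homogeneous Poisson points thinned
to the mask complement. Nucleus boundaries are ellipses of preserved
area πr² with axis ratio ~ N(mean, sd) clipped at 1, orientation from a
von Mises law on the half-circle (κ = 0 gives uniform), and one random
low-order harmonic (order 2–4) radial perturbation of relative
amplitude `boundary_irregularity`. Patches with fewer than 5 nuclei in
either compartment are regenerated, up to 20 retries, from sub-seeds
hashed from (seed, patient, patch, attempt); all output is a pure
function of the configuration and seed.

Defaults were chosen once to be tissue-plausible at desk scale: 448 px
patches, nest intensity 700/mm², ~8 nuclei per nest, stromal intensity
6000/mm², nuclear radius 8 px; the low-risk-like phenotype uses
cluster spread 15 px, irregularity 0.02, axis ratio 1.3 ± 0.1, κ = 3,
the high-risk-like phenotype spread 45 px, irregularity 0.25, axis
ratio 1.8 ± 0.4, κ = 0. The patch edge and stromal density ensure both
compartments usually retain at least five interior Voronoi cells.
Continuous phenotype parameters receive per-patient log-normal jitter
(SD 0.2): real cohorts are heterogeneous, and without inter-patient
variability any parameter gap between classes is trivially separable.
ODx scores are drawn uniformly within each class's interval and mBR
scores within concordant buckets, so labels and scores stay consistent
with the categorization rules by construction.

The compartment-separation ablation uses cohorts in which only stromal
nuclear shape differs (irregularity 0.08 vs 0.13, shared epithelium,
stroma a minority compartment at 3000/mm²), at 14 patients/class × 3
patches of 384 px with 3 CV iterations per mode. Two design points
matter. First, the gap is moderate so neither feature mode saturates at
AUC 1.0 — at full-strength gaps the separated-vs-pooled contrast
disappears into the ceiling. Second, the shared epithelial irregularity
is set to the midpoint (0.105) of the two stromal values: otherwise the
class difference changes the within-patch EP–ST shape contrast, which
pooled dispersion aggregates (SD, min/max ratio across all nuclei)
detect at full strength, bypassing dilution. With the midpoint design,
pooled within-patch dispersion is class-independent by construction and
pooling can only access the diluted mean shift — which is precisely the
effect compartment separation is supposed to recover.

What passing synthetic tests does and does not show: the generator
reproduces the statistical structure the features target (clustering,
pleomorphism, orientation coherence, compartmentalization) but not
stain variability, scanner differences, texture/chromatin patterns,
mitoses, tubules, or lymphocytes; recovery of synthetic effects
demonstrates that the pipeline measures what it claims and leaks no
label information, not that real-cohort accuracies are reproduced.
Study sizes in the test suite and acceptance script (30 patients/class
× 10 patches for effect recovery, 30 patients for the null, 25 ablation
replicates) were fixed as the package's own desk-scale study design.

## Known limitations

- The deep-learning segmentation and epithelium/stroma models of the
  original workflow are out of scope; the classical segmenter is a
  stand-in for rendered or H&E-like images, and external DL outputs are
  ingested as label masks/GeoJSON unchanged.
- The exact published 216-item feature enumeration is not printed in
  full anywhere public; the catalog here matches the family structure
  and all published feature names, with the remaining composition
  pinned as defaults.
- CCG construction parameters and the C/D/E clustering-coefficient
  definitions live in cited prior work; the defaults above are pinned
  and configurable.
- Whether features were ranked jointly over both compartments or
  separately is unstated; joint ranking over all 432 is implemented.
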
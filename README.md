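# nucmorph

Quantitative nuclear histomorphometry for early-stage ER+ breast cancer.

Pathologists grade breast tumors partly by how nuclei look and how they
are arranged; gene-expression assays such as Oncotype DX (ODx) produce a
0–100 recurrence score that drives chemotherapy decisions but is slow,
expensive, and tissue-destructive. This package implements an
image-analysis pipeline that asks how far computer-extracted nuclear
morphology from routine H&E patches can predict ODx risk categories
(low ≤ 17, intermediate 18–30, high ≥ 31):

1. **Nuclei in, compartments assigned.** Segmented nuclei enter as
   GeoJSON polygons or label masks (a classical color-deconvolution +
   watershed segmenter is included for rendered images); each nucleus is
   assigned to the epithelial or stromal compartment against a binary
   epithelium mask.
2. **216 features per compartment, 432 per patch.** Architecture (116):
   Voronoi cell, Delaunay triangle, and minimum-spanning-tree
   statistics, nearest-neighbor counts and distances, cell cluster
   graphs (edge rule: connect u,v iff d(u,v)^−α > r), and cell
   orientation co-occurrence entropy. Shape (100): mean / SD / median /
   min-max ratio over 25 per-nucleus descriptors (area and perimeter
   ratios, radial statistics, smoothness, length/width ratio, Hu
   invariant moments 1–7, fractal dimension, Fourier descriptors 1–10).
   The dispersion summary used throughout is the disorder statistic
   1 − 1/(1 + σ/μ).
3. **Rank, classify, vote.** Four feature rankers (Wilcoxon rank-sum,
   PLS-VIP, MRMR-MID, MRMR-MIQ) and four classifiers (bagged random
   forest, 4×10 neural network, degree-3 polynomial SVM, LDA) are
   evaluated under 100 iterations of patient-grouped 3-fold
   cross-validation — ranking, standardization, and threshold learning
   all happen inside training folds. Per-patch scores are aggregated to
   a per-patient call by comparing the fraction of positive patches to
   a threshold learned on training patients.

The study cohort behind the original analysis is not public, so a
seeded synthetic generator produces patches with the same statistical
structure: Thomas-process epithelial nests in Poisson stroma, elliptical
nuclei with tunable pleomorphism and orientation coherence, and
ODx/grade labels consistent with the phenotype.

## Worked example

```python
from nucmorph.synthetic import SyntheticCohortConfig, generate_cohort
from nucmorph.pipeline import (
    build_experiment, extract_feature_table, modeling_matrix,
)
from nucmorph.classify import ClassifierSpec, CVConfig, cross_validate

cases = generate_cohort(
    SyntheticCohortConfig(n_patients_per_class=8, patches_per_patient=3, seed=7)
)
table = extract_feature_table(cases)            # 48 patches x 432 features
_, labels = build_experiment(cases, "LvsH")     # low vs high ODx, positive = high
X, y, pids, names = modeling_matrix(table, labels)
result = cross_validate(
    X, y, pids, names,
    ClassifierSpec(kind="random_forest", seed=7),
    CVConfig(n_iterations=3, ranker="ranksum", seed=7),
)
print(f"AUC {result.auc_mean:.3f} +/- {result.auc_std:.3f}, "
      f"voting accuracy {result.voting_accuracy_mean:.3f}")
```

prints

```
AUC 0.983 +/- 0.013, voting accuracy 0.938
```

AUC is the probability that a randomly chosen high-risk patch scores
above a randomly chosen low-risk one (0.5 = chance); the voting accuracy
is the fraction of patients whose risk category the patch-percentage
vote calls correctly. On this deliberately strong-effect cohort
(tighter nests, smoother nuclei, coherent orientations in the low-risk
class) the pipeline recovers the phenotype almost perfectly.

The `analysis/` scripts run the same steps as a narrative sequence:
`01_simulate_cohort.py` → `02_extract_features.py` →
`03_rank_and_classify.py` (ranker × classifier grid) →
`04_compartment_ablation.py` (separated vs pooled compartments) →
`05_external_validation.py` (frozen model on a disjoint cohort). Data
land under `scratch/`, tables under `results/`.

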
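# immunokit

Statistical tools for quantifying age-related remodelling of immune tissue and
its reversal, built around the analyses used to study thymic rejuvenation:
spatial cell–cell interaction statistics, graph heat-kernel tissue-region
segmentation, hierarchical cell typing, ligand–receptor communication scoring,
T-cell-repertoire diversity and antigen-specific gating, inverse
age-calibration of vaccination responses, and small assay summaries
(TREC −ΔCt, pharmacokinetic AUC). A seeded synthetic-data module generates
every fixture the statistics are validated against.

## The scientific problem

Aging degrades the thymic niche: cortical/medullary thymic epithelial cells
(cTEC/mTEC) lose contact with developing T cells, stromal ligand expression
(e.g. Notch ligands) declines, T-cell clonal diversity collapses, and
vaccination responses weaken. Quantifying these effects — and whether a
treatment restores them — requires statistics over imaging-based spatial
transcriptomics, single-cell expression, TCR repertoires, and calibration
cohorts. `immunokit` implements those estimators with explicit null models and
uncertainty.

## Models and statistics

**Spatial interaction Z** (`immunokit.spatial`). For cell types *a, b* on one
array, let C(r) be the number of cross-type pairs within r µm. With
r_obs = 50 and r_null = 150,

    expected = C(r_null) · (r_obs / r_null)²,
    Z = (C(r_obs) − expected) / √expected.

Under complete spatial randomness pair density scales with neighbourhood area,
so the area ratio converts the outer count into the inner null expectation; a
label-permutation null is available as a cross-check
(`ZConfig(null_mode="permutation")`). Z trajectories across ages are tested
with Pearson's r.

**Region segmentation** (`immunokit.niche`). Expression is smoothed by the
random-walk heat kernel exp(−t·L_rw), t = 10, on the Delaunay graph of cell
positions (computed per connected component via the symmetric-Laplacian
eigendecomposition), then PCA + k-means labels tissue regions.

**Cell typing** (`immunokit.celltypes`). QC removes cells with fewer than two
reads or expressed in fewer than two genes; counts are median-total
normalised, log1p-transformed, and scaled; hierarchical k-means (k = 24 at
level 1 on a 19-gene panel) assigns clusters to types by maximal mean marker
signature, with nested level-2/3 refinement (15-marker T-cell panel).

**Ligand–receptor scoring** (`immunokit.ligand_receptor`). An interaction's
score at one age is ½(mean ligand over sender cells + mean receptor over
receiver cells) on log-normalised expression; significance by label
permutation within the age group, p = (1 + #{perm ≥ obs})/(n_perm + 1). Age
trends use Spearman rank correlation with exact enumeration p for ≤ 9 ages and
Bonferroni correction over the tested interactions.

**Repertoire** (`immunokit.repertoire`). Clones are called on CDR3 amino-acid
junctions (paired chains when present); Shannon diversity H = −Σ p ln p with
bootstrap downsampling for depth matching; ADT tags are CLR-normalised
(log1p(x) minus per-tag mean) and antigen-specific (Tet+) cells gated at
CLR > 1.7.

**Inverse age calibration** (`immunokit.immunoage`). A quadratic
response = a + b·age + c·age² is fitted by OLS to a calibration cohort
(residual d.f. = n − 3), with pointwise 95% confidence bands
mean ± t·√(x₀ᵀ Cov x₀). Inverting the curve maps an animal's observed response
to its *immunological vaccination response age*; groups are compared with a
pooled two-sample t-test.

## Worked example

```python
from immunokit.simulate import TissueSimConfig, gen_aging_series
from immunokit.spatial import SpatialInteractionModel

cfg = TissueSimConfig(n_cells_per_type={"T cell": 300, "cTEC": 300},
                      attraction={("T cell", "cTEC"): 0.8}, seed=11)
ages = [8.0, 16.0, 24.0, 32.0, 40.0, 52.0]
schedule = {8.0: 0.8, 16.0: 0.64, 24.0: 0.48, 32.0: 0.32, 40.0: 0.16, 52.0: 0.0}
maps = gen_aging_series(cfg, ages, schedule)
res = SpatialInteractionModel(maps, pairs=[("T cell", "cTEC")]).fit()
print(res.summary())
```

```
Spatial interaction Z-scores
  null: area (r_obs=50.0 um, r_null=150.0 um)
type_a type_b    age  observed  expected  null_sd      z
T cell   cTEC  8.000   187.000    35.444    5.954 25.456
T cell   cTEC 16.000   168.000    32.889    5.735 23.560
T cell   cTEC 24.000   120.000    24.778    4.978 19.130
T cell   cTEC 32.000    80.000    22.111    4.702 12.311
T cell   cTEC 40.000    46.000    16.111    4.014  7.446
T cell   cTEC 52.000     9.000    10.333    3.215 -0.415
```

The engineered decline in T cell–cTEC attraction shows up directly as a
falling Z. Calibration works the same way:

```python
from immunokit.simulate import CohortSimConfig, gen_age_response_cohort
from immunokit.immunoage import QuadraticCalibration

cohort = gen_age_response_cohort(CohortSimConfig(seed=3))
curve = QuadraticCalibration.from_dataframe(cohort).fit()
print(curve.summary())
print(curve.invert(5.0))
```

```
Quadratic age-response calibration (OLS)
  n = 32, residual d.f. = 29, R^2 = 0.9440
  response = 14.45 + -0.273*age + 0.001355*age^2
  calibration age range: 8-76 weeks
```

and `curve.invert(5.0)` returns an estimated age of 44.4 weeks
(`root_status="unique"`).

Every analysis follows the same shape: a `Model` class whose `fit()` returns a
`Results` object with `summary()` (and `plot()` where a figure makes sense).
A `click` CLI wraps the library: `ikit simulate|zscore|ztrend|regions|type|
lr|lrtrend|clones|diversity|gate|immunoage|assay`.

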
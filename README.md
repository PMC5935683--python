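# oligosnf

Integrative molecular subtyping and risk stratification of colorectal
liver metastases (CRCLM), built as a tested, reusable pipeline.

A minority of patients with liver-limited metastatic colorectal cancer are
cured by hepatic resection — the oligometastatic state. This package
implements the analysis used to identify that state molecularly: paired
mRNA and miRNA expression profiles are merged by **similarity network
fusion (SNF)** into one patient-similarity network, the network is
partitioned by spectral clustering into three molecular subtypes, the
association of subtypes with overall survival is tested against a
permutation null, subtype markers feed a nearest-centroid classifier, and
the subtypes are crossed with the **Clinical Risk Score (CRS)** into a
three-tier integrated risk classification. Because the matching patient
data are controlled-access, a synthetic-cohort generator with planted
subtypes, subtype-dependent survival, CRS features, mutations and
recurrence patterns makes every stage testable end to end.

## The method

For each platform (view) *v*, Euclidean distances on z-scored features
define a scaled exponential kernel

    W_v(i,j) = exp( -d²(i,j) / (μ · ε(i,j)) ),
    ε(i,j) = ( mean_K(i) + mean_K(j) + d²(i,j) ) / 3,

where `mean_K(i)` is the mean squared distance from sample *i* to its K
nearest neighbors (defaults K = 20, μ = 0.5). Each kernel yields a full
transition matrix `P_v` (row-stochastic, half-mass diagonal) and a sparse
K-nearest-neighbor kernel `S_v`. Cross-diffusion iterates

    P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ        (T = 20 rounds),

re-normalizing after each round; the fused network is the symmetrized,
normalized average of the views. Subtypes are the normalized-Laplacian
spectral clustering of the fused network at k = 3 (the eigengap diagnostic
is always reported). Survival contrasts use Kaplan–Meier curves, the
k-group log-rank test and Cox proportional-hazards regression; the
permutation test re-runs the entire fuse → cluster → log-rank pipeline on
B randomized cohorts and reports p = (1 + #{perm ≥ obs}) / (1 + B).

CRS counts five adverse features (disease-free interval < 12 months, > 1
metastasis, size > 5 cm, node-positive primary, high CEA); low CRS means
a score below 2. Integrated risk: subtypes 1/2 with low CRS → low risk;
subtype 2 with high CRS or subtype 3 with low CRS → intermediate;
subtypes 1/3 with high CRS → high.

## Worked example

```sh
oligosnf simulate --out cohort --seed 17
oligosnf fuse --mrna cohort/mrna.tsv --mirna cohort/mirna.tsv --out fused.tsv
oligosnf cluster --fused fused.tsv --k 3 --seed 17 --out labels.tsv
oligosnf survival --clinical cohort/clinical.csv --labels labels.tsv --out surv.json
oligosnf risk --clinical cohort/clinical.csv --labels labels.tsv --out risk.tsv
```

which prints (abridged):

```
wrote cohort of 120 samples to cohort
fused network (120 samples) -> fused.tsv
k=3 labels -> labels.tsv (eigengap best k = 3, runner-up 2)
log-rank p = 0.002349 -> surv.json
risk tiers: {'high': 65, 'low': 28, 'intermediate': 27} -> risk.tsv
```

The simulated cohort plants three expression subtypes (default mixing
33/28/39%) in both platforms; the eigengap confirms three clusters, the
log-rank p-value reflects the planted subtype hazard ratios (1.0, 0.45,
1.6 around a 0.018/month baseline), and the risk table crosses each
patient's subtype with their CRS class. `oligosnf permtest` adds the
permutation significance of that survival association, and
`oligosnf classify` trains and applies the subtype marker classifier.
The same operations are importable from Python (`import oligosnf`).

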
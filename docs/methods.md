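# Methods

## Problem setting

`oligosnf` reconstructs an integrative subtyping analysis of colorectal
liver metastases (CRCLM): given paired mRNA and miRNA expression for the
same patients plus clinical follow-up, find molecular subtypes, quantify
their association with overall survival (OS), and combine them with the
Clinical Risk Score (CRS) into a three-tier prognosis. The cohorts such an
analysis runs on are controlled-access, so the package ships a synthetic
cohort generator whose planted structure serves as ground truth for every
stage; all quantitative claims in the test suite are claims about this
synthetic world.

## Similarity network fusion

Each platform is reduced to a patient-similarity network. Distances are
Euclidean on per-feature z-scores (z-scoring is on by default, standing in
for whatever platform normalization preceded the analysis; zero-variance
features are dropped with a warning). The affinity kernel is the scaled
exponential similarity

    W(i,j) = exp( -d2(i,j) / (mu * eps(i,j)) ),
    eps(i,j) = ( mean_K(i) + mean_K(j) + d2(i,j) ) / 3,

where `d2` is the squared distance and `mean_K(i)` the mean squared
distance from `i` to its K nearest neighbors. Working in squared
distances makes the kernel exactly invariant to uniform rescaling of the
inputs, a property the pipeline relies on (it lets the permutation stage
permute precomputed distance matrices). Duplicate samples would zero the
local scale; `eps` is floored at machine tolerance instead of rejecting
them, so subsampling/consensus procedures never hard-fail.

Two operators derive from `W`: the full transition matrix
`P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k))` with `P(i,i) = 1/2`, and the
sparse KNN kernel `S` (row-normalized over each sample's K strongest
neighbors, ties at the K-th neighbor broken by sample order for
determinism). Note `P` is a fixed point of its own normalization — the
off-diagonal mass is exactly 1/2 after one pass — so re-normalization is
guarded by an explicit state check rather than by observable corruption.

Fusion iterates `P_v <- S_v . mean_{u != v}(P_u) . S_v^T` for T rounds,
re-normalizing each view per round, then averages the views, symmetrizes
and normalizes. Defaults K = 20 (capped at n/3), mu = 0.5, T = 20 — the
published recommended ranges for this family of methods; the analysis this
package reconstructs does not state its values, so all three are
configurable. A single-view "fusion" returns the view's transition matrix
unchanged (logged), which keeps single-platform baselines on the same code
path.

## Subtyping

The fused network is partitioned by normalized-Laplacian spectral
clustering: bottom-k eigenvectors, row-normalized, then k-means. k-means
uses 50 restarts seeded from the caller's seed; because the permutation
test re-clusters hundreds of fused networks, the restarts are implemented
as a vectorized Lloyd iteration over a (restarts, n, k) tensor rather than
repeated calls into a general-purpose library (the test suite checks
agreement with scikit-learn's k-means on separable data). Labels are
renumbered canonically (cluster 1 holds the lowest-index sample), so the
same input always yields the same labeling. The pipeline fixes k = 3 —
the subtype count the analysis is built around — and always reports the
eigengap ranking of candidate k (ties to the smaller k) as a diagnostic.
Consensus clustering (default 100 resamples at 80% subsampling, settings
unstated in the original analysis) quantifies stability as co-clustering
frequencies and can operate either on re-fused subsamples or on subsets of
one fused network; both modes exist because the original's procedure is
ambiguous between them.

Cluster numbers carry no intrinsic subtype identity. Where planted truth
exists, `match_to_reference` renames clusters by maximum-overlap
assignment — the synthetic analogue of naming discovered subtypes by
their molecular characterization.

## Survival and categorical statistics

Kaplan–Meier curves, the k-group log-rank test (hypergeometric covariance,
chi-square with k-1 df) and Cox proportional-hazards regression are
implemented in the package: they sit inside the permutation loop and the
risk stratification, and the tests pin them to hand-computed values,
brute-force oracles and lifelines. Cox fitting is Newton–Raphson with
step-halving on the partial likelihood, Breslow ties by default (adequate
at cohort scale) with Efron available; convergence at 1e-8 relative
change; monotone likelihood (perfect separation) raises an explicit error
advising penalization rather than returning a divergent estimate. The
score test at beta = 0 is exposed separately; for a binary covariate with
untied times it coincides with the two-group log-rank statistic, which the
tests verify numerically. Ten-year OS is read as the KM step function at
120 months. Fisher's exact test, the Pearson chi-square test and
Benjamini–Hochberg adjustment delegate to scipy/statsmodels; all p-values
are two-sided.

## Permutation significance

The null hypothesis concerns the clustering *procedure*: could fuse →
cluster → log-rank produce the observed OS separation by chance? Each of
B permutations therefore re-runs the entire pipeline; observed clusters
are never reused. The default null permutes the miRNA-to-sample
assignment, destroying cross-platform structure while preserving each
platform's marginal distribution and the mRNA–clinical linkage. Because
distances depend only on each platform's own columns, the permuted miRNA
distance matrix is the observed one reindexed (`D'[i,j] = D[pi(i),pi(j)]`),
and the pipeline permutes the precomputed matrix — an exact identity, not
an approximation, verified by a test. The empirical p-value uses the
add-one correction `(1 + #{perm >= obs}) / (1 + B)`, so p >= 1/(B+1) > 0.

A second mode permutes survival records against the fixed molecular data.
The two nulls answer different questions: with a strongly planted cohort
the pairing null *retains* the mRNA → subtype → survival pathway (the mRNA
view alone recovers survival-associated clusters in permuted runs), so its
p-value plateaus well above the floor; the survival null severs the
association entirely and saturates at 1/(B+1). Which randomization is
appropriate is a modelling decision, so the mode is an explicit argument
rather than a hidden default; pipeline-level calibration is demonstrated
on the pairing mode (null cohorts reject at ~5%), saturation on the
survival mode.

## Risk stratification

CRS is the count of five adverse features — disease-free interval under
12 months, more than one metastasis, largest lesion over 5 cm,
node-positive primary, high CEA — with "low" meaning a score strictly
below 2. Inputs are pre-thresholded booleans; a raw-value adapter applies
the thresholds, with CEA adverse strictly above 200 ng/mL by default and
an `cea_inclusive` flag for the >=200 convention (sources differ on the
boundary; both appear in practice). Missing features are an error, never
imputed. The integrated tier is a total function on the six
(subtype, CRS class) cells: subtypes 1/2 + low CRS → low; subtype 2 +
high CRS or subtype 3 + low CRS → intermediate; subtypes 1/3 + high CRS →
high. Recurrence patterns cross-tabulate tiers against none / limited
(1–3 subsequent metastases) / widespread (>3), with a chi-square across
tiers and per-tier Fisher contrasts among recurrent patients.

## Marker selection and classifier

Subtype markers come from one-vs-rest two-sided Wilcoxon rank-sum tests
per feature (rank tests are robust to the unspecified normalization of
mixed array/sequencing inputs), BH-adjusted within the platform, filtered
at FDR 0.05 and minimum absolute mean difference 1 (in the generator's
SD units); direction is recorded. The classifier is nearest-centroid by
Pearson correlation over the marker features, standardized with
training-set parameters stored in the model. Correlation is scale- and
shift-invariant per sample, so the model applies to one sample at a time —
the property required to classify an external cohort. A sample whose
standardized marker vector has zero variance is reported unclassifiable
rather than forced into a class. Subtype-2 performance is summarized as
sensitivity/specificity, with stratified 5-fold cross-validation that
re-selects markers inside each training fold.

## Synthetic cohorts

`simulate_cohort` plants three subtypes (default mixing 33/28/39%) as
disjoint marker blocks shifted by +delta (default 1.5 SD) over
zero-mean Gaussian noise in both platforms; disjoint blocks make the
partition identifiable and give the marker-selection stage unambiguous
truth. Default dimensions are 500 mRNA / 200 miRNA features with 40 / 15
markers per subtype — deliberately below genome scale so a full pipeline
run takes well under a second; the planted-signal geometry, not the
feature count, is what the downstream stages respond to. Survival is
exponential with multiplicative subtype hazards (Weibull shape exposed,
default 1), matching the proportional-hazards assumption of the Cox
stage: baseline 0.018 events/month, hazard ratios (1.0, 0.45, 1.6),
uniform censoring on [0, 120] months. These defaults were pinned to the
published cohort's marginals — roughly 58% death events, 34% low CRS
under the feature prevalences (0.61, 0.39, 0.22, 0.64, 0.05), and 68%
recurrence with subtype-wise recurrence probabilities (0.70, 0.50, 0.80)
and limited-recurrence probabilities (0.50, 0.90, 0.35). CRS features are
independent of subtype and of survival by default (a per-subtype 3×5
probability matrix is accepted for coupled scenarios); consequently
integrated-tier OS contrasts in the synthetic world reflect subtype
composition only, and tier-wise survival ordering is not expected to
reproduce observed clinical gradients. One `numpy` Generator seeded from
`seed` drives every draw, so identical parameters reproduce byte-identical
cohorts.

`complementary_cohort` builds the scenario where fusion is necessary:
mRNA shifts one marker block only in subtype 1, miRNA only in subtype 3,
so each platform separates two of the three blocks and only the fused
network resolves all three. Markers dominate the features here (80 of
100, delta 4): per-feature z-scoring caps any marker's contribution to
the squared between-group distance near 1/(p(1-p)) noise units, and
cross-diffusion dilutes a strictly complementary split through the other
platform's uninformative neighborhoods, so minority-marker versions of
this scenario leave too little eigen-contrast to recover exactly — a
property of the method, not of the implementation.

What the generator does not emulate: count noise and library-size effects,
batch structure, feature–feature correlation beyond the marker blocks,
informative censoring, CRS–survival dependence. Tests passing on these
cohorts demonstrate the pipeline's mechanics and calibration, not clinical
performance on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single CPU: permutation calibration uses 100 null cohorts of n = 60 at
B = 199, saturation and recovery checks n = 120, tier-wise endpoints
n = 600, classifier evaluation 120/60 train/test. Tolerances follow the
sources of error: exact assertions for closed-form arithmetic, 1e-8/1e-9
for linear-algebra identities, binomial-width bands for Monte Carlo rates.
Degenerate inputs fail loudly (isolated network rows, empty marker sets,
constant covariates, missing CRS features); ties are broken
deterministically everywhere (neighbor selection by sample order,
canonical cluster numbering by first appearance, eigengap ties to the
smaller k).
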
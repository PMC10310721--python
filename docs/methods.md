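# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Classification of use and threat

A species is *used* when its assessment lists at least one of the 18
use-and-trade categories. *Use considered a threat* means a threat code in
the biological-resource-use branch: 5.1 (hunting/collecting terrestrial
animals) and 5.4 (fishing/harvesting aquatic resources), including all
dotted descendants (5.1.1–5.1.4, 5.4.1–5.4.6). A `$` suffix on a code (a
convention of some scheme dumps for top-level categories) is normalized to
the bare code. The four groups partition retained species:

| group | definition |
|---|---|
| NOT_USED | no use category (including bycatch-only species) |
| USE_NOT_THREAT | used, no 5.1/5.4 threat code |
| USE_THREAT | used, 5.1/5.4 code present, status not VU/EN/CR |
| EXTINCTION_RISK_USE_THREAT | used, 5.1/5.4 code present, VU/EN/CR |

Decisions taken here: Data Deficient species are retained and can fall in
any group except the extinction-risk group, which is defined strictly by
VU/EN/CR; bycatch is modelled as a marker flag rather than a use category,
so bycatch-only species are NOT_USED by construction; species occupying
several realms are counted once per realm in realm breakdowns. Filtering
removes EX/EW species first, then any class left with fewer than 100
species (order matters at the boundary and is asserted in tests).

## Name reconciliation

Optimal string alignment (OSA) is the restricted Damerau–Levenshtein
distance: unit-cost insertions, deletions, substitutions and adjacent
transpositions, with no substring edited twice (so `osa("ca","abc") = 3`,
unlike the unrestricted metric's 2). Similarity is `1 − d/max(|a|,|b|)`;
comparisons are case-insensitive after whitespace normalization. The triage
thresholds (0.9 auto-resolve, 0.5 review floor) are interpreted on this
unit similarity scale — raw OSA distances are unbounded counts, so unit
normalization is the only reading under which both thresholds cohere; both
are configurable. Review-band candidates resolve only through an explicit
arbiter callback (standing in for a taxonomic authority lookup) and
otherwise stay excluded from diversity counts, as do unknowns. Ties at the
best similarity are broken lexicographically and always logged.

## Prey-diversity comparisons

"Within range" means any shared grid cell, with no fractional-area
threshold — the data are too coarse to support one, and the overlap measure
is explicitly invariant to human prey outside the predator's prey set. Only
prey resolved to species level and present in the reference list count;
`ratio_food <= ratio_all` holds structurally because food prey are a subset
of all-use prey.

## Spatial standardization

Grid cells are abstract ids; nothing downstream of tabulation depends on
geometry, which keeps the statistics independent of projection choices. The
model is a negative-binomial (NB2) GLM with log link, response = used count
per cell, covariate = log(species present), both coefficients and the
dispersion estimated by maximum likelihood (theta = 1/alpha); Pearson
residuals are `(y − mu)/sqrt(mu + mu²/theta)`. Cells with zero species are
retained in tables as zeros but excluded from the fit (log 0 undefined; they
are no-data, not evidence). Numerical notes: a BFGS solution flagged only
for precision loss is accepted when the gradient is below 1e-3 — with
underdispersed data the alpha estimate sits on its zero boundary, where the
flag is spurious — otherwise a Nelder–Mead restart runs before failing; a
constant covariate makes the slope unidentifiable, and the fit degenerates
explicitly to the intercept-only model (slope 0, intercept log of the mean,
moment-based theta). Outlier flagging uses a configurable |residual|
quantile (default 0.99).

## Trait pipeline

Diet axis: Gower distance (range-normalized mean absolute difference) on
the 7 diet proportions, classical scaling (double-centred −D²/2,
eigendecomposition), first axis oriented so invertebrate diet loads
positively. Variance explained is lambda_1 over the sum of positive
eigenvalues; negative eigenvalues (Gower is not always Euclidean) are
dropped from the normalization, with a Cailliez additive correction
available by flag. Loadings are reported as singular-value-scaled
regression slopes of each category on the unit-variance axis — an explicit
scale convention, not correlations. Raw-Gower coordinates reproduce the
distance matrix to Mantel r ≈ 0.98–0.99; after the Cailliez correction the
reconstruction is exact, which is how the scaling identity is tested.

Transforms: log10 for body mass and generation length, square root for
litter/clutch size and habitat breadth, then z-scoring; parameters are
stored so the transform inverts to raw units.

Phylogenetic eigenvectors: the first 10 eigenvectors of the double-centred
patristic distance matrix, descending eigenvalue, each sign-fixed so its
largest-magnitude entry is positive. Non-ultrametric trees are accepted
with a warning; duplicate tips are an error.

Imputation follows the missForest scheme: initialize missing entries with
column means; visit traits in ascending missingness; for each, fit a random
forest (default 500 trees, mtry 4 = round of sqrt(15 predictors): 4 other
traits + diet + 10 eigenvectors) on rows observed for that trait and
predict its missing rows; iterate until the normalized sum of squared
changes in imputed values increases, then keep the previous iterate.
Out-of-bag NRMSE (RMSE of OOB predictions / SD of observed values) is
recorded per trait; completely observed traits get a single OOB-only fit so
their predictability is still reported. Multiple sets (default 15) differ
only through forest randomness; observed entries pass through bit-identical.
Eigenvectors are computed once, not per set — the tree does not change with
imputation.

## Trait space

PCA is fit per imputed set; component signs are aligned to the first set by
the dot product of loadings (imputation noise can flip a component), and
species scores are averaged across sets. Density contours use a Gaussian
KDE with the Scott reference bandwidth — an intentional simplification of
pilot-bandwidth (SAMSE-style) selectors, whose effect on 50% contours is
second-order; the threshold for probability p is the (1−p) quantile of the
density at the sample points. Contours are 2-D (first two PCs);
hypervolumes use all five PCs.

Hypervolumes: a one-class SVM (Gaussian kernel, nu = 0.01, gamma = 0.5) is
fit on per-dimension standardized coordinates, so gamma is expressed in
squared-SD units and the estimator is exactly translation- and
scale-equivariant — volume then obeys the 2^d scaling law up to Monte-Carlo
noise and recovers unit hypercubes within a few percent at n ≈ 2000 (a raw
fixed-gamma boundary does neither). Volume is estimated by uniform sampling
over the data's bounding box padded by 1 SD per dimension: volume =
box volume × inside fraction, reported in SD^d of the input coordinates.
Unique volume of A vs B uses a single shared uniform sample over the union
box for both membership tests (variance reduction and consistent
intersections): `100 × #{in A, not in B} / #{in A}`.

Null models draw without-replacement samples of the observed group's size
from the species pool (default 333 replicates; drivers and the acceptance
script use 99, a deliberate scale-down) and apply the permutation p-value
`(#{random > observed} + 1)/(n + 1)` computed exactly on integers, ties
counting as non-exceedances. Because the observed unique-volume percent
depends on which random hypervolume it is intersected with, the package
records the full per-replicate vector and summarizes it by the median; the
p-value for uniqueness compares that median against the randoms'
unique-percents. Per-trait used-vs-not-used contrasts (Hedges' g with the
small-sample J correction; two-sided Mann–Whitney U, exact by enumeration
for small untied samples, normal approximation with continuity correction
otherwise) run per imputed set and are summarized by the mean.

## Synthetic data

The generators are study-condition emulators, not biogeography: species
tables with configurable class weights, independent per-category use
prevalence, threat codes satisfying P(5.x code | used) = `threat_given_use`,
and a Red List status mixture; pure-birth (Yule) trees sampled a waiting
time after the n-th speciation so no sister pair sits at zero distance;
traits simulated with covariance `lambda·C + (1−lambda)·I` (a Pagel-lambda
blend) and coupled through a shared phylogenetic "size" factor (loadings:
body mass +0.85, generation length +0.8, litter size −0.7, habitat breadth
+0.7) because iterative imputation presupposes mutually informative traits
— real bird/mammal compilations are, if anything, more integrated than
this; diet proportions as a softmax of latent autocorrelated normals (rows
sum to 1 exactly); ranges as 4-connected blobs grown by seeded accretion on
a rectangular grid (log-normal sizes, every species keeps ≥ 1 cell);
predator diets drawn from species co-occurring with a predator's range
blob, with a configured fraction of names perturbed by 1–2 character edits
(verified to keep OSA distance ≤ the edit count; true identities logged).
Missingness is completely at random per trait — the simplest mechanism
under which recovery is well-defined — with generation length left complete
for the bird class, mirroring its complete coverage in the compiled data.
Defaults: 2,000 species, 17% missingness, phylo-signal 0.8, 40×80 grid,
P(threat | used) = 0.5, 2% bycatch rate.

What passing tests therefore show: the estimators are calibrated (null
type-I error at nominal level, NB slope and theta recovered, imputation
recovers held-out values under strong signal lambda = 0.95, hypervolumes
match known geometric truths) and the pipeline's accounting identities hold
under randomized conditions. What they do not show: anything about real
spatial richness gradients, realm-specific use patterns, or the actual
magnitude of non-random trait selection by humans — in the synthetic world
use is assigned independently of traits and geography, so the pipeline's
correct behaviour there is to report null results, and it does.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; fixed seeds give
byte-identical outputs. The drivers and acceptance script run at
deliberately scaled sizes chosen as adequate for their estimands: 2,000
species end-to-end, 99 null replicates, 3–5 imputed sets of 100 trees,
20,000–100,000 Monte-Carlo samples; package defaults remain the full
protocol (333 replicates, 15 sets, 500 trees). Known limitations: the SVM
volume estimate degrades for small samples in five dimensions (n below a
few hundred underestimates); Gower PCoA axes beyond the first are not used;
the review band of the matcher requires a human or service arbiter to
resolve, and defaults to exclusion.
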
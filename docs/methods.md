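# Methods

## Overview

`paretosig` frames biomarker-signature discovery as a three-objective
minimization over binary vectors: each chromosome selects a subset of a
fixed candidate phosphosite list, and its fitness is the vector
(size, separation, relevance). A signature is *Pareto-optimal* when no other
signature is at least as good in all three objectives and strictly better in
one. The algorithm returns the whole first Pareto front, then condenses it
into a few representative signatures.

## Input model and assumptions

The quantitative input is a sites × samples matrix of log10-transformed
ratios (sample versus a common spike-in standard), with missing values
wherever a site was not quantified in a sample. Samples carry a binary
response label: sensitive (+1) or resistant (−1). The biological-context
input is an undirected protein–protein-interaction edge list with
confidences in [0, 1] (the STRING 0–999 integer dialect is converted by
dividing by 1000), plus the identifier of the drug's primary target protein.
Protein identifiers in the matrix and the network must share a namespace;
no mapping is attempted, and a join-failure report lists matrix proteins
absent from the network.

## Candidate prefilter

1. **Presence filter** — keep sites quantified in ≥ `min_presence`
   (default 2/3) of the samples of *each* class. The boundary is inclusive
   (4 of 6 passes).
2. **Fold-change filter** — keep sites with |mean(sensitive) −
   mean(resistant)| ≥ log10(`min_fold`) (default 4), computed
   pairwise-complete on the log10 scale, where a ratio fold-change is
   additive.
3. **Ranking** — a MeanRank-style rank combination: each site is ranked
   separately by (a) the absolute class-mean difference, (b) the magnitude
   of the Welch t statistic, and (c) the distance of the Wilcoxon rank-sum
   (Mann–Whitney U) statistic from its null mean n₁n₂/2; the final score is
   the mean of the three ranks (lower = better). The panel is configurable
   (`rank_stats`). This is a documented stand-in for the published
   rank-combination test it emulates, not a claim of exact equivalence.
   Sites with fewer than two observed values in a class are excluded with a
   warning; mean-rank ties are broken lexicographically by site id.
4. **Top-k with protein dedup** — walk the ranking, keep a site only if its
   protein is new, stop at `top_k` (default 100) sites. The resulting order
   defines the chromosome positions. A deliberate `k=1` request is honored;
   otherwise at least two candidates are required.

No multiple-testing correction is applied at this stage: the filter's
purpose is search-space reduction, not inference.

## Objectives

**Size** is the popcount of the chromosome.

**Separation** is `-min_i(c_i(1/2 - p_i) + 1/2)` over an inner leave-one-out
cross-validation: for each held-out sample, a linear soft-margin SVM
(cost `svm_c` = 1) is trained on the remaining samples restricted to the
selected sites, a posterior sigmoid `p = 1/(1 + exp(A f + B))` (probability
of *resistance*) is fitted on the training-fold decision values by
regularized maximum likelihood with the offset fixed at `B = 0` — so a
sample exactly on the hyperplane always gets p = 0.5 — and the held-out
posterior yields the margin. The score is always in [−1, 0]; −1 means every
held-out sample was classified correctly with full confidence. The sigmoid
fit uses the standard regularized targets t₊ = (N₊+1)/(N₊+2),
t₋ = 1/(N₋+2); the problem is one-dimensional and convex and is solved with
a bounded scalar minimizer (xatol 1e−9, bounds ±500), making the fit
deterministic. Degenerate folds in which a class vanishes get margin 0
(worst). Missing training values are imputed per fold by the mean of the two
class means computed from that fold's training samples only — the same
scheme used for validation imputation — so the held-out sample never leaks
into the imputation and only one imputation mechanism exists in the package.

**Relevance** is the arithmetic mean, over the *distinct* proteins of the
selected sites, of the penalty-weighted shortest-path distance to the target
protein. The network keeps only edges with confidence strictly above
`confidence_threshold` (default 0.9) and weights them by
ρ = 1/(−log10(1 − s)), a strictly decreasing transform mapping the retained
range [0.9, 0.999] onto [1, 1/3]; this amplifies differences among high
confidences. (The transform's domain is inclusive at the threshold; the
edge filter is strict.) An alternative increasing transform
ρ = 1 − log10(1 − s) is available via `penalty_form="literal"`. Distances
are computed once per run with Dijkstra from the target. Proteins absent
from the filtered network or disconnected from the target receive a finite
fallback distance, by default (maximum finite node-to-target distance) + 1 —
finite so such signatures remain comparable, worse than any connected
protein, and scale-aware; it is overridable via `fallback_distance`.
Published relevance values for real datasets depend on the (unstated)
fallback convention and on the network snapshot, so they are not
reproducible quantities; only the transform's endpoints are.

**Degenerate chromosomes.** An all-zero chromosome is never run through the
SVM; it is assigned the vector (0, 0, fallback) — its separation of 0 is the
worst possible, keeping it dominated in practice — and variation operators
repair all-zero outputs by setting one uniformly random bit. Objective
vectors are cached by bit pattern, so re-encountered individuals are free.

## Optimizer

Standard elitist NSGA-II over binary chromosomes:

| parameter | default | meaning |
|---|---|---|
| `population_size` | 200 | chromosomes per generation (must be even) |
| `init_set_fraction` | 0.10 | per-bit probability of 1 at initialization |
| `tournament_size` | 5 | entrants per selection tournament |
| `crossover_prob` | 0.8 | probability of single-point crossover |
| `mutation_prob` | 0.02 | per-bit flip probability |
| `stagnation_generations` | 200 | termination patience |
| `max_generations` | 5000 | safety cap |

Each generation draws N/2 parent pairs by 5-way tournament (lowest front
rank wins; ties by larger crowding distance, then uniformly at random),
applies single-point crossover (cut uniform in [1, K−1]) and bit-flip
mutation to both children, merges parents and offspring, sorts the merged
pool by non-domination and crowding, and keeps the top N (elitism). The run
terminates when the *set of first-front bit patterns* is unchanged for
`stagnation_generations` consecutive generations — a feature-space
criterion, stricter than objective-space equality — or at the safety cap
(absent from the classical description; added to guarantee termination).

Numerical choices: crowding distance gives +inf to fronts of ≤ 2
individuals; otherwise, per objective, boundary individuals get +inf and
interior ones accumulate the normalized neighbor gap, while an objective
with zero range across the front contributes nothing (neither gaps nor
boundary infinities) — this also makes survivor selection stable (ties cut
by merged-pool index, parents first) when all objectives tie. All
randomness flows through a single seeded generator consumed in a fixed
order, so full runs are bit-reproducible; the SVM subproblem is convex and
solved at fixed tolerance, so repeated evaluations are bit-stable.

## Postprocessing

Front solutions with separation ≥ `separation_cutoff` (default −0.6,
boundary removed) are discarded: Pareto optimality deliberately also keeps
very small, very relevant but poorly separating solutions, and removing
undesired regions post hoc is standard practice. The survivors are
clustered on their raw 0/1 vectors (no scaling) with Ward linkage on
Euclidean distances, the dendrogram cut into `n_clusters` (default 4)
groups; cluster labels follow dendrogram leaf order so they are stable
across reruns. No cut criterion is claimed for the default of 4 — it is a
knob, and `run_pipeline` clamps it (with a warning) when the accepted front
is smaller than requested, which is common at desk scale. Each cluster's
representative is the member with the smallest Euclidean distance to the
cluster centroid; exact ties go to the better (smaller) separation, then to
the lower solution index — the last rule is a determinism guarantee for a
case the tie-break convention leaves open.

Each representative becomes a final predictor: a linear SVM (C = 1) on the
full training set restricted to the signature (training missingness imputed
by the mean of the two class means), plus the zero-offset sigmoid fitted on
the training decision values. Validation samples are imputed with the same
per-site values; signature sites entirely absent from a validation matrix
are treated as all-missing (warned). Scoring: a sensitive sample is correct
iff p < 0.5, a resistant one iff p > 0.5 — p = 0.5 exactly counts as
*incorrect*, declaring the boundary explicitly — and the average probability
distance is (1/N) Σ (0.5 − p_i)c_i ∈ [−0.5, 0.5], which reaches 0.5 only for
maximally confident, fully correct predictions. Predictors serialize to the
run report (weights, intercept, sigmoid slope, imputation values), so
`paretosig validate` can apply them later without refitting.

## Synthetic-data generator

The generator emulates the statistical skeleton of a two-class
phosphoproteome screen at desk scale. Defaults (chosen once as this
package's study conditions): 500 sites on 400 proteins, 20 training and 6
validation samples, 3 informative sites on distinct proteins with a
between-class mean shift of `effect_log10 = 1.0` (10-fold — comfortably
above the 4-fold filter threshold, as an effect sitting exactly at the
threshold would be removed about half the time by sampling noise of the
class-mean difference), i.i.d. Gaussian cell noise `noise_sd = 0.25` on the
log10 scale, MCAR missingness at rate 0.10 (high enough to exercise the
presence filter and imputation, low enough that planted sites reliably meet
the 2/3-presence rule at these class sizes), a network of 800
high-confidence edges (confidence uniform in (0.901, 0.999)) plus 150
sub-threshold decoys, with the planted proteins wired to the target within
≤ 2 hops, and a validation cohort drawn from the same model with the effect
multiplied by `validation_attenuation = 0.7`, a qualitative analogue of the
domain shift between training and validation tumor types. Effect directions
are random per site; baselines are N(0, 0.4).

What it deliberately does **not** model: mass-spectrometry acquisition,
ratio compression, site-localization error, informative (non-MCAR)
missingness, correlated sites, or realistic PPI topology. Tests passing on
this generator therefore demonstrate the *workflow's* correctness —
filters, objectives, optimizer, postprocessing, determinism — not
performance claims about real phosphoproteome data. A consequence of the
generator's clean null (non-informative sites have zero class effect) is
that the 4-fold filter typically reduces the candidate set to approximately
the planted sites, so desk-scale fronts are small; the optimizer's search
behavior at realistic candidate counts is instead exercised by synthetic
objective functions with known exhaustively enumerated optima.

The hand-coded toy fixture (8 sites, 6+6 samples, 7-node network with a
disconnected component and a protein absent from the network, 3 documented
missing cells) provides fully hand-checkable values for unit tests.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
operator statistics over 10⁶ bits; oracle comparisons on 200 random
3-objective sets (n ≤ 60) and on graphs of ≤ 8 nodes; exhaustive front
recovery on a 10-bit problem (1,024 chromosomes); planted-signature
recovery on the default 500-site generator conditions with population 100
and stagnation 50; and byte-identity of repeated reports on a 120-site
dataset. These sizes keep every check exact or statistically
well-powered while remaining desk-scale.

## Known limitations

* The MeanRank statistic panel is a pluggable reconstruction; exact
  replication of the original test would require its published tie-handling
  details.
* Relevance scores depend on the network snapshot and the fallback
  convention; compare them only within a run.
* The separation objective costs one SVM fit per training sample per new
  chromosome; very large populations on large candidate sets are CPU-bound
  (memoization removes duplicate evaluations).
* Only linear SVMs with fixed cost are supported by design; there is no
  hyperparameter search.
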
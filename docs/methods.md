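# Methods

This note records the models and procedures `genefs` implements, the
defaults and why they were chosen, and what the synthetic benchmark does
and does not demonstrate.

## Differential screening

Each gene is tested with a two-sided Welch (unequal-variance) *t*-test
between the two classes. Welch rather than the pooled-variance test is the
safer default for expression data, where per-gene variances differ
substantially between conditions. A gene with zero variance in both
classes is resolved by its group means: identical means give p = 1.0 (no
evidence), distinct means give p = 0.0. P-values are adjusted by the
Benjamini–Hochberg step-up procedure (delegated to
`statsmodels.stats.multitest.multipletests`), and screening keeps genes
with q strictly below the threshold (default 0.2). BH assumes independent
or positively dependent tests; the generator's redundant genes introduce
exactly the kind of positive dependence BH tolerates. Under a complete
null the procedure bounds the expected false-discovery proportion by the
threshold; with all genes null this reduces to the probability of any
discovery, so single-run FDP estimates are coarse and only the average
over many simulations is meaningful.

## SVM contract

The soft-margin dual problem is solved by scikit-learn's libsvm binding;
the package's contract is the exposed dual solution: coefficients
α_i y_i ∈ [−C, C] summing to zero, support vectors, bias, and the decision
function f(x) = Σ α_i y_i K(x_i, x) + b. The weight vector used for
ranking is ω = Σ α_i y_i x_i. For the linear kernel this is the exact
primal weight. For the RBF kernel no input-space weight exists; the
package applies the same sum as a *pseudo-weight*, which is the
minimal-assumption way to combine an RBF classifier with the ω_k²
elimination criterion. Users wanting a kernel-consistent criterion can set
`criterion="kernel"` in `rfe_rank`, which scores feature k by the change
in the margin term αᵀdiag(y)K diag(y)α when k is removed from the kernel.
The two criteria usually agree on which genes are irrelevant but can
order mid-ranked genes differently.

Cross-validation uses a documented fold-assignment rule: within each
class, samples are ordered by identifier, shuffled by the seeded
generator, and dealt round-robin to folds. Fold membership therefore
depends only on (sample identifiers, labels, folds, seed) — never on row
order — which makes CV results invariant under sample reordering. Five
folds is the default, averaged unweighted. `folds` equal to the sample
count is treated as leave-one-out (stratification is vacuous there);
otherwise each class must have at least `folds` members.

## Recursive feature elimination

One gene is removed per iteration — never a chunk — so the elimination
order is a total ranking. Ties on the elimination score fall to the lowest
original column index, making runs with fixed parameters fully
deterministic. When an optimizer is active, (C, γ) are re-chosen by
maximizing CV accuracy on the surviving genes. The default cadence is
every iteration; because a PSO or GA run costs hundreds of CV evaluations,
a cheaper `reoptimize_every=k` cadence (reusing the last optimum in
between) is provided and is what the benchmark runs use (k = 25–50 with a
swarm of 8 × 10 iterations), trading a marginal ranking difference for an
order-of-magnitude speedup. With no optimizer, the default fixed pair is
C = 1, γ = 1/D.

## Parameter search

All searches operate on (log₂C, log₂γ) in the box C ∈ 2^[−5,15] step 2,
γ ∈ 2^[−15,3] step 2 — the long-established convention for RBF-SVM
tuning. Grid search enumerates the lattice once, breaking ties toward the
lexicographically smallest point so results are reproducible. PSO defaults
(swarm 20, 50 iterations, inertia 0.7, c₁ = c₂ = 1.5) and GA defaults
(population 30, 40 generations, crossover 0.9, mutation 0.1 per
coordinate, mutation σ = 10% of the coordinate range, BLX-0.5 crossover,
tournament size 2, elitism 1) follow canonical literature values; all are
configurable. Elitism makes the GA's running best non-decreasing.
Positions are clipped to the box, and both heuristics are pure functions
of (fitness, space, hyperparameters, seed).

## RFFS

Backward elimination ordered by random-forest impurity importance. Each
outer iteration deals the samples into stratified folds (default 10),
trains one forest per fold, records the fold accuracies (mean TLMean, max
TLMax), and averages the fold importances; the averaged vector supplies
both the importance order and the gene to drop (argmin, lowest column
index on ties). The best-set update fires on TGMax ≤ TLMean — ties
included — so a later (hence smaller) gene set with equal mean accuracy
replaces an earlier one. Elimination stops when two genes survive.
Averaging the per-fold importances is a deliberate resolution of an
otherwise ambiguous single-sort step: it uses all folds' models rather
than privileging the last fold trained. Defaults: 100 trees,
⌈√p⌉ features per split; RFFS-GS tunes over
n_estimators ∈ {50, 100, 200, 500} and
max_features ∈ {⌈√p⌉, ⌈p/3⌉, ⌈p/5⌉} by full-gene-set CV accuracy before
eliminating.

## mRMR

Expression is z-scored per gene (sample sd, ddof = 1) and coded to three
levels with strict cut-offs at ±1 sd; zero-variance genes code to all
zeros. Mutual information is the plug-in estimate on the empirical joint
distribution, in bits (computed via `sklearn.metrics.mutual_info_score`,
converted from nats). No small-sample bias correction is applied — the
bias is shared by all candidates at a given step, and the original mRMR
practice does the same. The default combination is MID
(relevance − mean redundancy); MIQ (quotient) is available behind a flag.
The candidate-set size rule: compute e_k = 1 − CV accuracy on each nested
prefix, take Ω = {k : e_k ≤ min e + tolerance} (default tolerance 0.01),
and return the smallest k in Ω attaining the minimum. The tolerance band
is the operational reading of a "stable low-error range"; a variance
criterion would need a window parameter with no principled default, so the
band alone defines Ω.

## Evaluation

Confusion counts take +1 (cancer) as the positive class. Precision,
recall, F and accuracy follow the standard definitions with empty
denominators mapped to 0. The ROC is swept over the unique SVM decision
values (`drop_intermediate=False`) and AUC is its trapezoidal area, which
equals the Mann–Whitney pair-counting estimate with ties counted half —
the suite verifies this equivalence on tied score vectors. Subset-size
selection sweeps nested top-k prefixes by training-set CV accuracy only
and returns the smallest maximizer; the test half never informs the
choice, so reported test metrics are leakage-free.

## Synthetic data

Gaussian mode: noise genes are N(0,1) in both classes; informative genes
are N(0,1) vs N(δ,1); redundant genes copy an informative source
(round-robin) plus N(0, redundancy_noise). Negative-binomial mode mimics
RNA-seq counts via a gamma-Poisson mixture (var = μ + αμ²) with baseline
mean 100 and the class effect applied as a factor e^δ on the mean;
redundant counts are the source scaled by a log-normal factor and rounded.
Gene columns are shuffled so position carries no information. Defaults (30
samples per class, 100 genes, 5 informative at δ = 2, 5 redundant at copy
noise 0.1) describe a small balanced cohort on which every selector
separates signal from noise while staying cheap to simulate repeatedly;
`n_negative` overrides the negative-class count to emulate heavily skewed
cohorts.

The generator deliberately omits gene–gene correlation beyond the copy
mechanism, batch effects, heteroscedastic per-gene variances and
library-size variation. Passing the planted-recovery benchmarks therefore
shows the selectors separate mean-shifted signal from independent noise at
realistic sample sizes — it does not certify performance on real cohorts,
where correlated blocks and technical artefacts can change rankings.

## Reproducibility

Every stochastic stage derives its seed from the single top-level seed by
a truncated BLAKE2b hash of the seed plus a stage tag (`genefs._rand`),
and the pipeline writes the resolved seeds to `run_log.json`. Re-running
with the same configuration produces byte-identical ranked lists.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each property is measured with adequate Monte-Carlo resolution while the
whole suite stays interactive: cohorts of 40–130 samples, 30–200 genes,
10–50 simulation replicates, and small PSO budgets (swarm 8 × 10
iterations at cadence 25–50) inside the RFE loop. The library itself has
no such limits; the same calls scale to full-study matrices at
correspondingly longer runtimes.

## Known limitations

- Binary classification only; multi-class extensions are out of scope.
- The RBF pseudo-weight criterion is a heuristic; its ranking is not
  invariant to monotone feature rescaling the way the kernel-space
  criterion is.
- Count data are screened with the same Welch/BH pipeline as continuous
  data — no negative-binomial dispersion modelling — so RNA-seq users
  wanting a count-aware screen should pre-screen externally and pass the
  reduced matrix in.
- Plug-in MI is biased upward at very small sample sizes; mRMR rankings on
  fewer than ~20 samples per class should be treated with caution.
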
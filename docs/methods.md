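# Methods

This note documents the models and procedures implemented in `hces`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish about real data.

## Data model

A `DataTable` is a rectangular record set with typed attribute specs:
exactly one discrete binary class (canonical states `"0"`/`"1"`, `"1"` the
positive event) and mixed continuous/discrete predictors. Missing values
are rejected at load time by default; an opt-in flag admits rows with
missing predictors, which are then handled only at inference time by
marginalization (the class may never be missing). Column kinds are
inferred from CSV/ARFF content — numeric columns with non-integer values
become continuous, everything else discrete — and the inference is
overridable per attribute, because integer-coded measurements (age, counts)
and integer-coded categories are indistinguishable from the file alone.

All entropies are in bits. Symmetrical uncertainty
`SU(X,Y) = 2·[H(X)+H(Y)−H(X,Y)]/[H(X)+H(Y)]` (defined 0 when both columns
are constant) serves as the correlation for CFS on discretized data.

## Supervised MDL discretization

Candidate cuts are boundary points only: midpoints between consecutive
distinct sorted values whose pooled label set is impure. A distinct-value
block containing both labels makes both flanking midpoints candidates.
Recursion is greedy top-down: take the candidate maximizing information
gain (ties break toward the smallest threshold, for determinism), keep it
iff the MDL test accepts

    Gain > log2(N−1)/N + Δ/N,
    Δ = log2(3^c − 2) − [c·Ent(S) − c1·Ent(S1) − c2·Ent(S2)],

where `c, c1, c2` count the classes *present* in the node and its two
children, then recurse on both sides. Intervals are half-open `[a, b)`; a
value equal to a cut belongs to the upper bin, and out-of-range values at
application time fall into the terminal bins (clamping). Attributes with
no accepted cut become single-state, are flagged *inert*, and are excluded
from ranking, selection and structure learning: they carry zero information
and would put 0 in SplitInfo denominators. In practice this makes the
discretizer double as a first relevance filter — independent continuous
noise almost never earns a cut.

The implementation is checked for exact agreement with an independently
written exhaustive-recursion oracle on random columns (n ≤ 30), and for
invariance under strictly increasing affine transforms of the values.

## Attribute selection

**Gain-ratio filter.** Each discrete predictor gets
`GR = Gain/SplitInfo` (defined 0 when SplitInfo = 0); the ranking is
presented in descending order with ties broken alphabetically. The
elimination threshold is half the maximum gain ratio, `α = max GR / 2`,
read as a threshold on the gain-ratio *value*: attributes strictly below α
are dropped, equality is kept.

**CFS.** Subsets are scored by the Hall merit
`k·r̄_zi / sqrt(k + k(k−1)·r̄_ii)` with SU as the correlation, and searched
by forward Best-First with stale limit 5. For ≤ 10 attributes the result
is verified against exhaustive subset enumeration.

**Wrappers.** Candidate subsets are scored by the classifier's own
stratified-CV AUC, pooling out-of-fold posteriors. One fold partition
(derived from the search seed) is reused for every subset within a search,
so scores are comparable and variance is not re-drawn per subset. The
default evaluator structure is naive Bayes — the configuration whose
factorization lets each attribute's per-record, per-fold log-likelihood
contribution be precomputed once, reducing a subset evaluation to a vector
sum (bit-identical in AUC to fitting the subset model fold by fold, which
a test asserts); a TAN evaluator is available when the wrapped classifier
should itself be tree-augmented.

Two decisions here matter and deserve their rationale:

- *Score resolution.* The pooled CV-AUC is a noisy statistic: its
  fold-partition standard deviation at n ≈ 2000 is of order 0.005–0.01.
  The evaluator therefore reports scores rounded to `score_precision`
  decimals (default 2), so differences below the evaluator's resolving
  power are ties, and the package-wide tie-break — smaller subset first,
  then lexicographic attribute order — can act. Without this, forward
  search provably absorbs irrelevant attributes whose jitter happens to be
  positive.
- *Genetic search.* Individuals are attribute bitmasks; population 20,
  20 generations, rank-proportional reproduction, single-point crossover
  (rate 0.6), per-bit mutation (rate 1/#attributes), all-zero individuals
  repaired to a random singleton, fully seeded. Equal-fitness individuals
  rank by the same parsimony tie-break, and the returned subset is the
  best individual ever evaluated under that ordering. Even so, a GA whose
  fitness is raw CV-AUC can retain attributes that correlate with the
  class by chance in the training sample — a form of selection overfitting
  inherent to wrapper methods, not a defect of the search — so its output
  should be expected to be less parsimonious than Best-First's.

## Bayesian-network classifier

Structures are acyclic parent maps over the class and predictors; the class
never has parents.

**TAN.** Conditional mutual information `I(X;Y|C)` (maximum-likelihood
frequencies, 0·log 0 = 0) weights every predictor pair; Prim's algorithm on
the dense matrix yields the maximum-weight spanning tree, with ties broken
toward the lexicographically smallest index pair. The tree is directed
away from the root — the first predictor in column order — and the class
is added as parent of every predictor. Root choice changes neither the
undirected tree nor the unsmoothed classifier's likelihood (asserted by a
test that re-roots the tree and compares posteriors).

**K2.** Given a node ordering (default: column order) and a parent cap
that counts the mandatory class parent, each node greedily gains the
predecessor parent maximizing the Cooper–Herskovits log-score

    Σ_j [ lnΓ(r) − lnΓ(N_j + r) + Σ_k lnΓ(N_jk + 1) ]

until nothing improves or the cap is hit. `max_parents = 1` reproduces
naive Bayes exactly.

**CPTs.** `P(v|pa) = (N_{v,pa} + s)/(N_pa + s·|states|)` over the full
Cartesian product of parent configurations, pseudocount `s = 0.5` by
default (unobserved configurations become uniform); with `s = 0`,
unobserved configurations are NaN and raise a named error if a query
touches them.

**Inference.** Posteriors under arbitrary partial evidence are exact:
barren (unobserved, childless) nodes are pruned — their CPTs integrate to
one — and the remaining hidden variables are eliminated in reverse
topological order. With TAN or bounded-parent structures the intermediate
factors stay small. Full-evidence scoring uses a vectorized log-product
path; batch partial-evidence scoring caches posteriors per observed-state
pattern. For ≤ 6 binary predictors the posterior is checked against
full-joint enumeration at 1e-10 under random partial evidence.

## Evaluation

Stratified k-fold plans shuffle each class under the seed and deal records
round-robin, guaranteeing per-fold class counts within one of perfect
stratification. Cross-validation refits structure *and* parameters per
fold and scores each record exactly once, out of fold; scores from all
folds are pooled into one ROC (the convention of the Weka-style evaluation
stack this mirrors; per-fold-mean AUC is not the default). Every AUC is
computed twice — trapezoid over the ROC points and tie-corrected midrank
statistic — and the two must agree to 1e-12 or the call raises.

The alert cutoff is the ROC point minimizing `(1−sens)² + (1−spec)²`,
i.e. nearest the ideal corner (FPR 0, sensitivity 1); ties resolve to the
smaller, more sensitive threshold. (A variant formula sometimes printed
with this rule, `(1−sens)² + spec²`, is inconsistent with the stated
geometric objective and is not used.) Classification alerts strictly when
the posterior exceeds the cutoff; equality does not alert.

**Incremental observation.** Attributes are ordered by descending gain
ratio. For each m, held-out records are scored by the *full* per-fold
models with evidence restricted to the top-m attributes, the rest
marginalized — the deployed-application reading, where a patient observes
symptoms one at a time against a fixed model. A retrain-per-m mode
(refit a reduced model for each m) is available behind a flag since either
protocol is defensible; at full m both coincide exactly with the standard
evaluation. At m = 0 the scorer is constant by construction: an empty
evidence set carries no record-specific information (per-fold prior
differences are fold arithmetic, not patient signal), so the AUC computed
from the constant scores is exactly 0.5. Mean AUC is non-decreasing in m
in expectation over seeds; single runs may dip at intermediate m, which is
expected behavior of pooled CV estimates, not a bug.

## Synthetic test bed

`make_spec` plants a TAN chain: class `Exacer` ~ Bernoulli(prevalence,
default 0.15), root predictor following the class with fidelity
`strength = 0.85`, and each later binary node with
`P(x=1|c, xp) = base + class_shift·c + parent_shift·xp`
(defaults 0.1/0.3/0.4, clipped to [0.02, 0.98]) — every attribute carries
both direct class signal and a strong tree dependence. The first
`n_emitted = 4` relevant attributes are emitted as per-state Gaussians with
means 3 standard deviations apart, giving the discretizer a planted,
recoverable cut; noise attributes (default 6 discrete + 6 continuous) are
independent of everything. The full-scale envelope of the motivating
dataset (~60 predictors, 20 continuous) is reached by raising the noise
counts. `GroundTruth.bayes_auc` is the closed-form AUC of the planted
posterior, enumerated over all discrete predictor configurations and
weighted by class-conditional mass — the ceiling any classifier on this
data can reach.

Two recovery checks intentionally use *balanced* planted models
(prevalence 0.5, class-independent chain): per-entry CPT recovery at
±0.03 for n = 5000 and empirical-frequency fidelity at ±0.01 for n = 1e5
are ~3σ bounds only when every parent configuration holds a proportional
share of the sample; under a 15% minority class the rare (class = 1)
configurations would need several times more data for the same tolerance.

What the synthetic bed does not show: real clinical attributes are not
conditionally binary, their dependencies are not a single chain, emissions
are not Gaussian or homoscedastic, and prevalence and measurement noise
drift over time. Passing tests establish the *algorithms* (discretizer,
selectors, structure/parameter learners, inference, evaluation protocol)
against their definitions and oracles — not any clinical performance claim.

## Problem sizes and numerics

The default test-bed sizes (n = 2000 for pipeline and selection runs,
n = 5000 for recovery, 10-fold CV throughout) were chosen as the smallest
sizes at which the planted signal dominates sampling noise for the stated
tolerances. Probabilities are multiplied in log space for full-evidence
scoring; variable elimination works in probability space on small factors.
CPT rows are validated to sum to 1 within 1e-12. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; the pipeline
expands one root seed deterministically per stage, and reports serialize
to byte-identical JSON across reruns.

## Known limitations

- Wrapper selection inherits selection bias: attributes chance-correlated
  with the class in the given sample can survive, especially under the
  genetic search (see above). Held-out validation of the *selected* model
  is the user's responsibility.
- The two pipeline stage orders (discretize-then-select, the recommended
  default, and select-then-discretize) nearly coincide here because the
  per-attribute MDL discretizer does not depend on other attributes; the
  order matters only for which attributes reach the selector as inert.
  Both are supported and reported for comparison.
- K2 honors a user-supplied ordering but provides no ordering search.
- No continuous (Gaussian) nodes at inference time: continuous attributes
  must pass through discretization; no latent variables; no
  expert-elicited structures.
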
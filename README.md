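# hces

Tabular risk prediction with Bayesian-network classifiers, built for the
kind of clinical early-warning problem where a binary event (the motivating
case is an acute COPD exacerbation, class `Exacer` with 1 = event) must be
predicted from a few dozen mixed continuous/discrete patient attributes —
and where the attributes a patient or nurse can realistically observe at any
moment are only a subset of them.

The toolkit chains the classical preprocessing-and-learning stack of this
problem family into one reproducible pipeline:

1. **Supervised discretization** of continuous predictors by the
   Fayyad–Irani minimum-description-length criterion: recursively cut each
   attribute at the boundary point maximizing class-information gain
   `Gain = Ent(S) − (N₁/N)·Ent(S₁) − (N₂/N)·Ent(S₂)`, accepting a cut iff
   `Gain > log₂(N−1)/N + Δ/N` with
   `Δ = log₂(3^c − 2) − [c·Ent(S) − c₁·Ent(S₁) − c₂·Ent(S₂)]`.
2. **Relevant-attribute selection**, either by filters — gain-ratio ranking
   `GR(T,A) = Gain(T,A)/SplitInfo(T,A)` with the half-of-maximum threshold
   `α = max GR / 2`, or CFS merit `k·r̄_zi / √(k + k(k−1)·r̄_ii)` under
   symmetrical uncertainty — or by wrappers (Best-First or genetic search
   scored by the classifier's own cross-validated AUC).
3. **Bayesian-network classifier**: `P(V₁,…,Vₙ) = ∏ᵢ P(Vᵢ | Pa(Vᵢ))`, with
   the structure learned from data rather than elicited from experts —
   TAN (tree-augmented naive Bayes, the maximum spanning tree under
   conditional mutual information `I(X;Y|C)`) or K2 (greedy parent search
   under the Cooper–Herskovits score, with the class as mandatory first
   parent; `max_parents = 1` is exactly naive Bayes).
4. **Evaluation**: stratified 10-fold cross-validation with pooled
   out-of-fold posteriors, ROC/AUC (trapezoid, cross-checked against the
   tie-corrected rank statistic), and an alert cutoff at the ROC point
   nearest (FPR 0, sensitivity 1).
5. **Incremental observation**: attributes are arranged in descending
   gain-ratio order; exact partial-evidence inference (variable
   elimination) tracks how the AUC ramps up as the top-m attributes are
   observed one by one, so an interface can put the most discriminating
   symptoms first and still guarantee a floor on accuracy.

A planted-model synthetic generator (`hces.synthetic`) samples datasets of
the same shape as the motivating learning base (~2000 records, mixed-type
predictors with Gaussian emissions, independent noise attributes, minority
class) and reports the closed-form Bayes-optimal AUC of the planted model,
so every stage is testable without any real patient data.

## Worked example

```python
import hces

spec = hces.make_spec(n=2000, seed=7)          # 8 relevant + 12 noise predictors
table, truth = hces.sample_dataset(spec)

report = hces.run_pipeline(hces.PipelineConfig(seed=7, start_m=1))
print(f"selected attributes : {report.selected}")
print(f"cross-validated AUC : {report.auc:.3f}  (Bayes-optimal ceiling {truth.bayes_auc:.3f})")
print(f"alert cutoff        : {report.cutoff:.3f}")
for m in sorted(report.auc_by_m, key=int):
    print(f"AUC with top {m} attributes observed: {report.auc_by_m[m]:.3f}")
```

prints

```
selected attributes : ['X01', 'X02', 'X03', 'X04', 'X06', 'X08']
cross-validated AUC : 0.958  (Bayes-optimal ceiling 0.962)
alert cutoff        : 0.150
AUC with top 1 attributes observed: 0.738
AUC with top 2 attributes observed: 0.843
AUC with top 3 attributes observed: 0.912
AUC with top 4 attributes observed: 0.936
AUC with top 5 attributes observed: 0.952
AUC with top 6 attributes observed: 0.958
```

The Best-First wrapper kept six of the eight planted relevant attributes
and none of the twelve noise attributes; the cross-validated AUC of the
fitted TAN sits just under the planted model's Bayes-optimal ceiling; and
observing attributes in gain-ratio order ramps the accuracy from 0.74 (one
symptom) to the full-evidence 0.958 — the posterior is exact at every m
because unobserved predictors are marginalized, not imputed.

The same stages are available as a CLI for file-based workflows:

```sh
hces simulate --seed 7 --out data.csv --truth truth.json
hces discretize --in data.csv --class Exacer --out scheme.json
hces select --in data.csv --method wrapper-bestfirst --folds 10 --seed 42
hces learn --in data.csv --structure tan --out model.json
hces predict --model model.json --in observations.csv --cutoff 0.1
hces run --config pipeline.yaml
```

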
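# emsflags

Interpretable opioid-overdose classification for emergency medical
services (EMS) encounter records.

## The problem

Overdose surveillance built on death certificates and emergency-department
diagnosis codes is slow and systematically undercounts people who are
stabilized in the field and refuse transport. EMS encounter records cover
the full range of overdose events, but their diagnostic signal lives in
free text: the 9-1-1 call nature, the provider's primary impression, the
chief complaint, the chief narrative, the medication list, and the medical
history. `emsflags` implements a lightweight, interpretable classifier for
this setting, for epidemiologists and harm-reduction programs who need
near-real-time, county-level overdose counts and want to understand *why*
each record was flagged.

## The method

The core featurization is **keyword flagging**: for two curated term sets
— 18 opioid terms (opioid, opiate, Narcan, naloxone, heroin, methadone,
fentanyl, ...) and 7 overdose terms (ingestion, substance, abuse, intox,
poisoning, OD, overdose) — count occurrences in each of the six text
fields. Matching is case-insensitive and boundary-aware (the "OD" inside
"body" never fires; "intox" is a left-anchored prefix so "intoxicated"
does), giving a 2 × 6 matrix of integer counts per record:

> x[s, f] = number of non-overlapping matches of term set *s* in field *f*

Flag features are benchmarked against TF-IDF (smoothed idf
ln((1+N)/(1+df)) + 1, L2-normalized rows) and against concept-embedding
vectorization of the chief narrative (a pluggable surface-form lexicon and
concept-id → vector table; the record vector is the mean of matched
concept embeddings). Each feature set trains four learners — logistic GLM,
single-hidden-layer neural network, naive Bayes (Gaussian or kernel-
density), and gradient-boosted trees — under repeated stratified k-fold
cross-validation (k = 5) with random-search hyperparameter selection on
AUROC, plus a stacked ensemble: a logistic combiner fitted on the base
models' out-of-fold probabilities.

Evaluation reports AUROC with DeLong variance
(var = var(V10)/m + var(V01)/n from placement values) and Wald 95%
confidence intervals, threshold confusion matrices, per-predictor filter
importance (each column's standalone AUROC), pairwise equality-of-
proportions tests of error rates across demographic groups (Yates
corrected), and ICC(2,1) for inter-annotator reliability.

Because real EMS records are protected health information, the package
ships a seeded synthetic cohort generator that emulates the documented
study conditions — ~15% positive prevalence across three county strata,
keyword-bearing text for positives, and the documented confusable
presentations (Narcan given without response, detailed denial of named
opioids, opioid history irrelevant to the event, behavioral-health-focused
narratives, unnamed drug products) — with exact ground truth of every
planted keyword, so featurizers are testable against an oracle.

## Worked example

```python
from emsflags import *
from emsflags.models import ModelSpec, CvConfig

config = GeneratorConfig(n=3000, prevalence=0.15, seed=7)
cohort, truth = generate_cohort(config)
train, test = split_train_test(cohort, 0.2, seed=7)

Xtr, Xte = featurize_flags(train), featurize_flags(test)
model = train_model(Xtr, train.labels().astype(int),
                    ModelSpec("glm"), CvConfig(repeats=1, search_n=1, seed=7))

roc = delong_ci(predict_proba(model, Xte), test.labels().astype(int))
print(f"held-out AUROC {roc.auc:.3f} (95% CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f})")

imp = variable_importance(Xtr, train.labels().astype(int))
print("top predictors:", imp.top(3))
```

prints

```
held-out AUROC 0.953 (95% CI 0.924-0.982)
top predictors: ['overdose__chief_narrative', 'opioid__chief_narrative', 'opioid__primary_impression']
```

A flags GLM recovers the keyword-borne signal on the held-out 20% split
(600 records), and the filter importances rank the chief-narrative and
primary-impression flags highest — the fields where the generator (like
field providers) concentrates diagnostic content. The same run via the
CLI: `emsflags simulate --n 3000 --seed 7 --out sim/` then
`emsflags benchmark --seed 7 --out bench/`.

## Layout

| module | contents |
| --- | --- |
| `emsflags.records` | encounter data model, CSV/JSONL I/O, summaries, stratified splitting |
| `emsflags.synth` | seeded synthetic cohort generator with ground truth |
| `emsflags.flags` | keyword term sets and flag featurization |
| `emsflags.textfeats` | TF-IDF and concept-embedding featurizers |
| `emsflags.models` | the four base learners and the CV training protocol |
| `emsflags.stacking` | linear stacking on out-of-fold probabilities |
| `emsflags.metrics` | AUROC/DeLong, confusion, importance, parity, ICC |
| `emsflags.pipeline` | benchmark grid, annotation batch selection, stopping rule |
| `emsflags.cli` | `emsflags` command-line interface |

See `docs/methods.md` for the statistical details and design choices.
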
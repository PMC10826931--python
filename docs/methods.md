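# Methods

This note documents the models and procedures implemented in `emsflags`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Keyword-flag featurization

A flag feature is the count of non-overlapping matches of a term set in
one text field. The default sets are the curated surveillance lists — 18
opioid terms and 7 overdose terms — applied to all six encounter fields,
yielding 12 integer columns named `<set>__<field>`.

Matching rules, and the reasoning where the rule was genuinely open:

* **Case-insensitive regular expressions with word boundaries on both
  sides** of every term. Numerals count as word characters, so
  "tylenol 3" does not match inside "tylenol 30". This is what prevents
  the classic false positive of "OD" firing inside "body".
* **"intox" is a left-anchored prefix**: it requires a boundary on the
  left only, so "intoxicated" and "intoxication" both count. All other
  terms require both boundaries; matching plural variants ("substances",
  "opioids") would require stemming, which is deliberately out of scope.
* **Longest term wins at equal start positions, matches never overlap.**
  "oxycodone" therefore counts once as oxycodone, not additionally as
  "oxy". The alternation is compiled longest-first and the scanner
  consumes each match, which realizes exactly this rule; the test suite
  checks it against an independent position-by-position scanner.
* **Counts, not binary indicators.** A record that names several opioids
  carries more evidence (and, in the denial failure mode, more
  *misleading* evidence) than one that names one; integer counts preserve
  that structure and remain interpretable.
* No negation handling, spelling correction, or causal reading: the
  method's documented failure modes (Narcan given without response,
  detailed denials) follow directly from this, and the synthetic
  generator reproduces them.

## Comparison featurizers

**TF-IDF** stands on scikit-learn's vectorizer with the smoothed dialect
idf(t) = ln((1 + N)/(1 + df(t))) + 1 and L2 row normalization; tokens are
lowercased word tokens of length ≥ 2, and documents concatenate all six
fields for parity with the flag features (a narrative-only mode is a
parameter). Test-set transforms reuse the training idf; out-of-vocabulary
terms are ignored.

**Concept vectorization** abstracts clinical concept embeddings behind
two plain TSV inputs: a surface-form → concept-id lexicon and a
concept-id → vector table. Surfaces are scanned case-insensitively,
longest-match-first, non-overlapping, over the chief narrative only (the
field written as a complete encounter summary); the record vector is the
unweighted mean of matched concept vectors, with multiplicity, and a zero
vector when nothing matches. The mean is the minimal aggregation choice
given that no weighting rule is canonical. The packaged
`demo_concept_resources()` is a synthetic stand-in (seeded Gaussian
vectors over the keyword surfaces plus a few clinical phrases) so that
benchmarks and tests need no external download; externally licensed
embedding releases can be supplied as the same TSV formats.

## Learners and training protocol

All four architectures share one protocol: stratified k-fold
cross-validation (default k = 5, 10 repeats) with random-search
hyperparameter selection (default 30 draws) scored by mean fold AUROC.
Fold assignments are drawn once per repeat, *before* the search, so every
candidate is compared on identical folds. The winner (ties: smaller model
by a per-architecture complexity key, then earlier draw) is refit on all
training rows. Out-of-fold predictions from the winner's first repeat are
retained; they are the stacking inputs. Class imbalance is handled by
stratification only — no weights or resampling.

Per-architecture notes:

* **glm** — logistic regression with a fixed tiny L2 ridge (λ = 1e-8).
  The ridge exists because flag counts can separate synthetic cohorts
  perfectly, where the pure maximum-likelihood solution diverges; at
  1e-8 the fit is numerically stable and separable data still yields
  AUROC exactly 1. No tuned hyperparameters, so its CV trace has one
  entry.
* **nnet** — one logistic hidden layer (size tuned over 1–10), logistic
  output, weight decay tuned log-uniformly over [1e-5, 1], lbfgs, inputs
  standardized inside the model.
* **naive_bayes** — Gaussian class-conditionals with a tuned variance
  floor, plus a tuned kernel-density variant (per-feature Gaussian KDE,
  Silverman bandwidth times a tuned adjustment, bandwidth floored at
  1e-3 so constant features stay well-defined). The KDE variant is
  implemented in-package.
* **xgb_tree** — gradient-boosted trees tuned over rounds (50–300),
  depth (2–8), log-uniform learning rate, row and column subsampling;
  single-threaded and seeded for determinism.

**Stacking** fits an unpenalized (C = 1e10, tol = 1e-10) logistic
regression of the training labels on the base models' out-of-fold
probabilities — probabilities, not logits, as inputs, with an intercept
and unconstrained coefficients. Fitting on out-of-fold rather than
in-sample predictions is what keeps the combiner honest; the suite
asserts the combiner never sees in-sample base predictions. A single-base
ensemble is a monotone transform of its base and reproduces its AUROC
exactly.

## Evaluation

* **AUROC** — Mann–Whitney with ties at 0.5, computed via midranks.
* **DeLong variance** — var(V10)/m + var(V01)/n from placement values
  (sample variances, ddof = 1); the fast midrank layout is verified
  against a naive double-loop oracle to 1e-12. Wald CIs are truncated to
  [0, 1]; perfect separation gives a zero-width interval at the point
  estimate rather than a pretense of uncertainty.
* **Confusion tables** — prediction positive iff score ≥ threshold
  (default 0.5, exposed as a flag since no canonical cutoff exists);
  undefined ratios are reported as unknown, never as 0.
* **Filter importance** — each column's standalone AUROC; the
  direction-agnostic score max(auc, 1 − auc) ranks a reverse-coded
  predictor as informative. Constant columns score 0.5. Ranks are unique
  (ties broken by column name).
* **Parity tests** — pairwise two-proportion chi-square with the Yates
  continuity correction, implemented directly with the standard clamp
  min(0.5, |o − e|) so identical proportions give a statistic of exactly
  zero. False-negative denominators are per-group condition positives;
  false-positive denominators per-group condition negatives. Groups with
  empty denominators are excluded with a warning. Holm adjustment is
  available but off by default. The correction makes the test
  conservative: its null rejection rate sits at or below α.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  rater, from the ANOVA decomposition
  (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n). A ratings matrix with
  no variance has an undefined coefficient and is reported as unknown.

## Synthetic cohort generator

The generator is the package's stand-in for protected EMS records. It
emulates: ~15% positive prevalence (Bernoulli per record); three county
strata weighted like the study counties; demographics with an explicit
"unknown" category; positive ages uniform on 16–90; and text built from a
~260-token neutral clinical vocabulary with keywords planted in signaled
fields (at least one opioid plus one overdose term, with
Poisson-distributed extras).

Defaults that define the benchmark conditions:

* **Per-field signal probabilities** (narrative 0.65, impression 0.45,
  complaint 0.30, call nature 0.12, medication/history 0.08) favor the
  chief narrative and primary impression, matching the observed
  importance ordering of flag features. They are deliberately
  sub-saturating: roughly one positive in ten carries no keyword at all,
  which keeps held-out flag AUROCs in the mid-0.90s — the regime a
  well-built flags classifier occupies on real records — rather than
  collapsing the benchmark into perfect separation where featurizers
  cannot be distinguished.
* **Zipf-skewed keyword frequencies**: common drug names dominate and
  some terms stay rare, as in real encounter language. Pooling rare
  terms into a single count is precisely the statistical advantage of
  the flag features over per-token bag-of-words weights.
* **Confounder rates** follow the documented error-tally ratios
  25 : 8 : 6 : 3 : 3 over the keys (narcan_no_response, detailed_denial,
  history_only, behavioral_health_focus, unnamed_product), rescaled to a
  total mass of 0.10 per eligible class. Each confounder rewrites a
  record the way the corresponding real-world failure mode reads: a
  negative gains "narcan ... no improvement"; a negative's narrative
  denies ≥ 3 distinct named opioids; opioid terms appear only in a
  negative's history/medication fields; a positive's narrative loses its
  keywords to a behavioral-health crisis description; a positive's drug
  is only an unnamed product ("unknown pain pills").
* **Filler is validated at config time** against the matching rules
  (including the prefix rule), and confounder phrase tokens also occur
  innocuously as ordinary filler. Together these guarantee the oracle
  property: the flag featurization of a generated cohort equals the
  ground-truth planted-count matrix exactly, cell for cell.
* The innocuous-keyword base rate for negatives defaults to 0 (a config
  knob, `negative_keyword_rate`): no defensible nonzero default exists,
  and zero preserves the exactness of the oracle linkage.

What the generator does *not* emulate: linguistic structure (word order
carries no meaning), misspellings and abbreviation noise, correlation
between demographics and outcome, county-specific documentation styles,
and genuinely ambiguous presentations. Consequently, passing benchmarks
demonstrate the correctness and relative behavior of the machinery —
featurizers, training protocol, stacking, inference — under the stated
conditions, not field performance on real records.

## Numerical and scale choices

Everything downstream of a seed is deterministic: generation, fold
assignment, candidate draws, fits (single-threaded, seeded), stacking,
and report serialization (sorted JSON keys), so a benchmark report is
byte-reproducible from its configuration. The test and acceptance
benchmarks run the protocol at reduced search budgets (1–2 repeats, 2–3
random-search draws) and n = 3000 cohorts; these sizes are the package's
declared benchmark conditions, and the production defaults (10 repeats,
30 draws) remain available through `CvConfig`.

Known limitations: no paired DeLong test between correlated ROC curves
(models are compared by overlapping CIs); no probability calibration; no
negation or causality handling in the featurizer; the annotation-phase
machinery (batch selection, stopping rule on the CI lower bound ≥ 0.90,
ICC) supports but does not replace human annotation.
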
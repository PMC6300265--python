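# Methods

This note documents the models, estimators and design choices of
`mps2screen` — what is computed, under which assumptions, with which
defaults, and what the synthetic-data experiments do and do not demonstrate.

## The screening problem and the model

The target condition, MPS II (Hunter syndrome), is an X-linked lysosomal
storage disorder screened for in male primary-care patients using 19
dichotomous symptom indicators plus a binary age class (≤ 21 vs > 21 years).
The classifier is a Bernoulli naive Bayes model:

- prior: `P(y) = n_y / n` from the training class counts;
- conditionals: `P(xᵢ=1|y) = (cᵢ,y + α) / (n_y + 2α)` with additive
  smoothing `α` (default 1, Laplace);
- posterior: `P(y|x) ∝ P(y)·Πᵢ P(xᵢ|y)^{xᵢ}(1−P(xᵢ|y))^{1−xᵢ}`;
- decision: MAP, with ties broken to the negative class — the conservative
  default for a screening tool whose false flags trigger an expensive
  confirmatory enzyme test.

All products are computed as log-sums; with 20 features and conditionals
near 10⁻³ a raw product underflows well before it becomes uninformative.
`α = 0` is supported for the exact small-model oracle tests; with `α = 0`
an impossible feature/class combination yields a −∞ log score, and a record
impossible under *both* classes gets NaN probabilities and MAP class 0.

### Why smoothing is on by default

With 73 positive training records, several symptom/class combinations are
never observed; `α = 0` would make a single unseen combination zero out an
entire posterior. Laplace smoothing keeps every conditional strictly inside
(0, 1) at negligible bias for the sample sizes involved.

## Training-set construction

- **MPS index.** `MPSi = Σₛ wₛ·xₛ` with the published per-symptom
  frequencies as weights (sum over all 19 = 9.855). It is used only to find
  *low*-symptom patients.
- **Negative selection.** Within each age stratum a normal law is fitted to
  MPSi (sample mean and SD — the reference line of the stratum's normal Q-Q
  plot, whose points use plotting positions `(i − 0.5)/n`). Patients whose
  fitted-normal percentile is strictly below a cutoff are eligible; the
  requested number (default 971, allocated to strata proportionally to
  stratum size) is drawn uniformly without replacement and labeled 0.
  **Default cutoff 0.30:** under the default background model more than
  half of all patients carry no symptom at all, which places MPSi = 0 near
  the 25th fitted-normal percentile; a 0.25 cutoff can therefore exclude
  even the minimum attainable index and empty the eligible set. 0.30
  guarantees the zero-symptom mass is always eligible while still selecting
  only bottom-of-distribution patients. The cutoff is a configuration knob.
- **Artificial positives.** Independent Bernoulli draws from the published
  frequencies (default 73 records), labeled 1.
- **Age.** Raw ages are used only to stratify; the classifier sees the
  binary class (1 iff age ≤ 21, boundary inclusive). The positives' age
  profile is not published; it is a parameter with default 75% ≤ 21,
  reflecting the pediatric onset of the disease. Binarization happens after
  selection, mirroring the study's ordering.

## Feature screening and selection

- **Phi coefficient** between binary features checks the independence
  assumption; on 0/1 coding it equals the Pearson correlation. Undefined
  values (constant vectors) are reported as NaN, never as 0.
- **Per-feature PPV** `P(y=1|x=1)` with retention cutoff 0.15; features
  exactly at the cutoff are retained (the published feature table keeps
  three features at 0.15). NaN (no carriers) cannot meet the cutoff.
- **ROC filter importance**: trapezoidal AUC from a cutoff sweep over the
  feature values — for a binary feature this is (sensitivity +
  specificity)/2 at the single nontrivial cutoff — folded to
  `max(AUC, 1 − AUC)` on a 0–1 scale. It equals the Mann-Whitney
  U statistic divided by n₁n₀ (tested).
- **Recursive backward elimination**: from all 20 attributes, tentatively
  drop each remaining feature, re-cross-validate the NBC (stratified
  k-fold, default 10 folds × 3 replicates; the same folds are used for all
  candidates within a step), and commit the drop that maximizes mean CV
  accuracy. Ties are resolved by dropping the candidate with the lower ROC
  importance, then lexicographically, so the path is deterministic given
  the seed. The path records accuracy/kappa mean and SD at every subset
  size; the best subset is the one with the largest mean accuracy (the
  larger subset on ties). The final model uses the intersection of the best
  subset with the PPV-filter survivors.
- **Stratified folds** are required because 73/1044 positives would
  otherwise produce positive-free folds; fold assignment is shuffled
  round-robin per class. Leave-one-out-style folds (k close to n) cannot
  hold both classes in every fold; single-class test folds still score
  accuracy, and fold-level kappa is skipped where undefined.

## Performance estimation

- **Validation-set approach**: one stratified 70/30 split (fraction
  configurable), fit on the large part, report confusion-matrix metrics,
  kappa and ASE/SSE on the held-out part.
- **Bootstrap** (default B = 1000): resample n with replacement, refit,
  evaluate on the out-of-bag records. The evaluation set for each replicate
  is not specified in the protocol this reimplements; out-of-bag evaluation
  is the standard uncertainty-estimation choice and is used here.
  Replicates with an empty OOB set or a single-class resample are skipped
  and counted.
- **Squared-error scores**: `SSE = Σ_cases Σ_{c∈{0,1}} (p_c − 1[y=c])²`,
  `ASE = SSE/(2n)`. Summing over both class coordinates is the convention
  under which the published SSE and ASE figures are mutually consistent
  (6600.840/(2·151950) = 0.0217 → 0.022).
- **Cohen's kappa** uses expected agreement from the row/column marginals;
  `p_e = 1` (both marginals degenerate) reports NaN. All zero-denominator
  metrics are NaN, never 0. Report rounding (3–4 decimals) happens only at
  display time; tests compare pre-rounded values.
- **Combination table**: distinct symptom patterns among flagged patients
  with incidence ≥ 1.6% (of flagged patients), plus per-symptom totals.
  Each symptom's percentage is its share of the *grand total of symptom
  occurrences*, not of the patient count — the convention that reproduces
  the published totals row (58 of 489 → 11.9%).

## TAN comparator

The tree-augmented naive Bayes relaxes conditional independence minimally:
a Chow-Liu maximum-weight spanning tree over pairwise class-conditional
mutual information `I(Xᵢ;Xⱼ|Y)` (estimated with the same smoothing α as the
CPTs; zero-count cells contribute 0), with deterministic tie-breaks
(lexicographic edge order in Kruskal's algorithm) and the root fixed at the
alphabetically first feature, edges directed away from the root. CPTs
`P(xᵢ|parent, y)` use additive smoothing; classification is MAP in log
space with ties to class 0. With a single feature the model degenerates to
a plain NBC. The richer Bayesian-network variants that appear in the
published comparison (BAN, MBN) were built in a proprietary tool with an
unspecified structure-learning method and are deliberately **not**
implemented; their published confusion counts are handled purely by the
metrics arithmetic.

Feature–target independence is tested with the Pearson chi-square statistic
on the 2×2 table, no continuity correction, 1 df (uncorrected Pearson is
the default in the framework this mirrors); zero marginals report NaN.

## Synthetic cohorts: what they emulate and what they do not

The generators reproduce the *assumed* structure of the source data:
independent Bernoulli symptom flags given the label (the NBC's own
generating assumption, and exactly how the artificial positives were
built), a two-stratum age structure (default 25% ≤ 21 in the population),
and a rare-disease mixture (default prevalence 2.5×10⁻⁴). The background
symptom prevalence of non-cases is not published; the default is a uniform
0.03 per symptom — chosen once because it yields right-skewed MPSi
distributions with most values below 2, qualitatively matching the
published Q-Q plots — and is configurable.

They do **not** emulate: symptom co-occurrence in real patients (comorbid
clusters violate conditional independence), age-dependent symptom
accumulation, coding/extraction noise from EMR text, or the real background
prevalence profile. Consequently, passing tests demonstrate correctness of
the *algorithms* and recoverability under the stated assumptions — not
field performance on real EMR data. In particular the synthetic screen
flags ~0.5% of patients (background carriers of ≥ 3 high-weight symptoms),
whereas the published screen flagged 0.025%; the published flag counts are
not reproducible without the original extract and are treated as
report-format inputs only.

## Pipeline and reproducibility

`run_full_study` executes all stages in order and writes every artifact
plus a manifest (config snapshot, per-stage seeds, output inventory,
timings). Each stage's seed is derived from the master seed by hashing the
stage name (SHA-256, reduced below 2³¹), so re-running any stage — or the
whole study — with the same configuration is bit-identical. The screening
universe excludes the selected training negatives (the published analysis
screens 505526 = 506497 − 971 patients, consistent with this reading).
Problem sizes used in the examples and tests (50,000-patient populations,
B = 200 bootstrap replicates) are scaled-down choices that keep the
demonstrations quick while leaving every estimator's behavior unchanged;
full-scale defaults (506497 patients, B = 1000) remain the configuration
defaults.

## Known limitations

- The published validation contingency table is internally inconsistent
  (its printed accuracy/kappa/sensitivity summaries are not derivable from
  its own counts); this package reproduces the count-derived values and
  documents the discrepancy in `mps2screen.reference`.
- PPV values on regenerated synthetic data differ from the published
  per-feature PPV column (which reflects the real extract's background
  rates); the published column is retained as reference input for the
  filter's arithmetic.
- Undefined statistics propagate as NaN; downstream consumers must treat
  NaN as "undefined", not as zero.
- The classifier assumes symptoms independent given class; on real EMR
  data, correlated symptom clusters will inflate posteriors for patients
  with comorbid presentations (the TAN comparator quantifies this risk
  only partially).
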
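# mps2screen

Rare-disease case detection from binary EMR symptom flags: a reusable
screening pipeline for **Hunter syndrome (mucopolysaccharidosis type II,
MPS II)** built around a from-equations Bernoulli naive Bayes classifier.

MPS II is an X-linked lysosomal storage disorder (iduronate 2-sulphatase
deficiency) whose presenting symptoms — hearing loss, recurrent otitis,
hernias, joint stiffness, airway obstruction — are individually common in
primary care. Finding the handful of true cases in a surveillance-network
extract of ~5×10⁵ male patients is therefore a needle-in-a-haystack
classification problem with essentially no labeled cases to train on. The
pipeline implemented here addresses that with three ideas:

1. **MPS index (MPSi).** A weighted symptom sum, `MPSi = Σₛ wₛ·xₛ`, with
   weights equal to the published per-symptom frequency of MPS II (e.g.
   Hearing 0.917, Hernia 0.814, Bladder 0.014). Within each age stratum
   (≤ 21 vs > 21 years) a normal law is fitted to the MPSi distribution and
   patients in the lowest percentiles are sampled as presumed **negative**
   training patients (default 971).
2. **Artificial positives.** Labeled MPS II cases are generated as
   independent Bernoulli draws from the same published frequencies
   (default 73), giving a 1044-patient, 20-attribute training table
   (19 symptoms + binary age class).
3. **Naive Bayes with MAP decision.** `P(y|x) ∝ P(y)·Πᵢ P(xᵢ|y)`, fitted by
   smoothed counting (Laplace α = 1 by default), computed in log space, and
   classified by `ŷ = argmax_y P(y)·Πᵢ P(xᵢ|y)` with ties to the negative
   class. Feature selection combines a per-feature PPV filter (cutoff 0.15),
   trapezoidal-ROC filter importance, and recursive backward elimination
   under repeated stratified 10-fold CV; performance is estimated by a
   stratified 70/30 validation split and bootstrap resampling (B = 1000),
   and a Chow-Liu tree-augmented naive Bayes (TAN) serves as the
   dependence-aware comparator.

Because the original EMR extract is not publicly available, the package
ships a first-class synthetic-cohort generator that reproduces the
statistical structure the analysis assumes (independent Bernoulli symptom
flags given the label, a two-stratum age structure, rare-prevalence
mixtures) with ground-truth labels retained so screening recall can be
measured.

## Worked example

```python
from mps2screen import SYMPTOMS, compute_mpsi

record = {s: 0 for s in SYMPTOMS}
record.update(Joint=1, COPD=1, Diarrhea=1)
print(compute_mpsi(record))
```

prints `1.347` — the weighted sum 0.290 + 0.536 + 0.521 for a patient whose
only present symptoms are joint pain, COPD and diarrhea. A full end-to-end
run on a 50,000-patient synthetic population:

```bash
python examples/06_full_study.py
```

prints (abridged):

```
"n_population": 50000,
"n_injected_positives": 11,
"n_training": 1044,
"validation_accuracy": 1.0,
"n_screened": 49029,
"n_flagged": 268,
"screen_recall_injected": 1.0,
"screen_specificity": 0.9948,
```

meaning: the 971 training negatives were drawn from the population and
excluded from screening; all injected positives were recovered, at a false
flag rate of ~0.5% driven by background patients who happen to carry three
or more high-weight symptoms. The `examples/` directory holds one short
script per capability (index scoring, train-and-screen, feature selection,
metrics from published counts, TAN comparison, full study); the same stages
are available from the shell via `mps2screen <subcommand>` (see
`mps2screen --help`).

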
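"""Published summary figures from the original CPCSSN MPS II screening study.

These constants are *inputs*: worked-example material and arithmetic
cross-checks for the evaluation code.  They are printed summary tables from
the published screen of ~5 x 10^5 male primary-care patients, not outputs of
this package.

A note on the published validation contingency table
(:data:`REPORTED_VALIDATION_CONFUSION`): it is internally inconsistent.  The
printed counts give accuracy 376248/384063 = 0.9797 (97.97% correct, matching
the accompanying text) and sensitivity 18997/26812 = 0.709, while the table's
own summary rows print accuracy 0.99, kappa 0.91 and sensitivity 0.84, and its
"Yes" column total (26992) differs from 18997 + 7815 = 26812.  This package
reproduces the count-derived values; the printed 0.99/0.91/0.84 summaries are
not derivable from the counts and are not used anywhere as expectations.
"""

from __future__ import annotations

from .evaluate import ConfusionMatrix

#: Patients flagged by the published screen, and the number screened.
REPORTED_N_FLAGGED = 125
REPORTED_N_SCREENED = 505526

#: Published per-feature positive predictive values (feature as sole
#: predictor) for the 20 training attributes.
REPORTED_FEATURE_PPV: dict[str, float] = {
    "age_class": 0.93,
    "Apnea": 0.49,
    "COPD": 0.51,
    "Hearing": 0.92,
    "SpinalInjury": 0.15,
    "Hernia": 0.78,
    "Otitis": 0.84,
    "Stature": 0.84,
    "Macrocephaly": 0.84,
    "Respiratory": 0.49,
    "Carpal": 0.62,
    "Cardiac": 0.70,
    "Hepatosplenomegaly": 0.86,
    "Skin": 0.27,
    "Vision": 0.15,
    "Seizure": 0.15,
    "Diarrhea": 0.52,
    "Joint": 0.29,
    "Pneumonia": 0.12,
    "Bladder": 0.01,
}

#: Published validation contingency counts (see module docstring for the
#: documented internal inconsistencies of this table).
REPORTED_VALIDATION_CONFUSION = ConfusionMatrix(
    tp=18997, fp=0, tn=357251, fn=7815
)

#: Published per-network confusion counts on the 151950-case validation set.
REPORTED_NETWORK_CONFUSIONS: dict[str, ConfusionMatrix] = {
    "NBC": ConfusionMatrix(tp=38, fp=4198, tn=147714, fn=0),
    "TAN": ConfusionMatrix(tp=38, fp=3813, tn=148099, fn=0),
    "BAN": ConfusionMatrix(tp=38, fp=3325, tn=148587, fn=0),
    "MBN": ConfusionMatrix(tp=17, fp=22, tn=151890, fn=21),
}

#: Published sum of squared error for each network on the same validation set.
REPORTED_NETWORK_SSE: dict[str, float] = {
    "NBC": 6600.840,
    "TAN": 5829.130,
    "BAN": 4836.650,
    "MBN": 62.720,
}

#: Published per-symptom flag totals among the 125 flagged patients (symptoms
#: with zero occurrences omitted); the grand total of occurrences is 489.
REPORTED_SYMPTOM_TOTALS: dict[str, int] = {
    "Hearing": 58,
    "Otitis": 58,
    "COPD": 47,
    "Hernia": 45,
    "Cardiac": 45,
    "Respiratory": 42,
    "Diarrhea": 39,
    "Apnea": 38,
    "Carpal": 35,
    "SpinalInjury": 33,
    "Skin": 19,
    "Hepatosplenomegaly": 13,
    "Seizure": 11,
    "Joint": 4,
    "Stature": 2,
}
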
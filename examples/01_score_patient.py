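"""Score a single patient with the MPS symptom index.

The index is a weighted sum of the 19 binary symptom flags, each weight being
the published frequency of that symptom among MPS II patients.  A higher
index means a heavier, more disease-like symptom burden; the pipeline uses
*low* index values to pick presumed-negative training patients.
"""

from mps2screen import SYMPTOMS, compute_mpsi, default_weights

record = {s: 0 for s in SYMPTOMS}
record.update(Joint=1, COPD=1, Diarrhea=1)

weights = default_weights()
score = compute_mpsi(record, weights)

print("present symptoms: Joint, COPD, Diarrhea")
print(f"weights: Joint={weights['Joint']}, COPD={weights['COPD']}, "
      f"Diarrhea={weights['Diarrhea']}")
print(f"MPS index = {score}")
# 0.290 + 0.536 + 0.521 = 1.347: a low-burden patient (a typical MPS II
# presentation sums near 9.9 when every symptom is present).
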
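"""Canonical symptom vocabulary and frequency/weight tables for MPS II screening.

Hunter syndrome (mucopolysaccharidosis type II, MPS II) is an X-linked lysosomal
storage disorder whose individually common presenting symptoms — hearing loss,
recurrent otitis, hernias, joint stiffness, airway disease — make case finding in
primary-care EMR data difficult.  The screening pipeline in this package works on
19 dichotomous symptom flags per (male) patient, plus a binary age class, for 20
attributes in total.

Two tabular objects are defined here:

``FrequencyTable``
    symptom -> probability in [0, 1].  Used by the synthetic-cohort generators as
    per-symptom Bernoulli parameters.

``WeightVector``
    symptom -> non-negative weight.  Used by the MPS index (a weighted symptom
    sum; see :mod:`mps2screen.index`).

The default values for both are the published per-symptom frequencies of MPS II
in previously reported patient populations (e.g. hearing loss, short stature and
macrocephaly each near 0.92; bladder obstruction at 0.014).  The same numbers
serve as index weights and as generating frequencies for artificial positive
patients, which is exactly how the screening design uses them.
"""

from __future__ import annotations

import csv
import json
import math
from collections.abc import Mapping
from pathlib import Path

import numpy as np

#: Canonical ordering of the 19 dichotomous symptom features.
SYMPTOMS: tuple[str, ...] = (
    "Stature",
    "Joint",
    "Apnea",
    "COPD",
    "Hearing",
    "SpinalInjury",
    "Hernia",
    "Otitis",
    "Respiratory",
    "Carpal",
    "Cardiac",
    "Hepatosplenomegaly",
    "Skin",
    "Seizure",
    "Diarrhea",
    "Macrocephaly",
    "Vision",
    "Pneumonia",
    "Bladder",
)

#: Published approximate frequency of each symptom among MPS II patients.
#: These double as the weights of the MPS index and as the Bernoulli
#: parameters for artificially generated positive patients.
MPS2_SYMPTOM_FREQUENCIES: dict[str, float] = {
    "Stature": 0.917,
    "Joint": 0.290,
    "Apnea": 0.537,
    "COPD": 0.536,
    "Hearing": 0.917,
    "SpinalInjury": 0.153,
    "Hernia": 0.814,
    "Otitis": 0.836,
    "Respiratory": 0.493,
    "Carpal": 0.643,
    "Cardiac": 0.699,
    "Hepatosplenomegaly": 0.863,
    "Skin": 0.274,
    "Seizure": 0.153,
    "Diarrhea": 0.521,
    "Macrocephaly": 0.917,
    "Vision": 0.155,
    "Pneumonia": 0.123,
    "Bladder": 0.014,
}


class SymptomTable(Mapping):
    """Ordered, validated symptom -> value map over the canonical 19 symptoms.

    Keys must be exactly :data:`SYMPTOMS` (any input order; stored canonically).
    Subclasses restrict the admissible value range.
    """

    _lo: float = -math.inf
    _hi: float = math.inf
    _kind: str = "value"

    def __init__(self, values: Mapping[str, float]):
        missing = [s for s in SYMPTOMS if s not in values]
        extra = [s for s in values if s not in SYMPTOMS]
        if missing or extra:
            raise ValueError(
                f"symptom names must match the canonical 19 exactly; "
                f"missing={missing!r} unexpected={extra!r}"
            )
        data: dict[str, float] = {}
        for s in SYMPTOMS:
            v = float(values[s])
            if not (self._lo <= v <= self._hi) or math.isnan(v):
                raise ValueError(
                    f"invalid {self._kind} {v!r} for symptom {s!r}: "
                    f"must lie in [{self._lo}, {self._hi}]"
                )
            data[s] = v
        self._data = data

    def __getitem__(self, key: str) -> float:
        return self._data[key]

    def __iter__(self):
        return iter(SYMPTOMS)

    def __len__(self) -> int:
        return len(SYMPTOMS)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self._data!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, SymptomTable):
            return self._data == other._data
        return NotImplemented

    def as_array(self) -> np.ndarray:
        """Values as a float array in canonical symptom order."""
        return np.array([self._data[s] for s in SYMPTOMS], dtype=float)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as a flat symptom -> value JSON object."""
        text = json.dumps(self._data, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path):
        return cls(json.loads(Path(path).read_text()))

    @classmethod
    def from_csv(cls, path: str | Path):
        """Read a two-column ``symptom,value`` CSV (with header)."""
        values: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("symptom", "feature"):
                    continue
                values[row[0].strip()] = float(row[1])
        return cls(values)

    @classmethod
    def from_file(cls, path: str | Path):
        path = Path(path)
        if path.suffix.lower() == ".csv":
            return cls.from_csv(path)
        return cls.from_json(path)


class FrequencyTable(SymptomTable):
    """Per-symptom Bernoulli probabilities, each in [0, 1]."""

    _lo, _hi, _kind = 0.0, 1.0, "probability"


class WeightVector(SymptomTable):
    """Per-symptom non-negative index weights."""

    _lo, _hi, _kind = 0.0, math.inf, "weight"


def mps2_frequencies() -> FrequencyTable:
    """The published MPS II symptom frequencies as a :class:`FrequencyTable`."""
    return FrequencyTable(MPS2_SYMPTOM_FREQUENCIES)


def default_weights() -> WeightVector:
    """The MPS-index weight vector (same numbers as the symptom frequencies)."""
    return WeightVector(MPS2_SYMPTOM_FREQUENCIES)


def uniform_background(prevalence: float = 0.03) -> FrequencyTable:
    """Uniform background symptom prevalence for non-cases.

    The real primary-care background rates are not published; a configurable
    uniform stand-in (default 0.03 per symptom) gives index distributions that
    are right-skewed with most values below 2, matching the qualitative shape
    reported for the source population.
    """
    return FrequencyTable({s: prevalence for s in SYMPTOMS})
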
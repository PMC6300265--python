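"""Patient cohorts: the tabular container shared by every pipeline stage.

A cohort is one row per patient with an opaque string id, age in years, the 19
binary symptom flags in canonical order and an optional 0/1 ``label`` column
(ground-truth disease status, available in simulation).  On disk a cohort is a
plain CSV with exactly those columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .symptoms import SYMPTOMS

ID_COL = "id"
AGE_COL = "age"
LABEL_COL = "label"


@dataclass
class AgeProfile:
    """Two-stratum age model: a proportion of patients aged <= 21 years.

    Ages are uniform within each stratum.  The screening model only ever uses
    the binary stratum membership, so the within-stratum law is a convenience
    for generating realistic-looking continuous ages.
    """

    prop_young: float = 0.25
    young_range: tuple[float, float] = (0.0, 21.0)
    old_range: tuple[float, float] = (21.0, 90.0)

    def __post_init__(self):
        if not 0.0 <= self.prop_young <= 1.0:
            raise ValueError(f"prop_young must be in [0,1], got {self.prop_young}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        young = rng.random(n) < self.prop_young
        ages = np.empty(n, dtype=float)
        ages[young] = rng.uniform(*self.young_range, size=int(young.sum()))
        # old stratum is strictly above 21
        lo = np.nextafter(self.old_range[0], np.inf)
        ages[~young] = rng.uniform(lo, self.old_range[1], size=int((~young).sum()))
        return ages


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in (ID_COL, AGE_COL, *SYMPTOMS) if c not in frame.columns]
    known = {ID_COL, AGE_COL, LABEL_COL, *SYMPTOMS}
    unknown = [c for c in frame.columns if c not in known]
    if missing or unknown:
        raise ValueError(
            f"cohort columns mismatch: missing={missing!r} unknown={unknown!r}"
        )
    frame = frame.copy()
    frame[ID_COL] = frame[ID_COL].astype(str)
    if frame[ID_COL].duplicated().any():
        dupes = frame.loc[frame[ID_COL].duplicated(), ID_COL].tolist()[:5]
        raise ValueError(f"duplicate patient ids in cohort: {dupes!r}")
    ages = pd.to_numeric(frame[AGE_COL])
    if (ages < 0).any():
        row = int(np.flatnonzero(ages.to_numpy() < 0)[0])
        raise ValueError(f"negative age at row {row}")
    frame[AGE_COL] = ages.astype(float)
    cols = [LABEL_COL] if LABEL_COL in frame.columns else []
    for col in (*SYMPTOMS, *cols):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-binary value {frame[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        frame[col] = vals.astype(np.int8)
    order = [ID_COL, AGE_COL, *SYMPTOMS] + cols
    return frame[order].reset_index(drop=True)


@dataclass
class Cohort:
    """An ordered collection of patient records.

    Parameters
    ----------
    frame
        Columns ``id, age, <19 symptoms>[, label]``.  Flags must be 0/1, ids
        unique.  Columns are reordered canonically on construction.
    provenance
        Free-text tag recording generator parameters or the file of origin.
    """

    frame: pd.DataFrame
    provenance: str = field(default="")

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_labels(self) -> bool:
        return LABEL_COL in self.frame.columns

    @property
    def ids(self) -> pd.Series:
        return self.frame[ID_COL]

    @property
    def ages(self) -> np.ndarray:
        return self.frame[AGE_COL].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise ValueError("cohort has no label column")
        return self.frame[LABEL_COL].to_numpy()

    def symptom_matrix(self) -> np.ndarray:
        """(n, 19) int8 matrix of flags in canonical symptom order."""
        return self.frame[list(SYMPTOMS)].to_numpy(dtype=np.int8)

    def with_labels(self, label: int) -> "Cohort":
        frame = self.frame.copy()
        frame[LABEL_COL] = np.int8(label)
        return Cohort(frame, provenance=self.provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.frame.to_csv(path, index=False)


def read_cohort(path: str | Path, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV, validating schema and flag values.

    Raises ``ValueError`` naming the offending column/row on any schema or
    value violation.
    """
    frame = pd.read_csv(path, dtype={ID_COL: str})
    return Cohort(frame, provenance=provenance if provenance is not None else str(path))


def empty_cohort(with_label: bool = True, provenance: str = "") -> Cohort:
    cols = [ID_COL, AGE_COL, *SYMPTOMS] + ([LABEL_COL] if with_label else [])
    return Cohort(pd.DataFrame(columns=cols), provenance=provenance)
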
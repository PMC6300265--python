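"""The MPS index (MPSi), age binarization, and training-set assembly.

The MPS index is a weighted sum of a patient's 19 binary symptom flags,

    MPSi = sum_s w_s * flag_s,

with weights equal to the published per-symptom frequency of MPS II (e.g. a
patient with joint pain, COPD and diarrhea only scores
0.290 + 0.536 + 0.521 = 1.347).  Its sole purpose in the pipeline is to find
patients with the *lowest* symptom burden: within each age stratum (<= 21 vs
> 21 years), a normal law is fitted to the MPSi distribution (the reference
line of a normal Q-Q plot) and patients whose fitted-normal percentile falls
below a cutoff are eligible to be sampled, uniformly without replacement, as
presumed-negative training patients.  Those selected negatives, together with
artificially generated positives, form the labeled training set (historically
971 + 73 = 1044 patients, 20 attributes: 19 symptoms + the binary age class).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_COL, ID_COL, LABEL_COL, Cohort
from .symptoms import SYMPTOMS, WeightVector, default_weights

AGE_CLASS_COL = "age_class"

#: The 20 training attributes: binary age class plus the 19 symptoms.
TRAINING_FEATURES: tuple[str, ...] = (AGE_CLASS_COL, *SYMPTOMS)

#: Default eligibility cutoff on the fitted-normal MPSi percentile.  Chosen so
#: that under the default 0.03 uniform background — where over half of all
#: patients carry no symptom at all, placing MPSi = 0 near the 25th fitted
#: percentile — the zero-symptom mass is always eligible.
DEFAULT_PERCENTILE_CUTOFF = 0.30


def compute_mpsi(record: Mapping[str, int] | pd.Series, weights: WeightVector | None = None) -> float:
    """MPS index of a single patient record (mapping symptom -> 0/1 flag).

    Extra non-symptom keys (id, age, label) are ignored; all 19 symptoms must
    be present.
    """
    weights = weights if weights is not None else default_weights()
    missing = [s for s in SYMPTOMS if s not in record]
    if missing:
        raise ValueError(f"record is missing symptom flags: {missing!r}")
    total = 0.0
    for s in SYMPTOMS:
        flag = record[s]
        if flag not in (0, 1):
            raise ValueError(f"non-binary flag {flag!r} for symptom {s!r}")
        total += weights[s] * flag
    return total


def mpsi_scores(cohort: Cohort | pd.DataFrame, weights: WeightVector | None = None) -> pd.Series:
    """Vectorized MPSi for every patient; Series aligned with the frame."""
    weights = weights if weights is not None else default_weights()
    frame = cohort.frame if isinstance(cohort, Cohort) else cohort
    flags = frame[list(SYMPTOMS)].to_numpy(dtype=float)
    return pd.Series(flags @ weights.as_array(), index=frame.index, name="mpsi")


def binarize_age(age):
    """Binary age class: 1 for age <= 21 years ("Y"), 0 otherwise ("N").

    Accepts a scalar or array; rejects negative ages.
    """
    arr = np.asarray(age, dtype=float)
    if (arr < 0).any():
        raise ValueError(f"negative age: {age!r}")
    out = (arr <= 21.0).astype(np.int8)
    return int(out) if np.isscalar(age) or arr.ndim == 0 else out


@dataclass
class QQPoints:
    """Normal Q-Q data for one age stratum's MPSi distribution.

    ``theoretical`` holds standard-normal quantiles at plotting positions
    (i - 0.5)/n; ``observed`` the sorted MPSi values.  ``mean``/``sd`` define
    the fitted reference line; ``degenerate`` is set when the stratum has zero
    variance (the reference line is then meaningless).
    """

    theoretical: np.ndarray
    observed: np.ndarray
    mean: float
    sd: float
    degenerate: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theoretical_quantile": self.theoretical, "observed_mpsi": self.observed}
        )


def qq_points(cohort: Cohort, weights: WeightVector | None = None, stratum: int = 1) -> QQPoints:
    """Q-Q plot points of MPSi within one age stratum (1 = young, 0 = old)."""
    scores = mpsi_scores(cohort, weights).to_numpy()
    in_stratum = binarize_age(cohort.ages) == stratum
    vals = np.sort(scores[in_stratum])
    n = len(vals)
    if n == 0:
        raise ValueError(f"age stratum {stratum} is empty")
    positions = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(positions)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return QQPoints(theo, vals, mean, sd, degenerate=(sd == 0.0))


def _stratum_allocation(total: int, stratum_sizes: dict[int, int]) -> dict[int, int]:
    """Proportional allocation of ``total`` across the two strata."""
    n = sum(stratum_sizes.values())
    if n == 0:
        raise ValueError("empty cohort")
    n_young = round(total * stratum_sizes.get(1, 0) / n)
    return {1: n_young, 0: total - n_young}


def select_low_mpsi_negatives(
    cohort: Cohort,
    weights: WeightVector | None = None,
    n_per_stratum: int | dict[int, int] = 971,
    percentile_cutoff: float = DEFAULT_PERCENTILE_CUTOFF,
    *,
    seed: int,
) -> Cohort:
    """Sample presumed negatives with the lowest MPS index, per age stratum.

    Within each stratum a normal law is fitted to MPSi (sample mean and SD,
    the Q-Q reference line); patients whose fitted-normal percentile is
    strictly below ``percentile_cutoff`` are eligible, and the requested
    number is drawn uniformly without replacement.  Returned records carry
    label 0 and keep their raw ages.

    ``n_per_stratum`` may be a mapping ``{1: n_young, 0: n_old}`` or a single
    total, allocated proportionally to stratum sizes.
    """
    if not 0.0 <= percentile_cutoff <= 1.0:
        raise ValueError(f"percentile_cutoff must be in [0,1], got {percentile_cutoff}")
    weights = weights if weights is not None else default_weights()
    scores = mpsi_scores(cohort, weights).to_numpy()
    strata = binarize_age(cohort.ages)
    sizes = {s: int((strata == s).sum()) for s in (1, 0)}
    wanted = (
        dict(n_per_stratum)
        if isinstance(n_per_stratum, dict)
        else _stratum_allocation(int(n_per_stratum), sizes)
    )
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for s in (1, 0):
        want = int(wanted.get(s, 0))
        if want == 0:
            continue
        idx = np.flatnonzero(strata == s)
        vals = scores[idx]
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if sd == 0.0:
            # all MPSi equal: everyone is jointly "lowest"
            eligible = idx
        else:
            pct = stats.norm.cdf((vals - mean) / sd)
            eligible = idx[pct < percentile_cutoff]
        if len(eligible) < want:
            raise ValueError(
                f"stratum {s}: only {len(eligible)} patients below the "
                f"{percentile_cutoff:.0%} MPSi percentile, need {want} "
                f"(shortfall {want - len(eligible)})"
            )
        chosen.append(rng.choice(eligible, size=want, replace=False))
    take = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    frame = cohort.frame.iloc[take].reset_index(drop=True).copy()
    frame[LABEL_COL] = np.int8(0)
    return Cohort(
        frame,
        provenance=(
            f"low-MPSi negatives cutoff={percentile_cutoff} n={wanted} seed={seed}"
        ),
    )


@dataclass
class TrainingSet:
    """Labeled training table: id, binary age class, 19 symptoms, label."""

    frame: pd.DataFrame

    def __post_init__(self):
        needed = [ID_COL, LABEL_COL]
        missing = [c for c in needed if c not in self.frame.columns]
        if missing:
            raise ValueError(f"training frame missing columns {missing!r}")
        feats = [c for c in self.frame.columns if c in TRAINING_FEATURES]
        if not feats:
            raise ValueError("training frame has no feature columns")
        unknown = [
            c for c in self.frame.columns if c not in (*needed, *TRAINING_FEATURES)
        ]
        if unknown:
            raise ValueError(f"unknown training columns {unknown!r}")
        order = [ID_COL] + [f for f in TRAINING_FEATURES if f in feats] + [LABEL_COL]
        self.frame = self.frame[order].reset_index(drop=True)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c in TRAINING_FEATURES)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.feature_names)]

    @property
    def y(self) -> np.ndarray:
        return self.frame[LABEL_COL].to_numpy(dtype=np.int8)

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())

    def __len__(self) -> int:
        return len(self.frame)

    def restrict(self, features) -> "TrainingSet":
        """A view keeping only the given feature columns (id/label retained)."""
        keep = [f for f in TRAINING_FEATURES if f in set(features)]
        if not keep:
            raise ValueError("cannot restrict to an empty feature set")
        return TrainingSet(self.frame[[ID_COL, *keep, LABEL_COL]])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingSet":
        return cls(pd.read_csv(path, dtype={ID_COL: str}))


def build_training_set(negatives: Cohort, positives: Cohort) -> TrainingSet:
    """Union of labeled cohorts with age replaced by the binary age class.

    Requires disjoint ids and at least one record of each class (a
    single-class table cannot train a classifier).
    """
    if not negatives.has_labels or not positives.has_labels:
        raise ValueError("both cohorts must carry labels")
    if len(negatives) == 0 or len(positives) == 0:
        raise ValueError(
            f"degenerate training set: {len(negatives)} negatives, "
            f"{len(positives)} positives — both classes are required"
        )
    overlap = set(negatives.ids) & set(positives.ids)
    if overlap:
        raise ValueError(f"overlapping patient ids: {sorted(overlap)[:5]!r}")
    rows = []
    for cohort in (negatives, positives):
        part = cohort.frame.copy()
        part[AGE_CLASS_COL] = binarize_age(part[AGE_COL].to_numpy())
        rows.append(part[[ID_COL, AGE_CLASS_COL, *SYMPTOMS, LABEL_COL]])
    return TrainingSet(pd.concat(rows, ignore_index=True))
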
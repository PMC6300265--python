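import numpy as np
import pandas as pd
import pytest

from mps2screen import SYMPTOMS, Cohort, TrainingSet
from mps2screen.cohort import AGE_COL, ID_COL, LABEL_COL
from mps2screen.index import AGE_CLASS_COL


def make_cohort(flags_rows, ages=None, labels=None, ids=None) -> Cohort:
    """Build a small cohort from sparse symptom dicts ({symptom: flag})."""
    n = len(flags_rows)
    frame = pd.DataFrame(
        [{s: row.get(s, 0) for s in SYMPTOMS} for row in flags_rows]
    )
    frame.insert(0, AGE_COL, ages if ages is not None else [30.0] * n)
    frame.insert(0, ID_COL, ids if ids is not None else [f"T{i:04d}" for i in range(n)])
    if labels is not None:
        frame[LABEL_COL] = labels
    return Cohort(frame, provenance="test fixture")


def make_training(X: pd.DataFrame, y) -> TrainingSet:
    """Wrap a binary feature frame into a TrainingSet (missing cols zeroed)."""
    frame = pd.DataFrame(index=X.index)
    frame[ID_COL] = [f"T{i:04d}" for i in range(len(X))]
    frame[AGE_CLASS_COL] = X[AGE_CLASS_COL] if AGE_CLASS_COL in X.columns else 0
    for s in SYMPTOMS:
        frame[s] = X[s] if s in X.columns else 0
    frame[LABEL_COL] = np.asarray(y, dtype=np.int8)
    return TrainingSet(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def study_design_training():
    """Training set with the study's design: 971 synthetic background
    negatives + 73 artificial positives from the published frequencies."""
    from mps2screen import (
        build_training_set,
        generate_negative_cohort,
        generate_positive_cohort,
    )

    negatives = generate_negative_cohort(971, seed=101, id_prefix="NEG")
    positives = generate_positive_cohort(73, seed=202, id_prefix="POS")
    return build_training_set(negatives, positives)
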
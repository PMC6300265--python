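"""Performance evaluation: confusion-matrix metrics, resampling, error scores.

Covers the full evaluation protocol of the screening study:

* confusion-matrix metrics (accuracy, sensitivity, specificity, PPV/NPV,
  misclassification rate, Cohen's kappa, percent correct);
* the validation-set approach — a single stratified 70/30 train/test split;
* bootstrap resampling (default B = 1000) with out-of-bag evaluation;
* squared-error scores of predicted class probabilities against one-hot
  truth, summed over BOTH class coordinates:  SSE = sum_cases sum_c
  (p_c - 1[y = c])^2 and ASE = SSE / (2 n).  This two-coordinate convention
  is the one under which the published SSE and ASE figures are mutually
  consistent (e.g. 6600.840 / (2 * 151950) = 0.022);
* the symptom-combination incidence table for a flagged cohort, where each
  symptom's percentage is taken of the grand total of symptom occurrences
  (not of the patient count).

Metrics with zero denominators are reported as NaN ("undefined"), never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .index import TrainingSet
from .nbc import NaiveBayesModel, fit_nbc, posterior_frame
from .symptoms import SYMPTOMS


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 contingency counts with class 1 = disease positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, truth, predicted) -> "ConfusionMatrix":
        t = np.asarray(truth, dtype=np.int8)
        p = np.asarray(predicted, dtype=np.int8)
        if t.shape != p.shape:
            raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
        if t.size == 0:
            raise ValueError("empty prediction vectors")
        return cls(
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
        )


def confusion(truth, predicted) -> ConfusionMatrix:
    return ConfusionMatrix.from_predictions(truth, predicted)


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    misclassification_rate: float
    kappa: float
    percent_correct: float
    ase: float = math.nan
    sse: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derived metrics from a confusion matrix; undefined ratios become NaN.

    Cohen's kappa uses expected agreement from the row/column marginals:
    p_e = [ (tp+fp)(tp+fn) + (fn+tn)(fp+tn) ] / n^2 and
    kappa = (p_o - p_e) / (1 - p_e), undefined when p_e = 1.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / n
    p_pos_pred = cm.tp + cm.fp
    p_pos_true = cm.tp + cm.fn
    p_e = (p_pos_pred * p_pos_true + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    return MetricsReport(
        accuracy=acc,
        sensitivity=_ratio(cm.tp, p_pos_true),
        specificity=_ratio(cm.tn, cm.fp + cm.tn),
        ppv=_ratio(cm.tp, p_pos_pred),
        npv=_ratio(cm.tn, cm.fn + cm.tn),
        misclassification_rate=1.0 - acc,
        kappa=kappa,
        percent_correct=100.0 * acc,
    )


def ase_sse(posteriors, truth) -> tuple[float, float]:
    """(ASE, SSE) of predicted class probabilities vs one-hot truth.

    ``posteriors`` is an (n, 2) array of [P(y=0|x), P(y=1|x)] rows, each
    required to sum to 1; the squared error is accumulated over both class
    coordinates, so ASE = SSE / (2 n).
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("posteriors must be an (n, 2) array")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    t = np.asarray(truth, dtype=np.int8)
    if len(t) != len(P):
        raise ValueError("length mismatch between posteriors and truth")
    onehot = np.stack([(t == 0), (t == 1)], axis=1).astype(float)
    sse = float(((P - onehot) ** 2).sum())
    return sse / (2.0 * len(t)), sse


def ase_from_sse(sse: float, n_cases: int) -> float:
    """ASE implied by an SSE over ``n_cases`` under the two-class convention."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    return sse / (2.0 * n_cases)


def prevalence_percent(n_flagged: int, n_screened: int) -> float:
    """Screening prevalence as a percentage, 100 * flagged / screened."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    return 100.0 * n_flagged / n_screened


# -- resampling --------------------------------------------------------------


def stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Index split preserving class balance; returns (train_idx, test_idx)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = int(round(fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)  # both parts keep >= 1 of each class
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class ValidationResult:
    report: MetricsReport
    cm: ConfusionMatrix
    model: NaiveBayesModel
    n_train: int
    n_test: int


def validation_set_approach(
    train: TrainingSet,
    fraction: float = 0.70,
    alpha: float = 1.0,
    *,
    seed: int,
) -> ValidationResult:
    """Single stratified split: fit on ``fraction``, evaluate on the rest.

    The report includes ASE/SSE computed from held-out posteriors.
    """
    y = train.y
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 records of each class to split")
    rng = np.random.default_rng(seed)
    tr, te = stratified_split(y, fraction, rng)
    model = fit_nbc(train.X.iloc[tr], y[tr], alpha=alpha)
    post = posterior_frame(model, train.X.iloc[te])
    cm = confusion(y[te], post["map_class"].to_numpy())
    report = metrics(cm)
    report.ase, report.sse = ase_sse(
        post[["p_negative", "p_positive"]].to_numpy(), y[te]
    )
    return ValidationResult(report, cm, model, len(tr), len(te))


@dataclass
class BootstrapResult:
    accuracy_mean: float
    accuracy_sd: float
    kappa_mean: float
    kappa_sd: float
    n_replicates: int
    n_skipped: int
    accuracies: np.ndarray = field(repr=False)


def bootstrap_performance(
    train: TrainingSet,
    B: int = 1000,
    alpha: float = 1.0,
    *,
    seed: int,
) -> BootstrapResult:
    """Bootstrap uncertainty of NBC accuracy/kappa, evaluated out-of-bag.

    Each replicate resamples n records with replacement, refits, and scores
    the records left out of the resample.  Replicates whose resample is
    single-class or whose out-of-bag set is empty are skipped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    X = train.X
    y = train.y
    n = len(y)
    accs, kappas = [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        yb = y[idx]
        if len(oob) == 0 or yb.min() == yb.max():
            skipped += 1
            continue
        model = fit_nbc(X.iloc[idx], yb, alpha=alpha)
        post = posterior_frame(model, X.iloc[oob])
        cm = confusion(y[oob], post["map_class"].to_numpy())
        rep = metrics(cm)
        accs.append(rep.accuracy)
        if not math.isnan(rep.kappa):
            kappas.append(rep.kappa)
    accs_arr = np.array(accs)
    return BootstrapResult(
        accuracy_mean=float(np.mean(accs_arr)) if len(accs_arr) else math.nan,
        accuracy_sd=float(np.std(accs_arr, ddof=1)) if len(accs_arr) > 1 else 0.0,
        kappa_mean=float(np.mean(kappas)) if kappas else math.nan,
        kappa_sd=float(np.std(kappas, ddof=1)) if len(kappas) > 1 else 0.0,
        n_replicates=B,
        n_skipped=skipped,
        accuracies=accs_arr,
    )


# -- symptom combination reporting -------------------------------------------


@dataclass
class CombinationTable:
    """Distinct symptom patterns among flagged patients, plus symptom totals.

    ``combinations``: one row per pattern with incidence >= the cutoff,
    symptom columns 0/1 plus ``count`` and ``percent`` (of flagged patients),
    sorted by incidence descending.  ``totals``: per-symptom flag counts over
    all flagged patients; ``percentages``: each symptom's share (in %) of the
    grand total of symptom occurrences.
    """

    combinations: pd.DataFrame
    totals: pd.Series
    percentages: pd.Series
    n_patients: int
    grand_total: int

    def to_frame(self) -> pd.DataFrame:
        """Report-style layout: 'x' markers, columns ordered by symptom total,
        zero-total symptoms dropped, with Total and (%) footer rows."""
        order = [s for s in self.totals.sort_values(ascending=False).index
                 if self.totals[s] > 0]
        rows = []
        for _, row in self.combinations.iterrows():
            rows.append(
                {s: ("x" if row[s] else "") for s in order}
                | {"percent": round(row["percent"], 1)}
            )
        rows.append({s: int(self.totals[s]) for s in order} | {"percent": ""})
        rows.append(
            {s: round(float(self.percentages[s]), 1) for s in order}
            | {"percent": 100.0}
        )
        out = pd.DataFrame(rows, columns=[*order, "percent"])
        out.index = [*[""] * len(self.combinations), "Total", "(%)"]
        return out


def combination_table(
    flagged: Cohort | pd.DataFrame, min_incidence: float = 0.016
) -> CombinationTable:
    """Tabulate symptom-flag patterns among screening-flagged patients.

    Patterns with incidence (count / flagged patients) below ``min_incidence``
    are omitted from the combination rows; totals always cover everyone.
    """
    frame = flagged.frame if isinstance(flagged, Cohort) else flagged
    n = len(frame)
    if n == 0:
        raise ValueError("no flagged patients to tabulate")
    flags = frame[list(SYMPTOMS)].astype(np.int8)
    counts = flags.groupby(list(SYMPTOMS), sort=False).size().rename("count")
    combos = counts.reset_index()
    combos["percent"] = 100.0 * combos["count"] / n
    combos = combos[combos["count"] / n >= min_incidence]
    combos = combos.sort_values(
        ["count", *SYMPTOMS], ascending=[False] + [False] * len(SYMPTOMS)
    ).reset_index(drop=True)
    totals = flags.sum()
    grand = int(totals.sum())
    percentages = 100.0 * totals / grand if grand > 0 else totals * math.nan
    return CombinationTable(combos, totals, percentages, n, grand)
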
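"""Bernoulli naive Bayes classifier, implemented from the defining equations.

The model assumes the binary features x_1..x_n are conditionally independent
given the binary class y (1 = MPS II positive), so

    P(y | x) ∝ P(y) * prod_i P(x_i | y),

and classifies by the maximum-a-posteriori (MAP) rule

    y_hat = argmax_y P(y) * prod_i P(x_i | y),

with ties broken to the negative class (the conservative choice for a
screening tool).  Fitting is closed-form counting with additive smoothing:

    P(y) = n_y / n,        P(x_i = 1 | y) = (c_{i,y} + alpha) / (n_y + 2*alpha),

where c_{i,y} counts training records of class y with x_i = 1.  The default
alpha = 1 (Laplace) keeps every conditional strictly inside (0, 1) so that a
feature/class combination unseen in 73 positive training records cannot zero
out an entire posterior; alpha = 0 gives the plain maximum-likelihood fit used
by the exact small-model oracles.

All products are computed as log-sums: with 20 features whose conditionals can
be ~1e-3, raw products underflow long before they become uninformative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ID_COL, LABEL_COL, Cohort
from .index import AGE_CLASS_COL, TrainingSet, binarize_age


@dataclass
class Posterior:
    """Normalized class posterior for one record plus its MAP class."""

    probs: np.ndarray  # shape (2,): P(y=0|x), P(y=1|x)
    map_class: int


@dataclass
class NaiveBayesModel:
    """Fitted priors and per-feature conditionals.

    ``feature_prob[i, y]`` is P(x_i = 1 | y); ``class_prior[y]`` is P(y).
    """

    feature_names: tuple[str, ...]
    class_prior: np.ndarray  # shape (2,)
    feature_prob: np.ndarray  # shape (n_features, 2)
    alpha: float

    def __post_init__(self):
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        self.feature_prob = np.asarray(self.feature_prob, dtype=float)
        if self.class_prior.shape != (2,) or not np.isclose(self.class_prior.sum(), 1.0):
            raise ValueError("class priors must be two probabilities summing to 1")
        if self.feature_prob.shape != (len(self.feature_names), 2):
            raise ValueError("feature_prob must have shape (n_features, 2)")
        if ((self.feature_prob < 0) | (self.feature_prob > 1)).any():
            raise ValueError("conditional probabilities must lie in [0, 1]")

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "class_prior": self.class_prior.tolist(),
            "feature_prob": self.feature_prob.tolist(),
            "alpha": self.alpha,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NaiveBayesModel":
        text = str(source)
        try:
            if Path(source).exists():
                text = Path(source).read_text()
        except OSError:
            pass  # a raw JSON string, not a path
        payload = json.loads(text)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            class_prior=np.array(payload["class_prior"], dtype=float),
            feature_prob=np.array(payload["feature_prob"], dtype=float),
            alpha=float(payload["alpha"]),
        )


def fit_nbc(
    train: TrainingSet | pd.DataFrame,
    y: np.ndarray | None = None,
    alpha: float = 1.0,
) -> NaiveBayesModel:
    """Fit priors and conditionals by smoothed counting.

    Accepts a :class:`TrainingSet` or an (X, y) pair where X is a DataFrame
    of binary feature columns.  Rejects single-class training data and
    negative smoothing.
    """
    if alpha < 0:
        raise ValueError(f"smoothing alpha must be >= 0, got {alpha}")
    if isinstance(train, TrainingSet):
        X, y = train.X, train.y
    else:
        X = train
        if y is None:
            raise ValueError("y required when passing a feature frame")
    names = tuple(X.columns)
    Xv = X.to_numpy(dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    n_y = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    if (n_y == 0).any():
        raise ValueError("training data must contain both classes")
    prior = n_y / n_y.sum()
    counts = np.stack([Xv[y == 0].sum(axis=0), Xv[y == 1].sum(axis=0)], axis=1)
    cond = (counts + alpha) / (n_y[None, :] + 2.0 * alpha)
    return NaiveBayesModel(names, prior, cond, alpha)


def _log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def log_joint_scores(model: NaiveBayesModel, X) -> np.ndarray:
    """(n, 2) matrix of log P(y) + sum_i log P(x_i | y) for each record.

    ``X`` is a DataFrame with the model's feature columns (order-checked) or a
    binary ndarray already in model feature order.  Computed entirely in log
    space; with alpha = 0, impossible feature/class combinations yield -inf.
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        extra = [c for c in X.columns if c not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing={missing!r} unexpected={extra!r}"
            )
        Xv = X[list(model.feature_names)].to_numpy(dtype=np.int8)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=np.int8))
        if Xv.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {Xv.shape[1]}"
            )
    if not np.isin(Xv, (0, 1)).all():
        raise ValueError("feature values must be binary 0/1")
    present = Xv.astype(bool)
    log_p1 = _log(model.feature_prob)  # (F, 2)
    log_p0 = _log(1.0 - model.feature_prob)
    scores = np.empty((Xv.shape[0], 2))
    for c in (0, 1):
        scores[:, c] = np.where(present, log_p1[:, c], log_p0[:, c]).sum(axis=1)
    return scores + _log(model.class_prior)[None, :]


def _normalize(scores: np.ndarray) -> np.ndarray:
    """Softmax over the class axis, tolerating -inf scores."""
    m = np.max(scores, axis=1, keepdims=True)
    finite = np.isfinite(m[:, 0])
    probs = np.full_like(scores, np.nan, dtype=float)
    if finite.any():
        z = np.exp(scores[finite] - m[finite])
        probs[finite] = z / z.sum(axis=1, keepdims=True)
    return probs


def posterior(model: NaiveBayesModel, record) -> Posterior:
    """Normalized posterior for a single record (mapping or binary vector).

    Ties (including the all-uninformative case) resolve to class 0.  If both
    class scores are -inf (a record impossible under either class with
    alpha = 0) the probabilities are NaN and the MAP class defaults to 0.
    """
    if isinstance(record, (dict, pd.Series)):
        try:
            vec = np.array([record[f] for f in model.feature_names], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"record is missing feature {exc.args[0]!r}") from exc
    else:
        vec = np.asarray(record, dtype=np.int8)
    scores = log_joint_scores(model, vec[None, :])
    probs = _normalize(scores)[0]
    map_class = int(scores[0, 1] > scores[0, 0])
    return Posterior(probs, map_class)


def classify(model: NaiveBayesModel, record) -> int:
    """MAP class of a record; ties go to the negative class."""
    return posterior(model, record).map_class


def posterior_frame(model: NaiveBayesModel, X) -> pd.DataFrame:
    """Vectorized posteriors: columns p_negative, p_positive, map_class."""
    scores = log_joint_scores(model, X)
    probs = _normalize(scores)
    return pd.DataFrame(
        {
            "p_negative": probs[:, 0],
            "p_positive": probs[:, 1],
            "map_class": (scores[:, 1] > scores[:, 0]).astype(np.int8),
        },
        index=X.index if isinstance(X, pd.DataFrame) else None,
    )


def _cohort_features(model: NaiveBayesModel, cohort: Cohort) -> pd.DataFrame:
    feats = cohort.frame.copy()
    if AGE_CLASS_COL in model.feature_names:
        feats[AGE_CLASS_COL] = binarize_age(cohort.ages)
    return feats[list(model.feature_names)]


def score_cohort(model: NaiveBayesModel, cohort: Cohort) -> pd.DataFrame:
    """Per-patient posteriors for a raw cohort (age binarized on the fly).

    Columns: id, posterior_positive, map_class, and label when available.
    """
    post = posterior_frame(model, _cohort_features(model, cohort))
    out = pd.DataFrame(
        {
            ID_COL: cohort.ids.to_numpy(),
            "posterior_positive": post["p_positive"].to_numpy(),
            "map_class": post["map_class"].to_numpy(),
        }
    )
    if cohort.has_labels:
        out[LABEL_COL] = cohort.labels
    return out


def screen_cohort(model: NaiveBayesModel, cohort: Cohort) -> pd.DataFrame:
    """Patients flagged positive by the MAP rule, sorted by posterior.

    Returns the subset with map_class == 1 ordered by descending posterior
    probability of disease (ties by id, for determinism).  Empty input yields
    an empty frame with the same columns.
    """
    scored = score_cohort(model, cohort)
    flagged = scored[scored["map_class"] == 1]
    return flagged.sort_values(
        ["posterior_positive", ID_COL], ascending=[False, True]
    ).reset_index(drop=True)
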
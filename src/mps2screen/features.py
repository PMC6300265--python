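"""Feature screening and selection for the NBC screening model.

Four tools, mirroring the study's protocol:

* ``phi`` / ``phi_matrix`` — the phi coefficient between binary features,
  used to check the conditional-independence assumption (phi on 0/1 vectors
  equals the Pearson correlation);
* ``feature_ppv`` / ``ppv_filter`` — each feature's positive predictive value
  as a sole predictor, P(y=1 | x=1), filtered at a cutoff (default 0.15,
  features *at* the cutoff retained);
* ``roc_auc_importance`` — filter importance from a trapezoidal ROC sweep
  over per-feature cutoffs, reported as max(AUC, 1 - AUC) on a 0-1 scale;
* ``recursive_backward_elimination`` — wrapper selection: starting from all
  features, repeatedly drop the feature whose removal maximizes mean
  cross-validated NBC accuracy (stratified k-fold, default 10 folds x 3
  replicates), recording accuracy/kappa mean and SD at every subset size.

Undefined quantities (phi of a constant vector, PPV with no carriers) are
reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import confusion, metrics
from .index import TrainingSet
from .nbc import fit_nbc, log_joint_scores


def phi(a, b) -> float:
    """Phi coefficient of two binary vectors from their 2x2 cross-table.

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0).  Returns NaN
    (undefined) when either vector is constant.
    """
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return math.nan
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def phi_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Symmetric feature-by-feature phi matrix (diagonal 1, NaN where undefined)."""
    cols = list(X.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            v = phi(X[ci].to_numpy(), X[cj].to_numpy())
            out.loc[ci, cj] = out.loc[cj, ci] = v
    return out


def feature_ppv(train: TrainingSet, feature: str) -> float:
    """P(y = 1 | x = 1): the feature's PPV as a sole predictor.

    NaN (undefined) when no record carries the feature.
    """
    if feature not in train.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    x = train.X[feature].to_numpy()
    carriers = int((x == 1).sum())
    if carriers == 0:
        return math.nan
    return float(((x == 1) & (train.y == 1)).sum() / carriers)


def feature_ppvs(train: TrainingSet) -> pd.Series:
    return pd.Series(
        {f: feature_ppv(train, f) for f in train.feature_names}, name="ppv"
    )


def ppv_filter(ppvs, cutoff: float = 0.15) -> list[str]:
    """Features whose PPV is >= the cutoff (kept in input order).

    Features exactly at the cutoff are retained.  Undefined (NaN) PPVs cannot
    meet the cutoff and are removed.  Rejects an empty survivor set.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0,1], got {cutoff}")
    items = ppvs.items() if hasattr(ppvs, "items") else ppvs
    kept = [f for f, v in items if not math.isnan(v) and v >= cutoff]
    if not kept:
        raise ValueError(f"PPV cutoff {cutoff} removes every feature")
    return kept


def trapezoidal_auc(x, y) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Sweeps cutoffs over the observed predictor values (predict positive when
    x >= cutoff), collects (FPR, TPR) points including the (0,0) and (1,1)
    endpoints, and integrates.  For a binary feature this reduces to
    (sensitivity + specificity) / 2 at the single nontrivial cutoff.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(x)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = x >= t
        tpr.append(((y == 1) & pred).sum() / n1)
        fpr.append(((y == 0) & pred).sum() / n0)
    return float(np.trapezoid(tpr, fpr))


def roc_auc_importance(x, y) -> float:
    """Filter importance of a predictor: max(AUC, 1 - AUC), scale 0-1."""
    auc = trapezoidal_auc(x, y)
    return max(auc, 1.0 - auc)


# -- cross-validation --------------------------------------------------------


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """k index folds with both classes in each (shuffled round-robin per class)."""
    y = np.asarray(y)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n={n}], got {k}")
    # leave-one-out style folds (k close to n) cannot hold both classes in
    # every fold; downstream scoring tolerates single-class test folds
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _fold_scores(Xv: np.ndarray, y: np.ndarray, cols: np.ndarray,
                 folds: list[np.ndarray], alpha: float):
    """Accuracy and kappa per fold for an NBC on the given columns."""
    accs, kappas = [], []
    all_idx = np.arange(len(y))
    for fold in folds:
        if len(fold) == 0:
            continue
        tr = np.setdiff1d(all_idx, fold, assume_unique=True)
        ytr = y[tr]
        if ytr.min() == ytr.max():
            continue  # degenerate split
        sub = Xv[np.ix_(tr, cols)]
        n_y = np.array([(ytr == 0).sum(), (ytr == 1).sum()], dtype=float)
        cnt = np.stack([sub[ytr == 0].sum(axis=0), sub[ytr == 1].sum(axis=0)], axis=1)
        cond = (cnt + alpha) / (n_y[None, :] + 2.0 * alpha)
        with np.errstate(divide="ignore"):
            lp1, lp0 = np.log(cond), np.log(1.0 - cond)
            lprior = np.log(n_y / n_y.sum())
        Xt = Xv[np.ix_(fold, cols)].astype(bool)
        s0 = np.where(Xt, lp1[:, 0], lp0[:, 0]).sum(axis=1) + lprior[0]
        s1 = np.where(Xt, lp1[:, 1], lp0[:, 1]).sum(axis=1) + lprior[1]
        pred = (s1 > s0).astype(np.int8)
        rep = metrics(confusion(y[fold], pred))
        accs.append(rep.accuracy)
        if not math.isnan(rep.kappa):
            kappas.append(rep.kappa)
    return accs, kappas


@dataclass
class CVResult:
    accuracy_mean: float
    accuracy_sd: float
    kappa_mean: float
    kappa_sd: float
    n_folds: int


def _summarize(accs: list[float], kappas: list[float]) -> CVResult:
    return CVResult(
        accuracy_mean=float(np.mean(accs)) if accs else math.nan,
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        kappa_mean=float(np.mean(kappas)) if kappas else math.nan,
        kappa_sd=float(np.std(kappas, ddof=1)) if len(kappas) > 1 else 0.0,
        n_folds=len(accs),
    )


def cross_validate_nbc(
    train: TrainingSet,
    features=None,
    k: int = 10,
    replicates: int = 3,
    alpha: float = 1.0,
    *,
    seed: int,
) -> CVResult:
    """Repeated stratified k-fold CV accuracy/kappa of an NBC."""
    names = list(train.feature_names)
    feats = names if features is None else list(features)
    cols = np.array([names.index(f) for f in feats])
    Xv = train.X.to_numpy(dtype=np.int8)
    y = train.y
    rng = np.random.default_rng(seed)
    accs: list[float] = []
    kappas: list[float] = []
    for _ in range(replicates):
        folds = stratified_folds(y, k, rng)
        a, kp = _fold_scores(Xv, y, cols, folds, alpha)
        accs.extend(a)
        kappas.extend(kp)
    return _summarize(accs, kappas)


# -- recursive backward elimination ------------------------------------------


@dataclass
class EliminationStep:
    features: tuple[str, ...]
    dropped: str | None
    accuracy_mean: float
    accuracy_sd: float
    kappa_mean: float
    kappa_sd: float


@dataclass
class FeatureReport:
    """Per-feature screening statistics plus the backward-elimination path."""

    ppv: pd.Series
    auc_importance: pd.Series
    path: list[EliminationStep]
    best_features: tuple[str, ...]

    @property
    def retained(self) -> pd.Series:
        return pd.Series(
            {f: f in self.best_features for f in self.ppv.index}, name="retained"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ppv": self.ppv, "auc_importance": self.auc_importance,
             "retained": self.retained}
        )

    def path_records(self) -> list[dict]:
        return [
            {
                "n_features": len(s.features),
                "features": list(s.features),
                "dropped": s.dropped,
                "accuracy_mean": s.accuracy_mean,
                "accuracy_sd": s.accuracy_sd,
                "kappa_mean": s.kappa_mean,
                "kappa_sd": s.kappa_sd,
            }
            for s in self.path
        ]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="feature")


def recursive_backward_elimination(
    train: TrainingSet,
    k: int = 10,
    replicates: int = 3,
    alpha: float = 1.0,
    *,
    seed: int,
) -> FeatureReport:
    """Greedy backward wrapper selection around the NBC.

    At each step every remaining feature is tentatively dropped and the NBC
    is re-cross-validated (same folds for all candidates within a step); the
    drop that maximizes mean CV accuracy wins, ties resolved by dropping the
    candidate with the lower ROC importance, then lexicographically.  The
    path runs from the full set down to a single feature; the reported best
    subset has the largest mean accuracy (earliest/largest subset on ties).
    """
    names = list(train.feature_names)
    Xv = train.X.to_numpy(dtype=np.int8)
    y = train.y
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    importance = pd.Series(
        {f: roc_auc_importance(train.X[f].to_numpy(), y) for f in names},
        name="auc_importance",
    )
    ppv = pd.Series(
        {f: feature_ppv(train, f) for f in names}, name="ppv"
    )
    rng = np.random.default_rng(seed)

    def cv_stats(feats: list[str], folds_for_step) -> CVResult:
        cols = np.array([names.index(f) for f in feats])
        accs: list[float] = []
        kappas: list[float] = []
        for folds in folds_for_step:
            a, kp = _fold_scores(Xv, y, cols, folds, alpha)
            accs.extend(a)
            kappas.extend(kp)
        return _summarize(accs, kappas)

    current = list(names)
    first_folds = [stratified_folds(y, k, rng) for _ in range(replicates)]
    first = cv_stats(current, first_folds)
    path = [
        EliminationStep(tuple(current), None, first.accuracy_mean,
                        first.accuracy_sd, first.kappa_mean, first.kappa_sd)
    ]
    while len(current) > 1:
        folds_for_step = [stratified_folds(y, k, rng) for _ in range(replicates)]
        results = {}
        for cand in current:
            feats = [f for f in current if f != cand]
            results[cand] = cv_stats(feats, folds_for_step)
        # drop maximizing accuracy; ties -> lower ROC importance, then name
        top_acc = max(results[f].accuracy_mean for f in current)
        tied = [f for f in current if results[f].accuracy_mean == top_acc]
        best = min(tied, key=lambda f: (importance[f], f))
        current = [f for f in current if f != best]
        r = results[best]
        path.append(
            EliminationStep(tuple(current), best, r.accuracy_mean,
                            r.accuracy_sd, r.kappa_mean, r.kappa_sd)
        )
    best_step = max(path, key=lambda s: s.accuracy_mean)
    return FeatureReport(ppv, importance, path, best_step.features)


def learning_curve(
    train: TrainingSet,
    sizes,
    k: int = 10,
    replicates: int = 3,
    alpha: float = 1.0,
    *,
    seed: int,
) -> pd.DataFrame:
    """CV accuracy as a function of (stratified, seeded) training-set size."""
    y = train.y
    n = len(y)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sorted(int(s) for s in sizes):
        if size > n:
            raise ValueError(f"size {size} exceeds pool size {n}")
        if size < k:
            raise ValueError(f"size {size} smaller than k={k}")
        if size == n:
            sub = np.arange(n)
        else:
            parts = []
            for c in (0, 1):
                idx = np.flatnonzero(y == c)
                want = max(1, int(round(size * len(idx) / n)))
                parts.append(rng.choice(idx, size=min(want, len(idx)), replace=False))
            sub = np.sort(np.concatenate(parts))
        subset = TrainingSet(train.frame.iloc[sub])
        # the same master seed drives the folds at every size, so the
        # full-pool point coincides with a direct cross_validate_nbc call
        res = cross_validate_nbc(
            subset, k=k, replicates=replicates, alpha=alpha, seed=seed
        )
        rows.append(
            {"size": len(sub), "accuracy_mean": res.accuracy_mean,
             "accuracy_sd": res.accuracy_sd, "kappa_mean": res.kappa_mean,
             "kappa_sd": res.kappa_sd}
        )
    return pd.DataFrame(rows)
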
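"""End-to-end study orchestration: simulate -> score -> train -> screen -> report.

``run_full_study`` executes the whole screening study against a synthetic
population and writes every artifact (training set, model, feature report,
metrics, screening list, combination table, TAN comparison, manifest) into an
output directory.  All randomness flows from one master seed; each stage draws
its own child seed from a stable hash of the stage name, so stages can be
re-run independently and two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import AgeProfile, Cohort, write_cohort
from .evaluate import (
    ase_sse,
    bootstrap_performance,
    combination_table,
    confusion,
    metrics,
    prevalence_percent,
    stratified_split,
    validation_set_approach,
)
from .features import (
    feature_ppvs,
    phi_matrix,
    ppv_filter,
    recursive_backward_elimination,
)
from .index import (
    DEFAULT_PERCENTILE_CUTOFF,
    TrainingSet,
    build_training_set,
    mpsi_scores,
    qq_points,
    select_low_mpsi_negatives,
)
from .nbc import fit_nbc, posterior_frame, score_cohort
from .simulate import generate_population, generate_positive_cohort
from .symptoms import FrequencyTable, WeightVector, mps2_frequencies, uniform_background
from .tan import build_tan, chi_square_independence, tan_posterior_frame


@dataclass
class PipelineConfig:
    """All knobs of the study; every published threshold is a default here.

    The defaults are the study conditions: a ~5 x 10^5-patient male
    population, disease prevalence 2.5e-4, 971 low-index negatives + 73
    artificial positives for training, Laplace smoothing, 10-fold CV x 3
    replicates, 1000 bootstrap replicates, a 70/30 validation split, the
    0.15 per-feature PPV cutoff and the 1.6% combination-table threshold.
    """

    seed: int
    out_dir: str = "mps2_run"
    n_total: int = 506_497
    prevalence: float = 2.5e-4
    n_neg_train: int = 971
    n_pos_train: int = 73
    percentile_cutoff: float = DEFAULT_PERCENTILE_CUTOFF
    background_prevalence: float = 0.03
    prop_young: float = 0.25
    positive_prop_young: float = 0.75
    alpha: float = 1.0
    cv_folds: int = 10
    cv_replicates: int = 3
    bootstrap_B: int = 1000
    validation_fraction: float = 0.70
    ppv_cutoff: float = 0.15
    min_incidence: float = 0.016
    frequency_table: str | None = None  # JSON/CSV path; default: published
    weight_table: str | None = None
    background_table: str | None = None

    def __post_init__(self):
        for name in ("prevalence", "percentile_cutoff", "validation_fraction",
                     "ppv_cutoff", "min_incidence", "prop_young",
                     "positive_prop_young"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    # resolved tables -----------------------------------------------------

    def frequencies(self) -> FrequencyTable:
        if self.frequency_table:
            return FrequencyTable.from_file(self.frequency_table)
        return mps2_frequencies()

    def weights(self) -> WeightVector:
        if self.weight_table:
            return WeightVector.from_file(self.weight_table)
        return WeightVector({s: v for s, v in self.frequencies().items()})

    def background(self) -> FrequencyTable:
        if self.background_table:
            return FrequencyTable.from_file(self.background_table)
        return uniform_background(self.background_prevalence)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage, below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    """Everything needed to audit or re-run a study bit-identically."""

    config: dict
    version: str
    stage_seeds: dict[str, int]
    outputs: dict[str, str]
    timings_s: dict[str, float]
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_full_study(config: PipelineConfig) -> RunManifest:
    """Run every stage of the screening study; returns the manifest.

    Stage order: simulate population, MPSi scoring + Q-Q export, low-index
    negative selection, artificial positives, training assembly, feature
    screening/selection, final NBC fit, validation + bootstrap evaluation,
    population screening (training negatives excluded), combination table,
    TAN comparison with chi-square independence tests, manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(config.seed, s)
        for s in ("simulate", "negatives", "positives", "features",
                  "evaluate", "bootstrap", "tan")
    }
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    summary: dict = {}

    def done(stage: str, t0: float, **files: Path):
        timings[stage] = round(time.perf_counter() - t0, 3)
        outputs.update({k: str(v) for k, v in files.items()})

    freqs = config.frequencies()
    weights = config.weights()
    background = config.background()
    pop_ages = AgeProfile(prop_young=config.prop_young)
    pos_ages = AgeProfile(prop_young=config.positive_prop_young)

    # 1. synthetic population ------------------------------------------------
    t0 = time.perf_counter()
    population = generate_population(
        config.n_total, config.prevalence, freqs, background,
        pop_ages, pos_ages, seed=seeds["simulate"],
    )
    summary["n_population"] = population.n
    summary["n_injected_positives"] = int(population.labels.sum())
    done("simulate", t0)

    # 2. MPS index + Q-Q exports ----------------------------------------------
    t0 = time.perf_counter()
    scores = mpsi_scores(population, weights)
    scores_path = out / "mpsi_scores.csv"
    population.frame[["id"]].assign(mpsi=scores).to_csv(scores_path, index=False)
    qq_files = {}
    for stratum, tag in ((1, "young"), (0, "old")):
        qq = qq_points(population, weights, stratum)
        p = out / f"qq_{tag}.csv"
        qq.to_frame().to_csv(p, index=False)
        qq_files[f"qq_{tag}"] = p
    done("score", t0, mpsi_scores=scores_path, **qq_files)

    # 3. training set ---------------------------------------------------------
    t0 = time.perf_counter()
    negatives = select_low_mpsi_negatives(
        population, weights, config.n_neg_train,
        config.percentile_cutoff, seed=seeds["negatives"],
    )
    positives = generate_positive_cohort(
        config.n_pos_train, freqs, pos_ages, seed=seeds["positives"],
        id_prefix="SYN",
    )
    train = build_training_set(negatives, positives)
    train_path = out / "training_set.csv"
    train.to_csv(train_path)
    summary["n_training"] = len(train)
    summary["n_training_pos"] = train.n_pos
    summary["n_training_neg"] = train.n_neg
    done("build-training", t0, training_set=train_path)

    # 4. feature screening and selection --------------------------------------
    t0 = time.perf_counter()
    report = recursive_backward_elimination(
        train, k=config.cv_folds, replicates=config.cv_replicates,
        alpha=config.alpha, seed=seeds["features"],
    )
    ppv_kept = ppv_filter(feature_ppvs(train), config.ppv_cutoff)
    selected = [f for f in report.best_features if f in set(ppv_kept)]
    if not selected:
        raise RuntimeError("feature selection removed every feature")
    phi_path = out / "phi_matrix.csv"
    phi_matrix(train.X).to_csv(phi_path)
    feat_path = out / "feature_report.csv"
    frame = report.to_frame()
    frame["ppv_retained"] = [f in set(ppv_kept) for f in frame.index]
    frame["selected"] = [f in set(selected) for f in frame.index]
    frame.to_csv(feat_path, index_label="feature")
    elim_path = out / "elimination_path.json"
    elim_path.write_text(json.dumps(report.path_records(), indent=1))
    summary["n_selected_features"] = len(selected)
    summary["selected_features"] = selected
    done("select-features", t0, feature_report=feat_path,
         elimination_path=elim_path, phi_matrix=phi_path)

    # 5. final model -----------------------------------------------------------
    t0 = time.perf_counter()
    final_train = train.restrict(selected)
    model = fit_nbc(final_train, alpha=config.alpha)
    model_path = out / "model.json"
    model.to_json(model_path)
    done("train", t0, model=model_path)

    # 6. evaluation ------------------------------------------------------------
    t0 = time.perf_counter()
    val = validation_set_approach(
        final_train, config.validation_fraction, config.alpha,
        seed=seeds["evaluate"],
    )
    boot = bootstrap_performance(
        final_train, config.bootstrap_B, config.alpha, seed=seeds["bootstrap"],
    )
    eval_path = out / "evaluation.json"
    eval_payload = {
        "validation": val.report.to_dict()
        | {"n_train": val.n_train, "n_test": val.n_test,
           "confusion": asdict(val.cm)},
        "bootstrap": {
            "accuracy_mean": boot.accuracy_mean,
            "accuracy_sd": boot.accuracy_sd,
            "kappa_mean": boot.kappa_mean,
            "kappa_sd": boot.kappa_sd,
            "n_replicates": boot.n_replicates,
            "n_skipped": boot.n_skipped,
        },
    }
    eval_path.write_text(json.dumps(eval_payload, indent=1))
    summary["validation_accuracy"] = val.report.accuracy
    summary["bootstrap_accuracy_mean"] = boot.accuracy_mean
    done("evaluate", t0, evaluation=eval_path)

    # 7. population screening --------------------------------------------------
    t0 = time.perf_counter()
    train_neg_ids = set(negatives.ids)
    screen_frame = population.frame[~population.ids.isin(train_neg_ids)]
    screen_pop = Cohort(screen_frame, provenance="population minus training negatives")
    scored = score_cohort(model, screen_pop)
    flagged = scored[scored["map_class"] == 1].sort_values(
        ["posterior_positive", "id"], ascending=[False, True]
    )
    screen_path = out / "screening.csv"
    flagged.to_csv(screen_path, index=False)
    n_flagged = len(flagged)
    summary["n_screened"] = len(scored)
    summary["n_flagged"] = n_flagged
    summary["prevalence_percent"] = (
        prevalence_percent(n_flagged, len(scored)) if len(scored) else float("nan")
    )
    truth = scored["label"].to_numpy()
    pred = scored["map_class"].to_numpy()
    if truth.sum() > 0:
        rep = metrics(confusion(truth, pred))
        summary["screen_recall_injected"] = rep.sensitivity
        summary["screen_specificity"] = rep.specificity
    done("screen", t0, screening=screen_path)

    # 8. combination table ------------------------------------------------------
    t0 = time.perf_counter()
    comb_path = out / "combinations.csv"
    if n_flagged:
        flagged_cohort = Cohort(
            population.frame[population.ids.isin(flagged["id"])],
            provenance="flagged by NBC screen",
        )
        combos = combination_table(flagged_cohort, config.min_incidence)
        combos.to_frame().to_csv(comb_path)
        summary["grand_total_symptom_occurrences"] = combos.grand_total
    else:
        comb_path.write_text("")
    done("report", t0, combinations=comb_path)

    # 9. TAN comparison ----------------------------------------------------------
    t0 = time.perf_counter()
    tan_model = build_tan(final_train, alpha=config.alpha)
    tan_path = out / "tan_model.json"
    tan_model.to_json(tan_path)
    rng = np.random.default_rng(seeds["tan"])
    tr, te = stratified_split(final_train.y, config.validation_fraction, rng)
    sub_train = TrainingSet(final_train.frame.iloc[tr])
    sub_test = TrainingSet(final_train.frame.iloc[te])
    nbc_cmp = fit_nbc(sub_train, alpha=config.alpha)
    tan_cmp = build_tan(sub_train, alpha=config.alpha)
    X_test, y_test = sub_test.X, sub_test.y
    comparison = {}
    for name, post in (
        ("NBC", posterior_frame(nbc_cmp, X_test)),
        ("TAN", tan_posterior_frame(tan_cmp, X_test)),
    ):
        cm = confusion(y_test, post["map_class"].to_numpy())
        rep = metrics(cm)
        rep.ase, rep.sse = ase_sse(
            post[["p_negative", "p_positive"]].to_numpy(), y_test
        )
        comparison[name] = rep.to_dict() | {"confusion": asdict(cm)}
    chi = {
        f: asdict(chi_square_independence(final_train.X[f].to_numpy(),
                                          final_train.y))
        for f in final_train.feature_names
    }
    tan_cmp_path = out / "tan_comparison.json"
    tan_cmp_path.write_text(
        json.dumps({"comparison": comparison, "chi_square": chi}, indent=1)
    )
    summary["tan_accuracy"] = comparison["TAN"]["accuracy"]
    summary["nbc_accuracy"] = comparison["NBC"]["accuracy"]
    done("compare-tan", t0, tan_model=tan_path, tan_comparison=tan_cmp_path)

    # write training cohort artifacts for audit
    neg_path = out / "training_negatives.csv"
    write_cohort(negatives, neg_path)
    outputs["training_negatives"] = str(neg_path)

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stage_seeds=seeds,
        outputs=outputs,
        timings_s=timings,
        summary=summary,
    )
    manifest.to_json(out / "manifest.json")
    outputs["manifest"] = str(out / "manifest.json")
    return manifest
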
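"""Synthetic cohort generators emulating a CPCSSN-like male EMR extract.

The real surveillance-network extract behind the MPS II screen (~5 x 10^5 male
patients with dichotomous symptom indicators) is not publicly deposited.  These
generators reproduce the statistical structure the analysis assumes:

* positives: symptom flags are independent Bernoulli draws from the published
  MPS II symptom frequencies (this is exactly how the study's 73 artificial
  positive patients were constructed);
* negatives: independent Bernoulli draws from a low uniform background
  prevalence (default 0.03 per symptom — a documented stand-in, since the true
  background rates are unpublished);
* a two-stratum age structure (<= 21 vs > 21 years);
* a screening population: a rare-prevalence mixture of the two with ground
  truth labels retained for recovery checks.

Flags are sampled independently given the label — the same conditional
independence the naive Bayes classifier assumes.  All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import AGE_COL, ID_COL, LABEL_COL, AgeProfile, Cohort
from .symptoms import SYMPTOMS, FrequencyTable, mps2_frequencies, uniform_background


def _make_frame(ids, ages, flags: np.ndarray, labels) -> pd.DataFrame:
    frame = pd.DataFrame(flags, columns=list(SYMPTOMS))
    frame.insert(0, AGE_COL, ages)
    frame.insert(0, ID_COL, ids)
    frame[LABEL_COL] = np.asarray(labels, dtype=np.int8)
    return frame


def _draw_flags(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((n, len(SYMPTOMS))) < probs).astype(np.int8)


def generate_positive_cohort(
    n: int,
    freqs: FrequencyTable | None = None,
    age_profile: AgeProfile | None = None,
    *,
    seed: int,
    id_prefix: str = "POS",
) -> Cohort:
    """Generate ``n`` artificial MPS II-positive patients (label 1).

    Each symptom flag is an independent Bernoulli draw with the symptom's
    published frequency; ages come from ``age_profile`` (default: 75% aged
    <= 21, reflecting the pediatric onset of the disease).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    freqs = freqs if freqs is not None else mps2_frequencies()
    age_profile = age_profile if age_profile is not None else AgeProfile(prop_young=0.75)
    rng = np.random.default_rng(seed)
    flags = _draw_flags(n, freqs.as_array(), rng)
    ages = age_profile.sample(n, rng)
    ids = [f"{id_prefix}{i:07d}" for i in range(n)]
    return Cohort(
        _make_frame(ids, ages, flags, np.ones(n, dtype=np.int8)),
        provenance=f"synthetic positives n={n} seed={seed}",
    )


def generate_negative_cohort(
    n: int,
    background: FrequencyTable | None = None,
    age_profile: AgeProfile | None = None,
    *,
    seed: int,
    id_prefix: str = "NEG",
) -> Cohort:
    """Generate ``n`` background (non-case) patients, label 0.

    Identical in construction to :func:`generate_positive_cohort` except for
    the frequency table (default: uniform 0.03 background) and the label.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    background = background if background is not None else uniform_background()
    age_profile = age_profile if age_profile is not None else AgeProfile()
    rng = np.random.default_rng(seed)
    flags = _draw_flags(n, background.as_array(), rng)
    ages = age_profile.sample(n, rng)
    ids = [f"{id_prefix}{i:07d}" for i in range(n)]
    return Cohort(
        _make_frame(ids, ages, flags, np.zeros(n, dtype=np.int8)),
        provenance=f"synthetic negatives n={n} seed={seed}",
    )


def generate_population(
    n_total: int,
    prevalence: float,
    freqs: FrequencyTable | None = None,
    background: FrequencyTable | None = None,
    age_profile: AgeProfile | None = None,
    positive_age_profile: AgeProfile | None = None,
    *,
    seed: int,
    id_prefix: str = "PT",
) -> Cohort:
    """Screening-scale mixture population with ground-truth labels.

    Each patient is positive with probability ``prevalence`` (so the expected
    positive count is ``n_total * prevalence``); flags are then drawn from the
    positive frequencies or the background accordingly.  Ages come from
    ``age_profile``; positives' ages may use a separate
    ``positive_age_profile`` (default: same as the population), since MPS II
    cases skew young.
    """
    if n_total < 0:
        raise ValueError(f"n_total must be >= 0, got {n_total}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0,1], got {prevalence}")
    freqs = freqs if freqs is not None else mps2_frequencies()
    background = background if background is not None else uniform_background()
    age_profile = age_profile if age_profile is not None else AgeProfile()
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_total) < prevalence).astype(np.int8)
    probs = np.where(labels[:, None] == 1, freqs.as_array(), background.as_array())
    flags = (rng.random((n_total, len(SYMPTOMS))) < probs).astype(np.int8)
    ages = age_profile.sample(n_total, rng)
    if positive_age_profile is not None and labels.any():
        pos = labels == 1
        ages[pos] = positive_age_profile.sample(int(pos.sum()), rng)
    ids = [f"{id_prefix}{i:07d}" for i in range(n_total)]
    return Cohort(
        _make_frame(ids, ages, flags, labels),
        provenance=(
            f"synthetic population n={n_total} prevalence={prevalence} seed={seed}"
        ),
    )
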
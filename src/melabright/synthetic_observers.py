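"""Synthetic magnitude-estimation and pupillometry data.

The generator reproduces the structure of the brightness-perception
experiment: 7 metameric white stimulus classes (a cone-and-rod-silent
pair A/B and a cone-silent quintet C-G, in decreasing melanopsin
excitation), luminance modulated between 22 and 112 cd/m^2, 9 observers,
3 repeats per condition, ratings normalised per observer so that the
reference condition (highest-melanopsin stimulus at the top luminance)
scores 100.

Generative model per trial:

* pupil diameter  = logistic pupil model + Gaussian noise (sigma_pupil mm)
* rating          = corneal brightness model x lognormal rating noise
                    x a per-observer lognormal scale factor

Repeats are averaged per observer and condition, then each observer's
ratings are divided by their own reference mean and multiplied by 100 —
exactly how magnitude estimation against a fixed reference removes the
observer's private scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .brightness import BrightnessParams, predict_brightness_corneal
from .pupil import PupilParams, predict_pupil

__all__ = [
    "PRINTED_MP_RATIOS",
    "DEFAULT_LUMINANCE_LEVELS",
    "ObserverConfig",
    "ObserverDataset",
    "build_condition_grid",
    "simulate_experiment",
    "compare_conditions",
]

#: M/P ratios printed for the three stimulus classes used in the pairwise
#: statistics (C the reference class, E intermediate, G the lowest)
PRINTED_MP_RATIOS = {"C": 9.3, "E": 5.6, "G": 2.6}

#: luminance levels (cd/m^2): the study modulated 22-112 cd/m^2 and ran
#: its pairwise tests at 102 and 112
DEFAULT_LUMINANCE_LEVELS = (22.0, 42.0, 66.0, 102.0, 112.0)


@dataclass(frozen=True)
class ObserverConfig:
    """Sample sizes, noise magnitudes and the seed for one simulation."""

    n_participants: int = 9
    n_repeats: int = 3
    rating_sigma: float = 0.1  # lognormal sigma, multiplicative rating noise
    participant_sigma: float = 0.1  # lognormal sigma of per-observer scale
    pupil_sigma_mm: float = 0.1  # additive Gaussian pupil noise
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_repeats < 1:
            raise ValueError("participant and repeat counts must be >= 1")
        if min(self.rating_sigma, self.participant_sigma, self.pupil_sigma_mm) < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class ObserverDataset:
    """Simulated (or imported) per-observer data plus condition means.

    ``trials`` has one row per observer x condition (repeats already
    averaged): participant, stimulus, luminance_cdm2, melanopic_cdm2,
    pupil_mm, rating.  ``condition_means`` averages over observers.
    """

    trials: pd.DataFrame
    reference: tuple  # (stimulus label, luminance)
    condition_means: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.condition_means is None:
            self.condition_means = (
                self.trials.groupby(["stimulus", "luminance_cdm2"], as_index=False)
                .agg(
                    melanopic_cdm2=("melanopic_cdm2", "mean"),
                    pupil_mm=("pupil_mm", "mean"),
                    rating=("rating", "mean"),
                )
                .sort_values(["stimulus", "luminance_cdm2"], ignore_index=True)
            )


def build_condition_grid(family, luminance_levels=DEFAULT_LUMINANCE_LEVELS) -> pd.DataFrame:
    """Cross stimulus classes with luminance levels.

    ``family`` may be a mapping ``label -> M/P ratio``, a
    :class:`~melabright.metamer.StimulusFamily`, or a list of labelled
    metamer solutions.  Melanopic luminance is M = (M/P) x L per row.
    """
    if hasattr(family, "mp_ratios"):
        ratios = family.mp_ratios()
    elif isinstance(family, dict):
        ratios = dict(family)
    else:
        ratios = {s.label: s.mp_ratio for s in family}
    rows = [
        {
            "stimulus": label,
            "mp_ratio": float(mp),
            "luminance_cdm2": float(lum),
            "melanopic_cdm2": float(mp) * float(lum),
        }
        for label in sorted(ratios)
        for lum in luminance_levels
        for mp in [ratios[label]]
    ]
    return pd.DataFrame(rows)


def simulate_experiment(
    conditions: pd.DataFrame,
    brightness_params: BrightnessParams,
    pupil_params: PupilParams,
    config: ObserverConfig = ObserverConfig(),
    reference: tuple | None = None,
) -> ObserverDataset:
    """Simulate ratings and pupil diameters over a condition grid.

    ``reference`` defaults to the highest-melanopsin stimulus at the top
    luminance; its per-observer mean rating is normalised to 100.  The run
    is fully reproducible from ``config.seed`` (independent substreams for
    observer scales, rating noise and pupil noise).
    """
    cond = conditions.reset_index(drop=True)
    M = cond["melanopic_cdm2"].to_numpy(float)
    L = cond["luminance_cdm2"].to_numpy(float)
    d_true = np.asarray(predict_pupil(M, L, pupil_params), float)
    r_true = np.asarray(
        predict_brightness_corneal(M, L, pupil_params, brightness_params), float
    )

    if reference is None:
        ref_idx = int(np.argmax(M))
        reference = (
            str(cond.loc[ref_idx, "stimulus"]),
            float(cond.loc[ref_idx, "luminance_cdm2"]),
        )
    ref_mask = (cond["stimulus"] == reference[0]) & np.isclose(
        cond["luminance_cdm2"], reference[1]
    )
    if not ref_mask.any():
        raise ValueError(f"reference condition {reference} not in the grid")
    ref_row = int(np.flatnonzero(ref_mask)[0])

    rng_scale = np.random.default_rng([config.seed, 1])
    rng_rating = np.random.default_rng([config.seed, 2])
    rng_pupil = np.random.default_rng([config.seed, 3])

    n_cond = len(cond)
    scales = np.exp(
        rng_scale.normal(0.0, config.participant_sigma, size=config.n_participants)
    )
    records = []
    for p in range(config.n_participants):
        rating_noise = np.exp(
            rng_rating.normal(0.0, config.rating_sigma, size=(config.n_repeats, n_cond))
        )
        pupil_noise = rng_pupil.normal(
            0.0, config.pupil_sigma_mm, size=(config.n_repeats, n_cond)
        )
        ratings = (r_true[None, :] * scales[p] * rating_noise).mean(axis=0)
        pupils = np.clip(d_true[None, :] + pupil_noise, 0.1, None).mean(axis=0)
        ratings = 100.0 * ratings / ratings[ref_row]
        for i in range(n_cond):
            records.append(
                {
                    "participant": p,
                    "stimulus": cond.loc[i, "stimulus"],
                    "luminance_cdm2": L[i],
                    "melanopic_cdm2": M[i],
                    "pupil_mm": pupils[i],
                    "rating": ratings[i],
                }
            )
    return ObserverDataset(trials=pd.DataFrame(records), reference=reference)


def compare_conditions(
    dataset: ObserverDataset,
    pair: tuple,
    luminance_cdm2: float,
    correction: str = "none",
    n_comparisons: int = 1,
) -> float:
    """Paired two-tailed t-test between two stimulus classes at one luminance.

    Each observer contributes one mean rating per class; ``bonferroni``
    multiplies the raw p-value by ``n_comparisons`` (capped at 1).
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError("correction must be 'none' or 'bonferroni'")
    t = dataset.trials
    sel = t[np.isclose(t["luminance_cdm2"], luminance_cdm2)]
    wide = sel.pivot(index="participant", columns="stimulus", values="rating")
    a, b = pair
    if a not in wide.columns or b not in wide.columns:
        raise ValueError(f"pair {pair} not present at luminance {luminance_cdm2}")
    x, y = wide[a].to_numpy(), wide[b].to_numpy()
    if np.allclose(x, y):
        return 1.0
    diff = x - y
    if np.std(diff) < 1e-12 * max(abs(diff.mean()), 1.0):
        # constant nonzero difference (noise-free data): t is unbounded
        return 0.0
    p = float(stats.ttest_rel(x, y).pvalue)
    if correction == "bonferroni":
        p = min(1.0, n_comparisons * p)
    return p
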
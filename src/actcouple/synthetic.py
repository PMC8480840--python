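"""Synthetic cohorts with known time-use effects on mortality.

The generator emulates the statistical structure a wrist-accelerometer
time-use analysis assumes, at 1-minute epoch resolution:

* activity as a semi-Markov chain over sleep / sedentary / light / MVPA with
  per-category dwell (bout-length) distributions — sedentary time accumulated
  in long bouts, MVPA in short bouts — and sleep concentrated at night via a
  diurnal weight on category selection;
* per-epoch emissions (mean vector magnitude and per-axis SDs, in
  milligravities) drawn from category-specific distributions, an ML activity
  label drawn from a row-stochastic confusion matrix, and non-wear episodes
  that overwrite emissions with stationary values;
* baseline confounders with configurable links to both activity propensity
  and the death hazard;
* death ages from a proportional-hazards model on the age scale whose
  log-hazard is linear in the TRUE per-10-minute activity composition, with a
  piecewise-constant baseline hazard, left truncation at the (uniform) entry
  age and administrative censoring at a fixed age.

Because survival is generated from the true, pre-noise composition, parameter
recovery by the coupling Cox model is a well-defined target, and the effects
of measurement error, non-wear and imputation can be studied as deviations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    CATEGORY_CODES,
    MINUTES_PER_DAY,
    ML_LABELS,
    MVPA_STRATA_COLS,
    SEDENTARY_STRATA_COLS,
    CovariateRecord,
    EpochSeries,
    LabelSeries,
    ParticipantSummary,
    SurvivalRecord,
)

# Night window used by the diurnal sleep weight: 22:00 -> 06:30.
NIGHT_START_MINUTE = 22 * 60
NIGHT_END_MINUTE = 6 * 60 + 30

_SEDENTARY_STRATA_EDGES = np.array([16, 41])  # digitize edges for 1-15/16-40/41+
_MVPA_STRATA_EDGES = np.array([10, 16, 41])  # 1-9/10-15/16-40/41+


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def raw_sample_count(freq_hz: float = 100.0, n_days: int = 7, n_axes: int = 3) -> int:
    """Raw tri-axial samples recorded by the device protocol.

    A device recording at ``freq_hz`` for ``n_days`` whole days across
    ``n_axes`` axes produces ``freq_hz * 86400 * n_days * n_axes`` values —
    over 181 million per participant at the default 100 Hz / 7 day / 3 axis
    protocol. The pipeline itself starts from 1-minute epoch summaries.
    """
    return int(freq_hz * 86400 * n_days * n_axes)


# ---------------------------------------------------------------------------
# configuration

def _default_dwell_params() -> dict[str, dict[str, Any]]:
    # Geometric dwells (memoryless at the minute scale): sedentary accumulated
    # in long bouts, MVPA in short ones, sleep in long overnight spells.
    return {
        "sleep": {"dist": "geometric", "mean": 200.0},
        "sedentary": {"dist": "geometric", "mean": 40.0},
        "light": {"dist": "geometric", "mean": 10.0},
        "mvpa": {"dist": "geometric", "mean": 3.0},
    }


def _default_category_weights() -> dict[str, float]:
    # Relative selection weights of the embedded chain; together with the
    # dwell means these set the marginal composition, targeting roughly
    # 540/535/300/65 min/day sleep/sedentary/light/MVPA.
    return {"sleep": 0.018, "sedentary": 0.11, "light": 0.65, "mvpa": 0.20}


def _default_emission_params() -> dict[str, dict[str, Any]]:
    # vm in m-grav; per-axis SDs shifted above the 13 m-grav stationarity
    # threshold so that injected non-wear is the only stationary signal.
    return {
        "sleep": {
            "vm": {"dist": "gamma", "shape": 3.0, "scale": 5.0},
            "sd": {"dist": "gamma", "shape": 2.0, "scale": 3.0, "loc": 14.0},
        },
        "sedentary": {
            "vm": {"dist": "gamma", "shape": 3.0, "scale": 8.0},
            "sd": {"dist": "gamma", "shape": 2.0, "scale": 4.0, "loc": 14.0},
        },
        "light": {
            "vm": {"dist": "gamma", "shape": 4.0, "scale": 15.0},
            "sd": {"dist": "gamma", "shape": 2.0, "scale": 10.0, "loc": 14.0},
        },
        "mvpa": {
            "vm": {"dist": "gamma", "shape": 2.0, "scale": 40.0, "loc": 100.0},
            "sd": {"dist": "gamma", "shape": 2.0, "scale": 25.0, "loc": 14.0},
        },
    }


def _default_ml_confusion() -> dict[str, dict[str, float]]:
    # Row-stochastic P(ML label | true category). Diagonal accuracies follow
    # the published classifier's headline figures (sleep ~91%, light ~25%,
    # MVPA ~58% correct); off-diagonals are plausible fillers.
    return {
        "sleep": {"sleep": 0.91, "sedentary": 0.05, "walking": 0.01, "light": 0.02, "mvpa": 0.01},
        "sedentary": {"sleep": 0.05, "sedentary": 0.85, "walking": 0.02, "light": 0.06, "mvpa": 0.02},
        "light": {"sleep": 0.05, "sedentary": 0.40, "walking": 0.20, "light": 0.25, "mvpa": 0.10},
        "mvpa": {"sleep": 0.01, "sedentary": 0.10, "walking": 0.21, "light": 0.10, "mvpa": 0.58},
    }


def _default_covariate_params() -> dict[str, Any]:
    return {
        # marginal distributions
        "sex_p_male": 0.455,
        "ethnicity_probs": {"white": 0.970, "black": 0.008, "asian": 0.009, "other": 0.013},
        "smoking_probs": {"never": 0.57, "previous": 0.33, "current": 0.10},
        "education_probs": {"none": 0.075, "secondary": 0.30, "further": 0.175, "degree": 0.45},
        "income_probs": {
            "lt_18k": 0.145,
            "18_31k": 0.242,
            "31_52k": 0.288,
            "52_100k": 0.252,
            "gt_100k": 0.073,
        },
        "townsend_mean": -1.71,
        "townsend_sd": 2.82,
        "bmi_mean": 26.7,
        "bmi_sd": 4.5,
        "prior_cvd_p": 0.31,
        "prior_cancer_p": 0.14,
        "prior_respiratory_p": 0.41,
        # centring constants for continuous covariate effects
        "bmi_center": 26.7,
        "age_center": 62.0,
        "season_peak_day": 172,  # late June
        # confounding: additive shifts on per-category log selection weights
        "activity_coefs": {
            "mvpa": {
                "sex": 0.10,
                "smoking_current": -0.30,
                "bmi": -0.04,
                "townsend": -0.02,
                "prior_cvd": -0.25,
                "entry_age": -0.02,
                "season_cos": 0.15,
            },
            "sedentary": {"bmi": 0.02, "prior_cvd": 0.10},
        },
        # lognormal person-level heterogeneity in activity propensity
        "activity_re_sd": {"sleep": 0.15, "sedentary": 0.25, "mvpa": 0.55},
        # direct log-hazard effects of covariates on mortality
        "hazard_coefs": {
            "sex": 0.45,
            "smoking_previous": 0.20,
            "smoking_current": 0.80,
            "bmi": 0.02,
            "townsend": 0.04,
            "prior_cvd": 0.40,
            "prior_cancer": 0.50,
            "prior_respiratory": 0.15,
        },
    }


def _default_true_log_hr() -> dict[str, float]:
    # Per-10-minute log hazard ratios relative to the reference (light).
    # HR 0.96 for MVPA-for-light and 1.02 for sedentary-for-light imply
    # sedentary-for-MVPA exp(ln1.02 - ln0.96) ~ 1.06.
    return {"sleep": 0.0, "sedentary": math.log(1.02), "mvpa": math.log(0.96)}


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort.

    All fields are plain scalars / dicts so a config round-trips through
    YAML/JSON unchanged. ``seed`` is the master seed; per-participant streams
    are derived with a fixed splitting rule (``SeedSequence([seed, 0])`` for
    covariates, ``([seed, 1, i])`` for participant *i*'s activity sequence,
    ``([seed, 2])`` for survival draws).
    """

    n_participants: int = 100
    n_days: int = 7
    epoch_minutes: int = 1
    start_clock_minute: int = 0
    dwell_params: dict = field(default_factory=_default_dwell_params)
    category_weights: dict = field(default_factory=_default_category_weights)
    sleep_diurnal_weight: float = 8.0
    emission_params: dict = field(default_factory=_default_emission_params)
    ml_confusion: dict = field(default_factory=_default_ml_confusion)
    nonwear_rate: float = 0.3
    nonwear_duration: dict = field(
        default_factory=lambda: {"dist": "shifted_exponential", "min": 60, "mean": 300.0}
    )
    covariate_params: dict = field(default_factory=_default_covariate_params)
    true_log_hr: dict = field(default_factory=_default_true_log_hr)
    reference_category: str = "light"
    baseline_hazard: dict = field(
        default_factory=lambda: {
            "breaks": [40.0, 55.0, 65.0, 75.0, 85.0],
            "rates": [0.00025, 0.001, 0.0025, 0.006, 0.020],
        }
    )
    entry_age_range: tuple = (48.0, 76.0)
    admin_censor_age: float = 82.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.epoch_minutes != 1:
            raise ConfigurationError("only 1-minute epochs are supported")
        if not 0 <= self.start_clock_minute < MINUTES_PER_DAY:
            raise ConfigurationError("start_clock_minute must be in [0, 1440)")
        for cat in CATEGORIES:
            if cat not in self.dwell_params:
                raise ConfigurationError(f"dwell_params missing category {cat!r}")
            if self.dwell_params[cat]["mean"] < 1.0:
                raise ConfigurationError("dwell means must be >= 1 minute")
            if self.category_weights.get(cat, 0.0) <= 0.0:
                raise ConfigurationError("category_weights must be positive")
        if self.sleep_diurnal_weight <= 0:
            raise ConfigurationError("sleep_diurnal_weight must be positive")
        for cat, row in self.ml_confusion.items():
            if cat not in CATEGORIES:
                raise ConfigurationError(f"ml_confusion row for unknown category {cat!r}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"ml_confusion row {cat!r} does not sum to 1")
            if any(k not in ML_LABELS for k in row):
                raise ConfigurationError(f"ml_confusion row {cat!r} has unknown labels")
        if self.nonwear_rate < 0:
            raise ConfigurationError("nonwear_rate must be >= 0")
        if self.nonwear_duration.get("min", 0) < 60:
            raise ConfigurationError("nonwear episodes must last >= 60 minutes")
        if self.reference_category not in CATEGORIES:
            raise ConfigurationError("reference_category must be a simulated category")
        for cat in self.true_log_hr:
            if cat not in CATEGORIES or cat == self.reference_category:
                raise ConfigurationError(
                    "true_log_hr keys must be non-reference categories"
                )
        bh = self.baseline_hazard
        if len(bh["breaks"]) != len(bh["rates"]):
            raise ConfigurationError("baseline_hazard breaks and rates must align")
        if any(np.diff(bh["breaks"]) <= 0):
            raise ConfigurationError("baseline_hazard breaks must be increasing")
        if any(r < 0 for r in bh["rates"]):
            raise ConfigurationError("baseline_hazard rates must be >= 0")
        if bh["rates"][-1] <= 0:
            raise ConfigurationError("last baseline_hazard band must have positive rate")
        lo, hi = self.entry_age_range
        if not lo < hi:
            raise ConfigurationError("entry_age_range must be an increasing pair")
        if self.admin_censor_age <= lo:
            raise ConfigurationError(
                "admin_censor_age below the entry age range leaves no follow-up"
            )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["entry_age_range"] = list(self.entry_age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "entry_age_range" in d:
            d["entry_age_range"] = tuple(d["entry_age_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# activity sequences

def _dwell_pool(rng: np.random.Generator, params: Mapping[str, Any], size: int) -> np.ndarray:
    """Draw ``size`` dwell lengths (whole minutes >= 1) for one category."""
    mean = float(params["mean"])
    if params["dist"] == "geometric":
        if mean <= 1.0:
            return np.ones(size, dtype=np.int64)
        return rng.geometric(1.0 / mean, size=size)
    if params["dist"] == "nbinom":
        # shifted negative binomial: 1 + NB(shape, p), mean 1 + shape(1-p)/p
        shape = float(params["shape"])
        if mean <= 1.0:
            return np.ones(size, dtype=np.int64)
        p = shape / (shape + mean - 1.0)
        return 1 + rng.negative_binomial(shape, p, size=size)
    raise ConfigurationError(f"unknown dwell distribution {params['dist']!r}")


def _simulate_dwells(
    rng: np.random.Generator,
    config: SimulationConfig,
    propensity_shift: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating (category, length) dwells covering n_days x 1440 minutes.

    Consecutive dwells always differ in category, so the dwell sequence *is*
    the true bout sequence. The final dwell is truncated at the series end.
    """
    total = config.n_days * MINUTES_PER_DAY
    w = np.array([config.category_weights[c] for c in CATEGORIES], dtype=float)
    if propensity_shift is not None:
        w = w * np.exp(np.asarray(propensity_shift, dtype=float))
    sdw = config.sleep_diurnal_weight
    w_night = w.copy()
    w_night[0] *= sdw
    w_day = w.copy()
    w_day[0] /= sdw

    # cumulative selection weights for each (previous category, night flag);
    # slot 0 is "no previous category" (series start)
    cum = np.empty((5, 2, 4))
    for prev in range(5):
        for night, wn in enumerate((w_day, w_night)):
            ww = wn.copy()
            if prev > 0:
                ww[prev - 1] = 0.0
            cum[prev, night] = np.cumsum(ww)

    # pre-drawn dwell pools per category and a uniform stream for selection
    mean_overall = min(float(config.dwell_params[c]["mean"]) for c in CATEGORIES)
    est = int(total / max(mean_overall, 1.0)) + 64
    pools = [_dwell_pool(rng, config.dwell_params[c], est) for c in CATEGORIES]
    ptr = [0, 0, 0, 0]
    unif = rng.random(est)
    uptr = 0

    start_clock = config.start_clock_minute
    ns, ne = NIGHT_START_MINUTE, NIGHT_END_MINUTE
    cats: list[int] = []
    lens: list[int] = []
    t = 0
    prev = 0
    while t < total:
        clock = (start_clock + t) % MINUTES_PER_DAY
        night = 1 if (clock >= ns or clock < ne) else 0
        cw = cum[prev, night]
        if uptr >= len(unif):
            unif = rng.random(est)
            uptr = 0
        u = unif[uptr] * cw[3]
        uptr += 1
        k = 0
        while cw[k] < u:
            k += 1
        if ptr[k] >= len(pools[k]):
            pools[k] = _dwell_pool(rng, config.dwell_params[CATEGORIES[k]], est)
            ptr[k] = 0
        length = int(pools[k][ptr[k]])
        ptr[k] += 1
        cats.append(k)
        lens.append(length)
        t += length
        prev = k + 1
    lens[-1] -= t - total  # truncate the final dwell at the series end
    return np.array(cats, dtype=np.int8), np.array(lens, dtype=np.int64)


def _dwell_composition(cats: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Total minutes per category from a dwell sequence."""
    return np.bincount(cats, weights=lens, minlength=4)


def _dwell_strata_minutes(cats: np.ndarray, lens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total minutes in sedentary and MVPA bout-length strata (by bout length)."""
    sed = lens[cats == CATEGORY_CODES["sedentary"]]
    mv = lens[cats == CATEGORY_CODES["mvpa"]]
    sed_idx = np.digitize(sed, _SEDENTARY_STRATA_EDGES)
    mv_idx = np.digitize(mv, _MVPA_STRATA_EDGES)
    sed_min = np.bincount(sed_idx, weights=sed, minlength=3)
    mv_min = np.bincount(mv_idx, weights=mv, minlength=4)
    return sed_min, mv_min


def _draw_dist(rng: np.random.Generator, spec: Mapping[str, Any], size) -> np.ndarray:
    kind = spec["dist"]
    if kind == "gamma":
        return spec.get("loc", 0.0) + rng.gamma(spec["shape"], spec["scale"], size=size)
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=size)
    if kind == "constant":
        return np.full(size, float(spec["value"]))
    raise ConfigurationError(f"unknown emission distribution {kind!r}")


def _draw_nonwear_duration(rng: np.random.Generator, spec: Mapping[str, Any]) -> int:
    if spec["dist"] == "shifted_exponential":
        return int(spec["min"] + rng.exponential(max(spec["mean"] - spec["min"], 0.0)))
    if spec["dist"] == "constant":
        return int(spec["value"])
    raise ConfigurationError(f"unknown nonwear duration distribution {spec['dist']!r}")


def _confusion_matrix(config: SimulationConfig) -> np.ndarray:
    m = np.zeros((len(CATEGORIES), len(ML_LABELS)))
    for i, cat in enumerate(CATEGORIES):
        for j, lab in enumerate(ML_LABELS):
            m[i, j] = config.ml_confusion[cat].get(lab, 0.0)
    return m


def simulate_activity_sequence(
    config: SimulationConfig,
    participant_seed: int,
    propensity_shift: np.ndarray | None = None,
    participant_id: str = "P00000",
    start_date: str | pd.Timestamp = "2014-06-02",
) -> tuple[LabelSeries, EpochSeries]:
    """Simulate one participant's true labels and observed epoch record.

    Returns the ground-truth :class:`LabelSeries` (pre-noise: non-wear does
    not erase true labels) and the observed :class:`EpochSeries` with
    emissions, ML labels and injected non-wear episodes.
    """
    config.validate()
    rng = np.random.default_rng(participant_seed)
    cats, lens = _simulate_dwells(rng, config, propensity_shift)
    labels = np.repeat(cats, lens)
    n = len(labels)

    vm = np.empty(n)
    sd = np.empty((n, 3))
    for k, cat in enumerate(CATEGORIES):
        mask = labels == k
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        vm[mask] = _draw_dist(rng, config.emission_params[cat]["vm"], cnt)
        sd[mask] = _draw_dist(rng, config.emission_params[cat]["sd"], (cnt, 3))
    vm = np.maximum(vm, 0.0)

    conf = _confusion_matrix(config)
    cum = np.cumsum(conf, axis=1)[labels.astype(int)]
    u = rng.random(n)
    ml = (u[:, None] > cum).sum(axis=1).astype(np.int8)

    n_episodes = rng.poisson(config.nonwear_rate * config.n_days / 7.0)
    for _ in range(n_episodes):
        start = int(rng.integers(0, n))
        dur = _draw_nonwear_duration(rng, config.nonwear_duration)
        seg = slice(start, min(start + dur, n))
        m = seg.stop - seg.start
        sd[seg] = rng.uniform(1.0, 10.0, size=(m, 3))
        vm[seg] = rng.uniform(0.0, 5.0, size=m)

    start_dt = pd.Timestamp(start_date) + pd.Timedelta(minutes=config.start_clock_minute)
    series = EpochSeries(participant_id, start_dt, vm, sd, ml)
    true = LabelSeries(participant_id, config.start_clock_minute, labels)
    return true, series


# ---------------------------------------------------------------------------
# covariates and confounding

def _simulate_covariates(rng: np.random.Generator, config: SimulationConfig, ids: Sequence[str]) -> pd.DataFrame:
    p = config.covariate_params
    n = len(ids)

    def cat_draw(probs: Mapping[str, float]) -> np.ndarray:
        names = list(probs)
        return np.array(names)[rng.choice(len(names), size=n, p=np.array(list(probs.values())))]

    lo, hi = config.entry_age_range
    df = pd.DataFrame(
        {
            "participant_id": list(ids),
            "sex": (rng.random(n) < p["sex_p_male"]).astype(int),
            "ethnicity": cat_draw(p["ethnicity_probs"]),
            "smoking": cat_draw(p["smoking_probs"]),
            "education": cat_draw(p["education_probs"]),
            "income": cat_draw(p["income_probs"]),
            "townsend": rng.normal(p["townsend_mean"], p["townsend_sd"], size=n),
            "bmi": rng.normal(p["bmi_mean"], p["bmi_sd"], size=n),
            "prior_cvd": (rng.random(n) < p["prior_cvd_p"]).astype(int),
            "prior_cancer": (rng.random(n) < p["prior_cancer_p"]).astype(int),
            "prior_respiratory": (rng.random(n) < p["prior_respiratory_p"]).astype(int),
            "wear_day_of_year": rng.integers(1, 366, size=n),
            "entry_age": rng.uniform(lo, hi, size=n),
        }
    )
    return df


def _covariate_signal(cov: pd.DataFrame, coefs: Mapping[str, float], params: Mapping[str, Any]) -> np.ndarray:
    """Linear combination of covariate features named by coefficient keys."""
    n = len(cov)
    out = np.zeros(n)
    for key, beta in coefs.items():
        if key == "sex":
            x = cov["sex"].to_numpy(float)
        elif key == "smoking_previous":
            x = (cov["smoking"] == "previous").to_numpy(float)
        elif key == "smoking_current":
            x = (cov["smoking"] == "current").to_numpy(float)
        elif key == "bmi":
            x = cov["bmi"].to_numpy(float) - params["bmi_center"]
        elif key == "townsend":
            x = cov["townsend"].to_numpy(float)
        elif key in ("prior_cvd", "prior_cancer", "prior_respiratory"):
            x = cov[key].to_numpy(float)
        elif key == "entry_age":
            x = cov["entry_age"].to_numpy(float) - params["age_center"]
        elif key == "season_cos":
            d = cov["wear_day_of_year"].to_numpy(float)
            x = np.cos(2 * np.pi * (d - params["season_peak_day"]) / 365.0)
        else:
            raise ConfigurationError(f"unknown covariate coefficient key {key!r}")
        out += beta * x
    return out


def _propensity_shifts(rng: np.random.Generator, config: SimulationConfig, cov: pd.DataFrame) -> np.ndarray:
    """Per-participant (n, 4) additive shifts on log category-selection weights."""
    p = config.covariate_params
    n = len(cov)
    shifts = np.zeros((n, 4))
    for cat, coefs in p.get("activity_coefs", {}).items():
        shifts[:, CATEGORY_CODES[cat]] += _covariate_signal(cov, coefs, p)
    for cat, sdv in p.get("activity_re_sd", {}).items():
        if sdv > 0:
            shifts[:, CATEGORY_CODES[cat]] += rng.normal(0.0, sdv, size=n)
    return shifts


# ---------------------------------------------------------------------------
# survival

def _hazard_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    breaks = np.asarray(config.baseline_hazard["breaks"], dtype=float)
    rates = np.asarray(config.baseline_hazard["rates"], dtype=float)
    cumh = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(breaks))])
    return breaks, rates, cumh


def baseline_cumulative_hazard(ages, config: SimulationConfig) -> np.ndarray:
    """Integrated piecewise-constant baseline hazard H0(age)."""
    breaks, rates, cumh = _hazard_arrays(config)
    ages = np.asarray(ages, dtype=float)
    idx = np.clip(np.searchsorted(breaks, ages, side="right") - 1, 0, len(breaks) - 1)
    return np.where(
        ages <= breaks[0], 0.0, cumh[idx] + rates[idx] * (ages - breaks[idx])
    )


def _inverse_cumulative_hazard(h, config: SimulationConfig) -> np.ndarray:
    breaks, rates, cumh = _hazard_arrays(config)
    h = np.asarray(h, dtype=float)
    idx = np.clip(np.searchsorted(cumh, h, side="right") - 1, 0, len(breaks) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = breaks[idx] + (h - cumh[idx]) / rates[idx]
    # zero-rate bands cannot contain an event; push to the next positive band
    for j in np.nonzero(rates == 0.0)[0]:
        in_band = idx == j
        if np.any(in_band):
            out[in_band] = breaks[j + 1] if j + 1 < len(breaks) else np.inf
    return out


def composition_log_hazard(minutes: Mapping[str, float], config: SimulationConfig) -> float:
    """Linear predictor contribution of an average daily composition.

    ``sum_k beta_k * minutes_k / 10`` over non-reference categories, where
    ``beta_k`` are the configured true per-10-minute log hazard ratios.
    """
    total = sum(minutes[c] for c in CATEGORIES)
    if abs(total - MINUTES_PER_DAY) > 1e-6:
        raise ConfigurationError(f"composition sums to {total}, not {MINUTES_PER_DAY}")
    return sum(
        beta * minutes[cat] / 10.0 for cat, beta in config.true_log_hr.items()
    )


def _simulate_survival_batch(
    rng: np.random.Generator,
    eta: np.ndarray,
    entry_ages: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    h_entry = baseline_cumulative_hazard(entry_ages, config)
    e = rng.exponential(size=len(eta))
    event_age = _inverse_cumulative_hazard(h_entry + e * np.exp(-eta), config)
    censor = config.admin_censor_age
    event = event_age <= censor
    exit_age = np.minimum(event_age, censor)
    # degenerate case: entry at/after the administrative censor age
    late = entry_ages >= censor
    exit_age = np.where(late, entry_ages, exit_age)
    event = np.where(late, False, event)
    return exit_age, event


def simulate_survival(
    composition: Mapping[str, float] | ParticipantSummary,
    covariates: CovariateRecord | None,
    config: SimulationConfig,
    participant_seed: int,
    entry_age: float | None = None,
) -> SurvivalRecord:
    """Draw one death/censoring record from the true composition.

    ``composition`` gives average daily minutes per category (closing to
    1,440). Covariate effects use the configured ``hazard_coefs``; pass
    ``covariates=None`` for a composition-only hazard.
    """
    config.validate()
    if isinstance(composition, ParticipantSummary):
        pid = composition.participant_id
        minutes = composition.minutes_per_day
    else:
        pid = covariates.participant_id if covariates is not None else "P00000"
        minutes = composition
    eta = composition_log_hazard(minutes, config)
    if entry_age is None:
        entry_age = getattr(covariates, "entry_age", None)
        if entry_age is None:
            entry_age = float(np.mean(config.entry_age_range))
    lo, hi = config.entry_age_range
    if not lo <= entry_age <= hi:
        raise ConfigurationError("entry age outside entry_age_range")
    if covariates is not None:
        cov_df = pd.DataFrame([covariates.__dict__])
        cov_df["entry_age"] = entry_age
        eta += float(
            _covariate_signal(
                cov_df, config.covariate_params.get("hazard_coefs", {}), config.covariate_params
            )[0]
        )
    rng = np.random.default_rng(participant_seed)
    exit_age, event = _simulate_survival_batch(
        rng, np.array([eta]), np.array([entry_age]), config
    )
    return SurvivalRecord(pid, float(entry_age), float(exit_age[0]), bool(event[0]))


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortDataset:
    """A simulated cohort: truth, observations, covariates and outcomes.

    ``true_summaries`` holds per-participant average daily minutes per
    category and bout-length stratum computed from the ground-truth dwell
    sequence (all days count; no noise, no missingness). ``epoch_series`` and
    ``true_labels`` are populated only when epochs were materialised.
    """

    config: SimulationConfig
    participant_ids: list[str]
    covariates: pd.DataFrame
    survival: pd.DataFrame
    true_summaries: pd.DataFrame
    epoch_series: list[EpochSeries] | None = None
    true_labels: list[LabelSeries] | None = None


def participant_seed(master_seed: int, index: int) -> int:
    """Deterministic per-participant seed (documented splitting rule)."""
    return int(np.random.SeedSequence([master_seed, 1, index]).generate_state(1)[0] % (2**31))


def generate_cohort(config: SimulationConfig, include_epochs: bool = True) -> CohortDataset:
    """Generate a full cohort; byte-identical for identical config + seed.

    With ``include_epochs=False`` only the dwell-level truth is simulated
    (composition, bout strata, covariates, survival) — the fast path for
    parameter-recovery experiments that skip the measurement layer.
    """
    config.validate()
    n = config.n_participants
    ids = [f"P{i:05d}" for i in range(n)]
    cov_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cov = _simulate_covariates(cov_rng, config, ids)
    shifts = _propensity_shifts(cov_rng, config, cov) if n else np.zeros((0, 4))

    comp = np.zeros((n, 4))
    sed_strata = np.zeros((n, 3))
    mv_strata = np.zeros((n, 4))
    epoch_series: list[EpochSeries] | None = [] if include_epochs else None
    true_labels: list[LabelSeries] | None = [] if include_epochs else None
    base_date = pd.Timestamp("2014-01-01")
    for i in range(n):
        pseed = participant_seed(config.seed, i)
        if include_epochs:
            start = base_date + pd.Timedelta(days=int(cov["wear_day_of_year"].iat[i]) - 1)
            true, series = simulate_activity_sequence(
                config, pseed, shifts[i], participant_id=ids[i], start_date=start
            )
            true_labels.append(true)
            epoch_series.append(series)
            cats = true.codes
            lens = np.diff(
                np.concatenate([[0], np.nonzero(np.diff(cats))[0] + 1, [len(cats)]])
            )
            cats = cats[np.concatenate([[0], np.nonzero(np.diff(cats))[0] + 1])]
        else:
            rng = np.random.default_rng(pseed)
            cats, lens = _simulate_dwells(rng, config, shifts[i])
        comp[i] = _dwell_composition(cats, lens)
        sed_strata[i], mv_strata[i] = _dwell_strata_minutes(cats, lens)

    days = float(config.n_days)
    summaries = pd.DataFrame({"participant_id": ids, "n_valid_days": config.n_days})
    for k, cat in enumerate(CATEGORIES):
        summaries[cat] = comp[:, k] / days
    for j, col in enumerate(SEDENTARY_STRATA_COLS):
        summaries[col] = sed_strata[:, j] / days
    for j, col in enumerate(MVPA_STRATA_COLS):
        summaries[col] = mv_strata[:, j] / days

    beta = np.array(
        [config.true_log_hr.get(cat, 0.0) for cat in CATEGORIES]
    )
    eta = (comp / days / 10.0) @ beta
    if n:
        eta += _covariate_signal(
            cov, config.covariate_params.get("hazard_coefs", {}), config.covariate_params
        )
    surv_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    entry = cov["entry_age"].to_numpy(float) if n else np.zeros(0)
    exit_age, event = (
        _simulate_survival_batch(surv_rng, eta, entry, config) if n else (np.zeros(0), np.zeros(0, bool))
    )
    survival = pd.DataFrame(
        {
            "participant_id": ids,
            "entry_age": entry,
            "exit_age": exit_age,
            "event": np.asarray(event, dtype=bool),
        }
    )
    return CohortDataset(config, ids, cov, survival, summaries, epoch_series, true_labels)
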
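"""Coupling (isotemporal substitution) Cox models on the age time scale.

Because the four activity categories (or bout-length strata plus the other
categories) partition the 1,440 minutes of a day, a Cox model that includes
every component would be unidentified. Omitting one *baseline* component
absorbs the constraint: the coefficient of a remaining component k, scaled
per 10 minutes, is then the log hazard ratio of spending 10 minutes more per
day in k coupled with 10 minutes less in the baseline. Refitting with a
different baseline b' reproduces coefficients via beta'_k = beta_k - beta_b'.

Follow-up runs on the age scale with left truncation at entry age (optionally
delayed by 1 or 2 years) and right censoring at exit age. Fits use lifelines'
Cox partial likelihood (Efron tie handling) with Wald confidence intervals.
The proportional-hazards diagnostic correlates scaled Schoenfeld residuals
with log(event age).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .core import CATEGORIES, MINUTES_PER_DAY, MVPA_STRATA_COLS, SEDENTARY_STRATA_COLS

#: Fixed reference levels for categorical covariates.
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "ethnicity": ["white", "black", "asian", "other"],
    "smoking": ["never", "previous", "current"],
    "education": ["none", "secondary", "further", "degree"],
    "income": ["lt_18k", "18_31k", "31_52k", "52_100k", "gt_100k"],
}

_SURV_COLS = ("entry_age", "exit_age", "event")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeasonCovariates:
    """Cosine-encoded day of year of accelerometer wear."""

    c1: float
    c2: float
    d: int


def compute_season_covariates(wear_day_of_year: int) -> SeasonCovariates:
    """c1 = cos(2*pi*d/365), c2 = sin(2*pi*d/365) for d in [1, 365]."""
    d = int(wear_day_of_year)
    if not 1 <= d <= 365:
        raise ValueError(f"day of year {d} outside [1, 365]")
    angle = 2.0 * math.pi * d / 365.0
    return SeasonCovariates(math.cos(angle), math.sin(angle), d)


@dataclass
class CouplingModelSpec:
    """What to fit: composition components, baseline, covariates, entry delay.

    ``components`` must partition the 1,440 minutes of a day — either the four
    overall categories, or the bout-length strata of one target category plus
    the other three categories. ``baseline`` is the omitted component.
    """

    components: tuple[str, ...] = tuple(CATEGORIES)
    baseline: str = "sleep"
    scale_minutes: float = 10.0
    covariate_set: str = "full"  # or "no_bmi_no_illness"
    entry_delay_years: float = 0.0
    ties_method: str = "efron"

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        if self.baseline not in self.components:
            raise ValueError("baseline must be one of the components")
        if self.covariate_set not in ("full", "no_bmi_no_illness"):
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}")
        if self.ties_method != "efron":
            raise ValueError("only Efron tie handling is implemented")
        if self.entry_delay_years not in (0, 0.0, 1, 1.0, 2, 2.0):
            raise ValueError("entry_delay_years must be 0, 1, or 2")

    @property
    def activity_columns(self) -> list[str]:
        return [f"act_{c}" for c in self.components if c != self.baseline]


def overall_spec(baseline: str = "sleep", **kwargs) -> CouplingModelSpec:
    """Model over the four overall categories."""
    return CouplingModelSpec(components=tuple(CATEGORIES), baseline=baseline, **kwargs)


def bout_spec(category: str, baseline: str = "light", **kwargs) -> CouplingModelSpec:
    """Model splitting one category into its bout-length strata."""
    if category == "sedentary":
        strata: Sequence[str] = SEDENTARY_STRATA_COLS
    elif category == "mvpa":
        strata = MVPA_STRATA_COLS
    else:
        raise ValueError("bout-length models exist for 'sedentary' and 'mvpa' only")
    components = tuple(strata) + tuple(c for c in CATEGORIES if c != category)
    return CouplingModelSpec(components=components, baseline=baseline, **kwargs)


def _covariate_design(covariates: pd.DataFrame, covariate_set: str) -> pd.DataFrame:
    out = pd.DataFrame(index=covariates.index)
    out["sex"] = covariates["sex"].astype(float)
    for var, levels in CATEGORICAL_LEVELS.items():
        values = covariates[var]
        unknown = set(values.unique()) - set(levels)
        if unknown:
            raise ValueError(f"unknown {var} levels: {sorted(unknown)}")
        for level in levels[1:]:  # first level is the reference
            out[f"{var}_{level}"] = (values == level).astype(float)
    out["townsend"] = covariates["townsend"].astype(float)
    season = covariates["wear_day_of_year"].astype(int).map(
        lambda d: compute_season_covariates(d)
    )
    out["c1"] = season.map(lambda s: s.c1)
    out["c2"] = season.map(lambda s: s.c2)
    if covariate_set == "full":
        out["bmi"] = covariates["bmi"].astype(float)
        for var in ("prior_cvd", "prior_cancer", "prior_respiratory"):
            out[var] = covariates[var].astype(float)
    return out


def build_design_matrix(
    summaries: pd.DataFrame, covariates: pd.DataFrame, spec: CouplingModelSpec
) -> pd.DataFrame:
    """Model matrix: per-10-minute activity columns plus covariate columns.

    One column per non-baseline component (average daily minutes divided by
    ``scale_minutes``); the baseline contributes no column. Indexed by
    participant_id.
    """
    missing = [c for c in spec.components if c not in summaries.columns]
    if missing:
        raise ValueError(f"summaries lack component columns: {missing}")
    s = summaries.set_index("participant_id")
    closure = s[list(spec.components)].sum(axis=1)
    bad = np.abs(closure - MINUTES_PER_DAY) > 1e-6
    if bad.any():
        raise ValueError(
            f"components do not close to {MINUTES_PER_DAY} min/day for "
            f"{int(bad.sum())} participants (e.g. {closure[bad].iloc[0]:.6f})"
        )
    X = pd.DataFrame(index=s.index)
    for comp in spec.components:
        if comp != spec.baseline:
            X[f"act_{comp}"] = s[comp] / spec.scale_minutes
    cov = covariates.set_index("participant_id").loc[X.index]
    X = X.join(_covariate_design(cov, spec.covariate_set))
    return X


@dataclass
class SubstitutionEstimate:
    """HR per 10-minute swap of `comparison` for `baseline`, with Wald CI."""

    baseline: str
    comparison: str
    hr: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high) or self.hr <= 0:
            raise ValueError("inconsistent hazard ratio estimate")


@dataclass
class CouplingFit:
    """A fitted coupling model with tidy estimates and PH diagnostics."""

    spec: CouplingModelSpec
    model: CoxPHFitter
    data: pd.DataFrame
    estimates: pd.DataFrame
    ph: pd.DataFrame
    n: int
    n_events: int
    n_dropped_pre_entry: int

    @property
    def coefs(self) -> pd.Series:
        return self.model.params_

    def substitution_estimates(self) -> list[SubstitutionEstimate]:
        return [
            SubstitutionEstimate(
                r.baseline, r.comparison, r.hr, r.ci_low, r.ci_high, r.p
            )
            for r in self.estimates.itertuples()
        ]


def fit_coupling_cox(
    design: pd.DataFrame, survival: pd.DataFrame, spec: CouplingModelSpec
) -> CouplingFit:
    """Partial-likelihood fit with left truncation and delayed-entry filtering.

    Entry is ``entry_age + entry_delay_years``; participants whose exit falls
    at or before their (delayed) entry never enter the risk set and are
    dropped. Raises if no events remain or the optimizer fails.
    """
    surv = survival.set_index("participant_id").loc[design.index, list(_SURV_COLS)].copy()
    surv["entry_age"] = surv["entry_age"] + spec.entry_delay_years
    keep = surv["exit_age"] > surv["entry_age"]
    n_dropped = int((~keep).sum())
    df = design.join(surv)[keep.values].copy()
    df["event"] = df["event"].astype(bool)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise ValueError("no events after delayed-entry filtering")
    # constant columns (e.g. an unobserved categorical level, or an empty
    # bout-length stratum) are unidentifiable; drop them from the fit
    degenerate = [
        c for c in df.columns if c not in _SURV_COLS and df[c].nunique() <= 1
    ]
    if degenerate:
        logger.warning(
            "dropping constant model columns: %s", degenerate
        )
        df = df.drop(columns=degenerate)
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="exit_age",
        event_col="event",
        entry_col="entry_age",
        show_progress=False,
    )
    summary = cph.summary
    rows = []
    for col in spec.activity_columns:
        if col in degenerate:
            continue
        rows.append(
            {
                "baseline": spec.baseline,
                "comparison": col.removeprefix("act_"),
                "hr": float(summary.loc[col, "exp(coef)"]),
                "ci_low": float(summary.loc[col, "exp(coef) lower 95%"]),
                "ci_high": float(summary.loc[col, "exp(coef) upper 95%"]),
                "p": float(summary.loc[col, "p"]),
            }
        )
    fit = CouplingFit(
        spec=spec,
        model=cph,
        data=df,
        estimates=pd.DataFrame(rows),
        ph=pd.DataFrame(),
        n=int(len(df)),
        n_events=n_events,
        n_dropped_pre_entry=n_dropped,
    )
    fit.ph = ph_test(fit)
    # attach per-column PH diagnostics to the activity estimates
    ph_idx = fit.ph.set_index("covariate")
    fit.estimates["ph_corr"] = [
        float(ph_idx.loc[f"act_{c}", "ph_corr"]) for c in fit.estimates["comparison"]
    ]
    fit.estimates["ph_p"] = [
        float(ph_idx.loc[f"act_{c}", "ph_p"]) for c in fit.estimates["comparison"]
    ]
    return fit


# ---------------------------------------------------------------------------
# Schoenfeld residuals and the proportional-hazards diagnostic

def schoenfeld_residuals(
    X: np.ndarray,
    entry: np.ndarray,
    duration: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Schoenfeld residuals at event times under left truncation.

    For each event at age t, the residual is the event's covariate vector
    minus the risk-set average weighted by exp(X beta), the risk set being
    everyone with entry < t <= exit. Returns (event_times, residuals) sorted
    by event time. Assumes continuous times (no heavy ties).
    """
    X = np.asarray(X, dtype=float)
    entry = np.asarray(entry, dtype=float)
    duration = np.asarray(duration, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(duration[event], kind="stable")
    times = duration[event][order]
    idx_event = np.flatnonzero(event)[order]
    w = np.exp(X @ beta)
    resid = np.empty((len(times), X.shape[1]))
    for k, t in enumerate(times):
        risk = (entry < t) & (duration >= t)
        ww = w[risk]
        xbar = (ww @ X[risk]) / ww.sum()
        resid[k] = X[idx_event[k]] - xbar
    return times, resid


def scaled_schoenfeld_residuals(
    resid: np.ndarray, vcov: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Grambsch–Therneau scaling: r* = d * r @ V(beta_hat) + beta_hat."""
    d = resid.shape[0]
    return d * resid @ np.asarray(vcov, dtype=float) + np.asarray(beta, dtype=float)


def ph_test(fit: CouplingFit) -> pd.DataFrame:
    """Correlation of scaled Schoenfeld residuals with log(event age).

    Returns one row per model column with the Pearson correlation and the
    two-sided p-value of the zero-correlation t-test (df = events - 2).
    Requires at least 2 events (p is undefined until 3).
    """
    df = fit.data
    cols = [c for c in df.columns if c not in _SURV_COLS]
    X = df[cols].to_numpy(float)
    beta = fit.model.params_.loc[cols].to_numpy(float)
    vcov = fit.model.variance_matrix_.loc[cols, cols].to_numpy(float)
    times, resid = schoenfeld_residuals(
        X,
        df["entry_age"].to_numpy(float),
        df["exit_age"].to_numpy(float),
        df["event"].to_numpy(bool),
        beta,
    )
    d = len(times)
    if d < 2:
        raise ValueError("PH diagnostic requires at least 2 events")
    scaled = scaled_schoenfeld_residuals(resid, vcov, beta)
    logt = np.log(times)
    rows = []
    for j, col in enumerate(cols):
        y = scaled[:, j]
        if np.std(y) == 0 or np.std(logt) == 0:
            corr, p = 0.0, float("nan")
        else:
            corr = float(np.corrcoef(logt, y)[0, 1])
            if d > 2 and abs(corr) < 1.0:
                tstat = corr * math.sqrt((d - 2) / (1.0 - corr**2))
                p = float(2 * stats.t.sf(abs(tstat), d - 2))
            else:
                p = float("nan")
        rows.append({"covariate": col, "ph_corr": corr, "ph_p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# isometric log-ratio sensitivity analysis

#: Default sequential binary partition for the 4-part composition.
DEFAULT_PARTITION: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("sleep",), ("sedentary", "light", "mvpa")),
    (("sedentary",), ("light", "mvpa")),
    (("light",), ("mvpa",)),
)


def close_composition(
    comp: pd.DataFrame, zero_replace: float = 0.5, total: float = MINUTES_PER_DAY
) -> pd.DataFrame:
    """Replace zero parts by ``zero_replace`` minutes and re-close to ``total``."""
    if (comp.to_numpy() < 0).any():
        raise ValueError("negative composition parts")
    out = comp.where(comp > 0, zero_replace)
    return out.div(out.sum(axis=1), axis=0) * total


def ilr_transform(
    comp: pd.DataFrame,
    partition: Sequence[tuple[Sequence[str], Sequence[str]]] = DEFAULT_PARTITION,
) -> pd.DataFrame:
    """Isometric log-ratio coordinates for a sequential binary partition.

    Coordinate i is ``sqrt(r*s/(r+s)) * ln(gmean(numerator)/gmean(denominator))``
    with r, s the part counts of the two sides. All parts must be positive
    (apply :func:`close_composition` first to replace zeros).
    """
    if (comp.to_numpy() <= 0).any():
        raise ValueError("ILR requires strictly positive parts")
    logc = np.log(comp)
    out = pd.DataFrame(index=comp.index)
    for i, (num, den) in enumerate(partition, start=1):
        r, s = len(num), len(den)
        gm_num = logc[list(num)].mean(axis=1)
        gm_den = logc[list(den)].mean(axis=1)
        out[f"ilr_{i}"] = math.sqrt(r * s / (r + s)) * (gm_num - gm_den)
    return out


def build_ilr_design(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: CouplingModelSpec,
    partition: Sequence[tuple[Sequence[str], Sequence[str]]] = DEFAULT_PARTITION,
    zero_replace: float = 0.5,
) -> pd.DataFrame:
    """Design matrix with ILR coordinates in place of per-10-minute columns."""
    s = summaries.set_index("participant_id")
    comp = close_composition(s[list(spec.components)], zero_replace)
    X = ilr_transform(comp, partition)
    cov = covariates.set_index("participant_id").loc[X.index]
    return X.join(_covariate_design(cov, spec.covariate_set))


def fit_ilr_cox(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    survival: pd.DataFrame,
    spec: CouplingModelSpec,
    partition: Sequence[tuple[Sequence[str], Sequence[str]]] = DEFAULT_PARTITION,
) -> CouplingFit:
    """Fit the Cox model on ILR coordinates (compositional sensitivity)."""
    design = build_ilr_design(summaries, covariates, spec, partition)
    surv = survival.set_index("participant_id").loc[design.index, list(_SURV_COLS)].copy()
    surv["entry_age"] = surv["entry_age"] + spec.entry_delay_years
    keep = surv["exit_age"] > surv["entry_age"]
    df = design.join(surv)[keep.values].copy()
    df["event"] = df["event"].astype(bool)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="exit_age", event_col="event", entry_col="entry_age")
    fit = CouplingFit(
        spec=spec,
        model=cph,
        data=df,
        estimates=pd.DataFrame(
            columns=["baseline", "comparison", "hr", "ci_low", "ci_high", "p"]
        ),
        ph=pd.DataFrame(),
        n=int(len(df)),
        n_events=int(df["event"].sum()),
        n_dropped_pre_entry=int((~keep).sum()),
    )
    fit.ph = ph_test(fit)
    return fit


def ilr_substitution_loghr(
    fit: CouplingFit,
    reference_composition: Mapping[str, float],
    baseline: str,
    comparison: str,
    minutes: float = 10.0,
    partition: Sequence[tuple[Sequence[str], Sequence[str]]] = DEFAULT_PARTITION,
) -> float:
    """Implied log-HR of a `minutes` swap of `comparison` for `baseline`.

    Evaluated as the change in the ILR linear predictor when the reference
    composition (e.g. the sample mean) gains ``minutes`` of ``comparison``
    and loses the same from ``baseline``.
    """
    parts = list(fit.spec.components)
    base = pd.DataFrame([dict(reference_composition)])[parts]
    shifted = base.copy()
    shifted[comparison] += minutes
    shifted[baseline] -= minutes
    coefs = fit.model.params_
    ilr_cols = [c for c in coefs.index if c.startswith("ilr_")]
    z0 = ilr_transform(base, partition)[ilr_cols].to_numpy()[0]
    z1 = ilr_transform(shifted, partition)[ilr_cols].to_numpy()[0]
    return float((z1 - z0) @ coefs.loc[ilr_cols].to_numpy())
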
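"""Other-cause mortality and prostate-cancer survival from clinical diagnosis.

The survival clock for prostate-cancer death always starts at the
(possibly counterfactual) age of clinical diagnosis a_c, never at the age of
screen detection: screening improves survival only by freezing stage, PSA
and treatment at the earlier detection age (stage shift), so lead time is
preserved and cannot by itself create a survival benefit.  Curative
treatment (radical prostatectomy or radiotherapy) raises the baseline
survivor function to the power 0.56; per-stratum calibration hazard ratios
from the second calibration step apply as additional powers.
"""

from __future__ import annotations

import warnings

import numpy as np

from .tables import LifeTable, SurvivalTable

__all__ = [
    "sample_other_cause_death",
    "cancer_survival",
    "sample_cancer_death_age",
    "km_estimate",
    "calibrate_survival_hr",
    "survival_exponent",
]

CURATIVE = frozenset({"RP", "RT"})


def sample_other_cause_death(cohort, current_age, table: LifeTable,
                             rng: np.random.Generator):
    """Sample the age at death from other causes, conditional on being alive.

    Walks the discrete life table year by year from each man's current age;
    deaths are placed uniformly within the year.  All draws close at the
    table's final age.
    """
    from .tables import band_index

    cohort = np.asarray(cohort, dtype=float)
    current_age = np.broadcast_to(
        np.asarray(current_age, dtype=float), cohort.shape).astype(float)
    n = cohort.size
    death = np.full(n, float(table.closing_age))
    alive = np.ones(n, dtype=bool)
    ci = band_index(cohort, table.cohorts)
    frac = rng.uniform(size=n)
    for i, a in enumerate(table.ages[:-1]):
        u = rng.uniform(size=n)
        at_risk = alive & (current_age < a + 1)
        dies = at_risk & (u < table.q[i, ci])
        death[dies] = np.maximum(a + frac[dies], current_age[dies])
        alive &= ~dies
    death[alive] = table.closing_age
    return death


def survival_exponent(treatment, hr_adjustment, treatment_hr: float):
    """Combined power applied to the baseline survivor function."""
    treatment = np.asarray(treatment)
    curative = np.isin(treatment, list(CURATIVE))
    return np.where(curative, treatment_hr, 1.0) * np.asarray(hr_adjustment)


def _baseline_survival(t, cure, shape, scale):
    t = np.clip(np.asarray(t, dtype=float), 0.0, None)
    return cure + (1.0 - cure) * np.exp(-((t / scale) ** shape))


def cancer_survival(t, stratum_idx, treatment, table: SurvivalTable,
                    treatment_hr: float = 0.56):
    """Survivor probability at ``t`` years since (counterfactual) clinical dx.

    ``stratum_idx`` is the tuple from ``SurvivalTable.stratum_index`` for
    the stage/Gleason/PSA/age frozen at detection.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("time since diagnosis must be >= 0")
    cure = table.cure[stratum_idx]
    shape = table.shape[stratum_idx]
    scale = table.scale[stratum_idx]
    hr_adj = table.hr_adjustment[stratum_idx]
    base = _baseline_survival(t, cure, shape, scale)
    return base ** survival_exponent(treatment, hr_adj, treatment_hr)


def sample_cancer_death_age(a_c, stratum_idx, treatment, table: SurvivalTable,
                            rng: np.random.Generator, treatment_hr: float = 0.56,
                            uniforms=None):
    """Sample the age at prostate-cancer death (inf = never).

    Inverse transform through the powered cure-mixture Weibull: with
    U ~ Uniform(0,1) and h the combined exponent, solve S(T)^h = U.  The
    cure mass maps to "never"; so does an infinite a_c (a man whose cancer
    would never present clinically cannot die of it).  Competing other-cause
    death is resolved by the caller as the minimum.
    """
    a_c = np.asarray(a_c, dtype=float)
    u = rng.uniform(size=a_c.shape) if uniforms is None else np.asarray(uniforms)
    h = survival_exponent(treatment, table.hr_adjustment[stratum_idx], treatment_hr)
    cure = table.cure[stratum_idx]
    shape = table.shape[stratum_idx]
    scale = table.scale[stratum_idx]
    s = u ** (1.0 / h)  # required baseline survivor value
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (s - cure) / (1.0 - cure)
        t = scale * (-np.log(frac)) ** (1.0 / shape)
    never = (s <= cure) | ~np.isfinite(a_c)
    return np.where(never, np.inf, a_c + t)


def km_estimate(times, events):
    """Product-limit (Kaplan-Meier) survivor estimate with right-censoring.

    Returns (event_times, survival) at the distinct event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events])
    n = times.size
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = n - np.searchsorted(times, t, side="left")
        d = np.sum(events & (times == t))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return uniq, np.array(surv)


def km_at(times, events, horizon: float) -> float:
    """Kaplan-Meier survivor probability at a fixed horizon."""
    t, s = km_estimate(times, events)
    idx = np.searchsorted(t, horizon, side="right") - 1
    return 1.0 if idx < 0 else float(s[idx])


def calibrate_survival_hr(sim_s10, sim_s15, obs_s10, obs_s15):
    """Per-stratum calibration hazard ratio from 10/15-year survival points.

    The log hazard ratio averages log(log S_obs / log S_sim) over the two
    horizons; the returned HR is applied as a power to simulated survival so
    that S_sim^HR matches the observed points.  A stratum missing one
    horizon (NaN) falls back to the single available horizon with a warning;
    survival of exactly 0 or 1 is rejected (log-log undefined).
    """
    sim_s10 = np.asarray(sim_s10, dtype=float)
    sim_s15 = np.asarray(sim_s15, dtype=float)
    obs_s10 = np.asarray(obs_s10, dtype=float)
    obs_s15 = np.asarray(obs_s15, dtype=float)
    for arr in (sim_s10, sim_s15, obs_s10, obs_s15):
        valid = ~np.isnan(arr)
        if np.any((arr[valid] <= 0) | (arr[valid] >= 1)):
            raise ValueError("survival points must lie strictly in (0, 1)")

    def log_hr_one(sim, obs):
        return np.log(np.log(obs) / np.log(sim))

    lhr10 = log_hr_one(sim_s10, obs_s10)
    lhr15 = log_hr_one(sim_s15, obs_s15)
    missing10 = np.isnan(lhr10)
    missing15 = np.isnan(lhr15)
    if np.any(missing10 & missing15):
        raise ValueError("at least one horizon is required in every stratum")
    if np.any(missing10 | missing15):
        warnings.warn("some strata have a single survival horizon; "
                      "using the single-horizon hazard ratio")
    log_hr = np.where(missing10, lhr15,
                      np.where(missing15, lhr10, 0.5 * lhr10 + 0.5 * lhr15))
    return np.exp(log_hr)
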
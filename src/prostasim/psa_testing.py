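"""PSA test uptake, re-testing and per-policy test schedules.

Under the current (opportunistic) pattern, the age at first PSA test follows
a log-logistic cure model — age-based for cohorts born from 1960,
calendar-based (anchored at 1995) for cohorts born before 1932, and a
cohort-weighted mixture in between.  Re-testing follows a Weibull cure model
stratified by 5-year age group and the PSA value at the previous test.
Organised policies overlay fixed-interval testing at ages 55-69 from 2015 on
the population of men who would test under the current pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .natural_history import AGE_START, measured_psa
from .params import TestingParams
from .tables import RetestTable

__all__ = [
    "TestSchedule",
    "uptake_cdf_age",
    "uptake_cdf_period",
    "sample_first_test_age",
    "sample_retest_time",
    "first_test_hazard",
    "fit_uptake_params",
    "fit_retest_model",
    "build_schedule",
]

COHORT_AGE_MODEL = 1960  # cohorts born from here use the age-based uptake
COHORT_PERIOD_MODEL = 1932  # cohorts born before here use the period model
PERIOD_ANCHOR = 1995


@dataclass
class TestSchedule:
    """Ordered PSA test ages for one man with measured values and referrals."""

    ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    psa: np.ndarray = field(default_factory=lambda: np.empty(0))
    referred: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.psa = np.asarray(self.psa, dtype=float)
        self.referred = np.asarray(self.referred, dtype=bool)
        if not (self.ages.size == self.psa.size == self.referred.size):
            raise ValueError("schedule arrays must have equal length")
        if self.ages.size > 1 and np.any(np.diff(self.ages) <= 0):
            raise ValueError("test ages must be strictly increasing")

    def __len__(self):
        return self.ages.size


# ---------------------------------------------------------------------------
# Uptake cure models


def uptake_cdf_age(t, c, p: TestingParams):
    """Age-based log-logistic cure CDF for the age at first PSA test."""
    t = np.asarray(t, dtype=float)
    if np.any(t < AGE_START):
        raise ValueError("age must be >= 35")
    x = (t - AGE_START) / p.b1
    return p.pi1 * (1.0 - 1.0 / (1.0 + x**p.a1))


def uptake_cdf_period(t, c, p: TestingParams):
    """Calendar-period log-logistic cure CDF, anchored at 1995."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    start = PERIOD_ANCHOR - c  # age in 1995
    if np.any(t < start):
        raise ValueError("age must be >= age in 1995 for the period model")
    x = (t - start) / p.b2
    return p.pi2 * (1.0 - 1.0 / (1.0 + x**p.a2))


def _loglogistic_quantile(u, pi, a, b):
    """Invert u = pi * (1 - 1/(1 + x^a)); never-testers (u >= pi) -> inf."""
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = u / pi
        x = (frac / (1.0 - frac)) ** (1.0 / a)
    return np.where(u < pi, b * x, np.inf)


def sample_first_test_age(c, p: TestingParams, rng: np.random.Generator):
    """Sample the age at first PSA test (inf = never) for each birth cohort.

    The intermediate cohorts (1932 <= c < 1960) select the age-based draw
    with probability (1960 - c)/28 as printed; set
    ``p.cohort_mixture_reversed`` to use the complementary weight.
    """
    c = np.asarray(c, dtype=float)
    u1 = rng.uniform(size=c.shape)
    u2 = rng.uniform(size=c.shape)
    usel = rng.uniform(size=c.shape)
    t1 = AGE_START + _loglogistic_quantile(u1, p.pi1, p.a1, p.b1)
    t2 = (PERIOD_ANCHOR - c) + _loglogistic_quantile(u2, p.pi2, p.a2, p.b2)
    w = np.clip((COHORT_AGE_MODEL - c) / (COHORT_AGE_MODEL - COHORT_PERIOD_MODEL),
                0.0, 1.0)
    if p.cohort_mixture_reversed:
        w = 1.0 - w
    pick_age_model = np.where(
        c >= COHORT_AGE_MODEL, True,
        np.where(c < COHORT_PERIOD_MODEL, False, usel < w),
    )
    return np.where(pick_age_model, t1, t2)


def sample_retest_time(t0, y0, p: TestingParams, rng: np.random.Generator):
    """Sample the age at the next PSA test after a test at age t0 with value y0.

    With probability 1 - pi3 of the (age group, PSA band) stratum the man
    never re-tests (inf); otherwise the gap is Weibull(a3, b3).
    """
    t0 = np.asarray(t0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    pi3, a3, b3 = p.retest_table.stratum(t0, y0)
    u = rng.uniform(size=t0.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = b3 * (-np.log1p(-np.minimum(u / pi3, 1.0))) ** (1.0 / a3)
    return np.where(u < pi3, t0 + gap, np.inf)


# ---------------------------------------------------------------------------
# Fitting


def _mixture_cdf_pdf(t, c, p: TestingParams):
    """First-test CDF and density of the cohort mixture, vectorised."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    w = np.clip((COHORT_AGE_MODEL - c) / (COHORT_AGE_MODEL - COHORT_PERIOD_MODEL),
                0.0, 1.0)
    if p.cohort_mixture_reversed:
        w = np.where((c >= COHORT_PERIOD_MODEL) & (c < COHORT_AGE_MODEL), 1.0 - w, w)

    def ll_cdf_pdf(t, start, pi, a, b):
        x = np.clip(t - start, 0.0, None) / b
        cdf = pi * (1.0 - 1.0 / (1.0 + x**a))
        with np.errstate(divide="ignore", invalid="ignore"):
            pdf = np.where(
                x > 0, pi * (a / b) * x ** (a - 1.0) / (1.0 + x**a) ** 2, 0.0)
        return cdf, pdf

    cdf1, pdf1 = ll_cdf_pdf(t, AGE_START, p.pi1, p.a1, p.b1)
    cdf2, pdf2 = ll_cdf_pdf(t, PERIOD_ANCHOR - c, p.pi2, p.a2, p.b2)
    return w * cdf1 + (1 - w) * cdf2, w * pdf1 + (1 - w) * pdf2


def first_test_hazard(t, c, p: TestingParams):
    """Modelled first-test rate (hazard) at age t for cohort c."""
    cdf, pdf = _mixture_cdf_pdf(t, c, p)
    return pdf / np.clip(1.0 - cdf, 1e-12, None)


def fit_uptake_params(rate_surface: pd.DataFrame,
                      init: TestingParams | None = None) -> dict:
    """Fit the uptake parameters to an observed first-test rate surface.

    ``rate_surface`` must have columns (age, year, tests, person_years) where
    ``tests`` counts first PSA tests and ``person_years`` is exposure among
    men without a prior test.  Maximises the Poisson likelihood of the
    modelled first-test hazard and returns the fitted parameters together
    with convergence diagnostics.
    """
    df = rate_surface
    if np.any(df["person_years"] <= 0):
        raise ValueError("rate surface must have positive exposure")
    age = df["age"].to_numpy(dtype=float) + 0.5  # mid-year evaluation
    cohort = df["year"].to_numpy(dtype=float) - df["age"].to_numpy(dtype=float)
    tests = df["tests"].to_numpy(dtype=float)
    py = df["person_years"].to_numpy(dtype=float)

    from .params import default_params

    base = init if init is not None else default_params().testing

    def unpack(x):
        pi1, pi2 = 1 / (1 + np.exp(-x[0])), 1 / (1 + np.exp(-x[1]))
        a1, b1, a2, b2 = np.exp(x[2:6])
        p = TestingParams(pi1=pi1, a1=a1, b1=b1, pi2=pi2, a2=a2, b2=b2,
                          retest_table=base.retest_table,
                          cohort_mixture_reversed=base.cohort_mixture_reversed)
        return p

    def nll(x):
        p = unpack(x)
        lam = np.clip(first_test_hazard(age, cohort, p), 1e-12, None) * py
        return float(np.sum(lam - tests * np.log(lam)))

    x0 = np.array([
        np.log(base.pi1 / (1 - base.pi1 + 1e-12)),
        np.log(base.pi2 / (1 - base.pi2 + 1e-12)),
        np.log(base.a1), np.log(base.b1), np.log(base.a2), np.log(base.b2),
    ])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    fitted = unpack(res.x)
    out = {
        "pi1": fitted.pi1, "a1": fitted.a1, "b1": fitted.b1,
        "pi2": fitted.pi2, "a2": fitted.a2, "b2": fitted.b2,
        "converged": bool(res.success), "nll": float(res.fun),
        "n_iter": int(res.nit),
    }
    if not res.success:
        warnings.warn(f"uptake fit did not converge: {res.message}")
    return out


def _fit_weibull_cure(gap: np.ndarray, event: np.ndarray):
    """Censored maximum likelihood for one (pi3, a3, b3) stratum."""
    gap = np.asarray(gap, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not np.any(event):
        return {"pi3": 0.0, "a3": 1.0, "b3": 1.0, "converged": True}

    mean_gap = float(np.mean(gap[event]))

    def nll(x):
        pi3 = 1 / (1 + np.exp(-x[0]))
        a3, b3 = np.exp(x[1]), np.exp(x[2])
        z = (gap / b3) ** a3
        logf = np.log(a3 / b3) + (a3 - 1) * np.log(np.clip(gap / b3, 1e-300, None)) - z
        ll_event = np.log(pi3) + logf
        surv = pi3 * np.exp(-z)
        ll_cens = np.log(np.clip(1.0 - pi3 + surv, 1e-300, None))
        return -float(np.sum(np.where(event, ll_event, ll_cens)))

    x0 = np.array([np.log(np.mean(event) / max(1 - np.mean(event), 1e-6)),
                   0.0, np.log(max(mean_gap, 1e-3))])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
    pi3 = 1 / (1 + np.exp(-res.x[0]))
    return {"pi3": float(pi3), "a3": float(np.exp(res.x[1])),
            "b3": float(np.exp(res.x[2])), "converged": bool(res.success)}


def fit_retest_model(records: pd.DataFrame, age_edges=None,
                     psa_edges=None) -> RetestTable:
    """Fit the stratified Weibull cure re-test model.

    ``records`` needs columns (t0, y0, gap, event): age and PSA at the index
    test, the observed or censored gap to the next test, and the event
    indicator.  Empty strata fall back to the fit pooled over all records
    (flagged with a warning).
    """
    if age_edges is None:
        age_edges = np.arange(30.0, 95.0, 5.0)
    if psa_edges is None:
        psa_edges = np.array([0.0, 1.0, 3.0, 10.0])
    age_edges = np.asarray(age_edges, dtype=float)
    psa_edges = np.asarray(psa_edges, dtype=float)

    from .tables import band_index

    ai = band_index(records["t0"].to_numpy(dtype=float), age_edges)
    pi = band_index(records["y0"].to_numpy(dtype=float), psa_edges)
    gap = records["gap"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)

    pooled = _fit_weibull_cure(gap, event)
    shape = (age_edges.size, psa_edges.size)
    pi3 = np.full(shape, pooled["pi3"])
    a3 = np.full(shape, pooled["a3"])
    b3 = np.full(shape, pooled["b3"])
    empty = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            mask = (ai == i) & (pi == j)
            if np.sum(event[mask]) < 1:
                empty.append((age_edges[i], psa_edges[j]))
                continue
            fit = _fit_weibull_cure(gap[mask], event[mask])
            pi3[i, j], a3[i, j], b3[i, j] = fit["pi3"], fit["a3"], fit["b3"]
    if empty:
        warnings.warn(
            f"{len(empty)} empty re-test strata fell back to the pooled fit")
    return RetestTable(age_edges, psa_edges,
                       np.clip(pi3, 0.0, 1.0),
                       np.clip(a3, 1e-6, None),
                       np.clip(b3, 1e-6, None))


# ---------------------------------------------------------------------------
# Schedules


POLICIES = ("current", "organised2", "organised8", "none", "erspc")

ORGANISED_START_YEAR = 2015
ORGANISED_AGE_LO = 55.0
ORGANISED_AGE_HI = 69.0


def _current_test_ages(profile, cohort, p: TestingParams, phi_noise,
                       first_test, rng, horizon_age, stop_year=None):
    """Recursive first-test / re-test draws for one man."""
    ages, psas, refs = [], [], []
    t = float(first_test)
    while np.isfinite(t) and t < horizon_age:
        if stop_year is not None and cohort + t >= stop_year:
            break
        y = float(measured_psa(profile, t, phi_noise, rng))
        ages.append(t)
        psas.append(y)
        refs.append(y >= p.threshold_psa)
        t = float(sample_retest_time(np.array([t]), np.array([y]), p, rng)[0])
    return ages, psas, refs


def build_schedule(policy: str, profile, cohort: float, testing: TestingParams,
                   phi_noise: float, first_test: float,
                   rng: np.random.Generator, horizon_age: float = 90.0,
                   interval: float | None = None) -> TestSchedule:
    """Build the PSA test schedule for one man under a testing policy.

    ``first_test`` is the man's age at first test under current testing
    (inf = never); organised policies only screen men with a finite
    ``first_test`` (participation preferences are assumed unchanged).
    Truncation by diagnosis or death happens at life-history assembly.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")

    def organised_ages(interval_years):
        if not np.isfinite(first_test):
            return []
        start_age = max(ORGANISED_AGE_LO, ORGANISED_START_YEAR - cohort)
        ages = np.arange(ORGANISED_AGE_LO, ORGANISED_AGE_HI + 1e-9, interval_years)
        return list(ages[ages >= start_age - 1e-9])

    if policy == "current":
        ages, psas, refs = _current_test_ages(
            profile, cohort, testing, phi_noise, first_test, rng, horizon_age)
    elif policy == "none":
        ages, psas, refs = _current_test_ages(
            profile, cohort, testing, phi_noise, first_test, rng, horizon_age,
            stop_year=ORGANISED_START_YEAR)
    elif policy in ("organised2", "organised8", "erspc"):
        if policy == "erspc":
            plan = list(np.arange(ORGANISED_AGE_LO, ORGANISED_AGE_HI + 1e-9, 4.0))
        else:
            interval_years = interval or (2.0 if policy == "organised2" else 8.0)
            if cohort < COHORT_AGE_MODEL:
                # cohorts not yet covered by the rollout keep current testing
                return build_schedule("current", profile, cohort, testing,
                                      phi_noise, first_test, rng, horizon_age)
            plan = organised_ages(interval_years)
        ages, psas, refs = [], [], []
        for t in plan:
            if t >= horizon_age:
                break
            y = float(measured_psa(profile, t, phi_noise, rng))
            ages.append(float(t))
            psas.append(y)
            refs.append(y >= testing.threshold_psa)
    return TestSchedule(np.array(ages), np.array(psas), np.array(refs, dtype=bool))
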
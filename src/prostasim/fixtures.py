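"""Synthetic inputs with known ground truth for every pipeline stage.

Every fixture is a pure function of its arguments (and an integer seed), so
the whole pipeline — calibration targets, trial emulation, scenario
predictions — runs end-to-end without any external data.  The packaged
default tables (life table, biopsy compliance, treatment assignment,
re-testing, survival baselines) are generated here: they are synthetic
stand-ins shaped like their registry-derived counterparts, not estimates
from person-level records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ComplianceTable, LifeTable, RetestTable, SurvivalTable, TreatmentTable

__all__ = [
    "FixtureSpec",
    "make_lifetable",
    "make_compliance_table",
    "make_treatment_table",
    "make_retest_table",
    "make_survival_table",
    "make_test_rate_surface",
    "make_retest_records",
    "make_survival_points",
    "make_staging_targets",
]


@dataclass
class FixtureSpec:
    """Everything needed to regenerate the full synthetic input bundle."""

    seed: int = 0
    n_population: int = 100_000
    theta_star: tuple = (0.064, 0.19, 9.7e-4, 1.5e-3, 0.53)
    staging_total: int = 4392
    lifetable_kwargs: dict = field(default_factory=dict)
    survival_kwargs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Static tables


def make_lifetable(q0: float = 2.3e-5, growth: float = 0.095,
                   cohort_trend: float = 0.004, age_lo: int = 35,
                   closing_age: int = 105,
                   cohorts=None) -> LifeTable:
    """Gompertz other-cause mortality by age with a mild cohort improvement.

    Annual death probability q(age, cohort) = q0 * exp(growth * age) *
    exp(-cohort_trend * (cohort - 1950)), capped at 1, closing at
    ``closing_age``.  The defaults mimic male all-cause mortality in a
    contemporary high-income population (q ~ 0.007 at 60, ~ 0.05 at 80).
    """
    if cohorts is None:
        cohorts = np.arange(1880.0, 2000.0, 20.0)
    ages = np.arange(age_lo, closing_age + 1)
    q = np.minimum(
        1.0,
        q0
        * np.exp(growth * ages)[:, None]
        * np.exp(-cohort_trend * (np.asarray(cohorts) - 1950.0))[None, :],
    )
    q[-1, :] = 1.0
    return LifeTable(ages, cohorts, q)


def make_compliance_table() -> ComplianceTable:
    """Biopsy compliance after a positive PSA test, by age x PSA band.

    Compliance falls with age and rises with PSA, echoing the pattern of an
    opportunistically tested population where it sits well below trial
    levels.
    """
    age_edges = np.array([35.0, 60.0, 70.0, 80.0])
    psa_edges = np.array([3.0, 10.0])
    prob = np.array([
        [0.72, 0.88],
        [0.66, 0.85],
        [0.50, 0.75],
        [0.30, 0.55],
    ])
    return ComplianceTable(age_edges, psa_edges, prob)


def make_treatment_table() -> TreatmentTable:
    """Treatment assignment (AS, RP, RT, ADT) by age band x Gleason band.

    Younger men with low-grade disease mostly enter active surveillance or
    surgery; high-grade and elderly men shift towards radiotherapy and
    androgen deprivation.
    """
    age_edges = np.array([35.0, 55.0, 65.0, 75.0, 85.0])
    prob = np.array([
        # G6-                    G7                      G8+
        [[0.55, 0.35, 0.07, 0.03], [0.15, 0.55, 0.25, 0.05], [0.03, 0.45, 0.42, 0.10]],
        [[0.50, 0.32, 0.13, 0.05], [0.12, 0.48, 0.32, 0.08], [0.03, 0.35, 0.47, 0.15]],
        [[0.45, 0.15, 0.28, 0.12], [0.12, 0.20, 0.48, 0.20], [0.04, 0.12, 0.52, 0.32]],
        [[0.50, 0.02, 0.18, 0.30], [0.20, 0.03, 0.32, 0.45], [0.06, 0.02, 0.30, 0.62]],
        [[0.45, 0.00, 0.05, 0.50], [0.20, 0.00, 0.10, 0.70], [0.08, 0.00, 0.07, 0.85]],
    ])
    return TreatmentTable(age_edges, prob)


def make_retest_table() -> RetestTable:
    """Weibull cure re-testing parameters by 5-year age group x PSA band.

    Higher previous PSA values shorten the re-test interval and raise the
    probability of ever re-testing; the youngest and oldest groups re-test
    least.
    """
    age_edges = np.arange(30.0, 95.0, 5.0)
    psa_edges = np.array([0.0, 1.0, 3.0, 10.0])
    pi_psa = np.array([0.74, 0.84, 0.90, 0.92])
    b3_psa = np.array([2.9, 2.1, 1.2, 0.7])
    age_mult = np.array(
        [0.70, 0.85, 0.95, 1.0, 1.0, 1.0, 1.0, 1.0, 0.95, 0.85, 0.70, 0.55, 0.45])
    pi3 = np.clip(age_mult[:, None] * pi_psa[None, :], 0.0, 1.0)
    a3 = np.full((age_edges.size, psa_edges.size), 1.3)
    b3 = np.broadcast_to(b3_psa[None, :], pi3.shape).copy()
    return RetestTable(age_edges, psa_edges, pi3, a3, b3)


def make_survival_table(g_cure=(0.82, 0.60, 0.28), g_scale=(16.0, 13.0, 8.0),
                        met_scale=(8.0, 6.5, 5.0), shape_nonmet: float = 1.1,
                        shape_met: float = 1.25, psa_cure_mult: float = 0.78,
                        psa_scale_mult: float = 0.72,
                        age_scale_mult: float = 0.92) -> SurvivalTable:
    """Cure-mixture Weibull survival baselines per diagnostic stratum.

    Prognosis worsens monotonically with Gleason band, with PSA >= 10 ng/mL,
    with metastatic disease and (mildly) with age at diagnosis.  These are
    synthetic parametric curves shaped to plausible cancer-specific survival
    (e.g. most Gleason <=6 non-metastatic men never die of their cancer;
    metastatic median survival a few years).
    """
    age_edges = np.array([35.0, 45.0, 55.0, 65.0, 75.0, 85.0])
    n_age = age_edges.size
    cure = np.zeros((2, 3, 2, n_age))
    shape = np.zeros_like(cure)
    scale = np.zeros_like(cure)
    for g in range(3):
        for p in range(2):
            for a in range(n_age):
                age_mult = age_scale_mult ** max(a - 2, 0)
                cure_nm = g_cure[g] * (psa_cure_mult if p else 1.0)
                cure_nm *= 1.0 - 0.05 * max(a - 2, 0)
                cure[0, g, p, a] = max(cure_nm, 0.0)
                shape[0, g, p, a] = shape_nonmet
                scale[0, g, p, a] = g_scale[g] * (psa_scale_mult if p else 1.0) * age_mult
                cure[1, g, p, a] = 0.0
                shape[1, g, p, a] = shape_met
                scale[1, g, p, a] = met_scale[g] * (0.85 if p else 1.0) * age_mult
    return SurvivalTable(age_edges, cure, shape, scale)


# ---------------------------------------------------------------------------
# Testing-rate fixtures


def make_test_rate_surface(truth, exposure: float = 2000.0,
                           ages=None, years=None, seed: int = 0) -> pd.DataFrame:
    """First-test rate surface (age x calendar year) with Poisson noise.

    ``truth`` is a ``TestingParams``; ``exposure`` is person-years of
    test-naive follow-up per (age, year) cell.  The returned frame carries
    the first-test counts used by ``fit_uptake_params`` plus a modelled
    total testing rate (first tests plus a renewal approximation to
    re-testing) for display.
    """
    from scipy.special import gamma as gamma_fn

    from .psa_testing import _mixture_cdf_pdf, first_test_hazard

    if ages is None:
        ages = np.arange(40, 81)
    if years is None:
        years = np.arange(1995, 2015)
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        for age in ages:
            cohort = float(year - age)
            h = float(first_test_hazard(age + 0.5, cohort, truth))
            tests = rng.poisson(h * exposure)
            cdf, _ = _mixture_cdf_pdf(age + 0.5, cohort, truth)
            pi3, a3, b3 = truth.retest_table.stratum(
                np.array([min(age, 90.0)]), np.array([1.5]))
            mean_gap = float(b3[0] * gamma_fn(1.0 + 1.0 / a3[0]) / max(pi3[0], 1e-9))
            total_rate = h * (1.0 - float(cdf)) + float(cdf) / mean_gap
            rows.append({
                "age": int(age), "year": int(year), "tests": int(tests),
                "person_years": float(exposure), "total_rate": float(total_rate),
            })
    return pd.DataFrame(rows)


def make_retest_records(pi3: float, a3: float, b3: float, n: int,
                        censor_time: float = 5.0, t0_range=(50.0, 70.0),
                        y0: float = 1.5, seed: int = 0) -> pd.DataFrame:
    """Simulated (t0, y0, gap, event) records from one known re-test stratum."""
    rng = np.random.default_rng(seed)
    t0 = rng.uniform(*t0_range, size=n)
    ever = rng.uniform(size=n) < pi3
    gap = b3 * rng.weibull(a3, size=n)
    event = ever & (gap <= censor_time)
    gap_obs = np.where(event, gap, censor_time)
    return pd.DataFrame({
        "t0": t0, "y0": np.full(n, y0), "gap": gap_obs, "event": event})


# ---------------------------------------------------------------------------
# Survival and staging fixtures


def make_survival_points(survival_table: SurvivalTable, hr_perturb: float = 1.0,
                         cohort_size: int | None = None,
                         treatment: str = "AS", seed: int = 0) -> pd.DataFrame:
    """Observed 10/15-year survival points from the packaged curves.

    Evaluates each stratum's survivor function at 10 and 15 years, raises it
    to ``hr_perturb`` (a known calibration target), and optionally adds
    binomial sampling noise for a stated cohort size per stratum.
    """
    from .survival import cancer_survival

    rng = np.random.default_rng(seed)
    rows = []
    for m in range(2):
        for g in range(3):
            for p in range(2):
                for a, age_lo in enumerate(survival_table.age_edges):
                    idx = (m, g, p, a)
                    s10 = float(cancer_survival(10.0, idx, treatment,
                                                survival_table) ** hr_perturb)
                    s15 = float(cancer_survival(15.0, idx, treatment,
                                                survival_table) ** hr_perturb)
                    if cohort_size:
                        s10 = rng.binomial(cohort_size, s10) / cohort_size
                        s15 = rng.binomial(cohort_size, s15) / cohort_size
                    rows.append({
                        "metastatic": m, "gleason": g, "psa_ge10": p,
                        "age_lo": float(age_lo), "s10": s10, "s15": s15,
                    })
    return pd.DataFrame(rows)


def make_staging_targets(theta_star, n: int, params=None, seed: int = 0,
                         total: int = 4392):
    """Calibration targets generated from the model at a known theta.

    Simulates diagnoses under current testing at ``theta_star``,
    cross-tabulates them into the age x staging-class grid, rescales the
    counts to ``total`` diagnoses by multinomial resampling, and attaches
    the sojourn-mean and screening incidence-rate-ratio targets.
    """
    from .calibration import CalibrationTargets, staging_classes
    from .params import default_params
    from .scenarios import simulate_staging_diagnoses

    if params is None:
        params = default_params()
    params = params.with_theta(theta_star)
    rng = np.random.default_rng(seed)
    records = simulate_staging_diagnoses(params, n, rng)
    counts = staging_classes(records)
    flat = counts.to_numpy().ravel().astype(float)
    if flat.sum() == 0:
        raise ValueError("no simulated diagnoses; increase n")
    resampled = rng.multinomial(total, flat / flat.sum()).reshape(counts.shape)
    counts_df = pd.DataFrame(resampled, index=counts.index, columns=counts.columns)
    return CalibrationTargets(staging_counts=counts_df)
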
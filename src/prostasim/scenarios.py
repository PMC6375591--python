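"""Life-history assembly, screening-trial emulation and policy predictions.

The engine overlays PSA testing, biopsy detection, treatment and survival on
the latent natural histories, fully vectorised over men.  Common random
numbers pair policies and trial arms: the same person index always carries
the same latent history, other-cause death age, first-test propensity and
outcome (treatment/survival) uniforms, so differences between scenarios are
driven by the policy alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import psa_testing
from .detection import STAGE_MET, assign_treatment, biopsy_detectable, stage_at
from .natural_history import log_median_psa, simulate_history_batch
from .params import ModelParams
from .psa_testing import (
    ORGANISED_AGE_HI,
    ORGANISED_AGE_LO,
    ORGANISED_START_YEAR,
    sample_first_test_age,
    sample_retest_time,
)
from .survival import sample_cancer_death_age, sample_other_cause_death

__all__ = [
    "LifeHistoryBatch",
    "ScenarioResult",
    "simulate_cohort",
    "simulate_population",
    "simulate_staging_diagnoses",
    "emulate_erspc",
    "poisson_rr",
    "flag_overdiagnosis",
    "rate_ratio_series",
    "life_years_gained",
    "age_standardised_rates",
]

MODE_NONE, MODE_CLINICAL, MODE_SCREEN = 0, 1, 2


@dataclass
class LifeHistoryBatch:
    """Vectorised life histories under one policy."""

    cohort: np.ndarray
    t_onset: np.ndarray
    gleason: np.ndarray
    t_t3: np.ndarray
    t_met: np.ndarray
    a_c: np.ndarray  # latent (possibly counterfactual) clinical dx age
    other_death_age: np.ndarray
    dx_age: np.ndarray  # inf if never diagnosed
    dx_mode: np.ndarray  # 0 none / 1 clinical / 2 screen
    stage_at_dx: np.ndarray
    psa_at_dx: np.ndarray
    treatment: np.ndarray
    cancer_death_age: np.ndarray  # inf if never
    death_age: np.ndarray
    overdiagnosed: np.ndarray
    policy: str = "current"

    def __len__(self):
        return self.cohort.size


@dataclass
class ScenarioResult:
    """Event counts and person-time by age x calendar year x batch."""

    ages: np.ndarray  # integer attained ages (1-year groups)
    years: np.ndarray  # calendar years (a single bucket for trial output)
    person_years: np.ndarray  # shape (n_ages, n_years, n_batches)
    at_risk_years: np.ndarray  # person-time free of diagnosis
    diagnoses: np.ndarray
    overdiagnoses: np.ndarray
    cancer_deaths: np.ndarray
    deaths: np.ndarray
    n_persons: int = 0
    policy: str = ""

    def totals(self, name: str) -> np.ndarray:
        """Per-batch totals of one outcome."""
        return getattr(self, name).sum(axis=(0, 1))

    def by_age(self, name: str) -> np.ndarray:
        return getattr(self, name).sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# Policy engines (vectorised)


def _screen_via_current_testing(params, batch, cohort, other_death, rng,
                                horizon_age=90.0, stop_year=None,
                                suppress_organised_window=False,
                                first_test=None):
    """Opportunistic testing loop; returns (screen_dx_age, psa_at_dx,
    first_test_age).  ``stop_year`` ends asymptomatic testing at a calendar
    year; ``suppress_organised_window`` removes opportunistic tests that
    fall inside the organised rollout window (they are replaced by the
    organised schedule)."""
    n = len(batch)
    testing = params.testing
    phi = params.psa_growth.phi_noise
    prof = (batch.b0, batch.b1, batch.b_onset, batch.t_onset)
    if first_test is None:
        first_test = sample_first_test_age(cohort, testing, rng)
    screen_dx = np.full(n, np.inf)
    screen_psa = np.full(n, np.nan)
    next_test = first_test.copy()
    for _ in range(200):
        u_dx = rng.uniform(size=n)
        noise = rng.normal(0.0, 1.0, size=n)
        u_retest = rng.uniform(size=n)
        t = next_test
        active = (
            np.isfinite(t)
            & (t < horizon_age)
            & (t < batch.t_clinical_dx)
            & (t < other_death)
            & ~np.isfinite(screen_dx)
        )
        if stop_year is not None:
            active &= cohort + t < stop_year
        if not np.any(active):
            break
        y = np.where(active, np.exp(log_median_psa(prof, np.where(active, t, 35.0))
                                    + phi * noise), np.nan)
        in_window = (
            (cohort >= psa_testing.COHORT_AGE_MODEL)
            & (t >= ORGANISED_AGE_LO) & (t <= ORGANISED_AGE_HI)
            & (cohort + t >= ORGANISED_START_YEAR)
        ) if suppress_organised_window else np.zeros(n, dtype=bool)
        testable = active & ~in_window
        referred = testable & (y >= testing.threshold_psa)
        cancer = referred & (t > batch.t_onset)
        detectable = cancer & biopsy_detectable(
            batch.t_onset, batch.t_t3, t, params.progression.phi_lag)
        comp = np.zeros(n)
        if np.any(referred):
            comp[referred] = params.compliance_table.probability(
                t[referred], y[referred])
        dx = detectable & (u_dx < comp)
        screen_dx[dx] = t[dx]
        screen_psa[dx] = y[dx]
        # next test for everyone still active and undiagnosed
        cont = active & ~dx
        nxt = np.full(n, np.inf)
        if np.any(cont):
            # suppressed tests still advance the clock through the window
            t_eff = np.where(cont, t, 60.0)
            y_eff = np.where(cont & ~np.isnan(y), y, 1.0)
            gaps = sample_retest_time(
                np.clip(t_eff, 30.0, 94.0), y_eff, testing,
                _FixedUniformRng(u_retest))
            nxt[cont] = gaps[cont]
        next_test = nxt
    return screen_dx, screen_psa, first_test


class _FixedUniformRng:
    """Adapter feeding pre-drawn uniforms to samplers (keeps draws aligned
    across policies for common random numbers)."""

    def __init__(self, u):
        self._u = u

    def uniform(self, size=None):
        return self._u


def _screen_via_fixed_schedule(params, batch, other_death, test_ages, rng,
                               compliance=None, follow_up_end=None):
    """Fixed test schedule (one row of ages per man); inf entries skipped."""
    n = len(batch)
    phi = params.psa_growth.phi_noise
    prof = (batch.b0, batch.b1, batch.b_onset, batch.t_onset)
    screen_dx = np.full(n, np.inf)
    screen_psa = np.full(n, np.nan)
    for k in range(test_ages.shape[1]):
        t = test_ages[:, k]
        noise = rng.normal(0.0, 1.0, size=n)
        u_dx = rng.uniform(size=n)
        active = (
            np.isfinite(t)
            & (t < batch.t_clinical_dx)
            & (t < other_death)
            & ~np.isfinite(screen_dx)
        )
        if follow_up_end is not None:
            active &= t < follow_up_end
        if not np.any(active):
            continue
        y = np.where(active,
                     np.exp(log_median_psa(prof, np.where(active, t, 35.0))
                            + phi * noise), np.nan)
        referred = active & (y >= params.testing.threshold_psa)
        cancer = referred & (t > batch.t_onset)
        detectable = cancer & biopsy_detectable(
            batch.t_onset, batch.t_t3, t, params.progression.phi_lag)
        if compliance is None:
            comp = np.zeros(n)
            if np.any(referred):
                comp[referred] = params.compliance_table.probability(
                    t[referred], y[referred])
        else:
            comp = np.full(n, compliance)
        dx = detectable & (u_dx < comp)
        screen_dx[dx] = t[dx]
        screen_psa[dx] = y[dx]
    return screen_dx, screen_psa


def _organised_schedule(cohort, first_test, interval):
    """Planned organised test ages (n, k) for participating men."""
    n = cohort.size
    n_tests = int(np.floor((ORGANISED_AGE_HI - ORGANISED_AGE_LO) / interval)) + 1
    ages = ORGANISED_AGE_LO + interval * np.arange(n_tests)
    plan = np.tile(ages, (n, 1))
    start_age = np.maximum(ORGANISED_AGE_LO, ORGANISED_START_YEAR - cohort)
    participating = (np.isfinite(first_test)
                     & (cohort >= psa_testing.COHORT_AGE_MODEL))
    plan[~participating] = np.inf
    plan[plan < start_age[:, None] - 1e-9] = np.inf
    return plan


# ---------------------------------------------------------------------------
# Life-history assembly


def _assemble(params, cohort, batch, other_death, screen_dx, screen_psa,
              rng_outcome, policy="", outcome_draws=None):
    """Combine latent history, screening and survival into LifeHistoryBatch.

    ``outcome_draws`` = (u_tx, u_surv, noise_cd) lets paired arms share the
    treatment/survival randomness (common random numbers).
    """
    n = len(batch)
    if outcome_draws is None:
        outcome_draws = draw_outcome_block(rng_outcome, n)
    u_tx, u_surv, noise_cd = outcome_draws

    a_c = batch.t_clinical_dx
    clinical_first = np.minimum(a_c, other_death) < screen_dx
    screen_detected = np.isfinite(screen_dx) & ~clinical_first
    clinically_dx = (a_c < other_death) & ~screen_detected
    diagnosed = screen_detected | clinically_dx

    dx_age = np.where(screen_detected, screen_dx,
                      np.where(clinically_dx, a_c, np.inf))
    dx_mode = np.where(screen_detected, MODE_SCREEN,
                       np.where(clinically_dx, MODE_CLINICAL, MODE_NONE))

    # stage, PSA and treatment frozen at the detection age
    prof = (batch.b0, batch.b1, batch.b_onset, batch.t_onset)
    safe_dx = np.where(diagnosed, dx_age, batch.t_onset + 1.0)
    stage = stage_at(batch.t_onset, batch.t_t3, batch.t_met, safe_dx)
    stage[~diagnosed] = -1
    psa_dx = np.where(
        screen_detected, screen_psa,
        np.exp(log_median_psa(prof, safe_dx)
               + params.psa_growth.phi_noise * noise_cd))
    psa_dx[~diagnosed] = np.nan
    treatment = np.full(n, "", dtype=object)
    if np.any(diagnosed):
        treatment[diagnosed] = assign_treatment(
            safe_dx[diagnosed], batch.gleason[diagnosed],
            params.treatment_table, None, uniforms=u_tx[diagnosed])

    # survival clock starts at a_c with the stratum frozen at detection
    table = params.survival.baseline
    cancer_death = np.full(n, np.inf)
    if np.any(diagnosed):
        age_for_stratum = np.clip(a_c[diagnosed], 35.0, 104.0)
        idx = table.stratum_index(
            stage[diagnosed] == STAGE_MET, batch.gleason[diagnosed],
            psa_dx[diagnosed], age_for_stratum)
        cancer_death[diagnosed] = sample_cancer_death_age(
            a_c[diagnosed], idx, treatment[diagnosed], table, None,
            treatment_hr=params.survival.treatment_hr,
            uniforms=u_surv[diagnosed])
    cancer_death = np.where(cancer_death < other_death, cancer_death, np.inf)
    death_age = np.minimum(other_death, np.where(np.isfinite(cancer_death),
                                                 cancer_death, np.inf))
    overdx = screen_detected & (a_c > other_death)
    return LifeHistoryBatch(
        cohort=cohort, t_onset=batch.t_onset, gleason=batch.gleason,
        t_t3=batch.t_t3, t_met=batch.t_met, a_c=a_c,
        other_death_age=other_death, dx_age=dx_age, dx_mode=dx_mode,
        stage_at_dx=stage, psa_at_dx=psa_dx, treatment=treatment,
        cancer_death_age=cancer_death, death_age=death_age,
        overdiagnosed=overdx, policy=policy,
    )


def _streams(seed, n_streams=5):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_streams)]


def simulate_cohort(params: ModelParams, cohort, policy: str, seed: int,
                    horizon_age: float = 90.0) -> LifeHistoryBatch:
    """Simulate full life histories for given birth cohorts under a policy.

    Latent histories, other-cause deaths and outcome uniforms come from
    policy-independent streams, so calling this with two policies and the
    same seed yields paired populations (common random numbers).
    """
    cohort = np.asarray(cohort, dtype=float)
    n = cohort.size
    rng_latent, rng_death, rng_outcome, rng_uptake, rng_policy = _streams(seed)
    batch = simulate_history_batch(params, rng_latent, n)
    other_death = sample_other_cause_death(cohort, 35.0, params.life_table,
                                           rng_death)
    first_test = sample_first_test_age(cohort, params.testing, rng_uptake)

    if policy == "current":
        screen_dx, screen_psa, _ = _screen_via_current_testing(
            params, batch, cohort, other_death, rng_policy,
            horizon_age=horizon_age, first_test=first_test)
    elif policy == "none":
        screen_dx, screen_psa, _ = _screen_via_current_testing(
            params, batch, cohort, other_death, rng_policy,
            horizon_age=horizon_age, stop_year=ORGANISED_START_YEAR,
            first_test=first_test)
    elif policy in ("organised2", "organised8"):
        interval = 2.0 if policy == "organised2" else 8.0
        dx1, psa1, _ = _screen_via_current_testing(
            params, batch, cohort, other_death, rng_policy,
            horizon_age=horizon_age, suppress_organised_window=True,
            first_test=first_test)
        plan = _organised_schedule(cohort, first_test, interval)
        dx2, psa2 = _screen_via_fixed_schedule(
            params, batch, other_death, plan, rng_policy)
        screen_dx = np.minimum(dx1, dx2)
        screen_psa = np.where(dx1 <= dx2, psa1, psa2)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return _assemble(params, cohort, batch, other_death, screen_dx, screen_psa,
                     rng_outcome, policy=policy)


# ---------------------------------------------------------------------------
# Aggregation


def _person_time_grid(start_age, end_age, cohort, ages, years, batch_ids,
                      n_batches):
    """Split person-time into (age, year, batch) cells (closed population)."""
    grid = np.zeros((ages.size, years.size, n_batches))
    year0 = years[0]
    for i, a in enumerate(ages):
        overlap = np.clip(np.minimum(end_age, a + 1.0) - np.maximum(start_age, a),
                          0.0, None)
        yr = (cohort + a).astype(int) - year0
        ok = (yr >= 0) & (yr < years.size) & (overlap > 0)
        np.add.at(grid, (i, yr[ok], batch_ids[ok]), overlap[ok])
    return grid


def _event_grid(event_age, mask, cohort, ages, years, batch_ids, n_batches):
    grid = np.zeros((ages.size, years.size, n_batches))
    ok = mask & np.isfinite(event_age)
    a = np.floor(event_age[ok]).astype(int) - ages[0]
    yr = (cohort[ok] + np.floor(event_age[ok])).astype(int) - years[0]
    inside = (a >= 0) & (a < ages.size) & (yr >= 0) & (yr < years.size)
    np.add.at(grid, (a[inside], yr[inside], batch_ids[ok][inside]), 1.0)
    return grid


def aggregate(lh: LifeHistoryBatch, years, ages=None,
              n_batches: int = 50) -> ScenarioResult:
    """Aggregate life histories into a ScenarioResult over calendar years."""
    years = np.asarray(years, dtype=int)
    if ages is None:
        ages = np.arange(35, 106)
    ages = np.asarray(ages, dtype=int)
    n = len(lh)
    batch_ids = (np.arange(n) * n_batches) // max(n, 1)
    start = np.full(n, 35.0)
    py = _person_time_grid(start, lh.death_age, lh.cohort, ages, years,
                           batch_ids, n_batches)
    at_risk_end = np.minimum(lh.death_age, lh.dx_age)
    at_risk = _person_time_grid(start, at_risk_end, lh.cohort, ages, years,
                                batch_ids, n_batches)
    dx = _event_grid(lh.dx_age, lh.dx_mode > MODE_NONE, lh.cohort, ages, years,
                     batch_ids, n_batches)
    odx = _event_grid(lh.dx_age, lh.overdiagnosed, lh.cohort, ages, years,
                      batch_ids, n_batches)
    cdeath = _event_grid(lh.cancer_death_age, np.isfinite(lh.cancer_death_age),
                         lh.cohort, ages, years, batch_ids, n_batches)
    death = _event_grid(lh.death_age, np.isfinite(lh.death_age), lh.cohort,
                        ages, years, batch_ids, n_batches)
    return ScenarioResult(ages=ages, years=years, person_years=py,
                          at_risk_years=at_risk, diagnoses=dx,
                          overdiagnoses=odx, cancer_deaths=cdeath,
                          deaths=death, n_persons=n, policy=lh.policy)


def simulate_population(params: ModelParams, policy: str, n: int, seed: int,
                        population: dict | None = None,
                        n_batches: int = 50) -> ScenarioResult:
    """Simulate a closed multi-cohort population under one policy.

    The default population spec draws integer birth cohorts uniformly from
    1935-1980 (a stationary synthetic age structure) and aggregates events
    over calendar years 2015-2034.  Common random numbers: the same
    ``seed`` pairs policies person by person.
    """
    spec = {"cohort_lo": 1935, "cohort_hi": 1980,
            "year_lo": 2015, "year_hi": 2034}
    if population:
        spec.update(population)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    cohort = rng.integers(spec["cohort_lo"], spec["cohort_hi"] + 1,
                          size=n).astype(float)
    lh = simulate_cohort(params, cohort, policy, seed)
    years = np.arange(spec["year_lo"], spec["year_hi"] + 1)
    return aggregate(lh, years, n_batches=n_batches)


def simulate_staging_diagnoses(params: ModelParams, n: int,
                               rng: np.random.Generator,
                               year_lo: int = 2011, year_hi: int = 2013,
                               age_lo: float = 50.0,
                               age_hi: float = 75.0) -> pd.DataFrame:
    """Diagnoses under current testing within a calendar window and age range.

    Used for the staging calibration target: returns one row per diagnosis
    with dx age, stage, Gleason band and mode.
    """
    seed = int(rng.integers(2**31 - 1))
    cohort = np.random.default_rng(seed + 1).integers(
        year_lo - int(age_hi) - 2, year_hi - int(age_lo) + 1, size=n).astype(float)
    lh = simulate_cohort(params, cohort, "current", seed,
                         horizon_age=age_hi + 1.0)
    year_dx = lh.cohort + lh.dx_age
    keep = (
        (lh.dx_mode > MODE_NONE)
        & (lh.dx_age >= age_lo) & (lh.dx_age < age_hi)
        & (year_dx >= year_lo) & (year_dx < year_hi + 1)
    )
    return pd.DataFrame({
        "dx_age": lh.dx_age[keep],
        "stage": lh.stage_at_dx[keep],
        "gleason": lh.gleason[keep],
        "mode": np.where(lh.dx_mode[keep] == MODE_SCREEN, "screen", "clinical"),
    })


# ---------------------------------------------------------------------------
# ERSPC trial emulation


def emulate_erspc(params: ModelParams, n_per_arm: int, seed: int,
                  compliance: float = 0.856, follow_up: float = 13.0,
                  interval: float = 4.0, n_batches: int = 50):
    """Emulate a two-arm screening trial with paired (CRN) arms.

    Flat entry ages uniform on 55-69; eligibility requires being alive and
    undiagnosed at entry; the control arm is unscreened while the screening
    arm gets PSA tests every ``interval`` years from entry while aged <= 69
    (threshold from the registry, flat biopsy compliance).  Returns
    (control, screening) ScenarioResults aggregated by attained age over the
    follow-up window.
    """
    rng_latent, rng_death, rng_outcome, rng_entry, rng_policy = _streams(seed)
    n = n_per_arm
    batch = simulate_history_batch(params, rng_latent, n)
    entry = rng_entry.uniform(55.0, 69.0, size=n)
    cohort = np.zeros(n)  # flat population: cohort only shifts the life table
    other_death = sample_other_cause_death(
        np.full(n, 1940.0), 35.0, params.life_table, rng_death)
    eligible = (other_death > entry) & (batch.t_clinical_dx > entry)

    # screening-arm schedule: entry + k * interval while age <= 69
    max_tests = int(np.floor((ORGANISED_AGE_HI - 55.0) / interval)) + 1
    plan = entry[:, None] + interval * np.arange(max_tests)[None, :]
    plan[plan > ORGANISED_AGE_HI + 1e-9] = np.inf
    plan[~eligible] = np.inf
    screen_dx, screen_psa = _screen_via_fixed_schedule(
        params, batch, other_death, plan, rng_policy, compliance=compliance,
        follow_up_end=entry + follow_up)

    no_screen = np.full(n, np.inf)
    draws = draw_outcome_block(rng_outcome, n)
    control = _assemble(params, cohort, batch, other_death, no_screen,
                        np.full(n, np.nan), None, policy="erspc-control",
                        outcome_draws=draws)
    screening = _assemble(params, cohort, batch, other_death, screen_dx,
                          screen_psa, None, policy="erspc-screening",
                          outcome_draws=draws)

    results = []
    for lh in (control, screening):
        results.append(_aggregate_trial(lh, entry, eligible, follow_up,
                                        n_batches, lh.policy))
    return tuple(results)


def draw_outcome_block(rng, n):
    """Treatment uniform, survival uniform and clinical-PSA noise per man."""
    return rng.uniform(size=n), rng.uniform(size=n), rng.normal(0.0, 1.0, size=n)


def _aggregate_trial(lh: LifeHistoryBatch, entry, eligible, follow_up,
                     n_batches, policy) -> ScenarioResult:
    """Aggregate a trial arm by attained 1-year age over follow-up."""
    ages = np.arange(55, int(70 + follow_up) + 1)
    years = np.array([0])
    n = len(lh)
    batch_ids = (np.arange(n) * n_batches) // max(n, 1)
    end_fu = entry + follow_up
    m = eligible

    def grid_pt(end_age):
        g = np.zeros((ages.size, 1, n_batches))
        for i, a in enumerate(ages):
            overlap = np.clip(
                np.minimum(end_age, np.minimum(end_fu, a + 1.0))
                - np.maximum(entry, a), 0.0, None)
            overlap[~m] = 0.0
            np.add.at(g, (i, 0, batch_ids), overlap)
        return g

    def grid_ev(age_ev, mask):
        g = np.zeros((ages.size, 1, n_batches))
        ok = m & mask & np.isfinite(age_ev) & (age_ev >= entry) & (age_ev < end_fu)
        a = np.floor(age_ev[ok]).astype(int) - ages[0]
        inside = (a >= 0) & (a < ages.size)
        np.add.at(g, (a[inside], 0, batch_ids[ok][inside]), 1.0)
        return g

    py = grid_pt(lh.death_age)
    at_risk = grid_pt(np.minimum(lh.death_age, lh.dx_age))
    dx = grid_ev(lh.dx_age, lh.dx_mode > MODE_NONE)
    odx = grid_ev(lh.dx_age, lh.overdiagnosed)
    cdeath = grid_ev(lh.cancer_death_age, np.isfinite(lh.cancer_death_age))
    death = grid_ev(lh.death_age, np.isfinite(lh.death_age))
    return ScenarioResult(ages=ages, years=years, person_years=py,
                          at_risk_years=at_risk, diagnoses=dx,
                          overdiagnoses=odx, cancer_deaths=cdeath,
                          deaths=death, n_persons=int(np.sum(m)), policy=policy)


# ---------------------------------------------------------------------------
# Estimators


def poisson_rr(events_a, pyears_a, events_b, pyears_b):
    """Maximum-likelihood rate ratio (arm a vs arm b) from stratified counts.

    Fits the Poisson model rate = mu_s * rho^{arm} by profile likelihood:
    for fixed rho the stratum rates have closed-form MLEs, and the score for
    log rho is solved by bisection.  Returns (rr, se_log_rr).  Strata with
    no person-time are dropped; all-zero events raise.
    """
    d1 = np.asarray(events_a, dtype=float).ravel()
    t1 = np.asarray(pyears_a, dtype=float).ravel()
    d0 = np.asarray(events_b, dtype=float).ravel()
    t0 = np.asarray(pyears_b, dtype=float).ravel()
    keep = (t0 > 0) | (t1 > 0)
    d1, t1, d0, t0 = d1[keep], t1[keep], d0[keep], t0[keep]
    if d0.sum() + d1.sum() == 0:
        raise ValueError("no events in either arm; rate ratio undefined")
    if d0.sum() == 0 or d1.sum() == 0:
        raise ValueError("zero events in one arm; rate ratio degenerate")

    def score(log_rho):
        rho = np.exp(log_rho)
        mu = (d0 + d1) / (t0 + rho * t1)
        return d1.sum() - rho * np.sum(t1 * mu)

    lo, hi = -10.0, 10.0
    log_rho = brentq(score, lo, hi, xtol=1e-12)
    rho = np.exp(log_rho)
    # observed information for log rho from the profile likelihood
    eps = 1e-5

    def profile_ll(lr):
        r = np.exp(lr)
        mu = (d0 + d1) / (t0 + r * t1)
        lam0, lam1 = mu * t0, r * mu * t1
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(d0 > 0, d0 * np.log(lam0), 0.0) - lam0
            ll = ll + np.where(d1 > 0, d1 * np.log(lam1), 0.0) - lam1
        return np.sum(ll)

    info = -(profile_ll(log_rho + eps) - 2 * profile_ll(log_rho)
             + profile_ll(log_rho - eps)) / eps**2
    se = float(1.0 / np.sqrt(max(info, 1e-12)))
    return float(rho), se


def trial_rate_ratio(arm_a: ScenarioResult, arm_b: ScenarioResult,
                     outcome: str = "diagnoses"):
    """Poisson rate ratio (a vs b) by 1-year age strata for a trial pair.

    Incidence uses diagnosis-free person-time; mortality uses all
    person-time.
    """
    pt = "at_risk_years" if outcome == "diagnoses" else "person_years"
    return poisson_rr(
        arm_a.by_age(outcome), arm_a.by_age(pt),
        arm_b.by_age(outcome), arm_b.by_age(pt),
    )


def flag_overdiagnosis(lh: LifeHistoryBatch) -> np.ndarray:
    """True where a screen-detected cancer would never have presented
    clinically before death from another cause."""
    return ((lh.dx_mode == MODE_SCREEN)
            & (lh.a_c > lh.other_death_age))


def rate_ratio_series(scenario: ScenarioResult, reference: ScenarioResult,
                      outcomes=("diagnoses", "overdiagnoses", "cancer_deaths")):
    """Cumulative rate ratios over the window with Monte-Carlo intervals.

    Per-batch RRs supply the 2.5/97.5 percentile interval; the point
    estimate uses the pooled counts and person-years.
    """
    if not np.array_equal(scenario.years, reference.years):
        raise ValueError("scenario and reference cover different windows")
    out = {}
    for name in outcomes:
        ev_s = scenario.totals(name)
        ev_r = reference.totals(name)
        py_s = scenario.totals("person_years")
        py_r = reference.totals("person_years")
        if ev_r.sum() == 0:
            raise ValueError(f"reference has no {name}; rate ratio undefined")
        rr = (ev_s.sum() / py_s.sum()) / (ev_r.sum() / py_r.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rr_b = (ev_s / py_s) / (ev_r / py_r)
        rr_b = rr_b[np.isfinite(rr_b)]
        lo, hi = (np.percentile(rr_b, [2.5, 97.5]) if rr_b.size
                  else (np.nan, np.nan))
        out[name] = {"rr": float(rr), "mci_lo": float(lo), "mci_hi": float(hi)}
    return out


def life_years_gained(scenario: ScenarioResult, reference: ScenarioResult,
                      per: float = 1000.0) -> dict:
    """Life-years gained per ``per`` persons within the window, with MCI."""
    if scenario.n_persons != reference.n_persons:
        raise ValueError("scenario and reference need a common population")
    ly_s = scenario.totals("person_years")
    ly_r = reference.totals("person_years")
    n = scenario.n_persons
    gain = (ly_s.sum() - ly_r.sum()) / n * per
    per_batch = (ly_s - ly_r) / (n / ly_s.size) * per
    lo, hi = np.percentile(per_batch, [2.5, 97.5])
    return {"life_years_gained": float(gain), "mci_lo": float(lo),
            "mci_hi": float(hi)}


def age_standardised_rates(result: ScenarioResult, weights: dict,
                           outcome: str = "diagnoses") -> pd.DataFrame:
    """Directly age-standardised rate series by calendar year.

    ``weights`` maps integer age to a standard-population weight (must sum
    to 1); every weighted age must have person-time in every year.
    """
    w_ages = np.array(sorted(weights))
    w = np.array([weights[a] for a in w_ages])
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("standard weights must sum to 1")
    idx = np.searchsorted(result.ages, w_ages)
    if np.any(idx >= result.ages.size) or np.any(result.ages[idx] != w_ages):
        raise ValueError("standard population ages missing from result")
    ev = getattr(result, outcome).sum(axis=2)[idx]
    py = result.person_years.sum(axis=2)[idx]
    if np.any(py == 0):
        raise ValueError("no person-time at a standardised age")
    rates = (w[:, None] * ev / py).sum(axis=0)
    return pd.DataFrame({"year": result.years, "rate": rates})
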
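"""Latent disease course: onset, Gleason grade, PSA growth and progression.

Disease onset from age 35 follows a Weibull (shape 2) hazard.  At onset a
Gleason band is drawn from a multinomial logistic model in age and is fixed
thereafter.  Log median PSA is piecewise linear in age with a steeper slope
after onset, and every progression hazard (T1-T2 -> T3-T4, T3-T4 ->
metastasis, and clinical presentation) is proportional to the noise-free
median PSA, lambda(t) = gamma * y(t).  Because y(t) is log-linear on each
segment, cumulative hazards have closed forms and event times are sampled by
exact inverse transform; a thinning sampler is kept in the test suite as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .params import ModelParams, OnsetGleasonParams, PsaGrowthParams

__all__ = [
    "PsaProfile",
    "DiseaseHistory",
    "DiseaseHistoryBatch",
    "sample_onset_age",
    "gleason_probs",
    "sample_gleason",
    "sample_truncated_normal",
    "sample_psa_profile",
    "log_median_psa",
    "median_psa",
    "measured_psa",
    "sample_hazard_event_time",
    "simulate_disease_history",
    "simulate_history_batch",
]

AGE_START = 35.0


@dataclass
class PsaProfile:
    """Realised PSA random effects for one man."""

    b0: float
    b1: float
    b_onset: float
    onset_age: float
    gleason: int  # 0 = Gleason <=6, 1 = Gleason 7, 2 = Gleason >=8

    def __post_init__(self):
        if self.b1 < 0 or self.b_onset < 0:
            raise ValueError("PSA slopes must be non-negative")
        if self.onset_age < AGE_START:
            raise ValueError("onset_age must be >= 35")


@dataclass
class DiseaseHistory:
    """One man's latent disease course (ages in years, +inf = never)."""

    profile: PsaProfile
    t_onset: float
    t_t3: float
    t_met: float
    t_clinical_dx: float


@dataclass
class DiseaseHistoryBatch:
    """Vectorised latent histories for a cohort of men.

    All arrays share one index; ``t_clinical_dx`` is +inf when clinical
    presentation is disabled or sampled beyond any horizon of interest.
    """

    t_onset: np.ndarray
    gleason: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    b_onset: np.ndarray
    t_t3: np.ndarray
    t_met: np.ndarray
    t_clinical_dx: np.ndarray

    def __len__(self):
        return self.t_onset.size

    def __getitem__(self, i: int) -> DiseaseHistory:
        prof = PsaProfile(
            b0=float(self.b0[i]),
            b1=float(self.b1[i]),
            b_onset=float(self.b_onset[i]),
            onset_age=float(self.t_onset[i]),
            gleason=int(self.gleason[i]),
        )
        return DiseaseHistory(
            profile=prof,
            t_onset=float(self.t_onset[i]),
            t_t3=float(self.t_t3[i]),
            t_met=float(self.t_met[i]),
            t_clinical_dx=float(self.t_clinical_dx[i]),
        )


# ---------------------------------------------------------------------------
# Onset and Gleason


def onset_cdf(t, gamma_o: float):
    """R_o(t) = 1 - exp(-gamma_o/2 * (t - 35)^2) for t >= 35."""
    t = np.asarray(t, dtype=float)
    return 1.0 - np.exp(-0.5 * gamma_o * np.clip(t - AGE_START, 0.0, None) ** 2)


def sample_onset_age(gamma_o: float, rng: np.random.Generator, size=None):
    """Sample age at cancer onset (Weibull shape 2 from age 35).

    Every draw is finite; onsets beyond the lifespan are truncated later by
    death from other causes, not here.
    """
    if gamma_o <= 0:
        raise ValueError("gamma_o must be > 0")
    e = rng.exponential(size=size)
    return AGE_START + np.sqrt(2.0 * e / gamma_o)


def gleason_probs(t, p: OnsetGleasonParams):
    """Multinomial logistic probabilities (G<=6, G7, G>=8) at onset age t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < AGE_START):
        raise ValueError("onset age must be >= 35")
    u = t - AGE_START
    e7 = np.exp(p.alpha7 + p.beta7 * u)
    e8 = np.exp(p.alpha8 + p.beta8 * u)
    denom = 1.0 + e7 + e8
    return np.stack([1.0 / denom, e7 / denom, e8 / denom], axis=-1)


def sample_gleason(t, p: OnsetGleasonParams, rng: np.random.Generator):
    """Draw a Gleason band (0, 1, 2) at each onset age."""
    probs = gleason_probs(t, p)
    u = rng.uniform(size=np.shape(np.asarray(t)))
    cum = np.cumsum(probs, axis=-1)
    return np.sum(u[..., None] > cum[..., :2], axis=-1).astype(np.int8)


# ---------------------------------------------------------------------------
# PSA random effects and trajectories


def sample_truncated_normal(mu, sigma, rng: np.random.Generator, size=None):
    """Sample N(mu, sigma^2) truncated to [0, inf) by inverse transform.

    The degenerate sigma = 0 limit returns max(mu, 0).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if size is None:
        size = np.broadcast_shapes(mu.shape, sigma.shape)
    if np.all(sigma == 0):
        return np.broadcast_to(np.clip(mu, 0.0, None), size).copy()
    u = rng.uniform(size=size)
    p0 = ndtr(-mu / np.where(sigma > 0, sigma, 1.0))  # mass below zero
    x = mu + sigma * ndtri(p0 + u * (1.0 - p0))
    x = np.where(sigma > 0, x, np.clip(mu, 0.0, None))
    return np.clip(x, 0.0, None)  # guard against roundoff at the boundary


def sample_psa_profile(onset_age, gleason, p: PsaGrowthParams,
                       rng: np.random.Generator):
    """Draw (b0, b1, b_onset) for each man.

    b0 is Gaussian; the pre-onset slope b1 and the Gleason-specific post-onset
    slope increment are zero-truncated normals, keeping log PSA non-decreasing.
    Returns three arrays aligned with ``onset_age``.
    """
    onset_age = np.asarray(onset_age, dtype=float)
    if np.any(onset_age < AGE_START):
        raise ValueError("onset_age must be >= 35")
    gleason = np.asarray(gleason, dtype=int)
    n = onset_age.shape
    b0 = rng.normal(p.mu0, p.sigma0, size=n)
    b1 = sample_truncated_normal(np.full(n, p.mu1), np.full(n, p.sigma1), rng)
    mu_k = p.post_onset_mu()[gleason]
    sd_k = p.post_onset_sigma()[gleason]
    b_onset = sample_truncated_normal(mu_k, sd_k, rng)
    return b0, b1, b_onset


def _profile_arrays(profile):
    if isinstance(profile, PsaProfile):
        return (np.asarray(profile.b0), np.asarray(profile.b1),
                np.asarray(profile.b_onset), np.asarray(profile.onset_age))
    return profile  # already a tuple of arrays


def log_median_psa(profile, t):
    """log of noise-free median PSA at age t."""
    b0, b1, b_onset, t_onset = _profile_arrays(profile)
    t = np.asarray(t, dtype=float)
    return b0 + b1 * (t - AGE_START) + b_onset * np.clip(t - t_onset, 0.0, None)


def median_psa(profile, t):
    """Noise-free median PSA (ng/mL) at age t; non-decreasing in t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < AGE_START):
        raise ValueError("age must be >= 35")
    return np.exp(log_median_psa(profile, t))


def measured_psa(profile, t, phi_noise: float, rng: np.random.Generator):
    """Median PSA times an independent log-normal measurement error."""
    base = median_psa(profile, t)
    if phi_noise == 0:
        return base
    return base * np.exp(rng.normal(0.0, phi_noise, size=np.shape(base)))


# ---------------------------------------------------------------------------
# Event-time sampling for PSA-proportional hazards


def _invert_cum_hazard(e, gamma, log_y_start, slope, start):
    """Solve Lambda(start, t) = e for hazard gamma * exp(log_y_start
    + slope * (t - start)); exact in the slope -> 0 limit."""
    y0 = np.exp(log_y_start)
    with np.errstate(divide="ignore", invalid="ignore"):
        dt = np.where(
            slope > 0,
            np.log1p(np.asarray(slope) * e / (gamma * y0)) / np.where(slope > 0, slope, 1.0),
            e / (gamma * y0),
        )
    return start + dt


def sample_hazard_event_time(gamma, profile, start, rng: np.random.Generator,
                             exp_draw=None):
    """Sample the event time for hazard lambda(t) = gamma * y(t) from ``start``.

    ``start`` must be at or after onset, so the active segment of log y is
    linear with slope b1 + b_onset.  ``exp_draw`` lets callers reuse unit
    exponential draws for common-random-number schemes.
    """
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("gamma must be > 0")
    b0, b1, b_onset, t_onset = _profile_arrays(profile)
    start = np.asarray(start, dtype=float)
    if np.any(start < t_onset):
        raise ValueError("start must be >= onset age for post-onset hazards")
    e = rng.exponential(size=start.shape) if exp_draw is None else exp_draw
    slope = b1 + b_onset
    logy0 = log_median_psa((b0, b1, b_onset, t_onset), start)
    return _invert_cum_hazard(e, gamma, logy0, slope, start)


def _clinical_dx_times(batch: DiseaseHistoryBatch, params: ModelParams,
                       e: np.ndarray) -> np.ndarray:
    """Clinical presentation times with a stage-dependent hazard.

    The localised rate gamma_lc applies throughout T1-T2 and T3-T4 (the
    Gleason <=6 and 7 bands share the pooled <=7 rate); after metastasis the
    rate switches to gamma_mc.  The unit exponential draws ``e`` are inverted
    through the piecewise cumulative hazard.
    """
    pr = params.progression
    g8 = batch.gleason == 2
    g_lc = np.where(g8, pr.gamma_lc_g8plus, pr.gamma_lc_g7minus)
    g_mc = np.where(g8, pr.gamma_mc_g8plus, pr.gamma_mc_g7minus)
    slope = batch.b1 + batch.b_onset
    prof = (batch.b0, batch.b1, batch.b_onset, batch.t_onset)
    logy_on = log_median_psa(prof, batch.t_onset)
    logy_met = log_median_psa(prof, batch.t_met)
    # cumulative localised hazard accrued from onset to metastasis
    with np.errstate(over="ignore"):
        lam_met = np.where(
            slope > 0,
            g_lc / slope * (np.exp(logy_met) - np.exp(logy_on)),
            g_lc * np.exp(logy_on) * (batch.t_met - batch.t_onset),
        )
    before_met = e < lam_met
    t_local = _invert_cum_hazard(e, g_lc, logy_on, slope, batch.t_onset)
    t_after = _invert_cum_hazard(
        np.clip(e - lam_met, 0.0, None), g_mc, logy_met, slope, batch.t_met)
    return np.where(before_met, t_local, t_after)


def simulate_history_batch(params: ModelParams, rng: np.random.Generator,
                           n: int, clinical_dx: bool = True) -> DiseaseHistoryBatch:
    """Simulate n latent disease histories.

    Onset, Gleason and PSA random effects are drawn first; T-stage
    progression and metastasis times follow by inverse transform of their
    PSA-proportional hazards; clinical presentation runs on the same clock
    with a stage-dependent hazard (suppressed when ``clinical_dx`` is False).
    Progression is simulated without censoring — death and diagnosis truncate
    histories downstream.
    """
    og = params.onset_gleason
    pr = params.progression
    t_onset = sample_onset_age(og.gamma_o, rng, size=n)
    gleason = sample_gleason(t_onset, og, rng)
    b0, b1, b_onset = sample_psa_profile(t_onset, gleason, params.psa_growth, rng)
    prof = (b0, b1, b_onset, t_onset)
    t_t3 = sample_hazard_event_time(pr.gamma_t, prof, t_onset, rng)
    t_met = sample_hazard_event_time(pr.gamma_m, prof, t_t3, rng)
    e_cd = rng.exponential(size=n)
    batch = DiseaseHistoryBatch(
        t_onset=t_onset, gleason=gleason, b0=b0, b1=b1, b_onset=b_onset,
        t_t3=t_t3, t_met=t_met, t_clinical_dx=np.full(n, np.inf),
    )
    if clinical_dx:
        batch.t_clinical_dx = _clinical_dx_times(batch, params, e_cd)
    return batch


def simulate_disease_history(params: ModelParams,
                             rng: np.random.Generator) -> DiseaseHistory:
    """Single-person convenience wrapper around ``simulate_history_batch``."""
    return simulate_history_batch(params, rng, 1)[0]
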
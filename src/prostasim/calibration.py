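"""Simulation-likelihood calibration of the natural-history parameters.

Step 1 estimates theta = (beta7, beta8, gamma_t, gamma_m, phi_lag) by
minimising a penalised simulation likelihood with three targets: the
multinomial likelihood of the age x staging distribution of incident
cancers, a quadratic penalty keeping the mean time from onset to metastasis
at its reference value, and a quadratic penalty on the log screening
incidence rate ratio from the emulated trial.  Nelder-Mead drives the
search (the objective is a noisy simulation output evaluated with common
random numbers, so it is deterministic given theta and the seed but not
smooth); standard errors come from a finite-difference Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .natural_history import simulate_history_batch
from .params import ModelParams, THETA_NAMES

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "AGE_GROUP_EDGES",
    "STAGING_CLASSES",
    "staging_classes",
    "staging_loglik",
    "sojourn_penalty",
    "irr_penalty",
    "sojourn_means",
    "combined_objective",
    "calibrate",
]

AGE_GROUP_EDGES = np.array([50, 55, 60, 65, 70])
AGE_GROUP_LABELS = ("50-54", "55-59", "60-64", "65-69", "70-74")

# six loco-regional Gleason x T-stage combinations plus metastatic
STAGING_CLASSES = (
    "T1-T2:G6-", "T1-T2:G7", "T1-T2:G8+",
    "T3-T4:G6-", "T3-T4:G7", "T3-T4:G8+",
    "metastatic",
)

MEAN_SOJOURN_TARGET = 25.9  # years, onset -> metastasis, reference model
IRR_TARGET = 1.57  # screening incidence rate ratio target


@dataclass
class CalibrationTargets:
    """Targets and weights for the step-1 penalised likelihood."""

    staging_counts: pd.DataFrame  # index age groups, columns STAGING_CLASSES
    mean_sojourn_target: float = MEAN_SOJOURN_TARGET
    irr_target: float = IRR_TARGET
    w2: float = 1.0
    w3: float = 1.0e4

    def __post_init__(self):
        if np.any(self.staging_counts.to_numpy() < 0):
            raise ValueError("staging counts must be non-negative")
        if self.mean_sojourn_target <= 0 or self.irr_target <= 0:
            raise ValueError("targets must be positive")

    @property
    def totals(self) -> np.ndarray:
        return self.staging_counts.to_numpy().sum(axis=1)


@dataclass
class CalibrationResult:
    theta_hat: np.ndarray
    standard_errors: np.ndarray
    objective_trace: list = field(default_factory=list)
    hessian: np.ndarray | None = None
    converged: bool = False
    n_evaluations: int = 0

    def as_dict(self) -> dict:
        return {
            "theta_hat": dict(zip(THETA_NAMES, map(float, self.theta_hat))),
            "standard_errors": dict(zip(THETA_NAMES,
                                        map(float, self.standard_errors))),
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
        }


# ---------------------------------------------------------------------------
# Target components


def staging_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate diagnosis records into age groups x staging classes.

    Loco-regional cancers split by Gleason band and T-stage; metastatic
    cancers form a single class regardless of Gleason.
    """
    from .detection import STAGE_MET

    age_idx = np.clip(
        np.searchsorted(AGE_GROUP_EDGES, records["dx_age"].to_numpy(),
                        side="right") - 1, 0, len(AGE_GROUP_LABELS) - 1)
    stage = records["stage"].to_numpy()
    gleason = records["gleason"].to_numpy()
    cls = np.where(stage == STAGE_MET, 6, stage * 3 + gleason)
    counts = np.zeros((len(AGE_GROUP_LABELS), len(STAGING_CLASSES)))
    np.add.at(counts, (age_idx, cls), 1.0)
    return pd.DataFrame(counts, index=list(AGE_GROUP_LABELS),
                        columns=list(STAGING_CLASSES))


def staging_loglik(y: np.ndarray, p_sim: np.ndarray,
                   m_sim: np.ndarray) -> float:
    """Multinomial log-likelihood of observed staging counts.

    ``y`` (age groups x classes) are observed counts, ``p_sim`` the
    simulated proportions and ``m_sim`` the simulated total count per age
    group.  Empty simulated cells receive the half-cell correction
    max(p, 0.5/m).
    """
    y = np.asarray(y, dtype=float)
    p_sim = np.asarray(p_sim, dtype=float)
    m_sim = np.asarray(m_sim, dtype=float)
    if y.shape != p_sim.shape:
        raise ValueError("count and proportion tables must share a shape")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n_i = y.sum(axis=1)
    floor = 0.5 / np.clip(m_sim, 1.0, None)
    p = np.maximum(p_sim, floor[:, None])
    return float(np.sum(gammaln(n_i + 1.0))
                 + np.sum(y * np.log(p) - gammaln(y + 1.0)))


def sojourn_penalty(mean_t12: float, mean_t34: float,
                    target: float = MEAN_SOJOURN_TARGET) -> float:
    """Quadratic penalty on the mean onset-to-metastasis time."""
    if mean_t12 < 0 or mean_t34 < 0:
        raise ValueError("sojourn means must be non-negative")
    return float((mean_t12 + mean_t34 - target) ** 2)


def irr_penalty(irr_sim: float, target: float = IRR_TARGET) -> float:
    """Quadratic penalty on the log screening incidence rate ratio."""
    if irr_sim <= 0:
        raise ValueError("simulated IRR must be positive")
    return float((np.log(target) - np.log(irr_sim)) ** 2)


def sojourn_means(params: ModelParams, n: int, seed: int):
    """Uncensored mean T1-T2 and T3-T4 sojourns (clinical diagnosis off).

    Every simulated history is followed to metastasis regardless of age, so
    these are the unconditional transition-time expectations entering the
    sojourn constraint.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    batch = simulate_history_batch(params, rng, n, clinical_dx=False)
    return (float(np.mean(batch.t_t3 - batch.t_onset)),
            float(np.mean(batch.t_met - batch.t_t3)))


# ---------------------------------------------------------------------------
# Combined objective and optimisation


def _staging_proportions(params, n, seed):
    from .scenarios import simulate_staging_diagnoses

    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    records = simulate_staging_diagnoses(params, n, rng)
    counts = staging_classes(records).to_numpy()
    m_i = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p_ij = np.where(m_i[:, None] > 0, counts / np.clip(m_i[:, None], 1, None),
                        0.0)
    return p_ij, m_i


def _erspc_irr(params, n_per_arm, seed):
    from .scenarios import emulate_erspc, trial_rate_ratio

    control, screening = emulate_erspc(params, n_per_arm, seed)
    rr, _ = trial_rate_ratio(screening, control, outcome="diagnoses")
    return rr


DEFAULT_SIM_SIZES = {"staging": 100_000, "sojourn": 50_000, "erspc": 50_000}


def combined_objective(theta, targets: CalibrationTargets,
                       params: ModelParams, sim_sizes: dict | None = None,
                       seed: int = 0) -> float:
    """Penalised negative simulation log-likelihood at theta.

    Runs three simulations (staging distribution under current testing,
    uncensored sojourns, emulated screening trial) with seeds derived from
    ``seed`` only, so repeated calls at the same theta return the same value
    (common random numbers across theta evaluations).
    """
    sizes = dict(DEFAULT_SIM_SIZES)
    if sim_sizes:
        sizes.update(sim_sizes)
    p = params.with_theta(theta)
    p_ij, m_i = _staging_proportions(p, sizes["staging"], seed)
    l1 = staging_loglik(targets.staging_counts.to_numpy(), p_ij, m_i)
    m12, m34 = sojourn_means(p, sizes["sojourn"], seed)
    l2 = sojourn_penalty(m12, m34, targets.mean_sojourn_target)
    irr = _erspc_irr(p, sizes["erspc"], seed)
    l3 = irr_penalty(irr, targets.irr_target)
    return float(-l1 + targets.w2 * l2 + targets.w3 * l3)


def _to_unconstrained(theta):
    b7, b8, gt, gm, lag = theta
    return np.array([np.log(b7), np.log(b8), np.log(gt), np.log(gm),
                     np.log(lag / (1.0 - lag))])


def _from_unconstrained(x):
    return np.array([np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), np.exp(x[3]),
                     1.0 / (1.0 + np.exp(-x[4]))])


def finite_difference_hessian(fun, x, rel_step: float = 0.01) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate relative steps.

    The simulation likelihood is noisy at machine scale, so the step is a
    deliberately large fraction of each parameter.
    """
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.abs(x)
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                val = (fun(x + ei + ej) - fun(x + ei - ej)
                       - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def calibrate(targets: CalibrationTargets, params: ModelParams,
              theta_init=None, sim_sizes: dict | None = None, seed: int = 0,
              maxiter: int = 200, compute_se: bool = True,
              objective=None) -> CalibrationResult:
    """Step-1 calibration by Nelder-Mead on the penalised likelihood.

    ``objective`` can replace the simulation objective (e.g. an analytic
    test function); it receives theta on the natural scale.  The search runs
    in a transformed space (log hazards, logit phi_lag) to respect bounds.
    Standard errors are sqrt(diag(H^-1)) of the natural-scale objective with
    relative finite-difference step 0.01.
    """
    if theta_init is None:
        theta_init = params.get_theta()
    theta_init = np.asarray(theta_init, dtype=float)

    if objective is None:
        def objective(th):
            return combined_objective(th, targets, params, sim_sizes, seed)

    trace = []

    def wrapped(x):
        th = _from_unconstrained(x)
        val = objective(th)
        trace.append((th.copy(), val))
        return val

    x0 = _to_unconstrained(theta_init)
    # a wide initial simplex (about +-25% per parameter on the natural
    # scale) keeps Nelder-Mead from collapsing in simulation noise
    simplex = np.vstack([x0] + [x0 + 0.25 * e for e in np.eye(x0.size)])
    res = minimize(wrapped, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-3,
                            "adaptive": True, "initial_simplex": simplex})
    theta_hat = _from_unconstrained(res.x)

    hess = None
    ses = np.full(theta_hat.size, np.nan)
    if compute_se:
        hess = finite_difference_hessian(objective, theta_hat, rel_step=0.01)
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            ses = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            pass
    return CalibrationResult(
        theta_hat=theta_hat, standard_errors=ses, objective_trace=trace,
        hessian=hess, converged=bool(res.success), n_evaluations=len(trace),
    )


# ---------------------------------------------------------------------------
# Step 2: survival calibration


def calibrate_survival(params: ModelParams, observed_points: pd.DataFrame,
                       n: int = 200_000, seed: int = 0) -> ModelParams:
    """Step-2 survival calibration: set per-stratum hazard-ratio adjustments.

    Simulates a current-testing population at the (fixed) step-1 theta,
    forms Kaplan-Meier cancer-specific survival from clinical diagnosis per
    stratum, and matches the observed 10/15-year points by the log-log
    hazard-ratio rule.  Strata without simulated events keep adjustment 1.
    Returns a copy of ``params`` with ``survival.baseline.hr_adjustment``
    updated.
    """
    from .scenarios import MODE_NONE, simulate_cohort
    from .survival import calibrate_survival_hr, km_at

    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))
    cohort = rng.integers(1930, 1970, size=n).astype(float)
    lh = simulate_cohort(params, cohort, "current", int(rng.integers(2**31 - 1)))
    dx = lh.dx_mode > MODE_NONE
    table = params.survival.baseline
    # time from (counterfactual) clinical diagnosis to cancer death,
    # censored by other-cause death
    t_death = np.where(np.isfinite(lh.cancer_death_age), lh.cancer_death_age,
                       lh.other_death_age)
    time = np.clip(t_death - lh.a_c, 0.0, None)
    event = np.isfinite(lh.cancer_death_age)
    idx = table.stratum_index(
        np.where(dx, lh.stage_at_dx, 0) == 2, lh.gleason,
        np.where(dx, lh.psa_at_dx, 1.0), np.clip(lh.a_c, 35.0, 104.0))

    out = params.copy()
    new_hr = out.survival.baseline.hr_adjustment
    obs = observed_points.set_index(["metastatic", "gleason", "psa_ge10", "age_lo"])
    for key, row in obs.iterrows():
        m, g, pband, age_lo = key
        a = int(np.searchsorted(table.age_edges, age_lo))
        sel = (dx & (idx[0] == m) & (idx[1] == g) & (idx[2] == pband)
               & (idx[3] == a) & np.isfinite(lh.a_c))
        if np.sum(event[sel]) < 5:
            continue
        s10 = km_at(time[sel], event[sel], 10.0)
        s15 = km_at(time[sel], event[sel], 15.0)
        if not (0 < s10 < 1 and 0 < s15 < 1):
            continue
        hr = calibrate_survival_hr(s10, s15, row["s10"], row["s15"])
        new_hr[m, g, pband, a] *= float(hr)
    return out
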
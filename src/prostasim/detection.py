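"""Biopsy detection, staging at diagnosis and treatment assignment.

A positive PSA test (measured PSA at or above the referral threshold) leads
to a diagnosis with probability

    P(Dx | PSA+) = P(Bx_sens) * P(Bx_comp(age, PSA)) * 1[cancer present],

where biopsy sensitivity is 0 while the cancer is within the first
``phi_lag`` fraction of its T1-T2 sojourn and 1 afterwards (including all
later stages), and biopsy compliance comes from an age x PSA band table.
A negative biopsy simply returns the man to the re-testing stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import ComplianceTable, TreatmentTable

__all__ = [
    "STAGE_T12",
    "STAGE_T34",
    "STAGE_MET",
    "DiagnosisRecord",
    "biopsy_detectable",
    "stage_at",
    "diagnose_at_test",
    "assign_treatment",
]

STAGE_T12, STAGE_T34, STAGE_MET = 0, 1, 2
STAGE_LABELS = ("T1-T2", "T3-T4", "metastatic")


@dataclass
class DiagnosisRecord:
    """Stage, grade, PSA and treatment frozen at the age of detection."""

    dx_age: float
    mode: str  # "screen" or "clinical"
    stage_at_dx: int
    gleason: int
    psa_at_dx: float
    counterfactual_clinical_dx_age: float  # a_c, +inf if never
    treatment: str

    def __post_init__(self):
        if self.psa_at_dx <= 0:
            raise ValueError("psa_at_dx must be positive")
        if self.mode == "screen" and self.dx_age > self.counterfactual_clinical_dx_age:
            raise ValueError("screen detection cannot follow the clinical diagnosis")


def biopsy_detectable(t_onset, t_t3, t, phi_lag: float):
    """Whether a biopsy at age ``t`` can detect the cancer.

    Detectability starts once a fraction ``phi_lag`` of the T1-T2 sojourn
    Delta = t_t3 - t_onset has elapsed and never reverts.  Accepts arrays.
    """
    t_onset = np.asarray(t_onset, dtype=float)
    t_t3 = np.asarray(t_t3, dtype=float)
    t = np.asarray(t, dtype=float)
    threshold = t_onset + (t_t3 - t_onset) * phi_lag
    return (t > t_onset) & (t > threshold)


def stage_at(t_onset, t_t3, t_met, t):
    """Latent stage occupied at age t (requires t > t_onset)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= np.asarray(t_onset)):
        raise ValueError("stage is undefined before cancer onset")
    return np.where(t >= np.asarray(t_met), STAGE_MET,
                    np.where(t >= np.asarray(t_t3), STAGE_T34, STAGE_T12)).astype(np.int8)


def screen_detection_probability(t_onset, t_t3, t, psa_measured,
                                 compliance: ComplianceTable, phi_lag: float,
                                 flat_compliance: float | None = None):
    """Vectorised P(Dx) at a referral-positive test.

    ``flat_compliance`` overrides the table (used for trial emulation with a
    single reported compliance).
    """
    sens = biopsy_detectable(t_onset, t_t3, t, phi_lag)
    if flat_compliance is not None:
        comp = flat_compliance
    else:
        comp = compliance.probability(t, psa_measured)
    return sens * comp


def diagnose_at_test(history, t: float, psa_measured: float, params,
                     rng: np.random.Generator,
                     flat_compliance: float | None = None):
    """Attempt a screen diagnosis at a referral-positive test for one man.

    Returns a ``DiagnosisRecord`` or None (no cancer yet, undetectable
    cancer, or biopsy not performed).  Treatment is assigned from the age x
    Gleason table at the detection age.
    """
    if psa_measured < params.testing.threshold_psa:
        raise ValueError("diagnose_at_test requires a referral-positive PSA")
    p_dx = float(
        screen_detection_probability(
            history.t_onset, history.t_t3, t, psa_measured,
            params.compliance_table, params.progression.phi_lag,
            flat_compliance=flat_compliance))
    if t <= history.t_onset:
        return None
    if rng.uniform() >= p_dx:
        return None
    stage = int(stage_at(history.t_onset, history.t_t3, history.t_met, t))
    tx = assign_treatment(np.array([t]), np.array([history.profile.gleason]),
                          params.treatment_table, rng)[0]
    return DiagnosisRecord(
        dx_age=float(t),
        mode="screen",
        stage_at_dx=stage,
        gleason=int(history.profile.gleason),
        psa_at_dx=float(psa_measured),
        counterfactual_clinical_dx_age=float(history.t_clinical_dx),
        treatment=tx,
    )


def assign_treatment(age, gleason, table: TreatmentTable,
                     rng: np.random.Generator, uniforms=None):
    """Multinomial treatment draw per man from the age x Gleason table.

    ``uniforms`` lets paired scenarios share treatment randomness.
    Returns an array of modality labels from ``tables.TREATMENTS``.
    """
    from .tables import TREATMENTS

    age = np.asarray(age, dtype=float)
    probs = table.probabilities(age, gleason)
    u = rng.uniform(size=age.shape) if uniforms is None else np.asarray(uniforms)
    cum = np.cumsum(probs, axis=-1)
    idx = np.sum(u[..., None] > cum[..., :-1], axis=-1)
    return np.asarray(TREATMENTS)[idx]
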
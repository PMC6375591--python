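"""Banded lookup tables used throughout the model.

All tables are keyed by lower band edges (ages, PSA values, birth cohorts)
and support vectorised lookup via ``numpy.searchsorted``.  Each table
round-trips losslessly through a list-of-records representation so the whole
parameter registry can live in a single YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "band_index",
    "LifeTable",
    "ComplianceTable",
    "TreatmentTable",
    "RetestTable",
    "SurvivalTable",
    "GLEASON_LABELS",
    "TREATMENTS",
]

#: Gleason grade bands: 0 = Gleason <=6, 1 = Gleason 7, 2 = Gleason >=8.
GLEASON_LABELS = ("G6-", "G7", "G8+")

#: Treatment modalities: active surveillance, radical prostatectomy,
#: radiotherapy, androgen deprivation therapy.
TREATMENTS = ("AS", "RP", "RT", "ADT")


def band_index(x, edges):
    """Map values to band indices given ascending lower band edges.

    Values below the first edge raise ``ValueError``; values at or above the
    last edge fall in the final (open-ended) band.
    """
    x = np.asarray(x)
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, x, side="right") - 1
    if np.any(idx < 0):
        bad = np.asarray(x)[idx < 0]
        raise ValueError(f"value(s) below first band edge {edges[0]}: {bad[:5]}")
    return idx


@dataclass
class LifeTable:
    """Annual other-cause death probability by age band x birth-cohort band.

    ``q[i, j]`` is the probability of dying of a cause other than prostate
    cancer between exact age ``ages[i]`` and ``ages[i] + 1`` for a man born in
    cohort band ``cohorts[j]``.  The closing age carries probability 1.
    """

    ages: np.ndarray  # integer ages, contiguous, e.g. 35..105
    cohorts: np.ndarray  # lower edges of cohort bands, e.g. 1900, 1910, ...
    q: np.ndarray  # shape (n_ages, n_cohorts)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.cohorts = np.asarray(self.cohorts, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.ages.size, self.cohorts.size):
            raise ValueError("life table q has wrong shape")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("life table probabilities must lie in [0, 1]")
        if not np.allclose(self.q[-1], 1.0):
            raise ValueError("life table must close with probability 1 at the last age")

    @property
    def closing_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age, cohort):
        """Vectorised lookup of the one-year death probability."""
        ai = band_index(np.floor(age), self.ages)
        ci = band_index(cohort, self.cohorts)
        return self.q[ai, ci]

    def to_records(self):
        recs = []
        for j, c in enumerate(self.cohorts):
            for i, a in enumerate(self.ages):
                recs.append({"age": int(a), "cohort": float(c), "q": float(self.q[i, j])})
        return recs

    @classmethod
    def from_records(cls, recs):
        ages = np.array(sorted({r["age"] for r in recs}))
        cohorts = np.array(sorted({r["cohort"] for r in recs}))
        q = np.full((ages.size, cohorts.size), np.nan)
        ai = {a: i for i, a in enumerate(ages)}
        ci = {c: j for j, c in enumerate(cohorts)}
        for r in recs:
            q[ai[r["age"]], ci[r["cohort"]]] = r["q"]
        if np.any(np.isnan(q)):
            raise ValueError("life table records do not cover the age x cohort grid")
        return cls(ages, cohorts, q)

    def __eq__(self, other):
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.cohorts, other.cohorts)
            and np.array_equal(self.q, other.q)
        )


@dataclass
class ComplianceTable:
    """P(biopsy | PSA-positive referral) by age band x PSA band."""

    age_edges: np.ndarray
    psa_edges: np.ndarray  # lower edges, first edge = referral threshold
    prob: np.ndarray  # shape (n_age, n_psa)

    def __post_init__(self):
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        self.psa_edges = np.asarray(self.psa_edges, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (self.age_edges.size, self.psa_edges.size):
            raise ValueError("compliance table prob has wrong shape")
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("compliance probabilities must lie in [0, 1]")

    def probability(self, age, psa):
        return self.prob[band_index(age, self.age_edges), band_index(psa, self.psa_edges)]

    def to_records(self):
        return [
            {"age_lo": float(a), "psa_lo": float(p), "prob": float(self.prob[i, j])}
            for i, a in enumerate(self.age_edges)
            for j, p in enumerate(self.psa_edges)
        ]

    @classmethod
    def from_records(cls, recs):
        ages = np.array(sorted({r["age_lo"] for r in recs}))
        psas = np.array(sorted({r["psa_lo"] for r in recs}))
        prob = np.full((ages.size, psas.size), np.nan)
        for r in recs:
            prob[np.searchsorted(ages, r["age_lo"]), np.searchsorted(psas, r["psa_lo"])] = r["prob"]
        if np.any(np.isnan(prob)):
            raise ValueError("compliance records do not cover the age x PSA grid")
        return cls(ages, psas, prob)

    def __eq__(self, other):
        return (
            isinstance(other, ComplianceTable)
            and np.array_equal(self.age_edges, other.age_edges)
            and np.array_equal(self.psa_edges, other.psa_edges)
            and np.array_equal(self.prob, other.prob)
        )


@dataclass
class TreatmentTable:
    """Treatment-assignment probabilities by age band x Gleason band.

    Rows are multinomial probabilities over (AS, RP, RT, ADT).
    """

    age_edges: np.ndarray
    prob: np.ndarray  # shape (n_age, 3 gleason, 4 treatments)

    def __post_init__(self):
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (self.age_edges.size, 3, 4):
            raise ValueError("treatment table prob has wrong shape")
        if np.any(self.prob < 0):
            raise ValueError("treatment probabilities must be non-negative")
        if not np.allclose(self.prob.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("treatment probabilities must sum to 1 in every stratum")

    def probabilities(self, age, gleason):
        return self.prob[band_index(age, self.age_edges), np.asarray(gleason, dtype=int)]

    def to_records(self):
        recs = []
        for i, a in enumerate(self.age_edges):
            for g in range(3):
                rec = {"age_lo": float(a), "gleason": GLEASON_LABELS[g]}
                for k, tx in enumerate(TREATMENTS):
                    rec[tx] = float(self.prob[i, g, k])
                recs.append(rec)
        return recs

    @classmethod
    def from_records(cls, recs):
        ages = np.array(sorted({r["age_lo"] for r in recs}))
        prob = np.full((ages.size, 3, 4), np.nan)
        gidx = {lab: g for g, lab in enumerate(GLEASON_LABELS)}
        for r in recs:
            i = np.searchsorted(ages, r["age_lo"])
            g = gidx[r["gleason"]]
            for k, tx in enumerate(TREATMENTS):
                prob[i, g, k] = r[tx]
        if np.any(np.isnan(prob)):
            raise ValueError("treatment records do not cover the age x Gleason grid")
        return cls(ages, prob)

    def __eq__(self, other):
        return (
            isinstance(other, TreatmentTable)
            and np.array_equal(self.age_edges, other.age_edges)
            and np.array_equal(self.prob, other.prob)
        )


@dataclass
class RetestTable:
    """Weibull cure-model re-testing parameters by 5-year age group x PSA band.

    Each stratum carries (pi3, a3, b3): the probability of ever re-testing,
    and the Weibull shape and scale (years) of the re-test gap among those
    who do re-test.
    """

    age_edges: np.ndarray  # 5-year lower edges 30, 35, ..., 90
    psa_edges: np.ndarray  # 0, 1, 3, 10
    pi3: np.ndarray
    a3: np.ndarray
    b3: np.ndarray

    def __post_init__(self):
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        self.psa_edges = np.asarray(self.psa_edges, dtype=float)
        shape = (self.age_edges.size, self.psa_edges.size)
        for name in ("pi3", "a3", "b3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise ValueError(f"retest table {name} has wrong shape")
        if np.any((self.pi3 < 0) | (self.pi3 > 1)):
            raise ValueError("retest cure fractions must lie in [0, 1]")
        if np.any(self.a3 <= 0) or np.any(self.b3 <= 0):
            raise ValueError("retest Weibull shape and scale must be positive")

    def stratum(self, age, psa):
        ai = band_index(age, self.age_edges)
        pi = band_index(psa, self.psa_edges)
        return self.pi3[ai, pi], self.a3[ai, pi], self.b3[ai, pi]

    def to_records(self):
        return [
            {
                "age_lo": float(a),
                "psa_lo": float(p),
                "pi3": float(self.pi3[i, j]),
                "a3": float(self.a3[i, j]),
                "b3": float(self.b3[i, j]),
            }
            for i, a in enumerate(self.age_edges)
            for j, p in enumerate(self.psa_edges)
        ]

    @classmethod
    def from_records(cls, recs):
        ages = np.array(sorted({r["age_lo"] for r in recs}))
        psas = np.array(sorted({r["psa_lo"] for r in recs}))
        arrs = {k: np.full((ages.size, psas.size), np.nan) for k in ("pi3", "a3", "b3")}
        for r in recs:
            i = np.searchsorted(ages, r["age_lo"])
            j = np.searchsorted(psas, r["psa_lo"])
            for k in arrs:
                arrs[k][i, j] = r[k]
        if any(np.any(np.isnan(v)) for v in arrs.values()):
            raise ValueError("retest records do not cover the age x PSA grid")
        return cls(ages, psas, arrs["pi3"], arrs["a3"], arrs["b3"])

    def __eq__(self, other):
        return (
            isinstance(other, RetestTable)
            and np.array_equal(self.age_edges, other.age_edges)
            and np.array_equal(self.psa_edges, other.psa_edges)
            and np.array_equal(self.pi3, other.pi3)
            and np.array_equal(self.a3, other.a3)
            and np.array_equal(self.b3, other.b3)
        )


@dataclass
class SurvivalTable:
    """Baseline prostate-cancer survivor curves by diagnostic stratum.

    The stratum grid crosses metastatic status, Gleason band, PSA band
    (< 10 / >= 10 ng/mL) and ten-year age group at diagnosis.  Each stratum
    carries a cure-mixture Weibull survivor function

        S(t) = cure + (1 - cure) * exp(-(t / scale)^shape)

    for time ``t`` in years since (counterfactual) clinical diagnosis, plus a
    per-stratum calibration hazard ratio applied as a power (default 1).
    """

    age_edges: np.ndarray  # 10-year lower edges, e.g. 45, 55, 65, 75, 85
    cure: np.ndarray  # shape (2 met, 3 gleason, 2 psa, n_age)
    shape: np.ndarray
    scale: np.ndarray
    hr_adjustment: np.ndarray = field(default=None)

    def __post_init__(self):
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        grid = (2, 3, 2, self.age_edges.size)
        for name in ("cure", "shape", "scale"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != grid:
                raise ValueError(f"survival table {name} has wrong shape")
        if self.hr_adjustment is None:
            self.hr_adjustment = np.ones(grid)
        self.hr_adjustment = np.asarray(self.hr_adjustment, dtype=float)
        if self.hr_adjustment.shape != grid:
            raise ValueError("survival table hr_adjustment has wrong shape")
        if np.any((self.cure < 0) | (self.cure >= 1)):
            raise ValueError("cure fractions must lie in [0, 1)")
        if np.any(self.shape <= 0) or np.any(self.scale <= 0):
            raise ValueError("Weibull shape and scale must be positive")
        if np.any(self.hr_adjustment <= 0):
            raise ValueError("hr_adjustment must be positive")

    def stratum_index(self, metastatic, gleason, psa, age):
        """Return index tuple arrays for vectorised curve lookup."""
        m = np.asarray(metastatic, dtype=int)
        g = np.asarray(gleason, dtype=int)
        p = (np.asarray(psa, dtype=float) >= 10.0).astype(int)
        a = band_index(age, self.age_edges)
        return m, g, p, a

    def to_records(self):
        recs = []
        for m in range(2):
            for g in range(3):
                for p in range(2):
                    for i, a in enumerate(self.age_edges):
                        recs.append(
                            {
                                "metastatic": int(m),
                                "gleason": GLEASON_LABELS[g],
                                "psa_ge10": int(p),
                                "age_lo": float(a),
                                "cure": float(self.cure[m, g, p, i]),
                                "shape": float(self.shape[m, g, p, i]),
                                "scale": float(self.scale[m, g, p, i]),
                                "hr_adjustment": float(self.hr_adjustment[m, g, p, i]),
                            }
                        )
        return recs

    @classmethod
    def from_records(cls, recs):
        ages = np.array(sorted({r["age_lo"] for r in recs}))
        grid = (2, 3, 2, ages.size)
        arrs = {k: np.full(grid, np.nan) for k in ("cure", "shape", "scale", "hr_adjustment")}
        gidx = {lab: g for g, lab in enumerate(GLEASON_LABELS)}
        for r in recs:
            key = (int(r["metastatic"]), gidx[r["gleason"]], int(r["psa_ge10"]),
                   np.searchsorted(ages, r["age_lo"]))
            for k in arrs:
                arrs[k][key] = r[k]
        if any(np.any(np.isnan(v)) for v in arrs.values()):
            raise ValueError("survival records do not cover the stratum grid")
        return cls(ages, arrs["cure"], arrs["shape"], arrs["scale"], arrs["hr_adjustment"])

    def __eq__(self, other):
        return (
            isinstance(other, SurvivalTable)
            and np.array_equal(self.age_edges, other.age_edges)
            and np.array_equal(self.cure, other.cure)
            and np.array_equal(self.shape, other.shape)
            and np.array_equal(self.scale, other.scale)
            and np.array_equal(self.hr_adjustment, other.hr_adjustment)
        )
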
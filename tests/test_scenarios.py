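import numpy as np
import pytest

from prostasim import scenarios as sc


class TestPoissonRR:
    def test_single_stratum_closed_form(self):
        rr, se = sc.poisson_rr([50.0], [10_000.0], [100.0], [10_000.0])
        assert rr == pytest.approx(0.5, rel=1e-9)

    def test_equal_rates_give_unity(self):
        rr, _ = sc.poisson_rr([10, 20, 30], [100, 200, 300],
                              [20, 40, 60], [200, 400, 600])
        assert rr == pytest.approx(1.0, rel=1e-9)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            k = rng.integers(2, 6)
            t0 = rng.uniform(500, 2000, k)
            t1 = rng.uniform(500, 2000, k)
            mu = rng.uniform(0.005, 0.05, k)
            rho = rng.uniform(0.3, 2.5)
            d0 = rng.poisson(mu * t0) + 1
            d1 = rng.poisson(rho * mu * t1) + 1
            rr, _ = sc.poisson_rr(d1, t1, d0, t0)
            # oracle: Poisson GLM with stratum dummies and an arm indicator
            y = np.concatenate([d0, d1])
            X = np.zeros((2 * k, k + 1))
            X[:k, :k] = np.eye(k)
            X[k:, :k] = np.eye(k)
            X[k:, k] = 1.0
            offset = np.log(np.concatenate([t0, t1]))
            fit = sm.GLM(y, X, family=sm.families.Poisson(),
                         offset=offset).fit()
            assert rr == pytest.approx(np.exp(fit.params[-1]), rel=1e-5)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sc.poisson_rr([0.0], [100.0], [0.0], [100.0])


@pytest.fixture(scope="module")
def arms(params):
    return sc.emulate_erspc(params, 60_000, seed=42)


@pytest.fixture(scope="module")
def pair(params):
    current = sc.simulate_population(params, "current", 40_000, seed=11)
    none = sc.simulate_population(params, "none", 40_000, seed=11)
    return current, none


class TestTrialEmulation:
    def test_screening_arm_detects_at_least_control(self, arms):
        control, screening = arms
        assert (screening.totals("diagnoses").sum()
                >= control.totals("diagnoses").sum())

    def test_control_arm_invariant_to_screening_intensity(self, params):
        """Common random numbers: the control arm is unchanged by the
        screening arm's compliance."""
        c1, _ = sc.emulate_erspc(params, 20_000, seed=7, compliance=0.856)
        c2, _ = sc.emulate_erspc(params, 20_000, seed=7, compliance=0.1)
        assert np.array_equal(c1.diagnoses, c2.diagnoses)
        assert np.array_equal(c1.cancer_deaths, c2.cancer_deaths)
        assert np.array_equal(c1.person_years, c2.person_years)

    def test_no_screen_detection_without_tests(self, arms):
        control, _ = arms
        assert control.totals("overdiagnoses").sum() == 0

    def test_person_time_bounded_by_follow_up(self, arms):
        control, _ = arms
        assert (control.totals("person_years").sum()
                <= control.n_persons * 13.0 + 1e-6)


class TestPopulationScenarios:
    def test_cessation_has_zero_overdiagnosis_in_window(self, pair):
        _, none = pair
        assert none.totals("overdiagnoses").sum() == 0

    def test_common_random_numbers_before_policy_divergence(self, params):
        """Policies identical before 2015 produce identical event streams
        before 2015 person by person."""
        cohort = np.full(5000, 1952.0)
        a = sc.simulate_cohort(params, cohort, "current", seed=3)
        b = sc.simulate_cohort(params, cohort, "none", seed=3)
        year_a = a.cohort + a.dx_age
        before = (year_a < 2015) & np.isfinite(a.dx_age)
        assert np.array_equal(a.dx_age[before], b.dx_age[before])
        assert np.array_equal(a.other_death_age, b.other_death_age)
        assert np.array_equal(a.t_onset, b.t_onset)

    def test_person_years_conservation(self, params):
        cohort = np.full(2000, 1950.0)
        lh = sc.simulate_cohort(params, cohort, "current", seed=3)
        years = np.arange(2000, 2060)
        res = sc.aggregate(lh, years, n_batches=4)
        start_age = np.maximum(35.0, years[0] - 1950.0)
        end_age = np.minimum(lh.death_age, years[-1] + 1 - 1950.0)
        expected = np.clip(end_age - start_age, 0.0, None).sum()
        assert res.totals("person_years").sum() == pytest.approx(expected,
                                                                 rel=1e-9)

    def test_batches_partition_counts(self, pair):
        current, _ = pair
        whole = current.diagnoses.sum()
        assert current.totals("diagnoses").sum() == pytest.approx(whole)

    def test_overdiagnosis_definition(self, pair):
        current, _ = pair
        # overdiagnoses are a subset of diagnoses
        assert (current.totals("overdiagnoses").sum()
                <= current.totals("diagnoses").sum())


class TestFlagOverdiagnosis:
    def _lh(self, mode, a_c, other_death):
        n = 1
        z = np.zeros(n)
        return sc.LifeHistoryBatch(
            cohort=z, t_onset=z + 50, gleason=z.astype(int), t_t3=z + 60,
            t_met=z + 70, a_c=np.array([a_c]), other_death_age=np.array(
                [other_death]),
            dx_age=np.array([65.0]), dx_mode=np.array([mode]),
            stage_at_dx=z.astype(int), psa_at_dx=z + 5,
            treatment=np.array(["AS"]), cancer_death_age=np.array([np.inf]),
            death_age=np.array([other_death]), overdiagnosed=np.array([False]),
        )

    def test_screen_detected_never_presenting(self):
        lh = self._lh(sc.MODE_SCREEN, a_c=80.0, other_death=75.0)
        assert sc.flag_overdiagnosis(lh)[0]

    def test_screen_detected_presenting_before_death(self):
        lh = self._lh(sc.MODE_SCREEN, a_c=70.0, other_death=75.0)
        assert not sc.flag_overdiagnosis(lh)[0]

    def test_clinical_diagnosis_never_overdiagnosed(self):
        lh = self._lh(sc.MODE_CLINICAL, a_c=80.0, other_death=75.0)
        assert not sc.flag_overdiagnosis(lh)[0]


class TestRateSeries:
    def test_identity_rate_ratios(self, params):
        res = sc.simulate_population(params, "current", 10_000, seed=2)
        out = sc.rate_ratio_series(res, res)
        for v in out.values():
            assert v["rr"] == pytest.approx(1.0, rel=1e-12)

    def test_life_years_identity_and_toy(self, params):
        res = sc.simulate_population(params, "current", 10_000, seed=2)
        assert sc.life_years_gained(res, res)["life_years_gained"] == 0.0

    def test_life_years_toy_population(self, params):
        # hand-computed on a 10-person toy population
        cohort = np.full(10, 1950.0)
        lh = sc.simulate_cohort(params, cohort, "current", seed=8)
        years = np.arange(2015, 2035)
        res = sc.aggregate(lh, years, n_batches=2)
        lh2 = sc.simulate_cohort(params, cohort, "current", seed=9)
        res2 = sc.aggregate(lh2, years, n_batches=2)

        def window_years(lh):
            lo, hi = 2015 - 1950, 2035 - 1950
            return np.clip(np.minimum(lh.death_age, hi) - np.maximum(35.0, lo),
                           0.0, None).sum()

        expected = (window_years(lh) - window_years(lh2)) / 10 * 1000
        got = sc.life_years_gained(res, res2)["life_years_gained"]
        assert got == pytest.approx(expected, rel=1e-9)


class TestAgeStandardisation:
    def _result(self, rates, ages=(60, 61, 62)):
        n_age, n_year = len(ages), 2
        py = np.full((n_age, n_year, 1), 100.0)
        dx = np.array(rates)[:, None, None] * py
        z = np.zeros_like(py)
        return sc.ScenarioResult(
            ages=np.array(ages), years=np.array([2015, 2016]),
            person_years=py, at_risk_years=py, diagnoses=dx, overdiagnoses=z,
            cancer_deaths=z, deaths=z, n_persons=100)

    def test_uniform_weights_equal_rates(self):
        res = self._result([0.02, 0.02, 0.02])
        out = sc.age_standardised_rates(res, {60: 1 / 3, 61: 1 / 3, 62: 1 / 3})
        assert np.allclose(out["rate"], 0.02)

    def test_single_age_standard(self):
        res = self._result([0.01, 0.05, 0.09])
        out = sc.age_standardised_rates(res, {61: 1.0})
        assert np.allclose(out["rate"], 0.05)

    def test_toy_three_age_hand_computation(self):
        res = self._result([0.01, 0.02, 0.04])
        w = {60: 0.5, 61: 0.3, 62: 0.2}
        out = sc.age_standardised_rates(res, w)
        assert np.allclose(out["rate"], 0.5 * 0.01 + 0.3 * 0.02 + 0.2 * 0.04)

    def test_weights_must_sum_to_one(self):
        res = self._result([0.01, 0.02, 0.04])
        with pytest.raises(ValueError, match="sum to 1"):
            sc.age_standardised_rates(res, {60: 0.5, 61: 0.2, 62: 0.2})
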
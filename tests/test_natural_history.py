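import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr
from scipy.stats import norm

from prostasim import natural_history as nh


def _profile(b0=0.0, b1=0.05, b_onset=0.1, onset=60.0, gleason=0):
    return nh.PsaProfile(b0=b0, b1=b1, b_onset=b_onset, onset_age=onset,
                         gleason=gleason)


class TestOnset:
    def test_cdf_zero_at_support_start(self):
        assert nh.onset_cdf(35.0, 1e-3) == 0.0

    def test_empirical_median_matches_closed_form(self, rng):
        gamma_o = 1e-3
        draws = nh.sample_onset_age(gamma_o, rng, size=100_000)
        expected = 35.0 + np.sqrt(2.0 * np.log(2.0) / gamma_o)
        assert np.median(draws) == pytest.approx(expected, rel=0.01)

    def test_empirical_cdf_sup_distance(self, rng):
        gamma_o = 1e-3
        draws = np.sort(nh.sample_onset_age(gamma_o, rng, size=100_000))
        ecdf = np.arange(1, draws.size + 1) / draws.size
        assert np.max(np.abs(ecdf - nh.onset_cdf(draws, gamma_o))) < 0.01

    def test_invalid_gamma(self, rng):
        with pytest.raises(ValueError):
            nh.sample_onset_age(0.0, rng)


class TestGleason:
    def test_probs_at_age_35(self, params):
        p = nh.gleason_probs(35.0, params.onset_gleason)
        assert np.allclose(p, [0.8319, 0.1664, 0.0017], atol=5e-5)

    def test_probs_at_age_60(self, params):
        p = nh.gleason_probs(60.0, params.onset_gleason)
        assert np.allclose(p, [0.450, 0.446, 0.104], atol=5e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(t=st.floats(35.0, 120.0))
    def test_probs_normalise(self, t, params):
        assert nh.gleason_probs(t, params.onset_gleason).sum() == pytest.approx(1.0)

    def test_age_below_support_rejected(self, params):
        with pytest.raises(ValueError):
            nh.gleason_probs(30.0, params.onset_gleason)


class TestPsaProfile:
    def test_truncated_normal_mean(self, rng):
        mu, sigma = 0.05, 0.1
        x = nh.sample_truncated_normal(np.full(100_000, mu),
                                       np.full(100_000, sigma), rng)
        expected = mu + sigma * norm.pdf(-mu / sigma) / (1 - ndtr(-mu / sigma))
        assert np.mean(x) == pytest.approx(expected, rel=0.01)
        assert np.all(x >= 0)

    def test_degenerate_sigma_limit(self, rng):
        x = nh.sample_truncated_normal(np.array([0.05, -0.2]),
                                       np.zeros(2), rng)
        assert np.allclose(x, [0.05, 0.0])

    def test_sampled_slopes_non_negative(self, params, rng):
        onset = np.full(10_000, 60.0)
        gleason = rng.integers(0, 3, size=10_000)
        b0, b1, b_onset = nh.sample_psa_profile(onset, gleason,
                                                params.psa_growth, rng)
        assert np.all(b1 >= 0) and np.all(b_onset >= 0)


class TestMedianPsa:
    def test_intercept_at_35(self):
        prof = _profile(b0=np.log(2.0))
        assert nh.median_psa(prof, 35.0) == pytest.approx(2.0)

    def test_piecewise_linear_log_at_onset(self):
        prof = _profile()
        eps = 1e-6
        below = np.log(nh.median_psa(prof, 60.0 - eps))
        above = np.log(nh.median_psa(prof, 60.0 + eps))
        assert above == pytest.approx(below, abs=1e-5)  # continuity
        slope_below = (np.log(nh.median_psa(prof, 59.0)) - np.log(nh.median_psa(prof, 58.0)))
        slope_above = (np.log(nh.median_psa(prof, 62.0)) - np.log(nh.median_psa(prof, 61.0)))
        assert slope_above - slope_below == pytest.approx(prof.b_onset)

    def test_worked_example(self):
        prof = _profile(b0=np.log(1.0), b1=0.05, b_onset=0.1, onset=60.0)
        assert nh.median_psa(prof, 70.0) == pytest.approx(np.exp(2.75), rel=1e-12)

    def test_monotone_in_age(self, params, rng):
        onset = nh.sample_onset_age(1e-3, rng, size=200)
        gleason = nh.sample_gleason(onset, params.onset_gleason, rng)
        b0, b1, b_onset = nh.sample_psa_profile(onset, gleason,
                                                params.psa_growth, rng)
        ages = np.linspace(35.0, 100.0, 131)
        for prof in zip(b0[:, None], b1[:, None], b_onset[:, None], onset[:, None]):
            y = nh.median_psa(prof, ages)
            assert np.all(np.diff(y) >= -1e-12)


class TestMeasuredPsa:
    def test_zero_noise_equals_median(self, rng):
        prof = _profile()
        assert nh.measured_psa(prof, 50.0, 0.0, rng) == nh.median_psa(prof, 50.0)

    def test_log_ratio_sd_matches_phi(self, rng):
        prof = _profile()
        phi = 0.3
        draws = np.array([nh.measured_psa(prof, np.full(10_000, 50.0), phi, rng)])
        log_ratio = np.log(draws / nh.median_psa(prof, 50.0))
        assert np.std(log_ratio) == pytest.approx(phi, rel=0.02)

    def test_independent_streams_differ(self):
        prof = _profile()
        a = nh.measured_psa(prof, 50.0, 0.3, np.random.default_rng(1))
        b = nh.measured_psa(prof, 50.0, 0.3, np.random.default_rng(2))
        assert a != b


def _thinning_oracle(gamma, prof, start, n, rng, dt=2.0, t_max=400.0):
    """Independent thinning sampler for hazard gamma * y(t) (y increasing)."""
    b0, b1, b_onset, t_onset = prof
    slope = b1 + b_onset

    def lam(t):
        logl = b0 + b1 * (t - 35.0) + b_onset * (t - t_onset)
        return gamma * np.exp(np.minimum(logl, 700.0))

    t = np.full(n, float(start))
    out = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    while np.any(active) and np.min(t[active]) < t_max:
        ub = lam(np.minimum(t + dt, t_max))  # majorant on [t, t+dt]
        w = rng.exponential(size=n) / ub
        cand = t + w
        crossed = cand > t + dt
        u = rng.uniform(size=n)
        accept = active & ~crossed & (u < lam(cand) / ub)
        out[accept] = cand[accept]
        active &= ~accept
        t = np.where(active, np.where(crossed, t + dt, cand), t)
    return out[~np.isnan(out)]


class TestHazardEventTimes:
    def test_constant_psa_exponential_limit(self, rng):
        # flat PSA of 10 ng/mL: event times are exponential, mean 1/(gamma*10)
        gamma = 9.7e-4
        prof = (np.full(100_000, np.log(10.0)), np.zeros(100_000),
                np.zeros(100_000), np.full(100_000, 35.0))
        t = nh.sample_hazard_event_time(gamma, prof, np.full(100_000, 35.0), rng)
        assert np.mean(t - 35.0) == pytest.approx(1.0 / (gamma * 10.0), rel=0.01)

    def test_survivor_function_matches_cumulative_hazard(self, rng):
        gamma = 9.7e-4
        prof = (np.full(100_000, 0.3), np.full(100_000, 0.04),
                np.full(100_000, 0.12), np.full(100_000, 60.0))
        t = nh.sample_hazard_event_time(gamma, prof, np.full(100_000, 60.0), rng)
        grid = np.linspace(60.0, 120.0, 200)
        # numerically integrated cumulative hazard on the grid
        fine = np.linspace(60.0, 120.0, 6001)
        lam = gamma * np.exp(0.3 + 0.04 * (fine - 35.0) + 0.12 * (fine - 60.0))
        cum = np.concatenate([[0.0], np.cumsum((lam[1:] + lam[:-1]) / 2
                                               * np.diff(fine))])
        surv_expected = np.exp(-np.interp(grid, fine, cum))
        surv_emp = np.array([(t > g).mean() for g in grid])
        assert np.max(np.abs(surv_emp - surv_expected)) < 0.01

    def test_matches_thinning_oracle(self, params):
        """Analytic inverse-transform sampler vs an independent thinning
        sampler: two-sample KS distance below 0.01 for random profiles."""
        rng = np.random.default_rng(777)
        gamma = 9.7e-4
        for _ in range(5):
            b0 = rng.normal(-1.0, 0.3)
            b1 = rng.uniform(0.02, 0.06)
            b2 = rng.uniform(0.08, 0.25)
            onset = rng.uniform(55.0, 75.0)
            prof = (np.full(100_000, b0), np.full(100_000, b1),
                    np.full(100_000, b2), np.full(100_000, onset))
            direct = nh.sample_hazard_event_time(
                gamma, prof, np.full(100_000, onset), rng)
            oracle = _thinning_oracle(
                gamma, (b0, b1, b2, onset), onset, 100_000, rng)
            grid = np.quantile(oracle, np.linspace(0.005, 0.995, 200))
            ks = np.max(np.abs(
                np.searchsorted(np.sort(direct), grid) / direct.size
                - np.searchsorted(np.sort(oracle), grid) / oracle.size))
            assert ks < 0.01

    def test_infinite_hazard_collapses_to_start(self, rng):
        prof = (np.zeros(100), np.full(100, 0.05), np.full(100, 0.1),
                np.full(100, 60.0))
        t = nh.sample_hazard_event_time(1e12, prof, np.full(100, 60.0), rng)
        assert np.all(t - 60.0 < 1e-6)

    def test_invalid_gamma_rejected(self, rng):
        prof = (np.zeros(1), np.zeros(1), np.zeros(1), np.full(1, 40.0))
        with pytest.raises(ValueError):
            nh.sample_hazard_event_time(-1.0, prof, np.full(1, 40.0), rng)


class TestDiseaseHistory:
    def test_event_ordering_invariants(self, params, rng):
        batch = nh.simulate_history_batch(params, rng, 20_000)
        assert np.all(batch.t_onset >= 35.0)
        assert np.all(batch.t_t3 >= batch.t_onset)
        assert np.all(batch.t_met >= batch.t_t3)
        assert np.all(batch.t_clinical_dx > batch.t_onset)
        assert np.isin(batch.gleason, [0, 1, 2]).all()

    def test_clinical_detection_disabled(self, params, rng):
        batch = nh.simulate_history_batch(params, rng, 1000, clinical_dx=False)
        assert np.all(np.isinf(batch.t_clinical_dx))
        assert np.all(np.isfinite(batch.t_met))  # followed to metastasis

    def test_zero_clinical_hazard_means_no_clinical_detection(self, params, rng):
        p = params.copy()
        p.progression.gamma_lc_g7minus = 0.0
        p.progression.gamma_lc_g8plus = 0.0
        p.progression.gamma_mc_g7minus = 0.0
        p.progression.gamma_mc_g8plus = 0.0
        p.validate()
        batch = nh.simulate_history_batch(p, rng, 2000)
        assert np.all(np.isinf(batch.t_clinical_dx))
        assert np.all(np.isfinite(batch.t_met))  # still reaches metastasis

    def test_huge_gamma_t_collapses_t12_sojourn(self, params, rng):
        p = params.copy()
        p.progression.gamma_t = 1e9
        batch = nh.simulate_history_batch(p, rng, 2000)
        assert np.mean(batch.t_t3 - batch.t_onset) < 1e-3

    def test_single_history_wrapper(self, params):
        h = nh.simulate_disease_history(params, np.random.default_rng(3))
        assert h.t_onset <= h.t_t3 <= h.t_met
        assert h.profile.gleason in (0, 1, 2)
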
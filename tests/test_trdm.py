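"""Race-model likelihood: closed forms, normalization, simulator agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import trdmjoint as tj
from trdmjoint.errors import DataIntegrityError, ParameterDomainError
from trdmjoint.trdm import dataset_trial_loglik, wald_sf


class TestWald:
    @pytest.mark.parametrize("t,gamma,sigma,alpha,expected", [
        # drift cancels the threshold at t = alpha/gamma: density is 1/sqrt(2 pi t^3)
        (0.5, 2.0, 1.0, 1.0, 1.0 / math.sqrt(2 * math.pi * 0.5**3)),
        # zero drift at t=1: (1/sqrt(2 pi)) exp(-1/2)
        (1.0, 0.0, 1.0, 1.0, math.exp(-0.5) / math.sqrt(2 * math.pi)),
        (-0.1, 1.0, 1.0, 1.0, 0.0),
        (0.0, 1.0, 1.0, 1.0, 0.0),
    ])
    def test_pdf_closed_forms(self, t, gamma, sigma, alpha, expected):
        assert tj.wald_pdf(t, gamma, sigma, alpha) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("t,gamma,sigma,alpha,expected", [
        # zero drift: reflection identity 2 Phi(-alpha/(sigma sqrt(t)))
        (1.0, 0.0, 1.0, 1.0, 0.3173105078629141),
        (0.0, 1.0, 1.0, 1.0, 0.0),
        (1e6, 1.0, 1.0, 1.0, 1.0),
    ])
    def test_cdf_closed_forms(self, t, gamma, sigma, alpha, expected):
        assert tj.wald_cdf(t, gamma, sigma, alpha) == pytest.approx(expected, abs=1e-7)

    def test_matches_scipy_invgauss(self):
        """For positive drift the first-passage law is inverse Gaussian."""
        from scipy import stats
        gamma, sigma, alpha = 2.0, 0.7, 1.0
        mu, lam = alpha / gamma, alpha**2 / sigma**2
        iv = stats.invgauss(mu / lam, scale=lam)
        t = np.array([0.05, 0.3, 1.0, 4.0])
        np.testing.assert_allclose(tj.wald_pdf(t, gamma, sigma, alpha), iv.pdf(t), rtol=1e-10)
        np.testing.assert_allclose(tj.wald_cdf(t, gamma, sigma, alpha), iv.cdf(t),
                                   rtol=1e-8, atol=1e-12)

    def test_pdf_integrates_to_cdf(self):
        for gamma in (0.0, 1.5):
            for t_hi in (0.4, 2.0):
                v, _ = integrate.quad(lambda t: tj.wald_pdf(t, gamma, 0.8, 1.0), 0, t_hi)
                assert v == pytest.approx(tj.wald_cdf(t_hi, gamma, 0.8, 1.0), abs=1e-6)

    def test_large_drift_no_overflow(self):
        # exp(2 alpha gamma / sigma^2) overflows naively; log-space form must not
        v = tj.wald_cdf(0.01, 500.0, 1.0, 1.0)
        assert 0.0 <= v <= 1.0 and np.isfinite(v)

    @pytest.mark.parametrize("bad", [dict(sigma=0.0), dict(sigma=-1.0), dict(alpha=0.0),
                                     dict(gamma=-0.5)])
    def test_domain_errors(self, bad):
        kw = dict(gamma=1.0, sigma=1.0, alpha=1.0)
        kw.update(bad)
        with pytest.raises(ParameterDomainError):
            tj.wald_pdf(0.5, **kw)

    @given(st.floats(0.01, 50), st.floats(0.0, 8), st.floats(0.1, 3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cdf_monotone_and_bounded(self, t, gamma, sigma):
        c1 = tj.wald_cdf(t, gamma, sigma)
        c2 = tj.wald_cdf(t * 1.3, gamma, sigma)
        assert 0.0 <= c1 <= c2 <= 1.0


class TestGoDensityAndNogoProb:
    def test_premature_responses_are_pure_timer(self, mid_params):
        """Before non-decision time has elapsed only the timer can respond."""
        t = 0.05
        assert t < mid_params.tau_E
        expected = mid_params.guess_go_prob * tj.wald_pdf(t, mid_params.gamma_T,
                                                          mid_params.sigma_T)
        assert tj.go_response_density(t, mid_params, "go") == pytest.approx(expected, rel=1e-12)

    def test_degenerate_fast_timer_dominates(self):
        p = tj.TRDMParams(1.0, 1.0, 1.0, 100.0, 1.0, 0.01, 0.2)
        assert tj.nogo_response_prob(p, "nogo") < 1e-6
        grid = np.linspace(0.001, 0.05, 400)
        dens = tj.go_response_density(grid, p, "nogo")
        assert abs(grid[np.argmax(dens)] - 0.01) < 0.003  # mass near alpha_T/gamma_T

    def test_dominant_nogo_accumulator(self):
        p = tj.TRDMParams(1.0, 0.5, 1000.0, 0.5, 1.0, 1.0, 0.1)
        assert tj.nogo_response_prob(p, "nogo") > 0.99

    def test_symmetric_racers_without_timer(self):
        # identical go/nogo drifts, timer effectively disabled
        p = tj.TRDMParams(2.0, 2.0, 2.0, 0.0, 1.0, 1e-6, 0.0)
        assert tj.nogo_response_prob(p, "nogo") == pytest.approx(0.5, abs=1e-4)

    def test_quadrature_and_complement_agree(self, random_param_sets):
        for p in random_param_sets:
            a = tj.nogo_response_prob(p, "nogo", method="quadrature")
            b = tj.nogo_response_prob(p, "nogo", method="complement")
            assert a == pytest.approx(b, abs=2e-5)

    def test_normalization(self, random_param_sets):
        for p in random_param_sets:
            for stim in ("go", "nogo"):
                pn = tj.nogo_response_prob(p, stim)
                pg, _ = integrate.quad(
                    lambda x: float(tj.go_response_density(math.exp(x), p, stim)) * math.exp(x),
                    math.log(1e-9), math.log(1e5), limit=400)
                assert pn + pg == pytest.approx(1.0, abs=1e-4)

    def test_normalization_with_unbiased_guessing(self):
        p = tj.TRDMParams(2.0, 1.0, 2.0, 1.5, 1.0, 0.8, 0.2, guess_go_prob=0.5)
        pn = tj.nogo_response_prob(p, "nogo")
        pg, _ = integrate.quad(
            lambda x: float(tj.go_response_density(math.exp(x), p, "nogo")) * math.exp(x),
            math.log(1e-9), math.log(1e5), limit=400)
        assert pn + pg == pytest.approx(1.0, abs=1e-4)

    def test_monotone_in_nogo_drift(self):
        probs = []
        for gnn in (0.5, 1.5, 3.0, 5.0):
            p = tj.TRDMParams(2.0, 1.0, gnn, 1.0, 1.0, 0.8, 0.2)
            probs.append(tj.nogo_response_prob(p, "nogo"))
        assert np.all(np.diff(probs) > 0)


class TestTrialLoglik:
    def test_near_certain_nogo(self):
        # instant nogo accumulator; only the timer's rare head start (during
        # the non-decision time) keeps P(withheld) fractionally below 1
        p = tj.TRDMParams(1.0, 0.1, 1000.0, 0.2, 1.0, 1.0, 0.1)
        trial = tj.TrialRecord("a", 0, "nogo", "withheld")
        assert tj.trial_loglik(trial, p) == pytest.approx(0.0, abs=5e-3)

    def test_negative_rt_rejected(self):
        with pytest.raises(DataIntegrityError):
            tj.TrialRecord("a", 0, "go", "go", rt=-0.2)

    def test_withheld_with_rt_rejected(self):
        with pytest.raises(DataIntegrityError):
            tj.TrialRecord("a", 0, "nogo", "withheld", rt=0.4)

    def test_packed_matches_per_trial(self, mid_params, rng):
        is_go, rt = tj.simulate_trials(mid_params, "nogo", 60, rng)
        rts = rt[is_go]
        total = sum(
            tj.trial_loglik(tj.TrialRecord("a", i, "nogo", "go", float(r)), mid_params)
            for i, r in enumerate(rts))
        total += (~is_go).sum() * tj.trial_loglik(
            tj.TrialRecord("a", 0, "nogo", "withheld"), mid_params)
        packed = dataset_trial_loglik([], 0, rts, int((~is_go).sum()), mid_params)
        assert packed == pytest.approx(total, rel=1e-6)

    def test_grid_search_peaks_near_truth(self, rng):
        """Summed log-likelihood over simulated data is maximized near the
        generating go drift on a coarse grid."""
        true = tj.TRDMParams(4.0, 1.0, 3.0, 1.5, 1.0, 0.6, 0.2)
        is_go, rt = tj.simulate_trials(true, "go", 3000, rng)
        rts = rt[is_go]
        nwh = int((~is_go).sum())
        grid = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        lls = []
        for g in grid:
            p = tj.TRDMParams(g, 1.0, 3.0, 1.5, 1.0, 0.6, 0.2)
            lls.append(dataset_trial_loglik(rts, nwh, [], 0, p))
        assert grid[int(np.argmax(lls))] == 4.0


class TestSimulator:
    def test_reproducible_under_seed(self, mid_params):
        a = tj.simulate_trial(mid_params, "go", 99)
        b = tj.simulate_trial(mid_params, "go", 99)
        assert a == b

    def test_dominant_nogo_frequency(self):
        p = tj.TRDMParams(1.0, 0.5, 1000.0, 0.5, 1.0, 1.0, 0.1)
        is_go, _ = tj.simulate_trials(p, "nogo", 10_000, 3)
        assert (~is_go).mean() > 0.995

    def test_outcome_frequencies_match_quadrature(self, random_param_sets):
        for i, p in enumerate(random_param_sets[:3]):
            n = 200_000
            is_go, _ = tj.simulate_trials(p, "nogo", n, 100 + i)
            pn = tj.nogo_response_prob(p, "nogo")
            se = math.sqrt(max(pn * (1 - pn), 1e-9) / n)
            assert abs((~is_go).mean() - pn) < 3 * se + 1e-4

    def test_rt_histogram_matches_density(self, mid_params):
        """Binned go-RT frequencies agree with integrals of the defective
        density (simulator and likelihood describe the same process)."""
        n = 200_000
        is_go, rt = tj.simulate_trials(mid_params, "nogo", n, 42)
        edges = np.array([0.0, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0, 2.0, np.inf])
        grid = np.linspace(1e-4, 12.0, 6001)
        dens = tj.go_response_density(grid, mid_params, "nogo")
        cum = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))])
        for lo, hi in zip(edges[:-1], edges[1:]):
            p_bin = (cum[-1] if np.isinf(hi) else np.interp(hi, grid, cum)) \
                - np.interp(lo, grid, cum)
            if np.isinf(hi):
                p_bin = (1 - tj.nogo_response_prob(mid_params, "nogo")) - np.interp(lo, grid, cum)
            emp = np.mean(is_go & (rt > lo) & (rt <= hi) if not np.isinf(hi)
                          else is_go & (rt > lo))
            se = math.sqrt(max(p_bin * (1 - p_bin), 1e-9) / n)
            assert abs(emp - p_bin) < 4 * se + 2e-4

    def test_guess_bias_splits_timer_wins(self):
        # with a dominant timer, go responses occur at the guess probability
        p = tj.TRDMParams(0.1, 0.1, 0.1, 50.0, 1.0, 0.1, 0.5, guess_go_prob=0.3)
        is_go, _ = tj.simulate_trials(p, "nogo", 50_000, 8)
        assert is_go.mean() == pytest.approx(0.3, abs=0.01)
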
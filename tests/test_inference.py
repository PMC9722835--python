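"""Priors, sampler contracts, and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trdmjoint as tj
from trdmjoint.inference import (PRIOR_MEAN_LOC, PRIOR_MEAN_SCALE, Hyperparams,
                                 PosteriorSamples, SamplerConfig, diagnostics, fit)
from trdmjoint.io import PROBE_COLUMNS, TRIAL_COLUMNS, Dataset


@pytest.fixture
def hyper():
    return Hyperparams(np.array([2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 0.2]),
                       np.array([0.5, 0.5, 0.5, 0.5, 0.3, 0.3, 0.1]))


class TestLogPrior:
    def test_unimodal_in_participant_value(self, hyper):
        at_mean = hyper.group_means.copy()
        away = at_mean + 3 * hyper.group_sds
        assert tj.log_prior(hyper, at_mean) > tj.log_prior(hyper, away)

    def test_out_of_domain_is_minus_inf(self, hyper):
        bad = hyper.group_means.copy()
        bad[4] = -0.5  # negative sigma_E
        assert tj.log_prior(hyper, bad) == -np.inf

    def test_negative_group_sd_rejected(self):
        with pytest.raises(Exception):
            Hyperparams(np.full(7, 1.0), np.array([1, 1, 1, 1, 1, 1, -1.0]))

    def test_closed_form_truncated_normal_term(self, hyper):
        """Difference of log priors at two points isolates one participant
        term, which must match the truncated-normal density ratio."""
        a = hyper.group_means.copy()
        b = a.copy()
        b[0] = 3.1
        mu, sd = hyper.group_means[0], hyper.group_sds[0]
        tn = stats.truncnorm((0 - mu) / sd, np.inf, loc=mu, scale=sd)
        expected = tn.logpdf(b[0]) - tn.logpdf(a[0])
        assert tj.log_prior(hyper, b) - tj.log_prior(hyper, a) == pytest.approx(
            expected, abs=1e-9)


class TestDiagnostics:
    @staticmethod
    def _samples_from_chains(chains):
        """chains: (n_chains, n_draws) for a single scalar parameter mapped
        onto the beta slot."""
        n_chains, n_draws = chains.shape
        sr = np.zeros((n_draws, n_chains, 4))
        sr[:, :, 0] = chains.T
        zeros = np.zeros((n_draws, n_chains))
        return PosteriorSamples(
            np.zeros((n_draws, n_chains, 0, 7)), np.zeros((n_draws, n_chains, 14)),
            sr, zeros, zeros, [], "gamma_nogo_given_nogo", burn=0, config=SamplerConfig())

    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(400)
        s = self._samples_from_chains(np.tile(row, (4, 1)))
        d = diagnostics(s).set_index("parameter")
        assert d.loc["beta", "rhat"] == pytest.approx(1.0, abs=0.02)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 400))
        chains[0] += 5.0
        s = self._samples_from_chains(chains)
        d = diagnostics(s).set_index("parameter")
        assert d.loc["beta", "rhat"] > 1.1

    def test_white_noise_ess_near_draw_count(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 500))
        s = self._samples_from_chains(chains)
        d = diagnostics(s).set_index("parameter")
        assert d.loc["beta", "ess"] == pytest.approx(2000, rel=0.25)


def _empty_dataset():
    return Dataset(pd.DataFrame(columns=TRIAL_COLUMNS).astype({"rt": float}),
                   pd.DataFrame(columns=PROBE_COLUMNS))


class TestFit:
    def test_smoke_tiny_fixture(self, small_joint_dataset):
        """Sampler runs on a 2-participant slice and reports diagnostics."""
        ds, _, spec, _ = small_joint_dataset
        keep = ds.participants[:2]
        sub = Dataset(ds.trials[ds.trials["participant"].isin(keep)],
                      ds.probes[ds.probes["participant"].isin(keep)])
        s = fit(sub, spec, SamplerConfig(n_chains=8, n_iters=60, seed=0))
        d = diagnostics(s)
        assert np.isfinite(d["rhat"]).all()
        assert "rhat_flagged" in s.meta  # non-convergence is flagged, not silent

    def test_deterministic_under_seed(self, small_joint_dataset):
        ds, _, spec, _ = small_joint_dataset
        keep = ds.participants[:2]
        sub = Dataset(ds.trials[ds.trials["participant"].isin(keep)],
                      ds.probes[ds.probes["participant"].isin(keep)])
        cfg = SamplerConfig(n_chains=8, n_iters=40, seed=5)
        a = fit(sub, spec, cfg)
        b = fit(sub, spec, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.selfreport, b.selfreport)

    def test_stored_logliks_reproducible_from_draws(self, small_joint_dataset):
        """PosteriorSamples invariant: stored data log-likelihoods match a
        recomputation from the stored draws."""
        from trdmjoint import _kernels as K
        ds, _, spec, _ = small_joint_dataset
        keep = ds.participants[:2]
        sub = Dataset(ds.trials[ds.trials["participant"].isin(keep)],
                      ds.probes[ds.probes["participant"].isin(keep)])
        s = fit(sub, spec, SamplerConfig(n_chains=8, n_iters=40, seed=1))
        glx, glw = K.gauss_legendre_grid()
        ids, rg, go_off, nwh_g, rn, ng_off, nwh_n, counts = sub.packed()
        it, c = 35, 3
        ll = K.dataset_data_loglik(
            s.theta[it, c], s.selfreport[it, c], rg, go_off, nwh_g, rn, ng_off,
            nwh_n, counts, spec.link_index, 1.0, glx, glw)
        assert s.data_loglik[it, c] == pytest.approx(ll, rel=1e-10)

    def test_empty_dataset_returns_prior(self):
        """With no data the sampler must reproduce the prior."""
        spec = tj.make_variant("gamma_nogo_given_nogo")
        s = fit(_empty_dataset(), spec, SamplerConfig(n_chains=16, n_iters=600, seed=2))
        h = s.hyper_post.reshape(-1, 14)
        sr = s.selfreport_post.reshape(-1, 4)
        # group-mean prior: truncated normal
        mu, sc = PRIOR_MEAN_LOC[0], PRIOR_MEAN_SCALE[0]
        tn = stats.truncnorm(-mu / sc, np.inf, loc=mu, scale=sc)
        assert h[:, 0].mean() == pytest.approx(tn.mean(), abs=0.35)
        assert h[:, 0].std() == pytest.approx(tn.std(), rel=0.2)
        # beta prior: N(0, 2)
        assert sr[:, 0].mean() == pytest.approx(0.0, abs=0.35)
        assert sr[:, 0].std() == pytest.approx(2.0, rel=0.2)
        # group SDs: half-normal(1)
        hn = stats.halfnorm(scale=1.0)
        assert h[:, 7].mean() == pytest.approx(hn.mean(), abs=0.2)

    def test_posterior_contraction_with_more_trials(self):
        """Doubling trials per participant shrinks participant-level drift
        posteriors."""
        spec = tj.make_variant("gamma_nogo_given_nogo")
        hy = tj.default_generating_hyper()
        sds = []
        for n_go, n_nogo, seed in ((50, 10, 0), (200, 40, 0)):
            design = tj.make_design(1, n_participants=4, n_go_trials=n_go,
                                    n_nogo_trials=n_nogo, n_probes=6, min_probe_gap=3)
            ds, _ = tj.generate_dataset(hy, design, spec, 31)
            s = fit(ds, spec, SamplerConfig(n_chains=12, n_iters=300, seed=seed))
            draws = s.participant_draws("gamma_go_given_go")
            sds.append(draws.std(axis=0).mean())
        assert sds[1] < sds[0]

    def test_beta_zero_data_covers_zero(self):
        """Data generated with no link: the beta posterior interval covers 0."""
        spec = tj.make_variant("gamma_nogo_given_nogo")
        hy = tj.default_generating_hyper(beta=0.0)
        design = tj.make_design(1, n_participants=6, n_go_trials=60, n_nogo_trials=12,
                                n_probes=15, min_probe_gap=3)
        ds, _ = tj.generate_dataset(hy, design, spec, 17)
        s = fit(ds, spec, SamplerConfig(n_chains=12, n_iters=500, seed=4))
        draws = s.selfreport_draws()[:, 0]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo < 0.0 < hi
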
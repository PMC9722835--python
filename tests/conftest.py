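import numpy as np
import pandas as pd
import pytest

import trdmjoint as tj


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mid_params():
    """A moderate, well-behaved TRDM parameter point."""
    return tj.TRDMParams(
        gamma_go_given_go=5.0, gamma_go_given_nogo=1.0, gamma_nogo_given_nogo=3.0,
        gamma_T=1.0, sigma_E=1.0, sigma_T=1.0, tau_E=0.2)


@pytest.fixture
def sr_params():
    return tj.SelfReportParams(beta=-0.4, lambda1=-1.0, lambda2=0.0, lambda3=1.0)


@pytest.fixture
def random_param_sets():
    """Randomized but valid TRDM parameter points spanning the useful range."""
    g = np.random.default_rng(777)
    out = []
    for _ in range(5):
        out.append(tj.TRDMParams(
            gamma_go_given_go=g.uniform(0.5, 6), gamma_go_given_nogo=g.uniform(0, 4),
            gamma_nogo_given_nogo=g.uniform(0.5, 6), gamma_T=g.uniform(0.2, 4),
            sigma_E=g.uniform(0.4, 1.8), sigma_T=g.uniform(0.2, 1.2),
            tau_E=g.uniform(0.0, 0.35)))
    return out


@pytest.fixture(scope="session")
def small_joint_dataset():
    """A small joint dataset with known ground truth (8 participants)."""
    spec = tj.make_variant("gamma_nogo_given_nogo")
    design = tj.make_design(1, n_participants=8, n_go_trials=90, n_nogo_trials=18,
                            n_probes=12, min_probe_gap=4)
    hyper = tj.default_generating_hyper()
    ds, truth = tj.generate_dataset(hyper, design, spec, 2024)
    return ds, truth, spec, design
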
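"""Synthetic SART + thought-probe datasets with the two experiments' designs.

Experiment 1: 19 participants, 640 go + 80 nogo trials (digits 1-9, target 3),
20 four-point probes.  Experiment 2: 192 participants, 1000 go + 24 nogo
trials (digits 0-9, target 3), 24 probes, with go responses slower than 1.5 s
removed from analysis.  Nogo trials and probes are placed pseudo-randomly
subject to minimum-spacing constraints (the originals used unspecified "small
windows"; defaults here are 3 trials between nogo stimuli and 10 between
probes, both configurable).

Choices and RTs come from the TRDM race simulator; probe responses come from
the Thurstonian model with the participant link ``psi_i = omega_i * beta``.
Probe placement is independent of simulated performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .inference import Hyperparams
from .io import PROBE_COLUMNS, TRIAL_COLUMNS, Dataset
from .joint import JointModelSpec
from .selfreport import simulate_probes
from .trdm import PARAM_NAMES, TRDMParams, simulate_trials

__all__ = ["DesignSpec", "make_design", "generate_stimulus_sequence",
           "sample_group_params", "generate_dataset", "default_generating_hyper"]


@dataclass(frozen=True)
class DesignSpec:
    """Structural description of one SART session."""

    n_participants: int
    n_go_trials: int
    n_nogo_trials: int
    n_probes: int
    digit_set: tuple = tuple(range(1, 10))
    target_digit: int = 3
    min_nogo_gap: int = 3
    min_probe_gap: int = 10
    rt_ceiling: Optional[float] = None

    def __post_init__(self):
        if min(self.n_participants, self.n_go_trials, self.n_nogo_trials, self.n_probes) <= 0:
            raise ValueError("participant, trial and probe counts must be positive")
        if self.min_nogo_gap < 1 or self.min_probe_gap < 1:
            raise ValueError("spacing gaps must be >= 1")
        if self.target_digit not in self.digit_set:
            raise ValueError("target digit must belong to the digit set")
        if self.rt_ceiling is not None and self.rt_ceiling <= 0:
            raise ValueError("rt_ceiling must be > 0")

    @property
    def n_trials(self) -> int:
        return self.n_go_trials + self.n_nogo_trials


def make_design(experiment=None, **custom) -> DesignSpec:
    """The two experiments' designs, or a fully custom one.

    ``make_design(1)`` -> 19 participants, 640 go + 80 nogo, 20 probes;
    ``make_design(2)`` -> 192 participants, 1000 go + 24 nogo, 24 probes
    with a 1.5 s RT ceiling.  Keyword overrides are applied on top.
    """
    if experiment == 1:
        base = DesignSpec(19, 640, 80, 20, tuple(range(1, 10)), 3)
    elif experiment == 2:
        base = DesignSpec(192, 1000, 24, 24, tuple(range(0, 10)), 3, rt_ceiling=1.5)
    elif experiment is None:
        return DesignSpec(**custom)
    else:
        raise ValueError(f"unknown experiment id {experiment!r}; use 1, 2 or custom fields")
    return replace(base, **custom) if custom else base


def _spaced_positions(n_slots: int, n_events: int, min_gap: int, rng) -> np.ndarray:
    """Uniformly sample ``n_events`` positions in [0, n_slots) with pairwise
    index differences >= ``min_gap``, via the gap-compression bijection."""
    shrink = (n_events - 1) * (min_gap - 1)
    m = n_slots - shrink
    if m < n_events:
        raise ValueError(
            f"infeasible spacing: {n_events} events with gap {min_gap} need "
            f">= {n_events + shrink} slots, have {n_slots}")
    comp = np.sort(rng.choice(m, size=n_events, replace=False))
    return comp + (min_gap - 1) * np.arange(n_events)


def generate_stimulus_sequence(design: DesignSpec, rng_seed):
    """One participant's trial sequence and probe placement.

    Returns ``(stimuli, digits, probe_after)``: per-trial stimulus class
    ('go'/'nogo'), the displayed digit, and the trial indices followed by a
    thought probe.  Exact go/nogo counts; nogo positions (and probe
    positions) respect their minimum spacing and are uniform over admissible
    configurations.
    """
    rng = np.random.default_rng(rng_seed)
    n = design.n_trials
    nogo_pos = _spaced_positions(n, design.n_nogo_trials, design.min_nogo_gap, rng)
    probe_after = _spaced_positions(n, design.n_probes, design.min_probe_gap, rng)
    stimuli = np.full(n, "go", dtype=object)
    stimuli[nogo_pos] = "nogo"
    nontargets = [d for d in design.digit_set if d != design.target_digit]
    digits = rng.choice(nontargets, size=n)
    digits[nogo_pos] = design.target_digit
    return stimuli, digits, probe_after


def sample_group_params(hyper: Hyperparams, n_participants: int, rng_seed,
                        guess_go_prob: float = 1.0) -> list[TRDMParams]:
    """Draw participant TRDM parameter vectors from the truncated-normal
    group distributions."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_participants):
        vec = np.empty(7)
        for k in range(7):
            mu, sd = hyper.group_means[k], hyper.group_sds[k]
            a = (0.0 - mu) / sd
            vec[k] = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
        vec[4:6] = np.maximum(vec[4:6], 1e-6)
        out.append(TRDMParams.from_vector(vec, guess_go_prob=guess_go_prob))
    return out


def default_generating_hyper(beta: float = -0.4) -> Hyperparams:
    """Group-level values used as the default generating truth.

    Chosen to reproduce the SART's descriptive signature: mean go RT near
    0.35 s with a fast, skewed distribution, a few percent of omissions on go
    trials, commission-error proportions averaging near 0.55 with wide
    individual spread, and bow-shaped probe response profiles.  The default
    link scaling ``beta = -0.4`` makes higher nogo-detection rates go with
    more on-task reports.
    """
    means = np.array([5.0, 1.8, 4.2, 2.5, 1.0, 0.6, 0.18])
    sds = np.array([0.8, 0.6, 1.0, 0.5, 0.15, 0.15, 0.04])
    return Hyperparams(means, sds, beta=beta, lambda1=-2.6, d2=1.0, d3=1.0)


def generate_dataset(hyper: Hyperparams, design: DesignSpec, spec: JointModelSpec,
                     rng_seed) -> tuple[Dataset, dict]:
    """Simulate a full joint dataset plus its ground truth.

    Returns ``(dataset, truth)`` where ``truth`` holds the generating
    hyperparameters, every participant's TRDM vector and latent probe mean —
    enough to recompute the exact joint log-likelihood of the generated data.
    An ``rt_ceiling`` in the design is applied as trial removal, as in the
    second experiment's preprocessing.
    """
    rng = np.random.default_rng(rng_seed)
    sr = hyper.selfreport_params()
    params = sample_group_params(hyper, design.n_participants, rng)
    trial_rows, probe_rows = [], []
    psis = {}
    for i, th in enumerate(params):
        pid = f"p{i + 1:03d}"
        stimuli, digits, probe_after = generate_stimulus_sequence(design, rng)
        for stim_class in ("go", "nogo"):
            idx = np.flatnonzero(stimuli == stim_class)
            is_go, rt = simulate_trials(th, stim_class, len(idx), rng)
            for j, tr in enumerate(idx):
                if is_go[j]:
                    trial_rows.append((pid, int(tr), stim_class, "go", float(rt[j])))
                else:
                    trial_rows.append((pid, int(tr), stim_class, "withheld", np.nan))
        omega = getattr(th, spec.link_target)
        psi = omega * sr.beta
        psis[pid] = psi
        responses = simulate_probes(psi, sr.epsilon, sr.cutpoints, design.n_probes, rng)
        for tr, resp in zip(probe_after, responses):
            probe_rows.append((pid, int(tr), int(resp)))
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS).sort_values(
        ["participant", "trial"], kind="stable")
    probes = pd.DataFrame(probe_rows, columns=PROBE_COLUMNS)
    ds = Dataset(trials, probes, {"generator_seed": rng_seed, "design": design,
                                  "link_target": spec.link_target})
    n_removed = 0
    if design.rt_ceiling is not None:
        from .io import filter_slow_trials
        ds, report = filter_slow_trials(ds, design.rt_ceiling)
        n_removed = report.n_removed
    truth = {
        "hyper": hyper,
        "selfreport": sr,
        "link_target": spec.link_target,
        "params": {f"p{i + 1:03d}": th for i, th in enumerate(params)},
        "psi": psis,
        "n_slow_removed": n_removed,
    }
    return ds, truth


def truth_table(truth: dict) -> pd.DataFrame:
    """Ground-truth participant parameters as a table (for export)."""
    rows = []
    for pid, th in truth["params"].items():
        rows.append((pid, *th.free_vector(), truth["psi"][pid]))
    return pd.DataFrame(rows, columns=["participant", *PARAM_NAMES, "psi"])
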
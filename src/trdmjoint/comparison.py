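"""Deviance Information Criterion and six-way model ranking.

Deviance is ``D(theta) = -2 log L`` of the joint data (SART + probes).  The
hierarchical DIC here uses the conditional focus: the deviance is a function
of the participant-level parameters and the group-level self-report block,
the levels at which the scientific claims live.  ``Dbar`` averages deviance
over post-burn-in draws; ``D(theta_bar)`` plugs in posterior means;
``pD = Dbar - D(theta_bar)``; ``DIC = Dbar + pD``.  Lower is better.

The plug-in point is taken on the scale the likelihood consumes: posterior
means of the participant TRDM vectors, of the per-participant latent probe
means ``psi_i = omega_i * beta``, and of the cut points.  Averaging
``omega`` and ``beta`` separately and then multiplying would charge linked
models for the posterior correlation between the two factors (pD is
parameterization-dependent); the product scale is the invariant choice here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .inference import PosteriorSamples
from .io import Dataset
from .joint import JointModelSpec

__all__ = ["DICResult", "dic", "compare"]

_GLX, _GLW = K.gauss_legendre_grid()


@dataclass(frozen=True)
class DICResult:
    """DIC decomposition for one fitted model variant."""

    label: str
    dbar: float
    d_at_mean: float
    data_hash: str = ""

    @property
    def pd(self) -> float:
        """Effective number of parameters."""
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def dic(samples: PosteriorSamples, dataset: Dataset, spec: JointModelSpec) -> DICResult:
    """DIC of one fitted variant on the dataset it was fitted to."""
    if spec.link_target != samples.link_target:
        raise ValueError(
            f"samples were drawn for link {samples.link_target!r}, not {spec.link_target!r}")
    if samples.meta.get("data_hash") and samples.meta["data_hash"] != dataset.content_hash():
        raise ValueError("samples were not fitted to this dataset")
    dbar = float(-2.0 * samples.data_loglik_post.mean())
    theta_bar, _ = samples.posterior_mean_state()
    ids, rg, go_off, nwh_g, rn, ng_off, nwh_n, counts = dataset.packed(samples.participants)
    ll_at_mean = 0.0
    for i in range(len(ids)):
        ll_at_mean += K.participant_trial_loglik(
            theta_bar[i], rg[go_off[i]:go_off[i + 1]], nwh_g[i],
            rn[ng_off[i]:ng_off[i + 1]], nwh_n[i],
            samples.config.guess_go_prob, _GLX, _GLW)
    # probe plug-in on the psi / cut-point scale
    sr_draws = samples.selfreport_draws()
    lam_bar = np.mean(np.column_stack([
        sr_draws[:, 1], sr_draws[:, 1] + sr_draws[:, 2],
        sr_draws[:, 1] + sr_draws[:, 2] + sr_draws[:, 3]]), axis=0)
    omega_draws = samples.participant_draws(spec.link_target)
    psi_bar = (omega_draws * sr_draws[:, [0]]).mean(axis=0)
    for i in range(len(ids)):
        ll_at_mean += K.probe_loglik_counts(counts[i], psi_bar[i], 1.0,
                                            lam_bar[0], lam_bar[1], lam_bar[2])
    return DICResult(samples.link_target, dbar, float(-2.0 * ll_at_mean),
                     samples.meta.get("data_hash", ""))


def dic_from_deviances(deviance_draws, deviance_at_mean: float, label: str = "") -> DICResult:
    """DIC directly from deviance draws and the plug-in deviance."""
    return DICResult(label, float(np.mean(deviance_draws)), float(deviance_at_mean))


def compare(fits: list[DICResult]) -> pd.DataFrame:
    """Rank fitted variants by DIC, zero-referenced to the best.

    All fits must be on identical data.  Exact DIC ties are broken by label
    order and flagged in the ``tied`` column.
    """
    if len(fits) < 2:
        raise ValueError("compare needs at least two fitted models")
    hashes = {f.data_hash for f in fits if f.data_hash}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    ordered = sorted(fits, key=lambda f: (f.dic, f.label))
    best = ordered[0].dic
    dics = [f.dic for f in fits]
    rows = [(f.label, f.dic - best, f.dic, f.dbar, f.pd, dics.count(f.dic) > 1)
            for f in ordered]
    return pd.DataFrame(rows, columns=["label", "delta_dic", "dic", "dbar", "pd", "tied"])


def comparison_table(results: list[tuple[DICResult, PosteriorSamples]]) -> pd.DataFrame:
    """Ranked comparison with the scaling coefficient per variant.

    One row per variant: hypothesis label, delta DIC, and the posterior mean
    and central 95% interval of beta.
    """
    from .joint import LINK_LABELS

    table = compare([r for r, _ in results])
    by_label = {r.label: s for r, s in results}
    betas, lo, hi, hyp = [], [], [], []
    for label in table["label"]:
        draws = by_label[label].selfreport_draws()[:, 0]
        betas.append(draws.mean())
        lo.append(np.percentile(draws, 2.5))
        hi.append(np.percentile(draws, 97.5))
        hyp.append(LINK_LABELS.get(label, label))
    table = table.assign(hypothesis=hyp, beta_mean=betas, beta_q2_5=lo, beta_q97_5=hi)
    return table[["hypothesis", "label", "delta_dic", "beta_mean", "beta_q2_5", "beta_q97_5",
                  "dic", "dbar", "pd", "tied"]]
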
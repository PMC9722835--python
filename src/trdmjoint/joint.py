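"""Joint model variants binding one TRDM parameter to probe responding.

Six variants, one per linkable TRDM parameter; each names the hypothesis it
operationalizes about what self-reported mind wandering reflects.  The
non-decision time is deliberately not linkable.  The joint log-likelihood of
a participant is the sum of the SART stream (race likelihood) and the probe
stream (ordinal probit with latent mean ``psi_i = omega_i * beta``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from . import selfreport as sr
from . import trdm
from .errors import DataIntegrityError
from .trdm import PARAM_NAMES, TRDMParams

__all__ = ["JointModelSpec", "LINK_TARGETS", "LINK_LABELS", "make_variant",
           "participant_joint_loglik"]

#: The six linkable TRDM parameters, with the hypothesis each link encodes.
LINK_LABELS = {
    "gamma_nogo_given_nogo": "executive control & selective attention to rare events",
    "gamma_go_given_nogo": "executive control & failure of selective attention to rare events",
    "sigma_E": "volatility of task-relevant information processing",
    "gamma_T": "executive control & selective attention to temporal information",
    "gamma_go_given_go": "selective attention to common events",
    "sigma_T": "volatility of temporal processing",
}

LINK_TARGETS = tuple(LINK_LABELS)


@dataclass(frozen=True)
class JointModelSpec:
    """Which TRDM parameter is the link target, plus self-report parameters."""

    link_target: str
    selfreport: Optional[sr.SelfReportParams] = None
    label: str = ""

    def __post_init__(self):
        if self.link_target not in LINK_TARGETS:
            raise ValueError(
                f"link_target must be one of {sorted(LINK_TARGETS)}, got {self.link_target!r}")

    @property
    def link_index(self) -> int:
        """Index of the link target in the canonical 7-parameter order."""
        return PARAM_NAMES.index(self.link_target)

    def omega(self, params: TRDMParams) -> float:
        """The linked parameter's value for one participant."""
        return getattr(params, self.link_target)

    def with_selfreport(self, params: sr.SelfReportParams) -> "JointModelSpec":
        return replace(self, selfreport=params)


def make_variant(link_target: str, selfreport: Optional[sr.SelfReportParams] = None
                 ) -> JointModelSpec:
    """Build one of the six joint-model variants.

    Any other name — in particular ``tau_E`` — is rejected.
    """
    return JointModelSpec(link_target, selfreport, LINK_LABELS[link_target]
                          if link_target in LINK_LABELS else "")


def participant_joint_loglik(trials, probes, trdm_params: TRDMParams,
                             spec: JointModelSpec) -> float:
    """Joint log-likelihood of one participant's SART trials and probes.

    ``trials``: iterable of TrialRecord; ``probes``: iterable of ProbeRecord;
    all must belong to a single participant.  With no probes this reduces
    exactly to the TRDM-only log-likelihood.
    """
    trials = list(trials)
    probes = list(probes)
    pids = {t.participant for t in trials} | {p.participant for p in probes}
    if len(pids) > 1:
        raise DataIntegrityError(f"records span multiple participants: {sorted(map(str, pids))}")
    ll = 0.0
    for t in trials:
        ll += trdm.trial_loglik(t, trdm_params)
    if probes:
        if spec.selfreport is None:
            raise ValueError("spec.selfreport is required when probes are present")
        p = spec.selfreport
        psi = sr.link_mean(spec.omega(trdm_params), p.beta)
        for probe in probes:
            ll += sr.probe_loglik(probe.response, psi, p.epsilon, p.cutpoints)
    return ll
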
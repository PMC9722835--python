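"""Thurstonian ordinal-probit model of thought-probe responses.

A participant's propensity to mind wander lives on a latent normal continuum.
When probed, the participant samples ``z ~ N(psi, epsilon)`` and reports the
Likert category (1-4) whose bin, delimited by three ordered group-level cut
points ``lambda_1 < lambda_2 < lambda_3``, contains the sample.  The latent
mean is structurally linked to a TRDM parameter: ``psi_i = omega_i * beta``,
with ``beta`` estimated at the group level.

The triple (beta, cut points, epsilon) is only identified up to a common
positive rescaling, so ``epsilon`` is fixed to 1 by convention; a
participant-specific epsilon can be supplied but is not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DataIntegrityError, ParameterDomainError

__all__ = [
    "SelfReportParams",
    "ProbeRecord",
    "link_mean",
    "probe_probs",
    "probe_loglik",
    "simulate_probe",
    "simulate_probes",
]

N_CATEGORIES = 4


@dataclass(frozen=True)
class SelfReportParams:
    """Group-level self-report parameters: scaling ``beta``, ordered cut
    points, and the latent SD ``epsilon`` (1 by the probit-scale convention)."""

    beta: float
    lambda1: float
    lambda2: float
    lambda3: float
    epsilon: float = 1.0

    def __post_init__(self):
        if not (self.lambda1 < self.lambda2 < self.lambda3):
            raise ParameterDomainError("cut points must satisfy lambda1 < lambda2 < lambda3")
        if self.epsilon <= 0:
            raise ParameterDomainError("epsilon must be > 0")

    @property
    def cutpoints(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])

    @classmethod
    def from_increments(cls, beta, lambda1, d2, d3, epsilon=1.0) -> "SelfReportParams":
        """Build from lambda1 plus two positive increments (sampler
        parameterization that enforces the ordering)."""
        if d2 <= 0 or d3 <= 0:
            raise ParameterDomainError("cut-point increments must be > 0")
        return cls(beta, lambda1, lambda1 + d2, lambda1 + d2 + d3, epsilon)


@dataclass(frozen=True)
class ProbeRecord:
    """One thought-probe event: a four-point Likert response."""

    participant: object
    trial_index: int
    response: int

    def __post_init__(self):
        if self.response not in (1, 2, 3, 4):
            raise DataIntegrityError(f"probe response must be in 1..4, got {self.response!r}")
        if self.trial_index < 0:
            raise DataIntegrityError("trial_index must be >= 0")


def link_mean(omega: float, beta: float) -> float:
    """Latent mind-wandering mean: psi = omega * beta."""
    return omega * beta


def _check_cutpoints(cutpoints):
    c = np.asarray(cutpoints, float)
    if c.shape != (3,) or not (c[0] < c[1] < c[2]):
        raise ParameterDomainError("cut points must be three strictly increasing values")
    return c


def probe_probs(psi: float, epsilon: float, cutpoints) -> np.ndarray:
    """Probability of each Likert category given the latent mean.

    ``p_k = Phi((lambda_k - psi)/eps) - Phi((lambda_{k-1} - psi)/eps)`` with
    lambda_0 = -inf and lambda_4 = +inf.
    """
    if epsilon <= 0:
        raise ParameterDomainError("epsilon must be > 0")
    c = _check_cutpoints(cutpoints)
    z = (c - psi) / epsilon
    cdf = special.ndtr(z)
    p = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return np.clip(p, 0.0, 1.0)


def probe_loglik(response: int, psi: float, epsilon: float, cutpoints) -> float:
    """Log probability of one probe response, stable for extreme psi."""
    if response not in (1, 2, 3, 4):
        raise DataIntegrityError(f"probe response must be in 1..4, got {response!r}")
    if epsilon <= 0:
        raise ParameterDomainError("epsilon must be > 0")
    c = _check_cutpoints(cutpoints)
    z = (c - psi) / epsilon
    if response == 1:
        return float(special.log_ndtr(z[0]))
    if response == 4:
        return float(special.log_ndtr(-z[2]))
    lo, hi = z[response - 2], z[response - 1]
    # Phi(hi) - Phi(lo) via the smaller tail for accuracy far from 0
    if lo + hi > 0:
        l_hi, l_lo = special.log_ndtr(-lo), special.log_ndtr(-hi)
    else:
        l_hi, l_lo = special.log_ndtr(hi), special.log_ndtr(lo)
    d = l_lo - l_hi
    if d >= 0:
        return -np.inf
    return float(l_hi + np.log1p(-np.exp(d)))


def simulate_probes(psi: float, epsilon: float, cutpoints, n: int, rng) -> np.ndarray:
    """Draw ``n`` probe responses by binning latent normal samples."""
    rng = np.random.default_rng(rng)
    c = _check_cutpoints(cutpoints)
    if epsilon <= 0:
        raise ParameterDomainError("epsilon must be > 0")
    z = rng.normal(psi, epsilon, size=n)
    return 1 + np.searchsorted(c, z, side="left").astype(np.int64)


def simulate_probe(psi: float, epsilon: float, cutpoints, rng_seed) -> int:
    """Draw one probe response."""
    return int(simulate_probes(psi, epsilon, cutpoints, 1, rng_seed)[0])
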
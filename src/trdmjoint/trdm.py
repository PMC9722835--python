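"""Timed racing diffusion model (TRDM) of go/nogo performance.

The model races three single-boundary diffusion processes: a go and a nogo
evidence accumulator (shared moment-to-moment SD ``sigma_E``, shared threshold
``alpha_E = 1``, onset shifted by the non-decision time ``tau_E``) and a
timing accumulator (drift ``gamma_T``, SD ``sigma_T``, threshold
``alpha_T = 1``, onset at stimulus presentation).  The first accumulator to
reach threshold determines the outcome: go-accumulator win -> go response at
its finishing time; nogo-accumulator win -> response withheld; timer win ->
the evidence race is abandoned and a guess is emitted, biased toward "go"
with probability ``guess_go_prob`` (1 by default, i.e. always go).

Each single-accumulator first-passage time is Wald (inverse-Gaussian)
distributed; zero drift is legal and yields the heavy-tailed Levy limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, special

from ._kernels import gauss_legendre_grid, nogo_prob_gl, participant_trial_loglik
from .errors import DataIntegrityError, NumericalError, ParameterDomainError

__all__ = [
    "TRDMParams",
    "TrialRecord",
    "PARAM_NAMES",
    "wald_pdf",
    "wald_cdf",
    "wald_sf",
    "go_response_density",
    "nogo_response_prob",
    "trial_loglik",
    "simulate_trial",
    "simulate_trials",
]

#: Canonical order of the seven estimated participant-level parameters.
PARAM_NAMES = (
    "gamma_go_given_go",
    "gamma_go_given_nogo",
    "gamma_nogo_given_nogo",
    "gamma_T",
    "sigma_E",
    "sigma_T",
    "tau_E",
)

_GLX, _GLW = gauss_legendre_grid()


@dataclass(frozen=True)
class TRDMParams:
    """Per-participant TRDM parameter vector.

    Seven free parameters (drift rates in evidence units per second, SDs of
    moment-to-moment noise, non-decision time in seconds) plus the fixed
    constants that identify the model: ``gamma_nogo_given_go = 0``,
    ``tau_T = 0`` s, ``alpha_E = alpha_T = 1``.
    """

    gamma_go_given_go: float
    gamma_go_given_nogo: float
    gamma_nogo_given_nogo: float
    gamma_T: float
    sigma_E: float
    sigma_T: float
    tau_E: float
    guess_go_prob: float = 1.0

    # fixed constants, never touched by inference
    gamma_nogo_given_go: float = field(default=0.0, init=False, repr=False)
    tau_T: float = field(default=0.0, init=False, repr=False)
    alpha_E: float = field(default=1.0, init=False, repr=False)
    alpha_T: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self):
        for name in ("gamma_go_given_go", "gamma_go_given_nogo",
                     "gamma_nogo_given_nogo", "gamma_T"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be >= 0")
        if self.sigma_E <= 0 or self.sigma_T <= 0:
            raise ParameterDomainError("sigma_E and sigma_T must be > 0")
        if self.tau_E < 0:
            raise ParameterDomainError("tau_E must be >= 0")
        if not 0.0 <= self.guess_go_prob <= 1.0:
            raise ParameterDomainError("guess_go_prob must lie in [0, 1]")

    def free_vector(self) -> np.ndarray:
        """The seven estimated parameters in canonical order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_vector(cls, vec, guess_go_prob: float = 1.0) -> "TRDMParams":
        vec = np.asarray(vec, float)
        if vec.shape != (7,):
            raise ParameterDomainError("parameter vector must have length 7")
        return cls(*vec, guess_go_prob=guess_go_prob)

    def drifts_for(self, stimulus: str) -> tuple[float, float]:
        """(go-accumulator drift, nogo-accumulator drift) for a stimulus class."""
        if stimulus == "go":
            return self.gamma_go_given_go, self.gamma_nogo_given_go
        if stimulus == "nogo":
            return self.gamma_go_given_nogo, self.gamma_nogo_given_nogo
        raise DataIntegrityError(f"unknown stimulus class {stimulus!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One SART trial: stimulus class, response, and RT for go responses."""

    participant: object
    trial_index: int
    stimulus: str
    response: str
    rt: Optional[float] = None

    def __post_init__(self):
        if self.stimulus not in ("go", "nogo"):
            raise DataIntegrityError(f"stimulus must be 'go' or 'nogo', got {self.stimulus!r}")
        if self.response not in ("go", "withheld"):
            raise DataIntegrityError(f"response must be 'go' or 'withheld', got {self.response!r}")
        if self.trial_index < 0:
            raise DataIntegrityError("trial_index must be >= 0")
        if self.response == "go":
            if self.rt is None or not np.isfinite(self.rt) or self.rt <= 0:
                raise DataIntegrityError("go responses require a finite rt > 0")
        elif self.rt is not None:
            raise DataIntegrityError("withheld trials carry no rt")


def _check_wald_args(sigma, alpha, gamma):
    if np.any(np.asarray(sigma) <= 0):
        raise ParameterDomainError("sigma must be > 0")
    if np.any(np.asarray(alpha) <= 0):
        raise ParameterDomainError("alpha must be > 0")
    if np.any(np.asarray(gamma) < 0):
        raise ParameterDomainError("gamma must be >= 0")


def wald_pdf(t, gamma, sigma, alpha=1.0):
    """First-passage density of a drift-``gamma`` diffusion to level ``alpha``.

    ``alpha / (sigma * sqrt(2 pi t^3)) * exp(-(alpha - gamma t)^2 / (2 sigma^2 t))``
    for t > 0, and 0 otherwise.  Vectorized over ``t``.
    """
    _check_wald_args(sigma, alpha, gamma)
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    m = t > 0
    tm = t[m]
    d = alpha - gamma * tm
    out[m] = alpha / (sigma * np.sqrt(2.0 * np.pi * tm**3)) * np.exp(
        -d * d / (2.0 * sigma * sigma * tm))
    return float(out[0]) if scalar else out


def wald_sf(t, gamma, sigma, alpha=1.0):
    """Survivor function 1 - CDF of the first-passage time, log-stable."""
    _check_wald_args(sigma, alpha, gamma)
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.ones_like(t)
    m = t > 0
    tm = t[m]
    st = sigma * np.sqrt(tm)
    l1 = special.log_ndtr((alpha - gamma * tm) / st)
    l2 = 2.0 * alpha * gamma / (sigma * sigma) + special.log_ndtr(-(gamma * tm + alpha) / st)
    d = l2 - l1
    out[m] = np.where(d < 0, np.exp(l1) * (-np.expm1(np.minimum(d, 0.0))), 0.0)
    return float(out[0]) if scalar else out


def wald_cdf(t, gamma, sigma, alpha=1.0):
    """CDF of the first-passage time; the exp(2 alpha gamma / sigma^2) factor
    is evaluated in log space so large drifts do not overflow."""
    s = wald_sf(t, gamma, sigma, alpha)
    return 1.0 - s


def go_response_density(t, params: TRDMParams, stimulus: str):
    """Defective density of a go response at time ``t`` from stimulus onset.

    Sum of the evidence-race term (go accumulator finishes first) and the
    timer-guess term (timer finishes first and the guess is "go").
    Integrates over t to P(go response | stimulus), not to 1.
    """
    g_go, g_nogo = params.drifts_for(stimulus)
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    te = t - params.tau_E
    s_e, s_t = params.sigma_E, params.sigma_T
    race = wald_pdf(te, g_go, s_e) * wald_sf(te, g_nogo, s_e) * wald_sf(t, params.gamma_T, s_t)
    guess = params.guess_go_prob * wald_pdf(t, params.gamma_T, s_t) \
        * wald_sf(te, g_go, s_e) * wald_sf(te, g_nogo, s_e)
    out = race + guess
    return float(out[0]) if scalar else out


def nogo_response_prob(params: TRDMParams, stimulus: str, method: str = "quadrature",
                       tol: float = 1e-6) -> float:
    """Probability the response is withheld on a trial of the given class.

    ``method="quadrature"`` (default) integrates the nogo-win density
    adaptively on a log-time axis; ``method="complement"`` returns
    1 - integral of :func:`go_response_density`.
    """
    g_go, g_nogo = params.drifts_for(stimulus)
    s_e, s_t, tau_e, g_t = params.sigma_E, params.sigma_T, params.tau_E, params.gamma_T
    lo, hi = math.log(1e-9), math.log(1e5)

    def _log_modes(pairs):
        """Breakpoints at each component density's mode so the adaptive rule
        cannot step over a narrow first-passage spike."""
        pts = []
        for g, s in pairs:
            if g < 1e-8:
                m = 1.0 / (3.0 * s * s)
            else:
                mu = 1.0 / g
                z = 1.5 * mu * s * s
                m = mu * (math.sqrt(1.0 + z * z) - z)
            pts.append(min(max(math.log(m), lo + 1e-6), hi - 1e-6))
        return sorted(pts)

    if method == "complement":
        def f(x):
            t = math.exp(x)
            return float(go_response_density(t, params, stimulus)) * t
        pts = _log_modes([(g_go, s_e), (g_t, s_t)])
        v, err = integrate.quad(f, lo, hi, limit=400, epsabs=tol * 1e-2, points=pts)
        if err > tol:
            raise NumericalError(f"go-density quadrature error {err:.2e} exceeds {tol:.1e}")
        return min(max(1.0 - v, 0.0), 1.0)
    if method != "quadrature":
        raise ValueError("method must be 'quadrature' or 'complement'")

    def f(x):
        u = math.exp(x)
        return float(
            wald_pdf(u, g_nogo, s_e) * wald_sf(u, g_go, s_e) * wald_sf(u + tau_e, g_t, s_t)) * u

    v, err = integrate.quad(f, lo, hi, limit=400, epsabs=tol * 1e-2,
                            points=_log_modes([(g_nogo, s_e)]))
    if err > tol:
        raise NumericalError(f"nogo-probability quadrature error {err:.2e} exceeds {tol:.1e}")
    if params.guess_go_prob < 1.0:
        def f2(x):
            t = math.exp(x)
            te = t - tau_e
            return float(wald_pdf(t, g_t, s_t) * wald_sf(te, g_go, s_e)
                         * wald_sf(te, g_nogo, s_e)) * t
        v2, err2 = integrate.quad(f2, lo, hi, limit=400, epsabs=tol * 1e-2,
                                  points=_log_modes([(g_t, s_t)]))
        if err2 > tol:
            raise NumericalError(f"timer-guess quadrature error {err2:.2e} exceeds {tol:.1e}")
        v += (1.0 - params.guess_go_prob) * v2
    return min(max(v, 0.0), 1.0)


def trial_loglik(trial: TrialRecord, params: TRDMParams) -> float:
    """Log-likelihood of one observed trial; -inf for zero-density outcomes."""
    if trial.response == "go":
        d = go_response_density(trial.rt, params, trial.stimulus)
        return math.log(d) if d > 0 else -math.inf
    p = _nogo_prob_fast(params, trial.stimulus)
    return math.log(p) if p > 0 else -math.inf


def _nogo_prob_fast(params: TRDMParams, stimulus: str) -> float:
    g_go, g_nogo = params.drifts_for(stimulus)
    return nogo_prob_gl(g_go, g_nogo, params.gamma_T, params.sigma_E, params.sigma_T,
                        params.tau_E, params.guess_go_prob, _GLX, _GLW)


def dataset_trial_loglik(rts_go, n_withheld_go, rts_nogo, n_withheld_nogo,
                         params: TRDMParams) -> float:
    """Summed SART log-likelihood for one participant from packed arrays."""
    return float(participant_trial_loglik(
        params.free_vector(), np.asarray(rts_go, float), int(n_withheld_go),
        np.asarray(rts_nogo, float), int(n_withheld_nogo),
        params.guess_go_prob, _GLX, _GLW))


def _first_passage(gamma, sigma, size, rng):
    """Sample unit-threshold first-passage times (inverse Gaussian; Levy at
    gamma = 0), vectorized via Michael-Schucany-Haas."""
    z = rng.standard_normal(size)
    if gamma == 0.0:
        return 1.0 / (sigma * sigma * z * z)
    mu = 1.0 / gamma
    lam = 1.0 / (sigma * sigma)
    y = z * z
    x = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * y + (mu * y) ** 2)
    u = rng.random(size)
    return np.where(u <= mu / (mu + x), x, mu * mu / x)


def simulate_trials(params: TRDMParams, stimulus: str, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials of one stimulus class.

    Returns ``(is_go_response, rt)``; rt is NaN on withheld trials.
    """
    rng = np.random.default_rng(rng)
    g_go, g_nogo = params.drifts_for(stimulus)
    t_go = params.tau_E + _first_passage(g_go, params.sigma_E, n, rng)
    t_nogo = params.tau_E + _first_passage(g_nogo, params.sigma_E, n, rng)
    t_tim = _first_passage(params.gamma_T, params.sigma_T, n, rng)
    times = np.column_stack([t_go, t_nogo, t_tim])
    winner = np.argmin(times, axis=1)
    # exact ties are measure-zero; break uniformly at random
    ties = (times == times.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        for j in np.flatnonzero(ties):
            cands = np.flatnonzero(times[j] == times[j].min())
            winner[j] = rng.choice(cands)
    guess_go = rng.random(n) < params.guess_go_prob
    is_go = (winner == 0) | ((winner == 2) & guess_go)
    rt = np.where(winner == 0, t_go, np.where((winner == 2) & guess_go, t_tim, np.nan))
    return is_go, rt


def simulate_trial(params: TRDMParams, stimulus: str, rng_seed) -> tuple[str, Optional[float]]:
    """Simulate a single trial; returns ('go', rt) or ('withheld', None)."""
    is_go, rt = simulate_trials(params, stimulus, 1, rng_seed)
    if is_go[0]:
        return "go", float(rt[0])
    return "withheld", None
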
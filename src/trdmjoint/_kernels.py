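"""Numba kernels for the race likelihood and the blocked DE-MCMC sampler.

Everything here works on the unit-threshold scale (alpha = 1), which is the
scale the model is estimated on.  Public, validated entry points live in
:mod:`trdmjoint.trdm` and :mod:`trdmjoint.inference`; these kernels are the
hot loops behind them.

Participant-level parameter vectors follow the canonical order
``(gamma_go_given_go, gamma_go_given_nogo, gamma_nogo_given_nogo, gamma_T,
sigma_E, sigma_T, tau_E)``.
"""

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# Base Gauss-Legendre rule on [-1, 1] for the withheld-response integral.
# The kernel lays three copies on the log-time axis — one zoomed onto the
# winning density's mode — so narrow first-passage spikes are resolved.
_GL_N = 48
_GL_LO = math.log(1e-7)
_GL_HI = math.log(1e4)


def gauss_legendre_grid():
    """Base nodes and weights on [-1, 1] for the composite quadrature."""
    return np.polynomial.legendre.leggauss(_GL_N)


@njit(cache=True)
def _wald_log_mode(gamma, sigma):
    """log of the unit-threshold first-passage density mode."""
    if gamma < 1e-8:
        return math.log(1.0 / (3.0 * sigma * sigma))
    mu = 1.0 / gamma
    z = 1.5 * mu * sigma * sigma
    return math.log(mu * (math.sqrt(1.0 + z * z) - z))


@njit(cache=True)
def _log_spread(gamma, sigma):
    """Approximate SD of log first-passage time (the CV for fast passages);
    sets the zoom width of the composite quadrature."""
    if gamma < 1e-8:
        return 2.0
    cv = sigma / math.sqrt(gamma)
    if cv > 2.0:
        return 2.0
    return cv


@njit(cache=True)
def log_ndtr(x):
    """log of the standard normal CDF, stable into the deep lower tail."""
    if x > -1.0:
        return math.log1p(-0.5 * math.erfc(x / _SQRT2))
    v = 0.5 * math.erfc(-x / _SQRT2)
    if v > 0.0:
        return math.log(v)
    return -0.5 * x * x - math.log(-x) - _LOG_SQRT_2PI


@njit(cache=True)
def wald_logpdf(t, gamma, sigma):
    """Log first-passage density of drift-gamma diffusion to unit threshold."""
    if t <= 0.0:
        return -np.inf
    d = 1.0 - gamma * t
    return -1.5 * math.log(t) - _LOG_SQRT_2PI - math.log(sigma) - d * d / (2.0 * sigma * sigma * t)


@njit(cache=True)
def wald_logsf(t, gamma, sigma):
    """Log survivor of the unit-threshold first-passage time."""
    if t <= 0.0:
        return 0.0
    st = sigma * math.sqrt(t)
    l1 = log_ndtr((1.0 - gamma * t) / st)
    l2 = 2.0 * gamma / (sigma * sigma) + log_ndtr(-(gamma * t + 1.0) / st)
    d = l2 - l1
    if d >= 0.0:
        return -np.inf
    return l1 + math.log1p(-math.exp(d))


@njit(cache=True)
def go_logdens(t, g_go, g_nogo, g_t, s_e, s_t, tau_e, pguess):
    """Log defective density of a go response at time t from stimulus onset.

    Race term: go evidence accumulator finishes at t (shifted by tau_e) while
    the nogo accumulator and the timer are still running.  Guess term: the
    timer finishes at t (unshifted) before either evidence accumulator, and
    the guess comes out "go" with probability pguess.
    """
    te = t - tau_e
    l1 = -np.inf
    if te > 0.0:
        l1 = wald_logpdf(te, g_go, s_e) + wald_logsf(te, g_nogo, s_e) + wald_logsf(t, g_t, s_t)
    l2 = -np.inf
    if pguess > 0.0 and t > 0.0:
        l2 = math.log(pguess) + wald_logpdf(t, g_t, s_t)
        if te > 0.0:
            l2 += wald_logsf(te, g_go, s_e) + wald_logsf(te, g_nogo, s_e)
    if l1 == -np.inf:
        return l2
    if l2 == -np.inf:
        return l1
    m = l1 if l1 > l2 else l2
    return m + math.log(math.exp(l1 - m) + math.exp(l2 - m))


@njit(cache=True)
def _race_integral_nogo_win(g_go, g_nogo, g_t, s_e, s_t, tau_e, glx, glw):
    """∫ g_E(u; g_nogo) S_E(u; g_go) S_T(u + tau_e) du on a composite grid
    whose middle segment brackets the mode of the winning density."""
    c = _wald_log_mode(g_nogo, s_e)
    if c < _GL_LO + 0.1:
        c = _GL_LO + 0.1
    elif c > _GL_HI - 0.1:
        c = _GL_HI - 0.1
    w = 10.0 * _log_spread(g_nogo, s_e)
    if w < 0.35:
        w = 0.35
    elif w > 2.0:
        w = 2.0
    c1 = c - w if c - w > _GL_LO else _GL_LO
    c2 = c + w if c + w < _GL_HI else _GL_HI
    tot = 0.0
    for seg in range(3):
        if seg == 0:
            a, b = _GL_LO, c1
        elif seg == 1:
            a, b = c1, c2
        else:
            a, b = c2, _GL_HI
        if b - a < 1e-12:
            continue
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for k in range(glx.shape[0]):
            x = half * glx[k] + mid
            u = math.exp(x)
            lf = wald_logpdf(u, g_nogo, s_e) + wald_logsf(u, g_go, s_e) \
                + wald_logsf(u + tau_e, g_t, s_t)
            if lf > -700.0:
                tot += half * glw[k] * math.exp(lf) * u
    return tot


@njit(cache=True)
def nogo_prob_gl(g_go, g_nogo, g_t, s_e, s_t, tau_e, pguess, glx, glw):
    """Probability of a withheld response, by composite Gauss-Legendre
    quadrature on the log-time axis.

    First integral: the nogo evidence accumulator wins the race.  Second
    (only when pguess < 1): the timer wins (shift the timer density into the
    evidence clock by integrating over t with survivors at t - tau_e) and the
    guess comes out "nogo".
    """
    tot = _race_integral_nogo_win(g_go, g_nogo, g_t, s_e, s_t, tau_e, glx, glw)
    if pguess < 1.0:
        c = _wald_log_mode(g_t, s_t)
        if c < _GL_LO + 0.1:
            c = _GL_LO + 0.1
        elif c > _GL_HI - 0.1:
            c = _GL_HI - 0.1
        w = 10.0 * _log_spread(g_t, s_t)
        if w < 0.35:
            w = 0.35
        elif w > 2.0:
            w = 2.0
        c1 = c - w if c - w > _GL_LO else _GL_LO
        c2 = c + w if c + w < _GL_HI else _GL_HI
        g = 0.0
        for seg in range(3):
            if seg == 0:
                a, b = _GL_LO, c1
            elif seg == 1:
                a, b = c1, c2
            else:
                a, b = c2, _GL_HI
            if b - a < 1e-12:
                continue
            half = 0.5 * (b - a)
            mid = 0.5 * (a + b)
            for k in range(glx.shape[0]):
                x = half * glx[k] + mid
                t = math.exp(x)
                te = t - tau_e
                lf = wald_logpdf(t, g_t, s_t)
                if te > 0.0:
                    lf += wald_logsf(te, g_go, s_e) + wald_logsf(te, g_nogo, s_e)
                if lf > -700.0:
                    g += half * glw[k] * math.exp(lf) * t
        tot += (1.0 - pguess) * g
    if tot < 0.0:
        tot = 0.0
    elif tot > 1.0:
        tot = 1.0
    return tot


@njit(cache=True)
def theta_in_domain(th):
    for k in range(4):
        if th[k] < 0.0:
            return False
    if th[4] <= 0.0 or th[5] <= 0.0 or th[6] < 0.0:
        return False
    return True


@njit(cache=True)
def participant_trial_loglik(th, rts_go, nwh_go, rts_nogo, nwh_nogo, pguess, glx, glw):
    """SART log-likelihood for one participant.

    rts_go / rts_nogo: RTs of go responses on go / nogo stimuli.
    nwh_go / nwh_nogo: counts of withheld responses per stimulus class.
    The nogo accumulator has zero drift on go stimuli.
    """
    if not theta_in_domain(th):
        return -np.inf
    g_gg, g_gn, g_nn, g_t, s_e, s_t, tau_e = th[0], th[1], th[2], th[3], th[4], th[5], th[6]
    ll = 0.0
    for j in range(rts_go.shape[0]):
        ll += go_logdens(rts_go[j], g_gg, 0.0, g_t, s_e, s_t, tau_e, pguess)
    for j in range(rts_nogo.shape[0]):
        ll += go_logdens(rts_nogo[j], g_gn, g_nn, g_t, s_e, s_t, tau_e, pguess)
    if ll == -np.inf:
        return -np.inf
    if nwh_go > 0:
        p = nogo_prob_gl(g_gg, 0.0, g_t, s_e, s_t, tau_e, pguess, glx, glw)
        if p <= 0.0:
            return -np.inf
        ll += nwh_go * math.log(p)
    if nwh_nogo > 0:
        p = nogo_prob_gl(g_gn, g_nn, g_t, s_e, s_t, tau_e, pguess, glx, glw)
        if p <= 0.0:
            return -np.inf
        ll += nwh_nogo * math.log(p)
    return ll


@njit(cache=True)
def ndtr(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def probe_loglik_counts(counts, psi, eps, lam1, lam2, lam3):
    """Ordinal-probit log-likelihood from per-category response counts."""
    c1 = ndtr((lam1 - psi) / eps)
    c2 = ndtr((lam2 - psi) / eps)
    c3 = ndtr((lam3 - psi) / eps)
    p1 = c1
    p2 = c2 - c1
    p3 = c3 - c2
    p4 = 1.0 - c3
    ll = 0.0
    if counts[0] > 0:
        if p1 <= 0.0:
            return -np.inf
        ll += counts[0] * math.log(p1)
    if counts[1] > 0:
        if p2 <= 0.0:
            return -np.inf
        ll += counts[1] * math.log(p2)
    if counts[2] > 0:
        if p3 <= 0.0:
            return -np.inf
        ll += counts[2] * math.log(p3)
    if counts[3] > 0:
        if p4 <= 0.0:
            return -np.inf
        ll += counts[3] * math.log(p4)
    return ll


@njit(cache=True)
def tn_logpdf(x, mu, sd):
    """Normal(mu, sd) truncated to [0, inf), log density."""
    if x < 0.0 or sd <= 0.0:
        return -np.inf
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI - log_ndtr(mu / sd)


@njit(cache=True)
def participant_logprior(th, hyper):
    """Sum of truncated-normal group densities over the 7 participant params."""
    lp = 0.0
    for k in range(7):
        lp += tn_logpdf(th[k], hyper[k], hyper[7 + k])
        if lp == -np.inf:
            return -np.inf
    return lp


@njit(cache=True)
def hyper_logprior_k(mu, sd, pm, ps, hs):
    """Hyperprior for one (group mean, group SD) pair."""
    lp = tn_logpdf(mu, pm, ps)
    if sd <= 0.0:
        return -np.inf
    z = sd / hs
    return lp - 0.5 * z * z - math.log(hs) - _LOG_SQRT_2PI + math.log(2.0)


@njit(cache=True)
def sr_logprior(sr, beta_sd, lam1_mu, lam1_sd, inc_sd):
    """Prior for (beta, lambda1, d2, d3); d2, d3 half-normal increments."""
    if sr[2] <= 0.0 or sr[3] <= 0.0:
        return -np.inf
    lp = -0.5 * (sr[0] / beta_sd) ** 2 - math.log(beta_sd) - _LOG_SQRT_2PI
    z = (sr[1] - lam1_mu) / lam1_sd
    lp += -0.5 * z * z - math.log(lam1_sd) - _LOG_SQRT_2PI
    for k in (2, 3):
        z = sr[k] / inc_sd
        lp += -0.5 * z * z - math.log(inc_sd) - _LOG_SQRT_2PI + math.log(2.0)
    return lp


@njit(cache=True)
def _accept(lp_new, lp_old):
    if lp_new == -np.inf:
        return False
    if lp_old == -np.inf:
        return True
    return math.log(np.random.random()) < lp_new - lp_old


@njit(cache=True)
def _pick_pair(n_chains, c):
    r1 = np.random.randint(0, n_chains)
    while r1 == c:
        r1 = np.random.randint(0, n_chains)
    r2 = np.random.randint(0, n_chains)
    while r2 == c or r2 == r1:
        r2 = np.random.randint(0, n_chains)
    return r1, r2


@njit(cache=True)
def _full_logpost(c, theta, hyper, sr, trial_ll, probe_ll,
                  pm, ps, hs, beta_sd, lam1_mu, lam1_sd, inc_sd):
    lp = sr_logprior(sr[c], beta_sd, lam1_mu, lam1_sd, inc_sd)
    for k in range(7):
        lp += hyper_logprior_k(hyper[c, k], hyper[c, 7 + k], pm[k], ps[k], hs)
    for i in range(theta.shape[1]):
        lp += trial_ll[c, i] + probe_ll[c, i] + participant_logprior(theta[c, i], hyper[c])
    return lp


@njit(cache=True)
def run_sampler(
    theta, hyper, sr,
    rts_go_flat, go_off, nwh_go, rts_nogo_flat, nogo_off, nwh_nogo, probe_counts,
    link_idx, pguess, glx, glw,
    pm, ps, hs, beta_sd, lam1_mu, lam1_sd, inc_sd,
    n_iters, seed, jump_every, burn_iters, migrate_every,
    theta_st, hyper_st, sr_st, datall_st, prior_st,
):
    """Blocked differential-evolution Metropolis-within-Gibbs sampler.

    One population of ``C`` interacting chains; each chain carries the full
    state (participant parameters, group hyperparameters, self-report block).
    Per iteration, each chain updates every participant's 7-vector, the seven
    (mean, SD) hyper pairs, and the 4-vector self-report block, all with DE
    crossover proposals built from two other randomly chosen chains.

    Two mixing aids: (1) a recentering move on the self-report block that
    shifts beta by delta and all cut points by mean(omega) * delta — the
    near-flat ridge of the probe likelihood — as a symmetric unit-Jacobian
    Metropolis proposal; (2) during burn-in, occasional migration in which a
    random subset of chains adopt a neighbour's full state under a
    Metropolis test, which reabsorbs outlier chains.
    """
    np.random.seed(seed)
    n_chains = theta.shape[0]
    n_part = theta.shape[1]

    g_part = 2.38 / math.sqrt(2.0 * 7.0)
    g_hyp = 2.38 / math.sqrt(2.0 * 2.0)
    g_sr = 2.38 / math.sqrt(2.0 * 4.0)
    b_jit = 1e-3

    # caches
    trial_ll = np.empty((n_chains, n_part))
    probe_ll = np.empty((n_chains, n_part))
    for c in range(n_chains):
        for i in range(n_part):
            trial_ll[c, i] = participant_trial_loglik(
                theta[c, i], rts_go_flat[go_off[i]:go_off[i + 1]], nwh_go[i],
                rts_nogo_flat[nogo_off[i]:nogo_off[i + 1]], nwh_nogo[i], pguess, glx, glw)
            psi = theta[c, i, link_idx] * sr[c, 0]
            probe_ll[c, i] = probe_loglik_counts(
                probe_counts[i], psi, 1.0, sr[c, 1], sr[c, 1] + sr[c, 2], sr[c, 1] + sr[c, 2] + sr[c, 3])

    prop = np.empty(7)
    sr_prop = np.empty(4)
    probe_new = np.empty(n_part)

    for it in range(n_iters):
        jump = (jump_every > 0) and (it % jump_every == jump_every - 1)
        for c in range(n_chains):
            # --- participant blocks ---
            for i in range(n_part):
                r1, r2 = _pick_pair(n_chains, c)
                g = 0.98 if jump else g_part
                for k in range(7):
                    prop[k] = theta[c, i, k] + g * (theta[r1, i, k] - theta[r2, i, k]) \
                        + b_jit * (2.0 * np.random.random() - 1.0)
                lp_pr_new = participant_logprior(prop, hyper[c])
                if lp_pr_new > -np.inf:
                    tll = participant_trial_loglik(
                        prop, rts_go_flat[go_off[i]:go_off[i + 1]], nwh_go[i],
                        rts_nogo_flat[nogo_off[i]:nogo_off[i + 1]], nwh_nogo[i], pguess, glx, glw)
                    psi = prop[link_idx] * sr[c, 0]
                    pll = probe_loglik_counts(
                        probe_counts[i], psi, 1.0, sr[c, 1], sr[c, 1] + sr[c, 2],
                        sr[c, 1] + sr[c, 2] + sr[c, 3])
                    lp_pr_old = participant_logprior(theta[c, i], hyper[c])
                    if _accept(tll + pll + lp_pr_new, trial_ll[c, i] + probe_ll[c, i] + lp_pr_old):
                        for k in range(7):
                            theta[c, i, k] = prop[k]
                        trial_ll[c, i] = tll
                        probe_ll[c, i] = pll
            # --- hyper blocks: 7 (mean, SD) pairs ---
            for k in range(7):
                r1, r2 = _pick_pair(n_chains, c)
                g = 0.98 if jump else g_hyp
                mu_p = hyper[c, k] + g * (hyper[r1, k] - hyper[r2, k]) \
                    + b_jit * (2.0 * np.random.random() - 1.0)
                sd_p = hyper[c, 7 + k] + g * (hyper[r1, 7 + k] - hyper[r2, 7 + k]) \
                    + b_jit * (2.0 * np.random.random() - 1.0)
                lp_new = hyper_logprior_k(mu_p, sd_p, pm[k], ps[k], hs)
                if lp_new > -np.inf:
                    lp_old = hyper_logprior_k(hyper[c, k], hyper[c, 7 + k], pm[k], ps[k], hs)
                    for i in range(n_part):
                        lp_new += tn_logpdf(theta[c, i, k], mu_p, sd_p)
                        lp_old += tn_logpdf(theta[c, i, k], hyper[c, k], hyper[c, 7 + k])
                    if _accept(lp_new, lp_old):
                        hyper[c, k] = mu_p
                        hyper[c, 7 + k] = sd_p
            # --- self-report block ---
            r1, r2 = _pick_pair(n_chains, c)
            g = 0.98 if jump else g_sr
            for k in range(4):
                sr_prop[k] = sr[c, k] + g * (sr[r1, k] - sr[r2, k]) \
                    + b_jit * (2.0 * np.random.random() - 1.0)
            lp_new = sr_logprior(sr_prop, beta_sd, lam1_mu, lam1_sd, inc_sd)
            if lp_new > -np.inf:
                lp_old = sr_logprior(sr[c], beta_sd, lam1_mu, lam1_sd, inc_sd)
                for i in range(n_part):
                    psi = theta[c, i, link_idx] * sr_prop[0]
                    probe_new[i] = probe_loglik_counts(
                        probe_counts[i], psi, 1.0, sr_prop[1], sr_prop[1] + sr_prop[2],
                        sr_prop[1] + sr_prop[2] + sr_prop[3])
                    lp_new += probe_new[i]
                    lp_old += probe_ll[c, i]
                if _accept(lp_new, lp_old):
                    for k in range(4):
                        sr[c, k] = sr_prop[k]
                    for i in range(n_part):
                        probe_ll[c, i] = probe_new[i]
            # --- ridge recentering of (beta, lambda1) ---
            if n_part > 0:
                omega_bar = 0.0
                for i in range(n_part):
                    omega_bar += theta[c, i, link_idx]
                omega_bar /= n_part
                delta = 0.3 * np.random.standard_normal()
                sr_prop[0] = sr[c, 0] + delta
                sr_prop[1] = sr[c, 1] + omega_bar * delta
                sr_prop[2] = sr[c, 2]
                sr_prop[3] = sr[c, 3]
                lp_new = sr_logprior(sr_prop, beta_sd, lam1_mu, lam1_sd, inc_sd)
                lp_old = sr_logprior(sr[c], beta_sd, lam1_mu, lam1_sd, inc_sd)
                for i in range(n_part):
                    psi = theta[c, i, link_idx] * sr_prop[0]
                    probe_new[i] = probe_loglik_counts(
                        probe_counts[i], psi, 1.0, sr_prop[1], sr_prop[1] + sr_prop[2],
                        sr_prop[1] + sr_prop[2] + sr_prop[3])
                    lp_new += probe_new[i]
                    lp_old += probe_ll[c, i]
                if _accept(lp_new, lp_old):
                    sr[c, 0] = sr_prop[0]
                    sr[c, 1] = sr_prop[1]
                    for i in range(n_part):
                        probe_ll[c, i] = probe_new[i]
        # --- burn-in migration: reabsorb outlier chains ---
        if migrate_every > 0 and it < burn_iters and (it % migrate_every == migrate_every - 1):
            n_mig = max(2, n_chains // 5)
            order = np.random.permutation(n_chains)[:n_mig]
            for m in range(n_mig):
                c_to = order[m]
                c_from = order[(m + 1) % n_mig]
                lp_to = _full_logpost(c_to, theta, hyper, sr, trial_ll, probe_ll,
                                      pm, ps, hs, beta_sd, lam1_mu, lam1_sd, inc_sd)
                lp_from = _full_logpost(c_from, theta, hyper, sr, trial_ll, probe_ll,
                                        pm, ps, hs, beta_sd, lam1_mu, lam1_sd, inc_sd)
                if _accept(lp_from, lp_to):
                    for i in range(n_part):
                        for k in range(7):
                            theta[c_to, i, k] = theta[c_from, i, k]
                        trial_ll[c_to, i] = trial_ll[c_from, i]
                        probe_ll[c_to, i] = probe_ll[c_from, i]
                    for k in range(14):
                        hyper[c_to, k] = hyper[c_from, k]
                    for k in range(4):
                        sr[c_to, k] = sr[c_from, k]
        # --- record ---
        for c in range(n_chains):
            dll = 0.0
            lpr = sr_logprior(sr[c], beta_sd, lam1_mu, lam1_sd, inc_sd)
            for k in range(7):
                lpr += hyper_logprior_k(hyper[c, k], hyper[c, 7 + k], pm[k], ps[k], hs)
            for i in range(n_part):
                dll += trial_ll[c, i] + probe_ll[c, i]
                lpr += participant_logprior(theta[c, i], hyper[c])
            datall_st[it, c] = dll
            prior_st[it, c] = lpr
            for i in range(n_part):
                for k in range(7):
                    theta_st[it, c, i, k] = theta[c, i, k]
            for k in range(14):
                hyper_st[it, c, k] = hyper[c, k]
            for k in range(4):
                sr_st[it, c, k] = sr[c, k]
    return 0


@njit(cache=True)
def dataset_data_loglik(theta, sr, rts_go_flat, go_off, nwh_go, rts_nogo_flat, nogo_off,
                        nwh_nogo, probe_counts, link_idx, pguess, glx, glw):
    """Joint data log-likelihood at one parameter point (all participants)."""
    n_part = theta.shape[0]
    ll = 0.0
    for i in range(n_part):
        ll += participant_trial_loglik(
            theta[i], rts_go_flat[go_off[i]:go_off[i + 1]], nwh_go[i],
            rts_nogo_flat[nogo_off[i]:nogo_off[i + 1]], nwh_nogo[i], pguess, glx, glw)
        psi = theta[i, link_idx] * sr[0]
        ll += probe_loglik_counts(probe_counts[i], psi, 1.0, sr[1], sr[1] + sr[2],
                                  sr[1] + sr[2] + sr[3])
    return ll
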
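"""Posterior-predictive checks and descriptive summaries.

Group RT distributions are formed by quantile averaging: percentiles are
computed within participant and then averaged across participants, which
preserves distribution shape when participants differ in speed.  Predictive
bands come from simulating full datasets at retained posterior draws (500 by
default) and taking 2.5/97.5 percentiles of each summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataIntegrityError
from .inference import PosteriorSamples
from .io import Dataset
from .joint import JointModelSpec
from .selfreport import SelfReportParams, simulate_probes
from .trdm import TRDMParams, simulate_trials

__all__ = ["PPCSummary", "quantile_average", "posterior_predict", "summarize_dataset",
           "commission_error_stats", "spearman_posterior", "ppc_coverage"]

DEFAULT_PERCENTILES = (10, 30, 50, 70, 90)


def quantile_average(rt_sets_by_participant, percentiles=DEFAULT_PERCENTILES):
    """Average within-participant RT percentiles across participants.

    ``rt_sets_by_participant``: iterable of 1-D RT arrays, one per
    participant.  Participants with no RTs are excluded; the number excluded
    is returned alongside the group percentile vector.
    """
    percentiles = np.asarray(percentiles, float)
    if np.any(percentiles <= 0) or np.any(percentiles >= 100):
        raise ValueError("percentiles must lie strictly between 0 and 100")
    per_part = []
    n_excluded = 0
    for rts in rt_sets_by_participant:
        rts = np.asarray(rts, float)
        rts = rts[np.isfinite(rts)]
        if rts.size == 0:
            n_excluded += 1
            continue
        per_part.append(np.percentile(rts, percentiles))
    if not per_part:
        raise DataIntegrityError("no participant has any response times")
    return np.mean(per_part, axis=0), n_excluded


@dataclass
class PPCSummary:
    """Observed summary statistics with posterior-predictive 95% bands.

    ``stats`` rows: statistic name, observed value, predictive lower/upper
    band and predictive mean.  ``probe_by_participant``: per-participant
    observed and predicted probe-response proportions (for individual-level
    adequacy plots).
    """

    stats: pd.DataFrame
    probe_by_participant: pd.DataFrame
    n_draws: int
    percentiles: tuple = DEFAULT_PERCENTILES
    meta: dict = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        """Fraction of observed statistics inside their 95% predictive band."""
        s = self.stats
        inside = (s["observed"] >= s["lo"]) & (s["observed"] <= s["hi"])
        return float(inside.mean())


def summarize_dataset(dataset: Dataset, percentiles=DEFAULT_PERCENTILES) -> dict:
    """The summary-statistic vector used for predictive checking.

    Quantile-averaged RT percentiles per stimulus class, go-response
    proportion per class, and the four group probe-response proportions.
    """
    t = dataset.trials
    out = {}
    for stim in ("go", "nogo"):
        sub = t[t["stimulus"] == stim]
        rts = [g.loc[g["response"] == "go", "rt"].to_numpy()
               for _, g in sub.groupby("participant", sort=True)]
        try:
            qs, _ = quantile_average(rts, percentiles)
        except DataIntegrityError:
            qs = np.full(len(percentiles), np.nan)
        for p, q in zip(percentiles, qs):
            out[f"rt_p{p}_{stim}"] = q
        out[f"prop_go_{stim}"] = float((sub["response"] == "go").mean()) if len(sub) else np.nan
    n_probes = len(dataset.probes)
    for k in range(1, 5):
        out[f"probe_prop_{k}"] = (float((dataset.probes["response"] == k).mean())
                                  if n_probes else np.nan)
    return out


def _probe_props_by_participant(probes: pd.DataFrame, ids) -> np.ndarray:
    props = np.zeros((len(ids), 4))
    for j, pid in enumerate(ids):
        r = probes.loc[probes["participant"] == pid, "response"]
        if len(r):
            for k in range(4):
                props[j, k] = float((r == k + 1).mean())
    return props


def posterior_predict(samples: PosteriorSamples, dataset: Dataset, spec: JointModelSpec,
                      n_draws: int = 500, rng_seed=0,
                      percentiles=DEFAULT_PERCENTILES) -> PPCSummary:
    """Simulate predictive datasets at retained draws and band the summaries.

    Each retained draw supplies every participant's TRDM vector and the
    self-report block; a full dataset with the observed design (trial counts,
    probe counts per participant) is simulated per draw.
    """
    rng = np.random.default_rng(rng_seed)
    total = samples.n_draws
    if n_draws > total:
        raise ValueError(f"requested {n_draws} draws but only {total} are retained")
    it, ch, n_part, _ = samples.theta_post.shape
    flat_idx = rng.choice(it * ch, size=n_draws, replace=False)
    theta_flat = samples.theta_post.reshape(it * ch, n_part, 7)
    sr_flat = samples.selfreport_post.reshape(it * ch, 4)

    ids = samples.participants
    t = dataset.trials
    design_counts = []
    for pid in ids:
        sub = t[t["participant"] == pid]
        design_counts.append((
            int((sub["stimulus"] == "go").sum()),
            int((sub["stimulus"] == "nogo").sum()),
            int((dataset.probes["participant"] == pid).sum())))

    stat_names = list(summarize_dataset(dataset, percentiles))
    sim_stats = np.full((n_draws, len(stat_names)), np.nan)
    probe_pred = np.zeros((n_draws, n_part, 4))
    for d, fi in enumerate(flat_idx):
        theta_d, sr_d = theta_flat[fi], sr_flat[fi]
        srp = SelfReportParams.from_increments(*sr_d)
        trial_rows, probe_rows = [], []
        for j, pid in enumerate(ids):
            th = TRDMParams.from_vector(theta_d[j], samples.config.guess_go_prob)
            n_go, n_nogo, n_pr = design_counts[j]
            for stim, n_s in (("go", n_go), ("nogo", n_nogo)):
                if n_s == 0:
                    continue
                is_go, rt = simulate_trials(th, stim, n_s, rng)
                for i in range(n_s):
                    trial_rows.append((pid, stim, "go" if is_go[i] else "withheld",
                                       rt[i] if is_go[i] else np.nan))
            if n_pr:
                psi = theta_d[j, spec.link_index] * srp.beta
                resp = simulate_probes(psi, srp.epsilon, srp.cutpoints, n_pr, rng)
                probe_rows.extend((pid, r) for r in resp)
                for k in range(4):
                    probe_pred[d, j, k] = float(np.mean(resp == k + 1))
        tdf = pd.DataFrame(trial_rows, columns=["participant", "stimulus", "response", "rt"])
        pdf = pd.DataFrame(probe_rows, columns=["participant", "response"])
        sim_stats[d] = _summaries_from_frames(tdf, pdf, percentiles)

    obs = summarize_dataset(dataset, percentiles)
    lo = np.nanpercentile(sim_stats, 2.5, axis=0)
    hi = np.nanpercentile(sim_stats, 97.5, axis=0)
    mean = np.nanmean(sim_stats, axis=0)
    stats_df = pd.DataFrame({
        "statistic": stat_names,
        "observed": [obs[n] for n in stat_names],
        "lo": lo, "hi": hi, "predictive_mean": mean,
    })
    obs_props = _probe_props_by_participant(dataset.probes, ids)
    rows = []
    for j, pid in enumerate(ids):
        for k in range(4):
            rows.append((pid, k + 1, obs_props[j, k], probe_pred[:, j, k].mean()))
    probe_df = pd.DataFrame(rows, columns=["participant", "response", "observed", "predicted"])
    return PPCSummary(stats_df, probe_df, n_draws, tuple(percentiles),
                      {"rng_seed": rng_seed})


def _summaries_from_frames(tdf, pdf, percentiles):
    out = []
    for stim in ("go", "nogo"):
        sub = tdf[tdf["stimulus"] == stim]
        rts = [g.loc[g["response"] == "go", "rt"].to_numpy()
               for _, g in sub.groupby("participant", sort=True)]
        try:
            qs, _ = quantile_average(rts, percentiles)
        except DataIntegrityError:
            qs = np.full(len(percentiles), np.nan)
        out.extend(qs)
        out.append(float((sub["response"] == "go").mean()) if len(sub) else np.nan)
    for k in range(1, 5):
        out.append(float((pdf["response"] == k).mean()) if len(pdf) else np.nan)
    return np.asarray(out)


def ppc_coverage(summary: PPCSummary) -> float:
    """Convenience alias for :attr:`PPCSummary.coverage`."""
    return summary.coverage


def commission_error_stats(dataset: Dataset) -> dict:
    """Mean and range of per-participant commission-error proportions.

    A commission error is a go response on a nogo (target) trial.
    Participants with no nogo trials are excluded and counted.
    """
    t = dataset.trials
    props = []
    excluded = 0
    for pid, g in t.groupby("participant", sort=True):
        ng = g[g["stimulus"] == "nogo"]
        if len(ng) == 0:
            excluded += 1
            continue
        props.append(float((ng["response"] == "go").mean()))
    if not props:
        raise DataIntegrityError("no participant has nogo trials")
    return {
        "mean": float(np.mean(props)),
        "min": float(np.min(props)),
        "max": float(np.max(props)),
        "per_participant": np.asarray(props),
        "n_excluded": excluded,
    }


def spearman_posterior(samples: PosteriorSamples, per_participant_stat,
                       param: str = "gamma_nogo_given_nogo") -> dict:
    """Spearman correlation between an observed per-participant statistic and
    the posterior draws of one participant-level parameter.

    Point estimate is the posterior mean of the per-draw rank correlation;
    the interval is the 2.5/97.5 percentile of the r_s draws.  Ties use
    average ranks (scipy convention).
    """
    stat = np.asarray(per_participant_stat, float)
    if stat.size < 3:
        raise ValueError("need at least 3 participants")
    if np.all(stat == stat[0]):
        return {"r_s": np.nan, "lo": np.nan, "hi": np.nan,
                "note": "observed statistic is constant; correlation undefined"}
    draws = samples.participant_draws(param)
    rs = np.empty(draws.shape[0])
    for d in range(draws.shape[0]):
        if np.all(draws[d] == draws[d][0]):
            rs[d] = np.nan
        else:
            rs[d] = stats.spearmanr(stat, draws[d]).statistic
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return {"r_s": np.nan, "lo": np.nan, "hi": np.nan,
                "note": "parameter draws are constant; correlation undefined"}
    return {"r_s": float(rs.mean()), "lo": float(np.percentile(rs, 2.5)),
            "hi": float(np.percentile(rs, 97.5)), "n_draws": int(rs.size)}


def plot_descriptive_adequacy(summary: PPCSummary, path=None):
    """Three-panel figure: quantile-averaged RT percentiles per stimulus
    class, go-response proportions, and group probe-response proportions,
    observed against 95% predictive bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = summary.stats.set_index("statistic")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    pct = summary.percentiles
    for stim, color in (("nogo", "tab:blue"), ("go", "tab:orange")):
        names = [f"rt_p{p}_{stim}" for p in pct]
        sub = s.loc[names]
        axes[0].errorbar(pct, sub["predictive_mean"],
                         yerr=[sub["predictive_mean"] - sub["lo"],
                               sub["hi"] - sub["predictive_mean"]],
                         fmt="-", color=color, capsize=3, label=f"{stim} predicted")
        axes[0].plot(pct, sub["observed"], "o", color=color, label=f"{stim} observed")
    axes[0].set_xlabel("percentile")
    axes[0].set_ylabel("RT (s)")
    axes[0].legend(fontsize=7)
    names = ["prop_go_nogo", "prop_go_go"]
    sub = s.loc[names]
    x = [0, 1]
    axes[1].errorbar(x, sub["predictive_mean"],
                     yerr=[sub["predictive_mean"] - sub["lo"], sub["hi"] - sub["predictive_mean"]],
                     fmt="s", color="gray", capsize=3)
    axes[1].plot(x, sub["observed"], "o", color="black")
    axes[1].set_xticks(x, ["target (nogo)", "non-target (go)"])
    axes[1].set_ylabel("P(go response)")
    names = [f"probe_prop_{k}" for k in range(1, 5)]
    sub = s.loc[names]
    x = [1, 2, 3, 4]
    axes[2].errorbar(x, sub["predictive_mean"],
                     yerr=[sub["predictive_mean"] - sub["lo"], sub["hi"] - sub["predictive_mean"]],
                     fmt="s", color="gray", capsize=3)
    axes[2].plot(x, sub["observed"], "o", color="black")
    axes[2].set_xlabel("probe response")
    axes[2].set_ylabel("proportion")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_individual_probe_fit(summary: PPCSummary, path=None):
    """Observed vs predicted per-participant probe proportions, one panel per
    response category, with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.probe_by_participant
    fig, axes = plt.subplots(4, 1, figsize=(3.2, 11), sharex=True, sharey=True)
    for k, ax in enumerate(axes, start=1):
        sub = df[df["response"] == k]
        ax.plot([0, 1], [0, 1], "-", color="gray", lw=1)
        ax.plot(sub["observed"], sub["predicted"], "o", ms=4, alpha=0.7)
        ax.set_ylabel(f"predicted (resp {k})")
    axes[-1].set_xlabel("observed proportion")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
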
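# Methods

## The joint model

`trdmjoint` models two streams of behaviour from a sustained-attention go/nogo
task (SART) as outputs of one latent cognitive system.

**Task stream — timed racing diffusion (TRDM).** Each trial races three
single-boundary diffusion processes. Two evidence accumulators evaluate the
stimulus: a go accumulator with drift γ_go|s and a nogo accumulator with
drift γ_nogo|s (s ∈ {go, nogo}), sharing moment-to-moment SD σ_E, threshold
α_E = 1 and non-decision time τ_E. A timing accumulator (drift γ_T, SD σ_T,
threshold α_T = 1, onset at stimulus presentation, τ_T = 0) represents the
time the decision-maker is willing to wait. The first process to reach its
threshold determines the outcome: go-accumulator win → go response at its
finishing time; nogo-accumulator win → the response is withheld (no RT);
timer win → the evidence race is abandoned and a guess is emitted, biased to
"go" with probability `guess_go_prob` (1 by default, reflecting the go habit
the task induces). Single-accumulator finishing times are Wald
(inverse-Gaussian) distributed; γ = 0 is legal and gives the heavy-tailed
Lévy limit. Identification constraints: α_E = α_T = 1 (scale), τ_T = 0, and
γ_nogo|go = 0 (nogo responses to go stimuli are negligible), leaving seven
free parameters per participant.

The defective go-RT density at time t from stimulus onset is

    f_go(t | s) = g(t−τ_E; γ_go|s, σ_E) S(t−τ_E; γ_nogo|s, σ_E) S(t; γ_T, σ_T)
                + guess_go_prob · g(t; γ_T, σ_T) S(t−τ_E; γ_go|s, σ_E) S(t−τ_E; γ_nogo|s, σ_E)

with g and S the Wald density and survivor. The withheld probability is the
integral of the nogo-win density plus, when `guess_go_prob < 1`, the
timer-win-then-guess-nogo branch, so the two outcome types always partition
probability one.

**Self-report stream — Thurstonian ordinal probit.** A thought probe on
trial j prompts participant i to draw z_ij ~ N(ψ_i, ε) on a latent
mind-wandering continuum and report the Likert category (1–4) delimited by
group-level cut points λ1 < λ2 < λ3. (β, λ, ε) are jointly unidentified
under common rescaling, so ε = 1 by the probit convention; a
participant-specific ε can be supplied but is never estimated.

**The structural link.** ψ_i = ω_i · β, where ω_i is one TRDM parameter of
participant i and β is a group-level scaling coefficient. Six variants bind
one parameter each — γ_nogo|nogo, γ_go|nogo, γ_go|go, γ_T, σ_E, σ_T — each
operationalizing a hypothesis about what self-reported mind wandering
reflects (executive control over habitual responding, failure to filter
misleading evidence, attention to common events, temporal calibration, or
processing volatility). Non-decision time is deliberately not linkable. ω
enters the link untransformed; the probes are conditionally independent
given participant parameters (the link is at the participant level, so there
is no trial-level coupling or temporal dependence).

## Numerics

* Wald survivor/CDF use `Φ((α−γt)/(σ√t)) − exp(2αγ/σ²) Φ(−(γt+α)/(σ√t))`
  with the exponential factor handled in log space (no overflow for large
  drifts) and the deep normal tail via an asymptotic `log Φ`.
* The withheld probability integrates the nogo-win density on a log-time
  axis. The public function uses adaptive quadrature (absolute tolerance
  1e-6, upper limit 1e5 s where all survivor products are < 1e-12) with
  breakpoints at each component density's mode so narrow first-passage
  spikes cannot be stepped over; a `method="complement"` route via
  1 − ∫ f_go is provided as a cross-check. The MCMC kernel uses a composite
  3-segment Gauss–Legendre rule (48 nodes per segment) whose middle segment
  zooms onto the winning density's mode with width 10 × the log-scale spread
  σ/√γ; it agrees with the adaptive rule to ~1e-6 over a deliberately harsh
  parameter range and to ~1e-11 over the range the posterior visits.
* Simulated races break exact ties (measure zero) uniformly at random.
  First-passage sampling uses Michael–Schucany–Haas for γ > 0 and the Lévy
  form for γ = 0. All times are in seconds from stimulus onset.

## Hierarchical estimation

Participant-level vectors are exchangeable draws from truncated-normal group
distributions (a mean and SD per parameter, truncated to the parameter
domain); β and the cut points are group-level. Priors are weakly informative
on the second-scale RT regime: group means — drift rates N(2, 3) on [0, ∞),
diffusion SDs N(1, 2) on (0, ∞), τ_E N(0.2, 0.3) on [0, ∞); group SDs
half-normal(1); β ~ N(0, 2); λ1 ~ N(−1, 2); cut-point increments
half-normal(1). Cut points are sampled as λ1 plus two positive increments,
which enforces ordering inside the sampler.

The sampler is blocked Metropolis-within-Gibbs with differential-evolution
(DE) crossover proposals: one population of interacting chains (default 24,
each reported as a chain for diagnostics), updating per-participant
7-dimensional blocks, seven (mean, SD) hyper pairs, and the 4-dimensional
self-report block, with γ_DE = 2.38/√(2d), small uniform jitter, and a
full-strength crossover every 10th iteration for mode jumping. Two mixing
aids matter in practice:

* a **ridge recentering move** on the self-report block — the probe
  likelihood is nearly flat along (β, λ) → (β + δ, λ + ω̄δ); the move
  proposes exactly that shift (symmetric, unit Jacobian), letting the
  between-participant correlation signal, not the marginal probe
  distribution, pin β;
* **chain migration during burn-in only** — a random subset of chains adopt
  a neighbour's full state under a Metropolis test, reabsorbing outlier
  chains (a known DE-MCMC failure mode that otherwise inflates R-hat).

Parameters are sampled on their natural scale with out-of-domain proposals
rejected; the truncated-normal priors are specified on that scale and DE
proposals adapt to the posterior geometry without a transform. Defaults:
24 chains, 1000 iterations, 50% burn-in, no thinning; every seed is logged.
Convergence is assessed with split-chain rank-normalized R-hat and ESS
(via ArviZ); parameters above the threshold (default 1.1) are listed in the
fit metadata, never silently dropped. In calibration runs at the first
experiment's scale, 1000 iterations give R-hat ≲ 1.15 for all group-level
parameters except the weakly-identified γ_go|nogo mean (informed only by
~80 nogo trials per participant), whose posterior is wide but centred.

Starting points are overdispersed, data-informed moment guesses (e.g. go
drift ≈ 1/(0.8 × mean RT)); they only seed the DE population and do not
enter the target.

## Model comparison

DIC with the conditional (participant-level) focus: deviance is a function
of the participant TRDM vectors and the group-level self-report block — the
levels carrying the scientific claims. D̄ averages over post-burn-in draws;
pD = D̄ − D(plug-in); DIC = D̄ + pD, lower preferred; tables are
zero-referenced to the best model, ties broken by label order and flagged.
pD is parameterization-dependent, and the plug-in point is therefore taken
on the scale the likelihood consumes: posterior means of the participant
TRDM vectors, of the per-participant latent probe means ψ_i = ω_i β, and of
the cut points. Averaging ω and β separately and multiplying would charge
linked models for the posterior correlation between the factors — in
calibration runs this inflated the generating variant's pD by ~2× and could
reverse rankings.

## Posterior-predictive checks

Group RT distributions are formed by quantile averaging (percentiles within
participant, then averaged across participants), which preserves
distributional shape under between-participant speed differences. Predictive
bands use 500 retained draws by default (300 in the heavier automated
checks); for each draw a full dataset with the observed design is simulated
and the summary vector recomputed: 10/30/50/70/90 RT percentiles per
stimulus class, go-response proportion per class, and the four probe
proportions. Spearman correlations between an observed per-participant
statistic and a participant-level parameter are summarized over posterior
draws (point estimate = posterior mean of r_s, interval = 2.5/97.5
percentiles); ties use average ranks; constant inputs are reported as
undefined rather than silently dropped.

## Synthetic data: what it emulates and what it does not

The generator reproduces the two experiments' designs: 19 participants ×
(640 go + 80 nogo) trials with 20 probes (digits 1–9, target 3), and 192 ×
(1000 go + 24 nogo) with 24 probes (digits 0–9, RT ceiling 1.5 s applied as
removal without renormalization). Nogo trials and probes are placed
uniformly over admissible configurations subject to minimum spacing; the
original "small windows" are unspecified, so the defaults are 3 trials
between nogo stimuli and 10 between probes, both configurable. Probe
placement is independent of simulated performance (no state-dependent
probing).

Default generating values were chosen once to match the published SART
signature: mean go RT ≈ 0.32 s with a fast, skewed distribution, ~2% go
omissions, commission-error proportions averaging ≈ .57 with range ≈
(.29, .95), a bow-shaped probe profile, and a strong negative rank
correlation between probe means and nogo-detection rates. Group means
(5.0, 1.8, 4.2, 2.5, 1.0, 0.6, 0.18) for (γ_go|go, γ_go|nogo, γ_nogo|nogo,
γ_T, σ_E, σ_T, τ_E); group SDs (0.8, 0.6, 1.0, 0.5, 0.15, 0.15, 0.04);
β = −0.4; λ = (−2.6, −1.6, −0.6).

What passing tests on these data do **not** show about real data: the
generator has no time-on-task drift, no temporal dependence between probe
responses, no post-error slowing, no stimulation-condition effects, and its
participants are exact draws from the assumed truncated-normal group
distributions — so recovery results certify the estimation machinery, not
the model's adequacy for any particular empirical dataset.

## Problem sizes in the automated checks

Likelihood/simulator agreement uses 10⁶-trial simulations per parameter set.
Parameter recovery runs at the first experiment's full scale (19 × 720
trials, 20 probes) with 24 chains × 1000 iterations. Model recovery runs 10
replications × 6 variants at a reduced scale chosen for desk-top runtimes —
12 participants, 100 go + 20 nogo trials, 20 probes (probe spacing 4, since
the full-scale spacing of 10 is infeasible in 120 trials) — with 16 chains ×
600 iterations, the point where the deviance trace has plateaued in
calibration runs. Posterior-predictive bands in the automated checks use 300
retained draws.

## Known limitations

* The DE population serves double duty as the diagnostic chains; chains
  interact, so R-hat is a practical rather than strict independence
  diagnostic (standard practice for this sampler family).
* γ_go|nogo is weakly identified from commission RTs alone; its group mean
  mixes slowest and carries the widest posterior.
* The conditional-focus DIC is one defensible choice; a marginal focus
  (integrating participant parameters) would penalize differently.
* The probe stream identifies β only through between-participant variation;
  designs with few participants recover its sign but not its magnitude
  precisely.
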
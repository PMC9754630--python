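# Methods

## The decision problem

An observer must report which of two latent states, s+ or s-, generated a
stream of noisy observations.  Observations arrive every δt time units and
are Gaussian, ξ | s± ~ N(±μδt, σ²δt); the quality of the evidence is
summarised by the signal-to-noise ratio m = 2μ²/σ² (units 1/time).  The
ideal observer tracks the log-likelihood ratio (LLR)

    y_n = ln Pr(s+ | ξ_1:n) / Pr(s- | ξ_1:n),

or equivalently the state likelihood p_n = 1/(1 + e^{-y_n}).  The objective
is the trial-averaged reward rate

    ρ = (⟨R⟩ − ⟨C(T_d)⟩) / (⟨T_t⟩ + ⟨t_i⟩),

with R the reward per choice, C(T_d) = c·T_d the accumulated evidence cost
(the incremental cost c is held constant so that threshold dynamics are
driven by the task, not the cost function), T_t the trial length and t_i the
inter-trial interval.

What makes this package's setting distinctive is that the *context* — the
reward for a correct choice Rc(t), or the evidence quality m(t) — may change
at known times **within** a single trial.  The optimal commitment rule is
then a time-varying pair of thresholds ±θ(t) on the belief, found by
dynamic programming.

## Dynamic programming on the belief grid

At each decision epoch the observer chooses among three actions, whose
values under the average-reward formulation are

    V+(p; ρ) = Rc p + Ri (1−p) − ⟨t_i⟩ρ          (commit to s+)
    V−(p; ρ) = Rc (1−p) + Ri p − ⟨t_i⟩ρ          (commit to s−)
    Vw(p; ρ) = ⟨V(p′; ρ) | p⟩ − c δt − ρ δt      (sample again)

and V = max of the three.  Every action is penalised by its time cost
scaled by ρ, which makes trials commensurable and turns the free-response
problem into a fixed-horizon one.  The expectation in Vw uses the one-step
likelihood transfer density f_p(p′ | p): the observation that moves the
belief from p to p′ is recovered by inverting the Bayesian update, weighted
by the two-component Gaussian mixture implied by the current belief, and
mapped through the change of variables dξ/dp′ = σ²/(2μ p′(1−p′)).  For
uninformative evidence (μ = 0) the kernel degenerates to the identity.

Numerical choices:

* **Belief grid.** 501 uniformly spaced points on [ε, 1−ε] with ε = 1e-4.
  The odd count makes p = 1/2 an exact grid point, and the grid maps onto
  itself under p ↦ 1−p.  This resolves thresholds to 0.2% likelihood.
* **Quadrature.** Trapezoid weights on the grid, rows renormalised to sum
  to one, then explicitly symmetrised so the kernel is bitwise
  mirror-symmetric.  Rows satisfy the martingale property Σ_j w_ij p_j = p_i
  to quadrature accuracy.
* **Horizon.** Backward induction starts from an artificial horizon
  T_f = 5× the analysis window (window 1.0, change at t = 0.5, δt = 0.01
  for the continuous tasks), far enough that the forced terminal decision
  does not contaminate the window; doubling T_f moves thresholds by less
  than one grid cell (tested).
* **Reward-rate co-optimisation.** The unknown ρ enters the value function;
  at the optimum V(p=1/2, t=0; ρ*) = 0.  g(ρ) = V(1/2, 0; ρ) is strictly
  decreasing, so the root is bracketed by expansion (the bracket may extend
  below zero: tokens-task parameters with heavy costs have ρ* < 0) and
  solved with Brent's method to 1e-9, giving residuals |g(ρ*)| ≲ 1e-6·Rc.
* **Tie-breaking.** At exact value equality, commitment is preferred over
  waiting, and the committed side is the one holding the belief (s+ for
  p ≥ 1/2).  On the symmetric tasks supported here the lower threshold is
  reported as 1 − upper by construction, which keeps the trace exactly
  symmetric and independent of razor-edge ties at the centre cell.
* **Value symmetry.** Choose-minus values are computed as the mirrored
  choose-plus values and the wait value is explicitly symmetrised each
  step, so V(p, t) = V(1−p, t) holds bitwise.

Thresholds are the boundaries of the wait region of the optimal-action map:
the upper threshold at a timestep is the smallest grid belief at which
committing to s+ is optimal, with an infinite sentinel (`inf` in CSV
output) when waiting is optimal at every belief.

## Task families

* **Reward-change**: Rc(t) = (R2−R1)·H(t−0.5) + R1 with punishment Ri = 0;
  step functions are right-continuous (the post-change value applies at the
  change time itself).  Defaults follow the single-change study conditions:
  m = 5, c = 1, ⟨t_i⟩ = 1.
* **SNR-change**: μ(t) steps at t = 0.5 at fixed Rc = 5; the solver switches
  transfer kernels at the change.
* **Tokens task**: 15 tokens jump from a centre target to the two flankers
  with probability 1/2 every 200 ms; the subject predicts the majority
  side.  The win probability of a state (U, L, C) is the binomial(C, 1/2)
  CDF at min{C, 7−L}, and the belief transfer is the two-successor fair
  coin.  Committing after n movements triggers the accelerated animation of
  the remaining 15−n tokens (170 ms per move in the slow condition, 20 ms
  in the fast one), so the effective inter-trial interval shrinks with n —
  the task is a gradual commitment-value ramp.  The fixed (non-animation)
  part of the inter-trial interval is not dictated by the task description;
  it defaults to 500 ms and is exposed in the context constructor (it
  rescales ρ without reorganising the motif structure).  The forced
  terminal choice at step 15 makes the trial naturally finite-horizon.
* **Inferred reward-change**: the reward alternates between R_H and R_L
  under a two-state Markov process with hazard h, observed only through an
  independent Gaussian stream of quality m_R.  The reward belief
  y_R follows the sinh-nonlinearity drift-diffusion equation
  dy_R = x(t) m_R dt − 2h sinh(y_R) dt + √(2 m_R) dW, and commitment values
  use the expected reward R_H q + R_L (1−q) with q = e^{y_R}/(1+e^{y_R}).
  The solver runs on the joint (p, q) grid (defaults 201 × 101); the q
  kernel is a two-component Gaussian mixture from one Euler step of the
  sinh-DDM, with underflowing boundary rows (strong sinh drift at extreme
  beliefs) collapsed to their nearest grid point.  Because here the reward
  change must be inferred rather than anticipated, thresholds track the
  expected reward monotonically instead of exhibiting the anticipatory
  motifs of the known-schedule tasks; the package validates this solver
  through its limiting cases (equal rewards reduce to the static task;
  pinned reward belief reduces to the known-reward task) rather than a full
  2-D census.

## Threshold motifs

Threshold time courses fall into qualitative classes ("motifs").  The
classifier is deterministic and operates on the analysis window with the
forced-choice terminal step dropped, traces smoothed over three timesteps,
and wiggles below three grid cells ignored:

1. a trace that descends to p = 1/2 around the change and stays collapsed →
   `collapse-to-zero-before-change` (all trials respond while the
   pre-change context holds);
2. the same descent followed by a post-change rebound →
   `nonmonotone-mixed` (a collapse episode plus a recovery);
3. an infinite epoch (≥ 2 consecutive all-wait steps) → `wait-then-respond`
   if the preceding finite part is flat, `nonmonotone-rise` if the
   threshold re-arms (rises) into the epoch;
4. otherwise, by significant interior extrema: one minimum →
   `nonmonotone-dip`; one maximum → `nonmonotone-rise`; several →
   `nonmonotone-mixed`; none → `monotone-collapsing` / `constant-like` /
   `stepped` by net slope.

Tokens-task traces are classified in token-lead coordinates (Nt = U − L).
Reachable leads alternate parity between steps, so the raw staircase
zig-zags by one token; a width-2 mean removes this, after which each
remaining unit-lead increase is a real re-arming event.  Clinched states
(a target already holds 8 tokens) are excluded from threshold extraction —
commitment there is trivially optimal and carries no behavioural
information.

The reference censuses use staggered 10×10 grids that sample strictly off
the no-change diagonal: rewards R1 ∈ {1..10} × R2 ∈ {0.5..9.5}; qualities
m1 ∈ {0.5..9.5} × m2 ∈ {0..9} (the m2 = 0 endpoint — evidence blackout —
is a legitimate and qualitatively distinct condition); tokens
Rc ∈ {0.5..9.5} × c ∈ {0, 0.5, .., 4.5} at Ri = −1 for both speeds.  On
these grids the censuses resolve five motif classes for reward changes,
three for quality changes (all monotone), and four for each tokens
condition.

## Observer models and noise

Three simulated observers share evidence streams (common random numbers),
so performance differences are attributable to commitment rules alone:

* **Noisy Bayesian (NB)** — belief dỹ = ±m dt + √(2m) dW + σ_y dW′ against
  the DP thresholds ±θ(t); the extra Wiener term is sensory noise of
  strength σ_y (discretised as additive N(0, σ_y²δt) per step).
* **Constant threshold (Const)** — the same noisy belief against ±θ0.
* **Urgency gating (UGM)** — the state likelihood low-pass filtered,
  τ dE = (−E + p − 1/2) dt + σ_y dW, against the hyperbolically collapsing
  bound ±θ0/(a·t).  The bound is infinite at t = 0, so the first response
  opportunity is after one step.  An alternative form θ0/(1 + a·t) exists
  in the literature; the hyperbolic form is the default here (note that it
  makes θ0 and a individually unidentifiable — only θ0/a matters — which
  the model-comparison penalty treats as an extra degree of freedom).

Measured response times pass through a Gaussian motor filter of width σ_mn,
rejection-resampled into the valid response window.  The filter jitters the
*report*; commitment, reward and cost accrue at the raw decision time.
Heuristic models are tuned noise-free by grid search over their parameters
(maximising the simulated reward rate under common random numbers) and are
then corrupted without retuning.  The combined noise strength is
(σ_y + σ_mn)/(σ̄_y + σ̄_mn) with maxima σ̄_y = 5 and σ̄_mn = 0.25.

First-possible-response convention: a strictly positive bound cannot fire
at the neutral belief y = 0, so the earliest response follows the first
observation; tokens-task subjects may respond at bin 0 only through motor
noise (the 16 response bins are 0..15).

## Fitting and model comparison

Models are fit to tokens-task response-time data only (the marginal
distribution over the 16 bins is the objective; per-trial token sequences
enter the trial-by-trial RMSE metric but not the likelihood — conditioning
the likelihood on each sequence is a possible alternative we did not
adopt).  The model distribution is a Monte-Carlo histogram (default 2000
simulated trials, floored at 1e-6 and renormalised).  Posteriors come from
a Metropolis chain with a diagonal Gaussian random-walk proposal under
bounded flat priors (Rc ∈ (0, 50], c ∈ [0, 10], σ_y ∈ [0, 5],
σ_mn ∈ [0, 0.25], θ0 ∈ (0, 10], a ∈ (0, 10], τ ∈ (0.01, 2]) — wide enough
to contain every threshold regime of the censuses.  Within one chain the
simulated likelihood reuses a fixed seed (common random numbers), making
the pseudo-likelihood surface deterministic.  Proposal scales were set to
give roughly 25% acceptance on synthetic tuning subjects; a chain that
never accepts during its first 500 steps aborts with a proposal-scale
diagnostic.  The first 10% of each chain is discarded before the MAP and
posterior summaries.

Selection metrics: AICc = 2k − 2 ln L̂ + (2k² + 2k)/(n − k − 1) with
k = 4 (NB), 3 (Const), 5 (UGM) free parameters; mean trial-by-trial RMSE
between observed response times and the mean of noisy replays on each
trial's own token sequence; and the KL divergence between data and model
bin distributions.  Ties are reported, never silently broken.

## Synthetic cohorts and what recovery shows

The cohort generator emulates the structure of the human tokens-task
dataset — 15 fair-coin movements per trial at 200 ms, slow/fast conditions,
one binned response time per trial, hundreds of trials per subject — with
subjects drawn from a known generator model.  Cohort parameter ranges are
chosen so each generator class lies in its identifiable regime (e.g. UGM
subjects have bounds that collapse mid-trial rather than instantly;
noise levels centre on a moderate combined strength), which is the regime a
recovery study is informative in.  What passing recovery shows is that the
pipeline can tell the model classes apart and order subjects correctly when
the generating process is one of the three models; it does not show that
human data are generated by any of them, and real data bring non-
stationarity, lapses and strategy mixtures that the generator deliberately
omits.

Raw parameters are not individually identifiable from response times:
NB's reward and cost trade off against each other, and the UGM bound scale
is θ0/a.  Parameter recovery is therefore assessed on the
threshold-governing quantity each parameter set induces — θ0 for Const,
θ0/a for UGM, and for NB the mean (clipped at LLR 8) policy-threshold
profile induced by its (Rc, c) — as a Spearman rank correlation across the
cohort.  Model recovery asks whether AICc selects the generating class for
a majority of subjects.

## Problem sizes

Reference experiment sizes, chosen as desk-scale defaults: motif censuses
on 10×10 grids; robustness comparisons with 20,000 trials per model and
condition; oracle checks with 1e5 Monte-Carlo samples; recovery cohorts of
20 subjects per class at 400 trials each with 2,000-sample chains (a
deliberate reduction from the 10,000-sample chains used for final
inference; the acceptance script further reduces the cohort to 8 subjects
per class and 1,500-sample chains, recording the sizes it used).

## Known limitations

* Asymmetric rewards or priors are unsupported; the solver exploits the
  p ↦ 1−p symmetry throughout.
* The cost function is constant per context piece; arbitrary c(t) shapes
  are not plumbed through.
* The likelihood is a pseudo-likelihood (Monte-Carlo histogram); chains
  mix on a slightly rough surface, which common random numbers mitigate
  but do not remove.
* The inferred-reward solver is a reconstruction on a joint grid; its
  discretisation (and the underflow handling at extreme reward beliefs)
  is ours, and only limiting cases are validated.
* Euler–Maruyama discretisation throughout; no exact SDE integration.
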
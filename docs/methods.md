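# Methods

## The task and the behavioral model

`somtask` analyses a social performance-tracking task. On every trial a
participant (S) is paired with one of two other players (the *relevant
other*, O) in a cooperative (+1) or competitive (−1) context. The
participant decides whether to engage with O against a trial-varying
threshold or to take a zero-mean default, and rates — as a binary
above/below judgement against a staircased half-integer *rating marker* —
the expected performance of S and of O. At the end of the trial all three
players receive integer performance feedback on a 1–15 scale.

The analysis model tracks six performance estimates (three players × two
minigames) with a delta rule,

    performance ← performance + α · (feedback − performance),

and maps estimates to decisions through a softmax with a single inverse
temperature β:

* P(positive rating) = σ(β · (performance − marker)), separately for S
  and O with their own markers;
* P(engage) = σ(β · EV_engage), where EV_engage is
  S − O − threshold in competition and (S + O)/2 − threshold in
  cooperation, and the avoid option is worth 0.

Per decision trial the likelihood has three equally weighted terms (S
rating, O rating, choice); the session negative log-likelihood sums them
over all main-phase trials. One (α, β) pair is fitted per experimental
group across all of its participants and sessions, mirroring the original
group-level fitting strategy. Expected rating values
((p − 0.5)·2·0.25 for positive ratings, 0 for negative ones), the chosen
expected value, and the reward prediction error
RPE = reward − EV_chosen are emitted per trial for downstream use.

Main-session estimates initialize at the last starter-phase feedback of
the same player and minigame. On false-start trials (the participant's
own performance too poor to yield feedback) the payoff is a fixed −3, no
self feedback is shown, the S estimate is not updated, and no S
prediction error exists.

## Self-other mergence (SOM) and the rating GLMs

SOM is the context-dependent intrusion of the *inappropriate* player's
performance history into ability ratings: one's own tracked performance
leaking into ratings of the other (S→O) and vice versa (O→S). It is
measured, per participant-session, as the performance-by-context
interaction coefficient in a logistic regression of the binary ratings
restricted to engage trials (only there does the social context carry
consequences). The interaction model for each rating target uses
{S-performance, O-performance, S-performance × context,
O-performance × context, context, marker}; the binned model drops the
context terms and fits each context separately, and serves as a
consistency check (the pooled interaction coefficient tracks the
cooperation-minus-competition difference of binned coefficients).

Numerical choices:

* all regressors are z-scored within the included trials of a session;
  interaction columns are products of z-scored factors, re-standardized
  afterwards, so coefficients are comparable across sessions;
* an intercept is always included (without one the context coefficient
  would absorb the base rate of positive ratings);
* effects come in a raw-coefficient flavor, used for the stimulation
  contrasts, and a variance-weighted flavor (coefficient / standard
  error), used for baseline descriptives to de-weight noisy sessions;
* perfect or quasi separation (possible with ~40–80 engage trials and 6
  regressors) is flagged per session rather than returning unstable
  estimates; flagged sessions are excluded from group tests with a logged
  count.

## Group-level inference

Baseline tests pool the unstimulated session of every participant and run
two-sided one-sample t-tests on the variance-weighted SOM coefficients
and context main effects. The stimulation analysis is a 2 (group:
dmPFC/vertex) × 2 (condition: cTBS/no-cTBS) mixed-design ANOVA on the raw
S→O SOM coefficient; with a two-level within factor the interaction F
equals the squared two-sample t on per-participant condition differences,
an identity the tests assert against a from-scratch sums-of-squares
oracle. A paired t-test within the dmPFC group accompanies the ANOVA.
Participants missing either session are dropped complete-case with a
logged count. A fully degenerate design (identical values in all cells)
reports F = 0, p = 1 rather than 0/0.

## The synthetic cohort generator

The generator is the ground truth for every pipeline test. It emulates:

* a fully crossed 2(context) × 2(partner) × 2(minigame) main session of
  88 trials (11 per cell, pseudorandom order), preceded by a 16-trial
  starter phase (2 per cell) whose first four trials carry no decisions
  and cover both minigames twice;
* per-player, per-minigame feedback from a slowly drifting latent level
  (reflected Gaussian walk, default drift sd 0.5 per minigame trial) plus
  observation noise (default sd 1.0), rounded and clipped to the integer
  1–15 scale; interleaving the two minigames lowers the lag-1
  autocorrelation of the feedback stream a player actually sees;
* default level means of 8 (S), 9 (O1) and 7 (O2), a realistic mild
  separation of the three players on the 15-point scale;
* thresholds equal to the trial's payoff-relevant feedback quantity plus
  Gaussian noise (default sd 2), which pins the expected engage payoff
  near zero and decorrelates winnings from ability levels (measured
  |r| < 0.1 over 880 trials);
* rating markers staircased ±1 per response, clipped to [1.5, 14.5],
  initialized at 7.5 — the scale midpoint on the half-integer grid; the
  clip keeps both responses meaningful at the scale edges;
* agents that track performance with the same delta rule and softmax as
  the analysis model and whose rating decision variables carry an
  additive SOM term: the inappropriate player's estimate, centred on the
  scale midpoint 8, multiplied by the context and a weight
  (`w_som_StoO`, `w_som_OtoS`). With zero weights the agent *is* the
  analysis model (its estimates re-initialize at the main-phase boundary
  exactly as the model does). The bias acts on the decision variable, not
  on the stored estimate — the minimal mechanism whose GLM signature is
  exactly the measured interaction coefficient;
* a two-group stimulation cohort (default 28 per group) in which every
  session of every participant replays one shared feedback schedule, each
  participant serves in one stimulated and one unstimulated session
  (order counterbalanced), and `ctbs_som_delta` shifts `w_som_StoO` only
  in dmPFC × cTBS sessions. Per-participant (α, β) are truncated normals
  (defaults 0.3 ± 0.1 and 0.8 ± 0.2); baseline SOM weights are normal
  (defaults 0.10 ± 0.15 for S→O, 0.07 ± 0.15 for O→S), producing pooled
  baseline t-statistics of the same order as observed in human cohorts of
  this size. The default `ctbs_som_delta` of 0.4 was calibrated so the
  emulated stimulation effect has the standardized magnitude (paired
  dz ≈ 0.5) reported for the dmPFC manipulation.

What the generator does **not** emulate: the optimism-like context main
effect on O-ability ratings that human participants show strongly (agents
have no such term, so the simulated context main effect sits near zero);
reaction times, fatigue, or order effects; veridical false-start
dynamics (false starts are Bernoulli exclusions, default off); and the
original study's hand-built feedback schedules, which are replaced by a
parameterized walk with the same statistical structure. Passing tests
therefore validate the estimation pipeline, not claims about human
behavior.

## Fitting and numerics

* Group fits minimize the summed session likelihood with bounded L-BFGS-B
  from a fixed 5 × 5 (α, β) start grid (α ∈ {0.1…0.9},
  β ∈ {0.05, 0.2, 0.8, 3, 10}); the three best grid points are refined
  and the final value is never worse than the best raw grid point. The
  procedure is deterministic given the data.
* β is bounded at 20 and decision probabilities floored at 1e-10, keeping
  the likelihood finite under saturation.
* The session pass is vectorized: the delta rule is a first-order linear
  filter in the feedback sequence, so per-series estimates come from
  `scipy.signal.lfilter`, with false-start trials removed from the update
  subsequence.
* Records missing a starter phase (truncated external data) fall back to
  initializing at the first observed main-phase feedback, with a warning.
* Ragged (incomplete) sessions are accepted by the likelihood and trace.

## Test harness choices

Simulation-based checks are scaled to run on one CPU in minutes:
parameter recovery uses one homogeneous 56-participant × 2-session cohort;
estimator calibration uses 200 replicates of 28 single sessions with the
latent pass run at the generating (α, β) — re-fitting the group model per
replicate would only re-test the (separately validated) fitter; the
stimulation-detection check uses 16 participants per group with a shift
of 0.4. The likelihood has a deliberately naive straight-line oracle
re-implementation in the test suite, the logistic fit is checked against
a hand-rolled IRLS, and the mixed ANOVA against a sums-of-squares oracle
plus the F = t² identity.

## Known limitations

* One (α, β) per group, as in the source analysis — no per-participant or
  hierarchical fitting, and no model comparison.
* The SOM mechanism is injected at the decision stage; the data cannot
  distinguish decision-stage from learning-stage mergence, and the
  package does not try.
* The external-data (`osf`) loader is mapping-driven and validates the
  native schema; it does not guess foreign layouts.
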
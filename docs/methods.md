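# Methods

This note documents the models implemented in `probtrack`, the assumptions
behind them, the numerical choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## The task and its generative model

The package models a two-category orientation-categorization experiment in
which the prior probability of category A changes at hidden change points.
The generative model of one session is:

- **Probability path (sample-and-hold).** The category-A probability `pi_t`
  is drawn from a discrete state set (default `{0.2, 0.35, 0.5, 0.65, 0.8}`)
  and held for a segment whose length is discrete-uniform on
  `[run_min, run_max]` (default `[80, 120]` trials). At each change point the
  new state is drawn uniformly from the set *excluding* the current state.
  Segment lengths are i.i.d.; the final segment is truncated at `n_trials`
  (default 800) and is not redrawn if it ends up shorter than `run_min`.
- **Stimuli.** Categories are Gaussian in orientation with equal SD
  `sigma_s = 10°` and means separated by `delta_theta`; the observer's
  measurement adds Gaussian sensory noise `sigma_v`. The separation is
  calibrated so that the discriminability on the *measurement* scale,
  `d' = delta_theta / sqrt(sigma_s² + sigma_v²)`, equals a target (default
  1.5). Defining d′ on the measurement distribution makes the textbook
  equal-prior accuracy `Phi(d'/2) ≈ 0.77` hold for the trained noise level.
- **Responses.** In the *covert* task the observer reports a category; in
  the *overt* task the observer reports the criterion line itself before the
  stimulus. Overt reports add Gaussian adjustment noise `sigma_a` (default
  16°, representative of fitted human observers). Lapses are fixed:
  `1e-4` (covert, uniform over the two choices) and `5e-5` (overt, uniform
  over the 180°-periodic orientation space). Orientations are represented on
  the real line relative to the neutral criterion — spreads are far below
  180°, so only the overt lapse density treats orientation as circular.

All orientations are degrees relative to the neutral criterion
`z_neutral = (mu_A + mu_B)/2`, with category A clockwise (below).

## Observer models

Every model (except RL) maintains a per-trial estimate `pi_hat_A,t` of the
category-A probability from the feedback labels `C_1:t-1` and places its
criterion at the point of posterior equality,

    z_t = z_neutral + sigma_dec² / (mu_B − mu_A) · ln(pi_A / pi_B).

The decision variance `sigma_dec²` is `sigma_s² + sigma_v²` in the covert
task (the decision is applied to the noisy measurement). For the overt task
the criterion is scored against the *true* stimulus, which argues for
`sigma_s²` alone; the source experiment does not pin this down, so the
choice is exposed as a switch (`CategoryModel.overt_uses_sensory_noise`,
default off).

### Bayesian change-point detection family

The observer assumes the sample-and-hold generative model above and filters
an exact joint posterior over the current run length `r_t` (labels since the
last change) and the state `xi_t` that governed the previous run.
Conditioned on `(r_t, xi_t)` the labels of the current run are a sufficient
statistic for the current state, so the weight table plus the label history
is the full posterior. The predictive category probability is the posterior
mean state.

Within one trial the update is: weight each `(r, xi)` by its predictive
probability of the incoming label; grow each run by one; apply the hazard of
the believed discrete-uniform run-length distribution *at the grown length*
(`h(r) = 1/(run_max − r + 1)` inside the support, 0 below, clamped to 1 at
`run_max`, which keeps the table finite without approximation), routing
change mass to `r = 0` with the new "previous state" distributed as the
posterior of the run that just ended; renormalize. This ordering is the one
that agrees *exactly* with brute-force enumeration over all segmentations
(the test suite checks agreement to 1e-10 at T = 10, three states,
run lengths 2–4); likelihood vectors are max-normalized per run length so
long runs cannot underflow.

Belief variants: `bayes_ideal` (veridical beliefs), `bayes_r` (believed run
lengths `Unif[⌊2r/3⌋, r]`, ideal at r = 120), `bayes_pi` (five states evenly
spaced on `[pi_min, 1 − pi_min]`), `bayes_beta` (a `Beta(beta, beta)`
hyperprior reweighting each fresh state draw — the discrete state set is
reweighted by the Beta density and renormalized, the minimal faithful
embedding of a continuous hyperprior on a discrete support), and `bayes_rpb`
(run support `[r, r + dr]`, states on `[pi_min, pi_max]`, `beta` free; we
parameterize the state range directly as `(pi_min, pi_max)`). The Beta
weighting is also applied to the *initial* state draw: at `beta = 1` this is
exactly the uniform initial draw of the task, and it keeps the t = 0 belief
consistent with the post-change prior. The reduction identities
`bayes_r(120) ≡ bayes_pi(0.2) ≡ bayes_beta(1) ≡ bayes_ideal` hold exactly
and are asserted in the tests.

One consequence of the exclusion rule worth noting: on an all-A label
stream the ideal observer's predictive approaches 0.8 only within the first
run window. Once a change is forced (every ≤ 120 trials) the resampled
state cannot remain 0.8, so the posterior hedges between "0.65 now" and
"0.8 again after another change" and the predictive settles near 0.67.

### Heuristic family

- **Fixed**: criterion pinned at neutral (assumes equal probability).
- **Exp**: delta rule `pi_hat ← pi_hat + alpha (C_t − pi_hat)`, initialized
  at 0.5; memory time constant `tau = −1/log(1 − alpha)`.
- **Exp_bias**: the Exp estimate shrunk toward the equal-probability prior,
  `pi_tilde = w·pi_hat + (1 − w)/2` (conservatism weight `w`).
- **Wilson et al. (2013)-style mixture of delta rules**: three nodes
  `l1 = 1 < l2 < l3` with learning rates `1/(l_i + nu_p)`; node weights are
  likelihood-weighted by each node's prediction, hazard mass (h = 0.01,
  matching the 100-trial mean block length) is routed to `l1`, and growth
  mass moves from node i to i+1 with fraction `1/(l_{i+1} − l_i)` so the
  represented mean run length advances by one per trial (top node
  absorbing). The published corrected recursion is not reproduced verbatim;
  the update is instead pinned by its stated limits, both tested: a
  single-node model is exactly Exp, and with h = 0 the top node behaves as a
  fixed-rate delta rule. All weight starts on `l1` (a change is assumed at
  t = 1).
- **RL**: no probability estimate; the criterion moves toward the
  measurement after errors only, `z ← z + alpha_RL (x_t − z)`, starting
  neutral.
- **Behrens et al. (2007)-style volatility learner**: joint grid posterior
  over (probability `pi`, volatility `v`, volatility rate `k`), where the
  probability transition is Beta with mean `pi_t` and concentration
  `exp(v_{t+1})` — shape parameters `(m·c, (1−m)·c)`, keeping the mean a
  martingale — and `v` follows a Gaussian random walk with variance
  `exp(k)`. The nested five-dimensional integral factorises into two
  sequential 1-D kernel convolutions on the grid axes, which is
  mathematically identical and tractable. Grid ranges are not recoverable
  from the source experiment and are configuration: `pi ∈ [0.01, 0.99]`
  linear, concentration `exp(v) ∈ [2, 1e4]` and diffusion
  `exp(k) ∈ [1e-4, 10]` log-spaced, 30 bins per axis, uniform prior.
  Transition kernels are column-normalized on the grid so mass is conserved
  to 1e-9 per trial. An optional conservatism blend (`behrens_bias`) reuses
  the Exp_bias weighting.

## Likelihoods and fitting

Covert: the choice probability is `Phi((z_t − s_t)/sigma_v)` mixed with the
lapse; overt: the report density is a Gaussian centred on the model
criterion with SD `sigma_a` mixed with a `lapse/180` floor. Trials are
conditionally independent given the label history, so the session log
likelihood is a sum. Per task one noise parameter is free — `sigma_v`
(covert) or `sigma_a` (overt, with `sigma_v` fixed at its known generative
value) — keeping model complexity equal across tasks.

The RL criterion depends on the latent measurement history, so its per-trial
probability is approximated by Monte Carlo over 5000 simulated measurement
vectors with common random numbers across parameter values within one fit
(two different seeds move an 800-trial log likelihood by well under 0.5 log
points). Feedback correctness on each trial is read from the observed data
(response vs true category; reported criterion vs true stimulus) rather than
re-simulated, since both are known from the trial table; the covert choice
probability averages `Phi((z_t − s_t)/sigma_v)` over the simulated criterion
paths, which has the same expectation as counting simulated choices but
lower variance.

Fitting evaluates `log p(data|theta) + log p(theta)` on a regular grid
(100 points per axis; 50 for the Wilson model) and integrates it by the
trapezoid rule in log space for the log marginal likelihood (LML). Priors
are uniform in a transformed space and the grid lives in that space:
identity for `sigma_v, sigma_a ∈ [1°, 30°]`, `alpha, w ∈ [0, 1]`,
`r ∈ [2, 200]`, `pi_min ∈ (0, 0.5)`; square root for `beta` (`√beta ∈
(0, 10]`) and the Wilson node gaps (`√delta1 ∈ [1.01, 5]`, `√delta2 ∈
[1.01, 14]`); natural log for `nu_p` (`ln nu_p ∈ [0, 5]` — the log base is
not stated in the source and natural log is the default). Closed bounds
include their endpoints; open bounds are inset by 1e-3 in the transformed
space. `r` values are rounded to integers for the run-length support (the
default 100-point grid on [2, 200] is already integer). Grid LML for a
two-parameter model moves by less than 0.1 log points between 50 and 100
grid points on a 400-trial session.

The six-parameter `bayes_rpb` model is deliberately refused by the grid
path and fitted by bounded multi-start maximum likelihood instead (Powell
with 20 random restarts in the transformed space), scored by AIC/BIC. No
variational approximation of the evidence is provided; the grid LML is the
evidence path for all ≤ 4-parameter models.

## Model comparison

Fixed effects: per-subject ΔLML against a reference model, with bootstrap
CIs (10,000 resamples of subjects with replacement, 2.5/97.5 percentiles).
Random effects: variational Dirichlet-multinomial model selection with a
uniform `Dir(1)` prior, iterated to 1e-6 on the concentration vector;
exceedance probabilities by Monte-Carlo Dirichlet sampling (1e6 seeded
draws, argmax with uniform random tie-breaking); protected exceedance
`phi = EP·(1 − BOR) + BOR/K`, where the Bayes omnibus risk compares the
free energy of the random-effects model against the equal-frequency null.
Evidence is invariant to per-subject additive constants, and `phi → 1/K`
as evidence differences vanish; both are asserted in the tests.

## Validation machinery

Posterior predictive bands resample grid nodes proportionally to posterior
mass and simulate the model on the subject's own stimuli; the covert
summary is the excess-A trajectory (cumulative A responses minus t/2), the
overt summary a 5-trial running-average criterion, both reported as
pointwise mean ± SD (a 68% band). Full-scale settings are 1000 parameter
draws × 10,000 response simulations; the package defaults are scaled to
200 × 1000 (with 30-point grid axes and 400-trial sessions in the recovery
defaults) so that every experiment runs at desk scale, and all counts are
keyword-adjustable back to full scale. Note that with response-averaged
trajectories the covert band reflects parameter uncertainty only and is
much narrower than a single session's random walk; calibration checks
therefore use single-realization simulations, for which the band covers the
generating observer's trajectory at roughly the nominal rate when averaged
over sessions.

Parameter recovery simulates sessions at true parameters drawn from stated
ranges, refits by grid MAP, and reports bias (flagged beyond 2 SE), RMSE
and true-vs-recovered correlation. Overt `sigma_a` recovery is known to be
overestimated on average and is reported, not failed. Model recovery draws
generating parameters from plausible regimes (intervals representative of
fitted human observers in this paradigm), fits every candidate by grid LML
and tallies the best model per dataset into a confusion matrix.

## Known limitations

- The synthetic generator emulates the experiment's statistical structure
  only: no stimulus rendering, reaction times, session breaks, learning of
  the category distributions, or sequential dependencies in lapsing. Passing
  recovery tests therefore demonstrate internal consistency of the pipeline,
  not that human data would be fit equally well.
- The Wilson weight update follows the documented contract and limits, not
  the externally published corrected algebra; results for three-node fits
  may differ in detail from that reference implementation.
- Behrens grid ranges are configuration, and results are sensitive to them
  at extreme volatilities.
- Grid fitting is exhaustive and scales exponentially in the number of
  parameters; it is refused above four dimensions by design.
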
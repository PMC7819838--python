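# Methods

This note documents the statistical procedures implemented in `neosleep`,
the assumptions they make, the design choices taken where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## 1. From epoch scores to censored bouts

A hypnogram is a sequence of 30-second epochs labelled W (wakefulness),
AS (active sleep), TS (transitional sleep) or QS (quiet sleep). The epoch
length is configurable through the `#epoch_length_s` directive in the
epoch table but is 30 s throughout the defaults.

**Minimum-state rule.** A state transition is scored only if the new
state persists for at least one minute (two epochs).
`enforce_min_state_rule` relabels any shorter maximal run: to the shared
flanking state when both neighbours agree, otherwise to the *preceding*
state — a conservative continuation of the ongoing bout, so the eventual
transition is scored at the start of the next full-length run. A
sub-minimum run at the recording start is left untouched (it has no
preceding state, and the first run is excluded from modelling anyway); a
sub-minimum run at the recording end merges backwards, since a state
change to a run that may have been cut short by the recording end is not
scoreable. The operation is idempotent and applied before extraction.

**Bout extraction.** One bout per maximal W/AS/QS run:

- The run in progress at recording start has an unobserved onset; it is
  *left-censored* and excluded from duration modelling (kept in a side
  list for occupancy bookkeeping). Every other run has an observed onset.
- A run extending to the recording end is *right-censored*
  (`event_observed = 0`): its duration is a lower bound, and it
  contributes survival mass to the likelihood.
- TS never forms a modelled bout. A TS run of at least the minimum
  length terminates the preceding bout, and the bout's `next_state` is
  the first non-TS state after the TS run. If the recording ends in TS
  the offset destination is unknown and the bout is treated as censored.
  If the first non-TS state after a TS run equals the bout's own state
  (e.g. W–TS–W), no scoreable state change occurred; the bout's offset is
  likewise treated as unobserved and the following same-state run starts
  a new bout. This situation is not covered by the observed transition
  bookkeeping (offsets are only recorded into W/AS/QS), so the
  conservative reading was chosen.
- Time convention: epoch indices are 0-based, a bout's onset is the
  start time of its first epoch, intervals are half-open [onset, offset),
  and durations are run length × 0.5 min. Bout durations, the
  left-censored first run and TS time partition the recording exactly
  (a tested invariant).

## 2. Censored AFT maximum likelihood

Candidate duration laws, in increasing right-skew: Weibull (shape k,
scale λ; light-tailed for k > 1), exponential (rate), lognormal (meanlog
µ, sdlog σ; heavy-tailed), and a continuous power law (Pareto with
exponent α and fixed lower bound x_min = 1 minute, the minimum scoreable
bout). The power law competes on AIC like the others; Clauset-style
x_min estimation is deliberately omitted because the lower bound is
pinned by the scoring convention.

Covariates enter as accelerated failure time effects: with centered
covariate row x and coefficients β, the bout's time scale is multiplied
by a = exp(βᵀx), giving likelihood terms f(t/a)/a for events and S(t/a)
for censored bouts. exp(β_j) is a duration ratio per covariate unit.
Default centering: PMA at 35 weeks, cortisol at 0.2 µg/dL (the cortisol
covariate is expressed in 0.1 µg/dL units, so one unit of the covariate
is one µg per 10 dL). Centering is recorded in each `FitResult` so fitted
survival curves can be drawn at natural covariate values.

**Optimization.** Parameters are optimized on an unconstrained working
scale (log rate; log shape, log scale; meanlog, log sdlog; log(α − 1))
with L-BFGS-B (ftol 1e-12, gtol 1e-8). Starting values are moment- or
rank-based: the exponential closed form (events ÷ total observed time),
log-duration mean/SD of observed events for the lognormal, rank
regression of log(−log S_KM) on log t for the Weibull, and a Hill-type
estimate for the power law; coefficients start at zero. On failure the
start is jittered (N(0, 0.5²), fixed seed, three restarts); persistent
failure raises a `ConvergenceError` carrying the attempt diagnostics.
Fits are deterministic given the data.

**Standard errors.** Inverse of a central-difference numerical Hessian
(relative step 1e-5) on the working scale, delta-method-transformed to
the natural scale. A non-positive-definite Hessian yields NaN standard
errors with a warning rather than a fabricated value. Confidence
intervals are Wald throughout (symmetric on the log scale for duration
ratios).

**Model selection and tails.** Models are ranked by AIC = 2k − 2 log L
(AICc is available but never the default, matching the reference
analysis); ties break by fewer parameters, then a fixed family order.
The winner maps to a tail class: lognormal/power law → heavy,
exponential → exponential-like, Weibull shape > 1 → light. A Weibull
winner with shape < 1 falls outside this taxonomy and is reported as
heavy with an explicit flag; shape exactly 1 is the exponential boundary.
Covariate entry follows forward inclusion against the PMA-only base
model, accepting additions that reduce AIC
(`forward_select_covariates`); a likelihood-ratio test is provided as a
companion (with the usual caveat that the exponential-in-Weibull null
lies on the boundary of the parameter space, making χ²(1) conservative).

**Kaplan–Meier.** `km_estimate` wraps the product-limit estimator from
`lifelines` and attaches a plain Greenwood pointwise band,
Var[Ŝ(t)] = Ŝ(t)² Σ d_i/(n_i(n_i − d_i)), clipped to [0, 1]. With no
censoring it reproduces the empirical survival function exactly (tested).
Fitted survival curves carry a delta-method band propagated from the
working-scale covariance.

Bouts from the same infant are treated as independent — no frailty or
clustering adjustment is applied, mirroring the reference analysis; with
few bouts per short recording the within-subject information is limited,
but standard errors may be slightly optimistic for covariates shared
within subjects.

## 3. Perturbation analysis

Observed bout offsets are transitions, classed *awakening* (into W) or
*sleep-to-sleep*. A transition is inside a post-event window if it falls
in the half-open interval [0, 5) minutes after any same-subject event of
the chosen kind; overlapping windows count a transition once. The 2×2
class-by-window table is tested with the likelihood-ratio (G) chi-square
statistic, G = 2 Σ O log(O/E) (0·log 0 = 0; a zero margin is an error),
and summarized with Cramér's V = √(G/n) for 2×2 tables. The G-test is
used because the hypothesis concerns a likelihood-ratio contingency
comparison; it agrees with Pearson's χ² within 10% when expected counts
are ≥ 10 (tested). Latencies are measured to the most recent prior
same-subject event and summarized with the adjusted Fisher–Pearson
skewness (the small-sample-corrected form); strongly right-skewed
awakening latencies indicate short-lag triggered awakenings. The cohort
splits at 34 weeks PMA (configurable) into younger/older groups, the
boundary above which lance-evoked awakenings appear. Repeated lances in
one subject are treated as independent events.

## 4. The semi-Markov generator

`simulate_subject` builds an alternating-renewal sequence:

- **Duration laws** (defaults, minutes): W ~ lognormal(3.187, 0.996),
  AS ~ lognormal(4.137, 0.891), QS ~ Weibull(2.181, 34.243) — the fitted
  cohort estimates used as generative truth.
- **Embedded chain** (defaults): W→AS always; AS→QS 49/75, AS→W 26/75;
  QS→AS 117/118, QS→W 1/118 — the observed offset proportions. Rows must
  sum to one; the configured chain must be irreducible for occupancy
  computations.
- **Covariate effects**, multiplicative on duration (AFT-consistent,
  centered at 35 weeks / 0.2 µg/dL): per-week PMA factors 1.146 (W),
  0.945 (AS), 1.027 (QS); cortisol factor 1.335 per 0.1 µg/dL on W. For
  AS the destination is drawn first and the duration of
  quiet-sleep-destined bouts is multiplied by 1.602 — one generative
  mechanism consistent with the fitted destination effect (the marginal
  AS law is then a two-component lognormal mixture slightly longer than
  the configured law; the configured parameters are exactly recovered
  when the destination indicator is included in the fit).
- **Recording window**: length uniform on 44–70 minutes (the cohort
  interquartile range), right-censoring the final bout. The initial bout
  is an equilibrium draw — state by renewal-reward occupancy, full
  duration length-biased (with destination odds weighted by component
  mean for AS), residual uniform — so window occupancy is unbiased; the
  extractor discards this first run as left-censored, mirroring the
  analysis pathway.
- **TS filler**: inserted after a bout with probability 0.3, duration
  lognormal(log 1.5, 0.5) minutes. TS exists purely to exercise the
  extraction rules; it is never fitted.
- **Quantization**: durations round to the nearest 30-s epoch with a
  two-epoch (one-minute) floor.
- **Sensory events**: one lance with probability 0.58 and one
  non-noxious stimulus with probability 0.77 per recording (the cohort
  fractions receiving each), at uniform times. In subjects of ≥ 34 weeks
  PMA, a lance falling inside an AS bout truncates it to an awakening
  with probability 0.5, at an exponential latency (mean 1.5 min,
  truncated below the 5-minute window), producing the right-skewed
  latency clustering the perturbation analysis detects. Non-noxious
  stimuli never trigger.

`expected_occupancy` is the analytic companion: stationary distribution
of the embedded chain weighted by mean bout durations (destination
mixture included for AS, TS filler added per transition), normalized. A
200-subject Monte-Carlo cohort matches it within 2% absolute per state
(tested) when the lance trigger is inactive; the trigger intentionally
shifts occupancy toward W in older infants, which the analytic formula
does not model.

Cohorts derive per-subject seeds from one master seed
(`SeedSequence.spawn`), so every hypnogram is reproducible from
(truth, seed, subject index) and cohorts are bit-identical across runs.
The default covariate sampler draws PMA uniform on 28–40 weeks,
postnatal age uniform on 0.5–60 days, a 0.3-probability high-risk flag
and lognormal cortisol (median 0.22 µg/dL, log-SD 0.5, spanning roughly
0.1–0.8 µg/dL).

Successive bout durations are conditionally independent given
covariates; no within-subject serial correlation is modelled (none is
quantified in the reference analysis). There is no circadian structure
(absent in neonates) and no feeding/caregiving model.

## 5. Recovery experiments and problem sizes

Because the infant recordings are not redistributable, validation is by
generator/estimator consistency (`neosleep.recovery`):

- **Duration laws**: 5,000 bouts per state, right-censored at uniform
  recording remainders — (44, 70) min for W, (20, 70) for QS and
  (30, 70) for AS, the latter two shortened to mimic onsets later in the
  recording so that the unobserved-offset fractions match the observed
  bookkeeping (~25% QS, ~59% AS). Recovered parameters fall within 3 SE
  of truth.
- **AFT factors**: 500 subjects (one bout each) with PMA uniform on
  28–40 weeks (cortisol uniform on 0.11–0.81 µg/dL for the stress
  effect; 800 uncensored bouts for the AS destination effect, since the
  destination is only knowable for observed offsets). Across 200
  replicates the Wald 95% CIs cover truth in ≥ 90% of replicates.
- **Model selection**: at 1,500 bouts per state, AIC selects the
  lognormal for W and AS and the Weibull for QS in ≥ 95% of 20
  replicates.

These sizes keep the full suite under two minutes on one CPU while
leaving the Monte-Carlo error well inside the assertion tolerances.

## 6. What passing tests do and do not show

The generator realizes exactly the model the estimator assumes, so
recovery tests validate the estimation machinery, not the model's
adequacy for real infants. Real hypnograms may violate conditional
independence of successive bouts, may mix scorer-dependent TS handling,
and may contain covariate measurement error (cortisol averaging) — none
of which the generator emulates. Parameter recovery under the emulated
censoring regime demonstrates that, *if* bout durations follow the
fitted laws, recordings of this length carry enough information to
identify them; it cannot confirm the laws themselves.

## 7. Known limitations

- No frailty/random effects, interval censoring, time-varying
  covariates or spline hazards (out of scope by design).
- Wald intervals and numerical Hessians can misbehave at small n or on
  flat likelihoods; standard errors are then reported as NaN rather than
  guessed.
- The power-law family with AFT covariates has support t ≥ a·x_min;
  bouts below the accelerated lower bound yield infinite negative
  log-likelihood (signalled, not clipped), so the family is effectively
  usable only without strongly negative accelerations.
- The perturbation report treats repeated lances as independent and
  latencies as unpaired; with very few events per subject this matches
  the reference treatment but understates within-subject correlation.
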
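# neosleep

Survival analysis of neonatal sleep–wake bout durations, with a
semi-Markov hypnogram simulator.

Preterm and term infants spend most of their time asleep, and the
*durations* of their wakefulness (W), active sleep (AS) and quiet sleep
(QS) bouts carry information about how these states are regulated: an
exponential bout-duration distribution implies memoryless exits, a
light-tailed (Weibull, shape > 1) distribution implies a bias toward the
opposing state, and a heavy-tailed (lognormal) distribution implies state
stability that makes long bouts last even longer. Because cot-side
recordings are short (typically 44–70 minutes), many bouts never end
within the recording and their durations are right-censored — which is
exactly the setting of parametric survival analysis.

`neosleep` is for researchers analysing epoch-scored neonatal sleep–wake
data (30-second epochs labelled W/AS/TS/QS). It provides:

- **Censored bout extraction** — the one-minute minimum-state rule,
  conversion of epoch sequences into bout records with onset/offset
  censoring flags, look-through of transitional sleep (TS), transition
  bookkeeping and state-occupancy summaries.
- **Duration-law fitting** — censored maximum likelihood for exponential,
  Weibull, lognormal and power-law bout-duration models with accelerated
  failure time (AFT) covariates, AIC model selection, tail
  classification, Kaplan–Meier curves, Wald duration-ratio confidence
  intervals and likelihood-ratio tests. The fitting engine is a
  scikit-learn-style estimator (`CensoredAFT`) that composes with
  sklearn tooling.
- **Perturbation analysis** — clustering of awakenings in the 5 minutes
  after a noxious heel lance versus a non-noxious control stimulus:
  window counts, likelihood-ratio (G) tests, Cramér's V and latency
  skewness, split by postmenstrual age (PMA) group.
- **A semi-Markov simulator** — synthetic cohorts of epoch-scored
  hypnograms with the exact statistical structure the analysis assumes
  (state-specific duration laws, embedded transition chain, AFT
  covariate effects, recording-window censoring, age-gated lance-evoked
  awakenings), used for testing, power studies and parameter recovery.

## The model

For a bout of state *s* with duration *T* and covariate row *x* (PMA in
weeks centered at 35, cortisol in 0.1 µg/dL units centered at 0.2 µg/dL,
…), the AFT model stretches time by the acceleration factor
*a* = exp(βᵀx):

  log-likelihood term = log *f*(*t*/*a*) − log *a*  (offset observed)
                 or  = log *S*(*t*/*a*)             (right-censored)

where *f* and *S* are the density and survival function of the candidate
family. exp(β_j) is the duration ratio per unit of covariate *j*. The
family minimizing AIC = 2k − 2·log L is selected per state and mapped to a
tail class (lognormal/power law → heavy, exponential → exponential-like,
Weibull shape > 1 → light).

## Worked example

```python
import numpy as np
from neosleep import (SimConfig, sample_bout_frame, fit_censored,
                      select_model, classify_tail, acceleration_factor)

config = SimConfig()              # defaults = the reference cohort model
rng = np.random.default_rng(0)

# 5,000 active-sleep bouts, right-censored at uniform recording remainders
frame = sample_bout_frame(config, "AS", 5000, rng, censor_range=(30, 70))
fits = [fit_censored(f, frame["duration_min"], frame["event_observed"])
        for f in ("exponential", "weibull", "lognormal")]
sel = select_model(fits)
print(sel.to_frame().to_string(index=False))
best = sel.best
print("tail:", classify_tail(best).label)
print("meanlog = %.3f (SE %.3f), sdlog = %.3f (SE %.3f)" % (
    best.baseline_params["meanlog"], best.se["meanlog"],
    best.baseline_params["sdlog"], best.se["sdlog"]))

# PMA effect on wake bouts: one bout per simulated subject
frame = sample_bout_frame(config, "W", 500, rng, pma=(28, 40),
                          censor_range=(44, 70))
fit = fit_censored("lognormal", frame["duration_min"],
                   frame["event_observed"], X=frame[["pma_weeks"]])
af = acceleration_factor(fit, "pma_weeks")
print("wake duration ratio per week of PMA: %.3f [95%% CI %.3f-%.3f]"
      % (af.factor, af.ci_low, af.ci_high))
```

prints

```
     family          aic  k      delta
  lognormal 21722.032567  2   0.000000
    weibull 21831.443462  2 109.410895
exponential 22501.942795  1 779.910228
tail: heavy
meanlog = 4.110 (SE 0.017), sdlog = 0.864 (SE 0.015)
wake duration ratio per week of PMA: 1.145 [95% CI 1.115-1.176]
```

The lognormal wins the AIC comparison for active sleep (heavy tail), and
the recovered parameters sit within two standard errors of the generating
truth (meanlog 4.137, sdlog 0.891); the wake AFT fit recovers the
generating 1.146-per-week PMA acceleration.

## Command line

```sh
neosleep simulate --seed 1 --out cohort/ --n-subjects 175
neosleep fit      --epochs cohort/epochs.tsv \
                  --covariates-table cohort/covariates.csv --out results/
neosleep perturb  --epochs cohort/epochs.tsv \
                  --covariates-table cohort/covariates.csv \
                  --events cohort/events.csv --out results/
neosleep report   --config run.yaml
```

`simulate` writes the three input tables (epoch TSV, covariate CSV, event
CSV) plus a `truth.json` record of the generating parameters; `fit`
writes `fit_report.json` (per-state fits, AIC deltas, tail classes,
duration-ratio CIs) with Kaplan–Meier and fitted survival curves as CSV;
`perturb` writes the window/association/latency report. Every report
embeds the seed, a config hash and the package version, and reruns are
byte-identical.

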
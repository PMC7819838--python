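"""Semi-Markov (alternating renewal) generator of synthetic neonatal hypnograms.

The generator realizes the statistical structure the analysis assumes, so
every downstream stage can be exercised and validated without real
recordings:

* state-specific bout-duration laws (lognormal wake and active sleep,
  Weibull quiet sleep, parameter defaults from the fitted cohort model);
* an embedded transition chain (wake always offsets into active sleep;
  quiet sleep almost always returns to active sleep);
* multiplicative accelerated-failure-time covariate effects: per-week
  postmenstrual-age factors per state, a cortisol factor on wake
  durations, and an active-sleep destination effect (bouts destined for
  quiet sleep run longer than those destined for wakefulness — the
  destination is drawn first, then the duration);
* transitional-sleep filler inserted at transitions, exercising the
  extraction rules without being modelled;
* finite recordings (length drawn uniformly over the cohort's
  interquartile range) that right-censor the final bout, with the initial
  bout drawn from the equilibrium (length-biased) law so the window is
  stationary — the extractor discards it as left-censored;
* age-gated lance-evoked awakenings: in subjects of at least 34 weeks
  postmenstrual age, a heel lance falling inside an active-sleep bout can
  truncate it to an awakening within the following minutes.

Durations are quantized to 30-second epochs with a two-epoch (one-minute)
floor, matching the scoring convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hypnogram import BOUT_STATES, Hypnogram, SensoryEvent, SubjectCovariates

_LAW_FAMILIES = ("lognormal", "weibull", "exponential", "powerlaw", "fixed")


@dataclass(frozen=True)
class DurationLaw:
    """A parametric bout-duration law (minutes) with a scale-factor hook.

    ``factor`` arguments below multiply duration (AFT convention):
    lognormal shifts meanlog by log(factor), Weibull multiplies scale,
    exponential divides rate.  The ``fixed`` family is a point mass used in
    degenerate test configurations.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _LAW_FAMILIES:
            raise ValueError(f"unknown duration-law family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))

    def sample(self, rng: np.random.Generator, n=None, factor: float = 1.0):
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(p["meanlog"] + math.log(factor), p["sdlog"], size=n)
        if self.family == "weibull":
            return factor * p["scale"] * rng.weibull(p["shape"], size=n)
        if self.family == "exponential":
            return rng.exponential(factor / p["rate"], size=n)
        if self.family == "powerlaw":
            u = rng.random(size=n)
            x_min = p.get("x_min", 1.0)
            return factor * x_min * (1.0 - u) ** (-1.0 / (p["alpha"] - 1.0))
        return factor * p["value"] * (np.ones(n) if n is not None else 1.0)

    def mean(self, factor: float = 1.0) -> float:
        p = self.params
        if self.family == "lognormal":
            return factor * math.exp(p["meanlog"] + 0.5 * p["sdlog"] ** 2)
        if self.family == "weibull":
            return factor * p["scale"] * math.gamma(1.0 + 1.0 / p["shape"])
        if self.family == "exponential":
            return factor / p["rate"]
        if self.family == "powerlaw":
            a = p["alpha"]
            if a <= 2:
                raise ValueError("power-law mean undefined for exponent <= 2")
            return factor * p.get("x_min", 1.0) * (a - 1.0) / (a - 2.0)
        return factor * p["value"]

    def sample_length_biased(self, rng: np.random.Generator, factor: float = 1.0) -> float:
        """One draw from the length-biased law t f(t) / E[T] (equilibrium bout)."""
        p = self.params
        if self.family == "lognormal":
            mu = p["meanlog"] + math.log(factor) + p["sdlog"] ** 2
            return float(rng.lognormal(mu, p["sdlog"]))
        if self.family == "weibull":
            k = p["shape"]
            y = rng.gamma(1.0 + 1.0 / k)
            return float(factor * p["scale"] * y ** (1.0 / k))
        if self.family == "exponential":
            return float(rng.gamma(2.0) * factor / p["rate"])
        if self.family == "fixed":
            return factor * p["value"]
        # powerlaw: length-biased Pareto(alpha-1) is Pareto(alpha-2) for alpha > 2
        a = p["alpha"]
        x_min = p.get("x_min", 1.0)
        if a <= 2:
            return float(self.sample(rng, factor=factor))
        u = rng.random()
        return float(factor * x_min * (1.0 - u) ** (-1.0 / (a - 2.0)))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DurationLaw":
        return cls(family=d["family"], params=dict(d["params"]))


def _default_duration_laws() -> dict[str, DurationLaw]:
    return {
        "W": DurationLaw("lognormal", {"meanlog": 3.187, "sdlog": 0.996}),
        "AS": DurationLaw("lognormal", {"meanlog": 4.137, "sdlog": 0.891}),
        "QS": DurationLaw("weibull", {"shape": 2.181, "scale": 34.243}),
    }


def _default_transition_probs() -> dict[str, dict[str, float]]:
    return {
        "W": {"AS": 1.0},
        "AS": {"QS": 49 / 75, "W": 26 / 75},
        "QS": {"AS": 117 / 118, "W": 1 / 118},
    }


@dataclass
class SimConfig:
    """Full parameterization of the semi-Markov hypnogram generator.

    Defaults reproduce the fitted cohort model: duration laws and
    transition proportions from the observed bout bookkeeping, per-week
    postmenstrual-age multipliers per state, a cortisol multiplier (per
    0.1 ug/dL above the 0.2 ug/dL reference) on wake durations, and the
    active-sleep destination effect (quiet-sleep-destined bouts 1.602x
    longer).  Recording lengths are uniform over the cohort interquartile
    range, 44-70 minutes.
    """

    duration_laws: dict[str, DurationLaw] = field(default_factory=_default_duration_laws)
    transition_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_transition_probs
    )
    pma_factors: dict[str, float] = field(
        default_factory=lambda: {"W": 1.146, "AS": 0.945, "QS": 1.027}
    )
    pma_center_weeks: float = 35.0
    cortisol_factor_w: float = 1.335
    cortisol_center10: float = 2.0  # 0.1 ug/dL units
    nextstate_factor_as: float = 1.602
    ts_insertion_prob: float = 0.3
    ts_law: DurationLaw = field(
        default_factory=lambda: DurationLaw("lognormal", {"meanlog": math.log(1.5), "sdlog": 0.5})
    )
    recording_min_range: tuple[float, float] = (44.0, 70.0)
    epoch_length_s: float = 30.0
    min_epochs: int = 2
    lance_prob: float = 0.58
    non_noxious_prob: float = 0.77
    awakening_trigger_prob: float = 0.5
    trigger_pma_min_weeks: float = 34.0
    trigger_latency_mean_min: float = 1.5
    trigger_window_min: float = 5.0

    def __post_init__(self) -> None:
        for state, row in self.transition_probs.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities for {state} sum to {total}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative transition probability for {state}")
            if state in row:
                raise ValueError(f"self-transition not allowed ({state})")
        for name, value in [
            *((f"pma_factors[{s}]", v) for s, v in self.pma_factors.items()),
            ("cortisol_factor_w", self.cortisol_factor_w),
            ("nextstate_factor_as", self.nextstate_factor_as),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ts_insertion_prob <= 1:
            raise ValueError("ts_insertion_prob must be in [0, 1]")

    @property
    def epoch_min(self) -> float:
        return self.epoch_length_s / 60.0

    def state_factor(self, state: str, covariates: SubjectCovariates) -> float:
        """Multiplicative AFT duration factor for a state given covariates."""
        f = 1.0
        pma = covariates.pma_weeks
        if pma is not None and state in self.pma_factors:
            f *= self.pma_factors[state] ** (pma - self.pma_center_weeks)
        if state == "W" and covariates.cortisol_ug_dl is not None:
            f *= self.cortisol_factor_w ** (
                10.0 * covariates.cortisol_ug_dl - self.cortisol_center10
            )
        return f

    def to_dict(self) -> dict:
        return {
            "duration_laws": {s: law.to_dict() for s, law in self.duration_laws.items()},
            "transition_probs": {s: dict(r) for s, r in self.transition_probs.items()},
            "pma_factors": dict(self.pma_factors),
            "pma_center_weeks": self.pma_center_weeks,
            "cortisol_factor_w": self.cortisol_factor_w,
            "cortisol_center10": self.cortisol_center10,
            "nextstate_factor_as": self.nextstate_factor_as,
            "ts_insertion_prob": self.ts_insertion_prob,
            "ts_law": self.ts_law.to_dict(),
            "recording_min_range": list(self.recording_min_range),
            "epoch_length_s": self.epoch_length_s,
            "min_epochs": self.min_epochs,
            "lance_prob": self.lance_prob,
            "non_noxious_prob": self.non_noxious_prob,
            "awakening_trigger_prob": self.awakening_trigger_prob,
            "trigger_pma_min_weeks": self.trigger_pma_min_weeks,
            "trigger_latency_mean_min": self.trigger_latency_mean_min,
            "trigger_window_min": self.trigger_window_min,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "duration_laws" in d:
            d["duration_laws"] = {
                s: DurationLaw.from_dict(v) for s, v in d["duration_laws"].items()
            }
        if "ts_law" in d:
            d["ts_law"] = DurationLaw.from_dict(d["ts_law"])
        if "recording_min_range" in d:
            d["recording_min_range"] = tuple(d["recording_min_range"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Simulated hypnograms together with the generating truth."""

    hypnograms: list[Hypnogram]
    truth: SimConfig
    seed: int | None = None


def _stationary_embedded(config: SimConfig) -> dict[str, float]:
    """Stationary distribution of the embedded bout-state transition chain.

    The chain is defined over the states the transition map specifies; a
    configuration may restrict itself to a subset (e.g. a pure AS/QS cycle).
    """
    states = [s for s in BOUT_STATES if s in config.transition_probs]
    targets = {t for row in config.transition_probs.values() for t in row}
    if not targets <= set(states):
        raise ValueError(
            f"transition targets {sorted(targets - set(states))} have no outgoing row; "
            "chain is reducible"
        )
    n = len(states)
    P = np.zeros((n, n))
    for i, s in enumerate(states):
        for t, p in config.transition_probs[s].items():
            P[i, states.index(t)] = p
    reach = np.linalg.matrix_power(np.eye(n) + (P > 0), n)
    if np.any(reach == 0):
        raise ValueError("transition chain is reducible; no stationary distribution")
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    return dict(zip(states, pi))


def _mean_bout_duration(config: SimConfig, state: str, covariates: SubjectCovariates) -> float:
    """Mean bout duration in minutes, marginal over the destination draw."""
    law = config.duration_laws[state]
    f = config.state_factor(state, covariates)
    if state != "AS":
        return law.mean(f)
    total = 0.0
    for dest, p in config.transition_probs["AS"].items():
        dest_f = config.nextstate_factor_as if dest == "QS" else 1.0
        total += p * law.mean(f * dest_f)
    return total


def expected_occupancy(
    config: SimConfig,
    covariates: SubjectCovariates | None = None,
    include_ts: bool = True,
) -> dict[str, float]:
    """Analytic stationary occupancy: visit rate x mean duration, normalized.

    Renewal-reward argument: each embedded-chain visit to state ``s``
    contributes its mean bout duration; transitional-sleep filler
    contributes ``ts_insertion_prob x mean TS duration`` per transition.
    """
    covariates = covariates or SubjectCovariates()
    pi = _stationary_embedded(config)
    weights = {s: pi[s] * _mean_bout_duration(config, s, covariates) for s in pi}
    if include_ts:
        weights["TS"] = config.ts_insertion_prob * config.ts_law.mean()
    total = sum(weights.values())
    return {s: w / total for s, w in weights.items()}


def _draw_from(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    states = list(probs)
    return states[rng.choice(len(states), p=np.array([probs[s] for s in states]))]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_subject(
    config: SimConfig,
    covariates: SubjectCovariates,
    seed,
    subject_id: str = "sim",
) -> Hypnogram:
    """Generate one subject's epoch-scored hypnogram with events.

    Deterministic for a fixed (config, covariates, seed) triple.  The
    initial bout is drawn from the equilibrium (length-biased residual)
    law and is left-censored by construction; the final bout is truncated
    at the drawn recording length (right-censored).
    """
    if not isinstance(covariates, SubjectCovariates):
        raise TypeError("covariates must be a SubjectCovariates instance")
    rng = _as_rng(seed)
    epoch_min = config.epoch_min
    rec_draw = rng.uniform(*config.recording_min_range)
    n_epochs = max(config.min_epochs, int(round(rec_draw / epoch_min)))
    rec_len = n_epochs * epoch_min

    events: list[SensoryEvent] = []
    if rng.random() < config.lance_prob:
        events.append(SensoryEvent(subject_id, float(rng.uniform(0, rec_len)), "lance"))
    if rng.random() < config.non_noxious_prob:
        events.append(SensoryEvent(subject_id, float(rng.uniform(0, rec_len)), "non_noxious"))
    events.sort(key=lambda e: e.time_min)
    lance_times = [e.time_min for e in events if e.kind == "lance"]

    occ = expected_occupancy(config, covariates, include_ts=False)
    state = _draw_from(rng, occ)
    age_gated = (
        covariates.pma_weeks is not None
        and covariates.pma_weeks >= config.trigger_pma_min_weeks
    )

    epochs: list[str] = []
    used_lances: set[int] = set()
    first = True
    while len(epochs) < n_epochs:
        row = config.transition_probs[state]
        law = config.duration_laws[state]
        base_factor = config.state_factor(state, covariates)
        if first:
            # equilibrium snapshot: the in-progress bout is length-biased, so
            # its destination is drawn with mean-duration-weighted odds and its
            # residual is uniform over a length-biased full duration
            weights = {
                d: p
                * law.mean(
                    base_factor
                    * (config.nextstate_factor_as if state == "AS" and d == "QS" else 1.0)
                )
                for d, p in row.items()
            }
            total_w = sum(weights.values())
            next_state = _draw_from(rng, {d: w / total_w for d, w in weights.items()})
            factor = base_factor
            if state == "AS" and next_state == "QS":
                factor *= config.nextstate_factor_as
            full = law.sample_length_biased(rng, factor)
            dur = float(rng.uniform(0.0, full))  # residual of the in-progress bout
            first = False
        else:
            next_state = _draw_from(rng, row)
            factor = base_factor
            if state == "AS" and next_state == "QS":
                factor *= config.nextstate_factor_as
            dur = float(law.sample(rng, factor=factor))
        n_ep = max(config.min_epochs, int(round(dur / epoch_min)))

        triggered = False
        if state == "AS" and age_gated:
            start_ep = len(epochs)
            for li, lt in enumerate(lance_times):
                if li in used_lances:
                    continue
                le = int(lt / epoch_min)
                if start_ep <= le < start_ep + n_ep:
                    if rng.random() < config.awakening_trigger_prob:
                        latency = min(
                            rng.exponential(config.trigger_latency_mean_min),
                            config.trigger_window_min - epoch_min,
                        )
                        n_trunc = (le - start_ep) + max(
                            1, int(round(latency / epoch_min))
                        )
                        n_trunc = max(config.min_epochs, n_trunc)
                        if n_trunc < n_ep:
                            n_ep = n_trunc
                            next_state = "W"
                            triggered = True
                    used_lances.add(li)
                    break
        epochs.extend([state] * n_ep)
        if not triggered and len(epochs) < n_epochs and rng.random() < config.ts_insertion_prob:
            ts_ep = max(
                config.min_epochs,
                int(round(config.ts_law.sample(rng) / epoch_min)),
            )
            epochs.extend(["TS"] * ts_ep)
        state = next_state

    return Hypnogram(
        subject_id=subject_id,
        states=epochs[:n_epochs],
        epoch_length=config.epoch_length_s,
        events=events,
        covariates=covariates,
    )


def default_covariate_sampler(rng: np.random.Generator) -> SubjectCovariates:
    """Cohort-like covariates: PMA uniform 28-40 weeks, lognormal cortisol."""
    pma = float(rng.uniform(28.0, 40.0))
    postnatal = float(rng.uniform(0.5, 60.0))
    cortisol = float(np.exp(rng.normal(math.log(0.22), 0.5)))
    return SubjectCovariates(
        pma_weeks=pma,
        postnatal_age_days=postnatal,
        risk_high=int(rng.random() < 0.3),
        cortisol_ug_dl=cortisol,
    )


def simulate_cohort(
    config: SimConfig,
    n_subjects: int,
    covariate_sampler: Callable[[np.random.Generator], SubjectCovariates] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate an independent-subject cohort from one master seed.

    Per-subject randomness comes from ``SeedSequence(seed).spawn``, so each
    hypnogram is reproducible from (truth, seed, subject index) and the
    cohort is bit-identical across runs.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    sampler = covariate_sampler or default_covariate_sampler
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    hypnograms = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        covs = sampler(rng)
        sid = f"S{i + 1:04d}"
        hypnograms.append(simulate_subject(config, covs, rng, subject_id=sid))
    return SyntheticCohort(hypnograms=hypnograms, truth=config, seed=seed)


def sample_bout_frame(
    config: SimConfig,
    state: str,
    n: int,
    rng,
    pma=None,
    cortisol_ug_dl=None,
    draw_destination: bool = False,
    censor_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Draw ``n`` bout durations of one state directly from the generator laws.

    This is the law-level sampler used for parameter-recovery studies: it
    applies the same covariate machinery as the hypnogram generator
    (per-week PMA factors, the wake cortisol factor, the active-sleep
    destination effect with the destination drawn first) but skips epoch
    quantization and sequence assembly.  ``pma`` / ``cortisol_ug_dl`` may
    be scalars, arrays of length n, or (lo, hi) tuples sampled uniformly.
    ``censor_range`` right-censors each bout at an independent uniform
    recording remainder.

    Returns a frame with ``duration_min``, ``event_observed`` and centered
    covariate columns (``pma_weeks``, ``cortisol10``, ``dest_qs``) ready
    for :func:`neosleep.survival.fit_censored`.
    """
    if state not in config.duration_laws:
        raise KeyError(f"no duration law for state {state!r}")
    rng = _as_rng(rng)

    def _expand(v, lo_hi_ok=True):
        if v is None:
            return None
        if np.isscalar(v):
            return np.full(n, float(v))
        v = np.asarray(v, dtype=float)
        if v.shape == (2,) and lo_hi_ok:
            return rng.uniform(v[0], v[1], size=n)
        if v.shape != (n,):
            raise ValueError("covariate array must have length n")
        return v

    pma_arr = _expand(pma)
    cort_arr = _expand(cortisol_ug_dl)
    factors = np.ones(n)
    out: dict[str, np.ndarray] = {}
    if pma_arr is not None:
        factors *= config.pma_factors[state] ** (pma_arr - config.pma_center_weeks)
        out["pma_weeks"] = pma_arr - config.pma_center_weeks
    if cort_arr is not None and state == "W":
        cort10 = 10.0 * cort_arr
        factors *= config.cortisol_factor_w ** (cort10 - config.cortisol_center10)
        out["cortisol10"] = cort10 - config.cortisol_center10
    dest = None
    if draw_destination:
        if state != "AS":
            raise ValueError("destination draw only applies to active sleep")
        row = config.transition_probs["AS"]
        p_qs = row.get("QS", 0.0)
        dest = (rng.random(n) < p_qs).astype(float)
        factors *= np.where(dest > 0, config.nextstate_factor_as, 1.0)
        out["dest_qs"] = dest
    law = config.duration_laws[state]
    base = law.sample(rng, n=n)
    durations = base * factors
    if censor_range is not None:
        c = rng.uniform(censor_range[0], censor_range[1], size=n)
        event = (durations <= c).astype(float)
        durations = np.minimum(durations, c)
    else:
        event = np.ones(n)
    frame = pd.DataFrame({"duration_min": durations, "event_observed": event})
    for k, v in out.items():
        frame[k] = v
    return frame
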
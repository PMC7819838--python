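"""End-to-end orchestration: ingest tables, extract bouts, fit, perturb, simulate.

Every run is parameterized by a :class:`RunConfig` (YAML-loadable), seeded
from a single master seed, and emits JSON/CSV reports that embed the config
hash, seed and package version so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .hypnogram import (
    Bout,
    Hypnogram,
    enforce_min_state_rule,
    extract_bouts,
    state_percentages,
    transition_table,
)
from .io import (
    read_hypnograms,
    write_bout_table,
    write_covariate_table,
    write_epoch_table,
    write_event_table,
)
from .perturbation import perturbation_report
from .simulate import SimConfig, simulate_cohort
from .survival import (
    ConvergenceError,
    CovariateSpec,
    acceleration_factor,
    classify_tail,
    covariate_value,
    fit_family,
    fitted_survival,
    km_estimate,
    select_model,
)

logger = logging.getLogger("neosleep")

DEFAULT_FAMILIES = ("exponential", "weibull", "lognormal")


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    epoch_path: str | None = None
    covariate_path: str | None = None
    event_path: str | None = None
    out_dir: str = "neosleep_out"
    states: tuple[str, ...] = ("W", "AS", "QS")
    families: tuple[str, ...] = DEFAULT_FAMILIES
    covariates: tuple[str, ...] = ("pma_weeks",)
    window_min: float = 5.0
    pma_split_weeks: float = 34.0
    n_subjects: int = 175
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        for key in ("states", "families", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "epoch_path": self.epoch_path,
            "covariate_path": self.covariate_path,
            "event_path": self.event_path,
            "out_dir": self.out_dir,
            "states": list(self.states),
            "families": list(self.families),
            "covariates": list(self.covariates),
            "window_min": self.window_min,
            "pma_split_weeks": self.pma_split_weeks,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "log_level": self.log_level,
            "sim": self.sim.to_dict(),
        }
        return d

    def config_hash(self) -> str:
        """Hash of the analytically relevant parameters (not output/log paths)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def setup_logging(config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handlers = [logging.StreamHandler()]
    handlers.append(logging.FileHandler(out / "run.log"))
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _provenance(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_and_extract(config: RunConfig) -> tuple[dict[str, Hypnogram], list[Bout]]:
    """Read input tables, apply the minimum-state rule, extract modelled bouts."""
    if config.epoch_path is None:
        raise ValueError("epoch_path is required")
    hypnograms = read_hypnograms(
        config.epoch_path, config.covariate_path, config.event_path
    )
    bouts: list[Bout] = []
    for h in hypnograms.values():
        h.states = enforce_min_state_rule(h.states)
        bouts.extend(extract_bouts(h))
    logger.info("loaded %d subjects, %d modelled bouts", len(hypnograms), len(bouts))
    return hypnograms, bouts


def _usable_covariates(bouts: Sequence[Bout], names: Sequence[str]) -> tuple[list[Bout], list[str]]:
    """Keep covariates available for (nearly) all bouts; drop bouts missing them."""
    usable = []
    for name in names:
        have = 0
        for b in bouts:
            try:
                covariate_value(b, name)
                have += 1
            except (ValueError, KeyError):
                pass
        if have == len(bouts):
            usable.append(name)
        else:
            logger.warning(
                "covariate %s available for %d/%d bouts; excluded from the overall model",
                name, have, len(bouts),
            )
    return list(bouts), usable


def run_fit(config: RunConfig) -> dict:
    """Fit candidate duration laws per state, rank by AIC, classify tails.

    Writes ``fit_report.json``, per-state survival-curve CSVs and the bout
    table into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hypnograms, bouts = load_and_extract(config)
    write_bout_table(bouts, out / "bouts.csv")

    occupancy = {
        sid: state_percentages(h) for sid, h in hypnograms.items()
    }
    report: dict = dict(_provenance(config))
    report["n_subjects"] = len(hypnograms)
    report["mean_state_percentages"] = {
        s: float(np.mean([o[s] for o in occupancy.values()]))
        for s in ("W", "AS", "TS", "QS")
    }
    report["transition_table"] = transition_table(bouts).to_dict()
    report["states"] = {}

    for state in config.states:
        sbouts = [b for b in bouts if b.state == state]
        n_events = sum(b.offset_captured for b in sbouts)
        if n_events == 0:
            logger.warning("state %s: no observed bout offsets; skipped", state)
            report["states"][state] = {
                "skipped": True,
                "n_bouts": len(sbouts),
                "n_events": 0,
            }
            continue
        durations = [b.duration_min for b in sbouts]
        observed = [int(b.offset_captured) for b in sbouts]
        km = km_estimate(durations, observed)
        km.to_frame().to_csv(out / f"km_{state}.csv", index=False)

        sbouts_used, cov_names = _usable_covariates(sbouts, config.covariates)
        spec = CovariateSpec(tuple(cov_names)) if cov_names else None
        fits = []
        for family in config.families:
            try:
                fits.append(fit_family(family, sbouts_used, spec))
            except (ValueError, ConvergenceError) as exc:
                logger.warning("state %s family %s fit failed: %s", state, family, exc)
        if not fits:
            report["states"][state] = {
                "skipped": True,
                "n_bouts": len(sbouts),
                "n_events": int(n_events),
            }
            continue
        selection = select_model(fits)
        best = selection.best
        tail = classify_tail(best)
        times = np.linspace(0.0, float(np.max(durations)), 200)
        fitted_survival(best, None, times).to_frame().to_csv(
            out / f"fitted_{state}.csv", index=False
        )
        factors = {}
        for name in best.coefficients:
            af = acceleration_factor(best, name)
            factors[name] = {
                "factor": af.factor,
                "ci_low": af.ci_low,
                "ci_high": af.ci_high,
                "coefficient": af.coefficient,
                "se": af.se,
            }
        report["states"][state] = {
            "n_bouts": len(sbouts),
            "n_events": int(n_events),
            "fits": [
                dict(f.to_dict(), delta=delta)
                for f, delta in zip(selection.ranked, selection.deltas)
            ],
            "best_family": best.family,
            "tail_class": {"label": tail.label, "flagged": tail.flagged, "note": tail.note},
            "acceleration_factors": factors,
        }
        logger.info(
            "state %s: best=%s tail=%s (n=%d, events=%d)",
            state, best.family, tail.label, len(sbouts), n_events,
        )
    _write_json(report, out / "fit_report.json")
    return report


def run_simulate(config: RunConfig) -> dict:
    """Simulate a cohort and emit the three input tables plus the truth record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.sim, config.n_subjects, seed=config.seed)
    write_epoch_table(cohort.hypnograms, out / "epochs.tsv")
    write_covariate_table(cohort.hypnograms, out / "covariates.csv")
    write_event_table(cohort.hypnograms, out / "events.csv")
    truth = dict(_provenance(config))
    truth["sim"] = config.sim.to_dict()
    truth["n_subjects"] = config.n_subjects
    _write_json(truth, out / "truth.json")
    logger.info("simulated %d subjects into %s", config.n_subjects, out)
    return truth


def run_perturbation(config: RunConfig) -> dict:
    """Event-window association analysis split at the configured PMA threshold."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hypnograms, bouts = load_and_extract(config)
    events = [e for h in hypnograms.values() for e in h.events]
    report = dict(_provenance(config))
    if not events:
        logger.warning("no sensory events in input; empty perturbation report")
        report["groups"] = {}
    else:
        report.update(
            perturbation_report(
                bouts,
                events,
                window_min=config.window_min,
                pma_split_weeks=config.pma_split_weeks,
            )
        )
    _write_json(report, out / "perturbation_report.json")
    return report


def run_report(config: RunConfig) -> dict:
    """Full pipeline: duration-law fits plus perturbation analysis."""
    fit = run_fit(config)
    perturb = run_perturbation(config)
    combined = dict(_provenance(config))
    combined["fit"] = fit
    combined["perturbation"] = perturb
    _write_json(combined, Path(config.out_dir) / "report.json")
    return combined
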
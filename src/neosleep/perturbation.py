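"""Association between sensory events and subsequent sleep-state transitions.

The question: do awakenings cluster in the minutes after a noxious heel
lance, while sleep-to-sleep transitions (active <-> quiet) do not?  Each
observed bout offset is a transition, classed ``awakening`` (into W) or
``sleep_to_sleep``.  A transition falls *within* a window if it occurs in
the half-open interval [0, window) minutes after any event of the chosen
kind.  The 2x2 class-by-window table is tested with the likelihood-ratio
(G) chi-square and summarized with Cramer's V; latencies from the most
recent prior event are summarized by their (small-sample-corrected)
skewness — strongly right-skewed latencies indicate triggered, short-lag
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hypnogram import Bout, SensoryEvent

TRANSITION_CLASSES = ("awakening", "sleep_to_sleep")


@dataclass(frozen=True)
class TransitionEvent:
    """An observed bout offset: a state change at a known time."""

    subject_id: str
    time_min: float
    from_state: str
    to_state: str

    @property
    def transition_class(self) -> str:
        return "awakening" if self.to_state == "W" else "sleep_to_sleep"


@dataclass(frozen=True)
class AssociationResult:
    g_statistic: float
    df: int
    p: float
    cramers_v: float


def bouts_to_transitions(bouts: Iterable[Bout]) -> list[TransitionEvent]:
    """Observed bout offsets as transition events (censored bouts contribute none)."""
    out = []
    for b in bouts:
        if b.offset_captured:
            out.append(
                TransitionEvent(
                    subject_id=b.subject_id,
                    time_min=b.offset_min,
                    from_state=b.state,
                    to_state=b.next_state,
                )
            )
    return out


def window_counts(
    transitions: Sequence[TransitionEvent],
    events: Sequence[SensoryEvent],
    window_min: float = 5.0,
    kind: str | None = "lance",
) -> pd.DataFrame:
    """2x2 counts of transition class x (within | outside) post-event windows.

    A transition is *within* if ``0 <= t_transition - t_event < window_min``
    for any (same-subject) event of the requested kind; overlapping windows
    count a transition once.  Rows: awakening, sleep_to_sleep; columns:
    within, outside.
    """
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    evs = [e for e in events if kind is None or e.kind == kind]
    table = pd.DataFrame(
        0, index=list(TRANSITION_CLASSES), columns=["within", "outside"], dtype=int
    )
    for tr in transitions:
        inside = any(
            e.subject_id == tr.subject_id and 0.0 <= tr.time_min - e.time_min < window_min
            for e in evs
        )
        table.loc[tr.transition_class, "within" if inside else "outside"] += 1
    return table


def association_test(table) -> AssociationResult:
    """Likelihood-ratio (G) chi-square test of independence with Cramer's V.

    ``table`` is an r x c count array (typically the 2x2 from
    :func:`window_counts`).  Zero observed cells contribute nothing
    (0 log 0 = 0); a zero row or column margin is degenerate and raises.
    Cramer's V uses the G statistic: sqrt(G / (n * min(r-1, c-1))).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    n = obs.sum()
    if n <= 0:
        raise ValueError("table must have a positive grand total")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: a zero row or column margin")
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    g = max(g, 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(g, df))
    v = float(np.sqrt(g / (n * min(obs.shape[0] - 1, obs.shape[1] - 1))))
    return AssociationResult(float(g), int(df), p, min(v, 1.0))


def latency_skewness(latencies: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson standardized third moment (bias-corrected)."""
    x = np.asarray(latencies, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("skewness undefined for zero-variance data")
    return float(stats.skew(x, bias=False))


def latencies_to_transition(
    transitions: Sequence[TransitionEvent],
    events: Sequence[SensoryEvent],
    kind: str = "lance",
) -> np.ndarray:
    """Per-transition latency to the most recent prior same-subject event.

    Transitions with no prior event of the requested kind are excluded.
    """
    evs = [e for e in events if e.kind == kind]
    if not evs:
        raise ValueError(f"no events of kind {kind!r}")
    out = []
    for tr in transitions:
        prior = [e.time_min for e in evs if e.subject_id == tr.subject_id and e.time_min <= tr.time_min]
        if prior:
            out.append(tr.time_min - max(prior))
    return np.asarray(out, dtype=float)


def perturbation_report(
    bouts: Sequence[Bout],
    events: Sequence[SensoryEvent],
    window_min: float = 5.0,
    pma_split_weeks: float = 34.0,
    kinds: Sequence[str] = ("lance", "non_noxious"),
) -> dict:
    """Window/association/latency summary per event kind and age group.

    Subjects are split at ``pma_split_weeks`` PMA into younger and older
    groups (the maturational boundary at which nociceptive stimuli start to
    evoke awakenings).  Kinds with no events are omitted.
    """
    transitions = bouts_to_transitions(bouts)
    report: dict = {"window_min": window_min, "pma_split_weeks": pma_split_weeks, "groups": {}}

    def pma_of(subject_id: str) -> float | None:
        for b in bouts:
            if b.subject_id == subject_id:
                return b.covariates.pma_weeks
        return None

    groups = {
        "younger": lambda p: p is not None and p < pma_split_weeks,
        "older": lambda p: p is not None and p >= pma_split_weeks,
        "all": lambda p: True,
    }
    for gname, member in groups.items():
        g_tr = [t for t in transitions if member(pma_of(t.subject_id))]
        g_ev = [e for e in events if member(pma_of(e.subject_id))]
        entry: dict = {"n_transitions": len(g_tr)}
        for kind in kinds:
            evk = [e for e in g_ev if e.kind == kind]
            if not evk:
                continue
            counts = window_counts(g_tr, evk, window_min=window_min, kind=kind)
            kind_entry: dict = {"counts": counts.to_dict()}
            try:
                assoc = association_test(counts.to_numpy())
                kind_entry["association"] = {
                    "g_statistic": assoc.g_statistic,
                    "df": assoc.df,
                    "p": assoc.p,
                    "cramers_v": assoc.cramers_v,
                }
            except ValueError as exc:
                kind_entry["association"] = {"error": str(exc)}
            awak = [t for t in g_tr if t.transition_class == "awakening"]
            try:
                lat = latencies_to_transition(awak, evk, kind=kind)
                kind_entry["n_awakening_latencies"] = int(lat.size)
                if lat.size >= 3 and np.ptp(lat) > 0:
                    kind_entry["awakening_latency_skewness"] = latency_skewness(lat)
            except ValueError:
                pass
            entry[kind] = kind_entry
        report["groups"][gname] = entry
    return report
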
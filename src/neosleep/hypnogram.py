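"""Epoch-scored sleep-wake recordings and their conversion to censored bout records.

A neonatal hypnogram is a sequence of 30-second epochs, each scored as
wakefulness (W), active sleep (AS), transitional sleep (TS) or quiet sleep
(QS).  The unit of downstream survival analysis is the *bout*: a maximal
uninterrupted run of one state.  Because recordings are short (typically
under an hour and a half), many bouts are right-censored — their offset is
never observed — and the run in progress at recording start is
left-censored and excluded from duration modelling altogether.

Scoring convention: a state transition is only scored when the new state
persists for at least one minute (two epochs).  ``enforce_min_state_rule``
applies this rule to raw epoch sequences; ``extract_bouts`` then emits one
:class:`Bout` per observed-onset run, with TS runs acting as bout
terminators rather than bouts in their own right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STATES = ("W", "AS", "TS", "QS")
#: states whose bout durations are modelled; TS never forms a modelled bout
BOUT_STATES = ("W", "AS", "QS")

DEFAULT_EPOCH_LENGTH_S = 30.0
#: minimum run length (epochs) for a scored state change: 1 minute at 30 s epochs
MIN_STATE_EPOCHS = 2


class HypnogramError(ValueError):
    """Invalid hypnogram content or structure."""


class ParseError(HypnogramError):
    """Malformed input table."""


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject covariates used in accelerated-failure-time modelling.

    Parameters
    ----------
    pma_weeks : float, optional
        Postmenstrual age (gestational + postnatal age) in decimal weeks.
    postnatal_age_days : float, optional
        Postnatal age in days.
    risk_high : int, optional
        1 if at higher risk of adverse neurodevelopment, else 0. Opaque binary.
    cortisol_ug_dl : float, optional
        Mean salivary cortisol over the recording, in micrograms per decilitre.
    """

    pma_weeks: float | None = None
    postnatal_age_days: float | None = None
    risk_high: int | None = None
    cortisol_ug_dl: float | None = None

    def __post_init__(self) -> None:
        if self.pma_weeks is not None and not (22.0 <= self.pma_weeks <= 46.0):
            raise HypnogramError(
                f"pma_weeks={self.pma_weeks} outside plausible neonatal range [22, 46]"
            )
        if self.cortisol_ug_dl is not None and self.cortisol_ug_dl < 0:
            raise HypnogramError("cortisol_ug_dl must be non-negative")


@dataclass(frozen=True)
class SensoryEvent:
    """A timestamped sensory event during a recording.

    ``kind`` is one of ``lance`` (noxious heel lance), ``non_noxious``
    (control somatosensory stimulus), ``held_start`` or ``held_end``.
    Times are minutes from recording start.
    """

    subject_id: str
    time_min: float
    kind: str

    VALID_KINDS = ("lance", "non_noxious", "held_start", "held_end")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise HypnogramError(f"unknown event kind {self.kind!r}")
        if self.time_min < 0:
            raise HypnogramError("event time must be non-negative")


@dataclass
class Hypnogram:
    """One subject's epoch-scored recording plus annotations."""

    subject_id: str
    states: list[str]
    epoch_length: float = DEFAULT_EPOCH_LENGTH_S
    events: list[SensoryEvent] = field(default_factory=list)
    covariates: SubjectCovariates = field(default_factory=SubjectCovariates)

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if self.epoch_length <= 0:
            raise HypnogramError("epoch_length must be positive")
        bad = sorted({s for s in self.states if s not in VALID_STATES})
        if bad:
            raise HypnogramError(f"unknown state codes: {bad}")
        total_min = self.duration_min
        for ev in self.events:
            if ev.time_min > total_min:
                raise HypnogramError(
                    f"event at {ev.time_min} min beyond recording end {total_min} min"
                )

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_length / 60.0

    @property
    def epoch_min(self) -> float:
        """Epoch length in minutes."""
        return self.epoch_length / 60.0


@dataclass(frozen=True)
class Bout:
    """A maximal run of one sleep-wake state — the unit of survival analysis.

    ``offset_captured`` is the survival-analysis event indicator: True means
    the bout ended within the recording (its duration is fully observed),
    False means the duration is right-censored.  ``next_state`` is defined
    only for observed offsets and looks through any intervening TS run.
    """

    subject_id: str
    state: str
    onset_min: float
    duration_min: float
    onset_captured: bool
    offset_captured: bool
    next_state: str | None = None
    covariates: SubjectCovariates = field(default_factory=SubjectCovariates)

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise HypnogramError(f"invalid bout state {self.state!r}")
        if self.duration_min <= 0:
            raise HypnogramError("bout duration must be positive")
        if self.offset_captured != (self.next_state is not None):
            raise HypnogramError("next_state must be present iff offset_captured")
        if self.next_state == self.state:
            raise HypnogramError("next_state must differ from bout state")

    @property
    def offset_min(self) -> float:
        return self.onset_min + self.duration_min


def _runs(states: Sequence[str]) -> list[tuple[str, int, int]]:
    """Maximal runs as (state, start_index, length)."""
    out: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((states[start], start, i - start))
            start = i
    return out


def enforce_min_state_rule(
    states: Sequence[str], min_epochs: int = MIN_STATE_EPOCHS
) -> list[str]:
    """Apply the one-minute minimum rule for scoring a state change.

    Any maximal run shorter than ``min_epochs`` is relabelled: to the shared
    flanking state when both neighbours agree, otherwise to the *preceding*
    state (conservative continuation of the ongoing bout, so the eventual
    transition is scored at the start of the next full-length run).  A
    sub-minimum run at the very start of the recording is left untouched
    (no preceding state, and it is left-censored downstream anyway); a
    sub-minimum run at the very end is merged into the preceding state.
    The operation is idempotent.
    """
    if len(states) == 0:
        raise HypnogramError("empty state sequence")
    seq = list(states)
    while True:
        runs = _runs(seq)
        changed = False
        for k, (state, start, length) in enumerate(runs):
            if length >= min_epochs or k == 0:
                continue
            # same flank on both sides -> that state; different flanks or recording
            # end -> the preceding state. Both resolve to the run before this one.
            prev_state = runs[k - 1][0]
            seq[start : start + length] = [prev_state] * length
            changed = True
            break  # runs are stale; recompute
        if not changed:
            return seq


def extract_bouts(
    h: Hypnogram,
    min_epochs: int = MIN_STATE_EPOCHS,
    return_left_censored: bool = False,
) -> list[Bout] | tuple[list[Bout], list[Bout]]:
    """Convert a hypnogram into censored bout records.

    One :class:`Bout` is emitted per maximal W/AS/QS run whose onset
    transition falls within the recording.  The run in progress at
    recording start has an unobserved onset; it is excluded from the
    modelling set and (optionally) returned separately as left-censored.
    A run extending to the recording end is right-censored
    (``offset_captured=False``).  TS runs are never emitted: a TS run
    terminates the preceding bout, and ``next_state`` is the first non-TS
    state after it (absent — hence censored — if the recording ends in TS).

    Assumes ``h.states`` already satisfy the minimum-state rule; apply
    :func:`enforce_min_state_rule` first on raw sequences.
    """
    epoch_min = h.epoch_min
    runs = _runs(h.states)
    bouts: list[Bout] = []
    left: list[Bout] = []
    for k, (state, start, length) in enumerate(runs):
        if state == "TS":
            continue
        onset_captured = k > 0
        # find what this run offsets into, looking through TS
        next_state: str | None = None
        offset_captured = False
        for j in range(k + 1, len(runs)):
            if runs[j][0] != "TS":
                next_state = runs[j][0]
                offset_captured = True
                break
        if next_state == state:
            # TS flanked by the same state: no scoreable state change occurred,
            # so the bout's offset is treated as unobserved (conservative)
            next_state = None
            offset_captured = False
        bout = Bout(
            subject_id=h.subject_id,
            state=state,
            onset_min=start * epoch_min,
            duration_min=length * epoch_min,
            onset_captured=onset_captured,
            offset_captured=offset_captured,
            next_state=next_state,
            covariates=h.covariates,
        )
        if onset_captured:
            bouts.append(bout)
        else:
            left.append(bout)
    if return_left_censored:
        return bouts, left
    return bouts


def state_percentages(h: Hypnogram) -> dict[str, float]:
    """Fraction of recording time per state, as epoch counts / total epochs."""
    n = h.n_epochs
    if n == 0:
        raise HypnogramError("empty hypnogram")
    counts = {s: 0 for s in VALID_STATES}
    for s in h.states:
        counts[s] += 1
    return {s: c / n for s, c in counts.items()}


def transition_table(bouts: Iterable[Bout]) -> pd.DataFrame:
    """Counts of observed bout offsets by (state, next_state), plus censored.

    Rows are origin states (W, AS, QS); columns are destination states plus
    a ``censored`` column counting bouts whose offset was not captured.
    Row sums equal the number of modelled bouts per state.
    """
    table = pd.DataFrame(
        0, index=list(BOUT_STATES), columns=list(BOUT_STATES) + ["censored"], dtype=int
    )
    for b in bouts:
        if b.state not in BOUT_STATES:
            continue
        if b.offset_captured:
            table.loc[b.state, b.next_state] += 1
        else:
            table.loc[b.state, "censored"] += 1
    return table


def bouts_to_frame(bouts: Iterable[Bout]) -> pd.DataFrame:
    """Tabulate bouts, one row each, with survival-convention ``event_observed``."""
    rows = []
    for b in bouts:
        rows.append(
            {
                "subject_id": b.subject_id,
                "state": b.state,
                "onset_min": b.onset_min,
                "duration_min": b.duration_min,
                "onset_captured": int(b.onset_captured),
                "event_observed": int(b.offset_captured),
                "next_state": b.next_state if b.next_state is not None else "",
                "pma_weeks": b.covariates.pma_weeks,
                "postnatal_age_days": b.covariates.postnatal_age_days,
                "risk_high": b.covariates.risk_high,
                "cortisol_ug_dl": b.covariates.cortisol_ug_dl,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "state",
            "onset_min",
            "duration_min",
            "onset_captured",
            "event_observed",
            "next_state",
            "pma_weeks",
            "postnatal_age_days",
            "risk_high",
            "cortisol_ug_dl",
        ],
    )
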
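"""Reading and writing the delimited-text formats for hypnograms and bouts.

Formats
-------
Epoch table (TSV or CSV, sniffed from the delimiter):
    columns ``subject_id, epoch_index, state``; an optional directive line
    ``#epoch_length_s=30`` anywhere before the header overrides the default
    30-second epoch length.
Covariate table (CSV):
    ``subject_id, gestational_age_weeks, postnatal_age_days, pma_weeks,
    risk_high, cortisol_ug_dl`` (missing cortisol left blank).
Event table (CSV):
    ``subject_id, time_s, event_type`` with event_type in
    {lance, non_noxious, held_start, held_end}.
Bout table (CSV):
    one row per bout; censoring encoded as ``event_observed`` (1 = offset
    captured), the usual survival-analysis convention.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .hypnogram import (
    DEFAULT_EPOCH_LENGTH_S,
    VALID_STATES,
    Bout,
    Hypnogram,
    HypnogramError,
    ParseError,
    SensoryEvent,
    SubjectCovariates,
    bouts_to_frame,
)

EPOCH_COLUMNS = ("subject_id", "epoch_index", "state")
COVARIATE_COLUMNS = (
    "subject_id",
    "gestational_age_weeks",
    "postnatal_age_days",
    "pma_weeks",
    "risk_high",
    "cortisol_ug_dl",
)
EVENT_COLUMNS = ("subject_id", "time_s", "event_type")


def _read_directives(path: Path) -> tuple[float, str]:
    """Scan leading ``#key=value`` lines; return (epoch_length_s, body_text)."""
    epoch_length = DEFAULT_EPOCH_LENGTH_S
    body_lines = []
    with open(path, "rt") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                directive = stripped.lstrip("#").strip()
                if "=" in directive:
                    key, _, value = directive.partition("=")
                    if key.strip() == "epoch_length_s":
                        try:
                            epoch_length = float(value)
                        except ValueError as exc:
                            raise ParseError(
                                f"{path}: bad epoch_length_s directive {value!r}"
                            ) from exc
                continue
            body_lines.append(line)
    return epoch_length, "".join(body_lines)


def read_epoch_table(path: str | Path) -> tuple[dict[str, list[str]], float]:
    """Parse an epoch table into per-subject state sequences.

    Returns a mapping subject_id -> ordered state list, and the epoch length
    in seconds.  Rows for each subject must cover epoch indices 0..n-1
    without gaps; unknown state codes are rejected with the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    epoch_length, body = _read_directives(path)
    sep = "\t" if "\t" in body.splitlines()[0] else "," if body else ","
    try:
        df = pd.read_csv(_io.StringIO(body), sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: cannot parse epoch table: {exc}") from exc
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    try:
        df["epoch_index"] = df["epoch_index"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer epoch_index") from exc
    bad = df.loc[~df["state"].isin(VALID_STATES)]
    if len(bad):
        row = bad.iloc[0]
        # +2 for the header line, 1-based
        raise ParseError(
            f"{path}: unknown state code {row['state']!r} for subject "
            f"{row['subject_id']!r} at epoch {row['epoch_index']}"
        )
    out: dict[str, list[str]] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("epoch_index")
        idx = grp["epoch_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ParseError(f"{path}: subject {sid!r} epoch indices not contiguous from 0")
        out[str(sid)] = grp["state"].tolist()
    if not out:
        raise ParseError(f"{path}: no epoch rows")
    return out, epoch_length


def read_covariate_table(path: str | Path) -> dict[str, SubjectCovariates]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id",) if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    def _get(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    out = {}
    for _, row in df.iterrows():
        risk = _get(row, "risk_high")
        out[str(row["subject_id"])] = SubjectCovariates(
            pma_weeks=_get(row, "pma_weeks"),
            postnatal_age_days=_get(row, "postnatal_age_days"),
            risk_high=int(risk) if risk is not None else None,
            cortisol_ug_dl=_get(row, "cortisol_ug_dl"),
        )
    return out


def read_event_table(path: str | Path) -> dict[str, list[SensoryEvent]]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out: dict[str, list[SensoryEvent]] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            ev = SensoryEvent(
                subject_id=sid,
                time_min=float(row["time_s"]) / 60.0,
                kind=str(row["event_type"]),
            )
        except HypnogramError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        out.setdefault(sid, []).append(ev)
    for evs in out.values():
        evs.sort(key=lambda e: e.time_min)
    return out


def read_hypnograms(
    epoch_path: str | Path,
    covariate_path: str | Path | None = None,
    event_path: str | Path | None = None,
) -> dict[str, Hypnogram]:
    """Assemble validated hypnograms from the epoch/covariate/event tables."""
    states_by_subject, epoch_length = read_epoch_table(epoch_path)
    covs = read_covariate_table(covariate_path) if covariate_path else {}
    events = read_event_table(event_path) if event_path else {}
    out = {}
    for sid, states in states_by_subject.items():
        out[sid] = Hypnogram(
            subject_id=sid,
            states=states,
            epoch_length=epoch_length,
            events=events.get(sid, []),
            covariates=covs.get(sid, SubjectCovariates()),
        )
    return out


def read_hypnogram(
    epoch_path: str | Path,
    subject_id: str | None = None,
    covariate_path: str | Path | None = None,
    event_path: str | Path | None = None,
) -> Hypnogram:
    """Read a single subject's hypnogram (the only subject unless named)."""
    all_h = read_hypnograms(epoch_path, covariate_path, event_path)
    if subject_id is None:
        if len(all_h) != 1:
            raise ParseError(
                f"{epoch_path}: {len(all_h)} subjects present; pass subject_id"
            )
        return next(iter(all_h.values()))
    try:
        return all_h[subject_id]
    except KeyError as exc:
        raise ParseError(f"{epoch_path}: no subject {subject_id!r}") from exc


def write_epoch_table(
    hypnograms: Iterable[Hypnogram], path: str | Path, sep: str = "\t"
) -> None:
    hs = list(hypnograms)
    if not hs:
        raise ValueError("nothing to write")
    epoch_lengths = {h.epoch_length for h in hs}
    if len(epoch_lengths) != 1:
        raise ValueError("all hypnograms in one table must share epoch_length")
    rows = []
    for h in hs:
        for i, s in enumerate(h.states):
            rows.append((h.subject_id, i, s))
    df = pd.DataFrame(rows, columns=list(EPOCH_COLUMNS))
    with open(path, "wt") as fh:
        fh.write(f"#epoch_length_s={epoch_lengths.pop():g}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_covariate_table(hypnograms: Iterable[Hypnogram], path: str | Path) -> None:
    rows = []
    for h in hypnograms:
        c = h.covariates
        ga = (
            c.pma_weeks - (c.postnatal_age_days or 0.0) / 7.0
            if c.pma_weeks is not None
            else None
        )
        rows.append(
            {
                "subject_id": h.subject_id,
                "gestational_age_weeks": ga,
                "postnatal_age_days": c.postnatal_age_days,
                "pma_weeks": c.pma_weeks,
                "risk_high": c.risk_high,
                "cortisol_ug_dl": c.cortisol_ug_dl,
            }
        )
    pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS)).to_csv(path, index=False)


def write_event_table(hypnograms: Iterable[Hypnogram], path: str | Path) -> None:
    rows = []
    for h in hypnograms:
        for ev in h.events:
            rows.append(
                {
                    "subject_id": ev.subject_id,
                    "time_s": ev.time_min * 60.0,
                    "event_type": ev.kind,
                }
            )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def write_bout_table(bouts: Iterable[Bout], path: str | Path) -> None:
    bouts_to_frame(bouts).to_csv(path, index=False)
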
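"""Readers and writers for the long-format CSV tables.

Trials table schema (one row per movement event):
``subject_id, group, tempo_bpm, trial_index, event_index, time_s``.
Summary tables mirror the fields of :class:`~beatsync.types.TrialSummary`
and :class:`~beatsync.types.SubjectTempoSummary`. Angles are written in
degrees with explicit sign, floats at six decimal places, so tables
round-trip exactly at that precision.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import DomainError, SchemaError, TrialValidationError
from .types import MovementTrial, SubjectTempoSummary, TrialSummary

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "write_summaries",
    "read_trial_summaries",
    "read_subject_summaries",
]

TRIAL_COLUMNS = ("subject_id", "group", "tempo_bpm", "trial_index", "event_index", "time_s")

_FLOAT_FMT = "%.6f"


def read_trials(path) -> list[MovementTrial]:
    """Read a long-format trials CSV into a list of :class:`MovementTrial`.

    One trial per unique ``(subject_id, tempo_bpm, trial_index)``; rows
    within a trial are ordered by ``event_index``.

    Raises
    ------
    SchemaError
        If a required column is missing.
    TrialValidationError
        If a trial has duplicated event indices or non-monotonic times.
    """
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trials table is missing required column {col!r}")
    trials = []
    keys = ["subject_id", "tempo_bpm", "trial_index"]
    for (subject, tempo, idx), rows in df.groupby(keys, sort=True):
        rows = rows.sort_values("event_index")
        label = f"subject={subject} tempo={tempo} trial={idx}"
        if rows["event_index"].duplicated().any():
            raise TrialValidationError(f"duplicated event_index within trial ({label})")
        times = rows["time_s"].to_numpy(dtype=float)
        if (times[1:] <= times[:-1]).any():
            raise TrialValidationError(f"event times not strictly increasing ({label})")
        group = rows["group"].iloc[0]
        trials.append(
            MovementTrial(
                subject_id=str(subject),
                group=str(group),
                tempo_bpm=float(tempo),
                trial_index=int(idx),
                event_times_s=tuple(times),
            )
        )
    return trials


def write_trials(trials: Sequence[MovementTrial], path) -> None:
    """Write trials to the long-format CSV (inverse of :func:`read_trials`)."""
    if not trials:
        raise DomainError("refusing to write an empty trials table")
    records = []
    for t in trials:
        for j, ts in enumerate(t.event_times_s, start=1):
            records.append(
                dict(
                    subject_id=t.subject_id,
                    group=t.group,
                    tempo_bpm=t.tempo_bpm,
                    trial_index=t.trial_index,
                    event_index=j,
                    time_s=ts,
                )
            )
    pd.DataFrame.from_records(records, columns=list(TRIAL_COLUMNS)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def summaries_frame(summaries: Sequence) -> pd.DataFrame:
    """Convert a homogeneous list of summary dataclasses to a DataFrame."""
    if not summaries:
        raise DomainError("refusing to build a table from an empty summary list")
    kinds = {type(s) for s in summaries}
    if len(kinds) != 1:
        raise DomainError("summaries must all be of the same type")
    cols = [f.name for f in fields(summaries[0])]
    return pd.DataFrame.from_records([asdict(s) for s in summaries], columns=cols)


def write_summaries(summaries: Sequence, path) -> None:
    """Write trial or subject-by-tempo summaries to CSV (6 decimal places)."""
    summaries_frame(summaries).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_summary_table(path, cls):
    df = pd.read_csv(path)
    expected = [f.name for f in fields(cls)]
    for col in expected:
        if col not in df.columns:
            raise SchemaError(f"summary table is missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields(cls):
            v = row[f.name]
            if f.type in ("int", int):
                v = int(v)
            elif f.type in ("float", float):
                v = float(v)
            else:
                v = str(v)
            kwargs[f.name] = v
        out.append(cls(**kwargs))
    return out


def read_trial_summaries(path) -> list[TrialSummary]:
    return _read_summary_table(path, TrialSummary)


def read_subject_summaries(path) -> list[SubjectTempoSummary]:
    return _read_summary_table(path, SubjectTempoSummary)
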
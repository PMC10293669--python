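"""Session-log serialization: JSON-lines logs and per-trial CSV tables.

Two on-disk forms are used. The JSON-lines log is the full-fidelity record
(one JSON object per line, ``record`` field naming its type: ``header`` with
the config snapshot and seed, then ``trial`` and ``event`` lines); reading
it back reproduces the :class:`~nosepoke.session_types.SessionLog` exactly.
The trial CSV is the analysis-facing tabular view with columns

    trial_index, phase, minute, trial_type, intensity_value,
    intensity_units, outcome, first_poke_ms, punished, timeout_s, distracted

consumed by the metrics and threshold-fitting entry points (and writable by
external rigs that want to use this package's analysis path only).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .scheduler import Phase, TrialKind
from .session_types import Event, Outcome, SessionLog, TrialRecord

__all__ = [
    "write_session_log",
    "read_session_log",
    "write_trial_csv",
    "read_trial_csv",
    "TRIAL_CSV_COLUMNS",
    "ParseError",
]

TRIAL_CSV_COLUMNS = [
    "trial_index", "phase", "minute", "trial_type", "intensity_value",
    "intensity_units", "outcome", "first_poke_ms", "punished", "timeout_s",
    "distracted",
]


class ParseError(ValueError):
    """A session-log file violated the documented schema."""


def write_session_log(log: SessionLog, path: str | Path) -> None:
    """Write the full session log as JSON-lines (round-trips exactly)."""
    with open(path, "w") as fh:
        header = {
            "record": "header",
            "config": log.config,
            "seed": log.seed,
            "pellets": log.pellets,
            "manual_dispenses": log.manual_dispenses,
        }
        fh.write(json.dumps(header) + "\n")
        for t in log.trials:
            row = {
                "record": "trial",
                "index": t.index,
                "phase": t.phase.value,
                "trial_type": t.trial_type.value,
                "intensity_value": t.intensity_value,
                "intensity_units": t.intensity_units,
                "trial_start_ms": t.trial_start_ms,
                "trial_window_s": t.trial_window_s,
                "hit_window_s": t.hit_window_s,
                "poke_times_ms": t.poke_times_ms,
                "outcome": t.outcome.value,
                "punished": t.punished,
                "timeout_s": t.timeout_s,
                "distracted": t.distracted,
            }
            fh.write(json.dumps(row) + "\n")
        for e in log.events:
            fh.write(
                json.dumps(
                    {"record": "event", "time_ms": e.time_ms, "kind": e.kind,
                     "detail": e.detail}
                )
                + "\n"
            )


def read_session_log(path: str | Path) -> SessionLog:
    """Read a JSON-lines session log written by :func:`write_session_log`."""
    log: SessionLog | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            rec = obj.get("record")
            if rec == "header":
                log = SessionLog(
                    config=obj["config"], seed=obj["seed"],
                    pellets=obj.get("pellets", 0),
                    manual_dispenses=obj.get("manual_dispenses", 0),
                )
            elif rec == "trial":
                if log is None:
                    raise ParseError(f"{path}:{lineno}: trial before header")
                try:
                    log.trials.append(
                        TrialRecord(
                            index=obj["index"],
                            phase=Phase(obj["phase"]),
                            trial_type=TrialKind(obj["trial_type"]),
                            intensity_value=obj["intensity_value"],
                            intensity_units=obj["intensity_units"],
                            trial_start_ms=obj["trial_start_ms"],
                            trial_window_s=obj["trial_window_s"],
                            hit_window_s=obj["hit_window_s"],
                            poke_times_ms=list(obj["poke_times_ms"]),
                            outcome=Outcome(obj["outcome"]),
                            punished=obj["punished"],
                            timeout_s=obj["timeout_s"],
                            distracted=obj["distracted"],
                        )
                    )
                except KeyError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: trial record missing field {exc}"
                    ) from exc
            elif rec == "event":
                if log is None:
                    raise ParseError(f"{path}:{lineno}: event before header")
                log.events.append(
                    Event(obj["time_ms"], obj["kind"], obj.get("detail", ""))
                )
            else:
                raise ParseError(
                    f"{path}:{lineno}: unknown record type {rec!r}"
                )
    if log is None:
        raise ParseError(f"{path}: no header record found")
    return log


def trials_to_frame(log: SessionLog) -> pd.DataFrame:
    """The per-trial CSV view of a session log as a DataFrame."""
    rows = [
        {
            "trial_index": t.index,
            "phase": t.phase.value,
            "minute": t.minute,
            "trial_type": t.trial_type.value,
            "intensity_value": t.intensity_value,
            "intensity_units": t.intensity_units,
            "outcome": t.outcome.value,
            "first_poke_ms": t.first_poke_ms,
            "punished": t.punished,
            "timeout_s": t.timeout_s,
            "distracted": t.distracted,
        }
        for t in log.trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def write_trial_csv(log: SessionLog, path: str | Path) -> None:
    trials_to_frame(log).to_csv(path, index=False)


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-trial CSV, validating the documented schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    bad = ~df["outcome"].isin([o.value for o in Outcome])
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based
        raise ParseError(
            f"{path}:{row}: invalid outcome {df.loc[bad, 'outcome'].iloc[0]!r}"
        )
    for col in ("punished", "distracted"):
        df[col] = df[col].astype(bool)
    return df
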
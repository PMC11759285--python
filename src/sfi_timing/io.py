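"""Event-log and results I/O.

Sessions serialize to a headered CSV with one row per event: every
press is a ``press`` row and the rewarded press additionally emits a
``reward`` row, so each trial carries exactly one reward.  Event times
are trial-relative seconds written with fixed 3-decimal (1 ms)
precision — the resolution floor for all comparisons — and block and
trial indices are 1-based.  Reading validates the trial invariants and
reports the first violation with its row number.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path

import numpy as np
import yaml

from .agent import AgentParams, PRESETS
from .protocol import Protocol
from .simulate import Session, Trial

__all__ = ["EventLogError", "write_event_log", "read_event_log",
           "RunConfig", "load_config", "save_config"]

HEADER = ["subject_id", "day", "block_index", "trial_index_in_block",
          "fi_duration", "event_type", "event_time"]

TIME_RESOLUTION = 1e-3


class EventLogError(ValueError):
    """Malformed event log; message names the offending row."""


def write_event_log(sessions: list[Session] | Session, path) -> None:
    """Write sessions to the event-log CSV (times at 1 ms precision)."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(HEADER)
        for s in sessions:
            for t in s.trials:
                base = [s.subject_id, s.day, t.block_index,
                        t.trial_index_in_block, f"{t.fi_duration:.3f}"]
                # two presses within the same millisecond are one event
                # at the log's resolution
                presses = np.unique(np.round(t.press_times, 3))
                for p in presses:
                    w.writerow(base + ["press", f"{p:.3f}"])
                w.writerow(base + ["reward", f"{presses[-1]:.3f}"])


def read_event_log(path) -> list[Session]:
    """Reconstruct sessions (grouped by subject and day) from a CSV log.

    Validates per-trial invariants: strictly increasing press times, a
    single reward per trial equal to the last press and at or after the
    FI deadline.  Raises :class:`EventLogError` naming the first bad row.
    """
    path = Path(path)
    trials: dict[tuple, dict[tuple, dict]] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        rdr = csv.reader(fh)
        header = next(rdr, None)
        if header != HEADER:
            raise EventLogError(f"row 1: expected header {HEADER}, got {header}")
        for i, row in enumerate(rdr, start=2):
            if len(row) != len(HEADER):
                raise EventLogError(f"row {i}: expected {len(HEADER)} fields")
            sid, day, block, tidx, fi, etype, etime = row
            try:
                day, block, tidx = int(day), int(block), int(tidx)
                fi, etime = float(fi), float(etime)
            except ValueError:
                raise EventLogError(f"row {i}: malformed numeric field") from None
            if etime < 0:
                raise EventLogError(f"row {i}: negative event time")
            if etype not in ("press", "reward"):
                raise EventLogError(f"row {i}: unknown event type {etype!r}")
            skey = (sid, day)
            tkey = (block, tidx)
            if skey not in trials:
                trials[skey] = {}
                order.append(skey)
            rec = trials[skey].setdefault(
                tkey, {"fi": fi, "presses": [], "reward": None, "rows": []})
            rec["rows"].append(i)
            if etype == "press":
                if rec["presses"] and etime <= rec["presses"][-1]:
                    raise EventLogError(f"row {i}: press times not strictly increasing")
                rec["presses"].append(etime)
            else:
                if rec["reward"] is not None:
                    raise EventLogError(f"row {i}: duplicate reward in trial")
                rec["reward"] = etime

    sessions = []
    for skey in order:
        sid, day = skey
        tlist = []
        for (block, tidx) in sorted(trials[skey]):
            rec = trials[skey][(block, tidx)]
            row0 = rec["rows"][0]
            if rec["reward"] is None:
                raise EventLogError(f"row {row0}: trial has no reward event")
            if not rec["presses"]:
                raise EventLogError(f"row {row0}: trial has no press events")
            if abs(rec["reward"] - rec["presses"][-1]) > TIME_RESOLUTION / 2:
                raise EventLogError(
                    f"row {row0}: reward time must equal the last press")
            if rec["reward"] < rec["fi"] - TIME_RESOLUTION / 2:
                raise EventLogError(
                    f"row {row0}: reward before the FI deadline")
            tlist.append(Trial(
                block_index=block, trial_index_in_block=tidx,
                fi_duration=rec["fi"],
                press_times=np.asarray(rec["presses"]),
                reward_time=rec["reward"],
            ))
        sessions.append(Session(
            subject_id=sid, day=day, trials=tlist,
            protocol=Protocol(), rng_seed=-1,
        ))
    return sessions


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    variant: str = "fixed"
    agent_preset: str = "rat_fast"
    agent_overrides: dict = dataclasses.field(default_factory=dict)
    n_subjects: int = 10
    n_days: int = 1
    n_post_trials: int = 10
    seed: int = 0

    def protocol(self) -> Protocol:
        from .protocol import de_novo_protocol, novel_protocol

        if self.variant == "novel":
            return novel_protocol()
        if self.variant == "de_novo":
            return de_novo_protocol()
        return Protocol()

    def agent(self) -> AgentParams:
        base = PRESETS[self.agent_preset]
        return dataclasses.replace(base, **self.agent_overrides)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    """Write the resolved configuration beside the run outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
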
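"""Reading long-format event tables and aligning patients on the index event.

Each patient's raw claims rows (one code per row, dated either by calendar
date or by a pre-computed integer day offset) are mapped through a
:class:`~cohortflow.factors.FactorMap` and re-expressed as a *trajectory*:
an ordered sequence of (factor set, relative day) records where day 0 is the
first occurrence of the index factor.  Patients with no index-factor event
are excluded and counted, mirroring cohort extraction on an index diagnosis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import pandas as pd

from .factors import FactorMap, match_code

__all__ = ["EventRecord", "Trajectory", "Population", "read_events", "build_trajectories"]

When = Union[date, int]


@dataclass(frozen=True)
class EventRecord:
    patient_id: str
    when: When  # calendar date, or an int day offset when pre-aligned
    code: str

    @property
    def pre_aligned(self) -> bool:
        return isinstance(self.when, int)


@dataclass
class Trajectory:
    """One patient's index-aligned record sequence.

    ``records`` is sorted by relative day; same-day events are merged so each
    day appears at most once and carries the union of that day's factors.
    """

    patient_id: str
    records: list[tuple[frozenset[str], int]]
    index_day_absolute: str | int

    def factor_union(self) -> frozenset[str]:
        out: set[str] = set()
        for fs, _ in self.records:
            out |= fs
        return frozenset(out)


@dataclass
class Population:
    trajectories: list[Trajectory]
    excluded: dict[str, int] = field(default_factory=dict)
    unmatched_codes: int = 0  # events mapping to no factor, silently dropped

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def patient_ids(self) -> list[str]:
        return [t.patient_id for t in self.trajectories]

    # -- line-delimited JSON serialization (one patient per line) ------------
    def to_ldjson(self, fh: TextIO) -> None:
        header = {
            "_meta": True,
            "excluded": self.excluded,
            "unmatched_codes": self.unmatched_codes,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for t in self.trajectories:
            row = {
                "patient_id": t.patient_id,
                "index_day_absolute": t.index_day_absolute
                if isinstance(t.index_day_absolute, int)
                else str(t.index_day_absolute),
                "records": [[sorted(fs), d] for fs, d in t.records],
            }
            fh.write(json.dumps(row, sort_keys=True) + "\n")

    @classmethod
    def from_ldjson(cls, fh: TextIO) -> "Population":
        lines = [ln for ln in fh if ln.strip()]
        header = json.loads(lines[0])
        trajectories = []
        for ln in lines[1:]:
            row = json.loads(ln)
            trajectories.append(
                Trajectory(
                    row["patient_id"],
                    [(frozenset(fs), int(d)) for fs, d in row["records"]],
                    row["index_day_absolute"],
                )
            )
        return cls(trajectories, dict(header["excluded"]), int(header["unmatched_codes"]))


def read_events(
    path: str | Path | TextIO,
    *,
    patient_col: str = "patient_id",
    date_col: str = "date",
    day_col: str = "day",
    code_col: str = "code",
) -> list[EventRecord]:
    """Parse a long-format CSV of events, in file order, duplicates preserved.

    Exactly one of ``date_col`` (ISO-8601 calendar dates) or ``day_col``
    (signed integer day offsets, already aligned) must be present; records
    read from a day column are flagged pre-aligned.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if patient_col not in df.columns:
        raise ValueError(f"missing required column {patient_col!r}")
    if code_col not in df.columns:
        raise ValueError(f"missing required column {code_col!r}")
    has_date, has_day = date_col in df.columns, day_col in df.columns
    if not has_date and not has_day:
        raise ValueError(f"need a {date_col!r} or {day_col!r} column")

    pids = df[patient_col].tolist()
    codes = df[code_col].tolist()
    days = df[day_col].tolist() if has_day else [""] * len(df)
    dates = df[date_col].tolist() if has_date else [""] * len(df)

    records: list[EventRecord] = []
    for i, (pid, code, day, raw) in enumerate(zip(pids, codes, days, dates)):
        if not pid:
            raise ValueError(f"row {i + 2}: empty patient id")
        if day != "":
            when: When = int(day)
        else:
            try:
                when = datetime.strptime(raw, "%Y-%m-%d").date()
            except ValueError:
                raise ValueError(f"row {i + 2}: unparseable date {raw!r}") from None
        records.append(EventRecord(pid, when, code))
    return records


def build_trajectories(events: Sequence[EventRecord], fm: FactorMap) -> Population:
    """Map codes to factors and align each patient on the first index event.

    Per patient: events mapping to no factor are dropped (counted); day 0 is
    the first chronological occurrence of any index-factor code; all
    timestamps become signed day offsets; same-day events merge into one
    record (union of factor sets).  Patients without any index-factor event
    are excluded and tallied, as are patients whose events match no factor
    at all.
    """
    if not events:
        raise ValueError("no events supplied")
    index_factor = fm.index_factor

    by_patient: dict[str, list[tuple[When, frozenset[str]]]] = {}
    unmatched = 0
    for ev in events:
        fs = match_code(ev.code, fm)
        if not fs:
            unmatched += 1
            continue
        by_patient.setdefault(ev.patient_id, []).append((ev.when, frozenset(fs)))

    all_ids = {ev.patient_id for ev in events}
    excluded = {"no_mapped_factors": len(all_ids - by_patient.keys())}

    trajectories: list[Trajectory] = []
    n_no_index = 0
    for pid, rows in by_patient.items():
        index_days = [when for when, fs in rows if index_factor in fs]
        if not index_days:
            n_no_index += 1
            continue
        day0 = min(index_days)
        merged: dict[int, set[str]] = {}
        for when, fs in rows:
            offset = (when - day0).days if isinstance(when, date) else when - day0
            merged.setdefault(offset, set()).update(fs)
        records = [(frozenset(fs), d) for d, fs in sorted(merged.items())]
        trajectories.append(Trajectory(pid, records, day0 if isinstance(day0, int) else day0))
    excluded["no_index_event"] = n_no_index
    return Population(trajectories, excluded, unmatched)
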
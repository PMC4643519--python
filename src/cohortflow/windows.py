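"""Partitioning aligned trajectories into time windows.

A window specification is a strictly increasing list of L+1 day boundaries
defining L half-open windows [t_l, t_{l+1}).  Within each window a patient's
records merge into a single factor set (the union of the sets observed in
that window); records outside the covered span are dropped.  Optional
per-window *watched* factor subsets intersect each merged set, focusing a
window on the factors of interest for that phase of the disease course.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .factors import FactorMap
from .trajectories import Population

__all__ = ["WindowSpec", "WindowedTrajectory", "partition", "comorbidity_key"]

EMPTY_KEY = "(none)"


def comorbidity_key(factors: Iterable[str]) -> str:
    """Canonical label of a factor combination: sorted, "|"-joined; empty -> "(none)"."""
    fs = sorted(factors)
    return "|".join(fs) if fs else EMPTY_KEY


@dataclass
class WindowSpec:
    """L half-open windows from L+1 strictly increasing day boundaries."""

    boundaries: list[int]
    watch: list[set[str] | None] | None = None  # per-window watched factors
    labels: list[str] | None = None
    carry_forward: bool = False  # union earlier in-range diagnosis factors

    def __post_init__(self) -> None:
        if len(self.boundaries) < 2:
            raise ValueError("need at least two boundaries (one window)")
        if any(b >= c for b, c in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if self.watch is not None and len(self.watch) != self.n_windows:
            raise ValueError("watch list length must equal the number of windows")
        if self.labels is not None and len(self.labels) != self.n_windows:
            raise ValueError("labels length must equal the number of windows")

    @property
    def n_windows(self) -> int:
        return len(self.boundaries) - 1

    def window_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [
            f"[{lo}, {hi})"
            for lo, hi in zip(self.boundaries, self.boundaries[1:])
        ]

    def window_of(self, day: int) -> int | None:
        """Index of the window containing ``day``, or None if out of range."""
        if day < self.boundaries[0] or day >= self.boundaries[-1]:
            return None
        for l, hi in enumerate(self.boundaries[1:]):
            if day < hi:
                return l
        return None  # pragma: no cover

    def to_dict(self) -> dict:
        return {
            "boundaries": list(self.boundaries),
            "watch": None
            if self.watch is None
            else [sorted(w) if w is not None else None for w in self.watch],
            "labels": self.labels,
            "carry_forward": self.carry_forward,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindowSpec":
        watch = d.get("watch")
        if watch is not None:
            watch = [set(w) if w is not None else None for w in watch]
        return cls(
            [int(b) for b in d["boundaries"]],
            watch,
            d.get("labels"),
            bool(d.get("carry_forward", False)),
        )


@dataclass
class WindowedTrajectory:
    patient_id: str
    window_sets: list[frozenset[str]]  # length L; empty sets allowed


def windowed_to_dict(wtrajs: Sequence[WindowedTrajectory], spec: WindowSpec) -> dict:
    return {
        "spec": spec.to_dict(),
        "patients": [
            {"patient_id": wt.patient_id, "window_sets": [sorted(s) for s in wt.window_sets]}
            for wt in wtrajs
        ],
    }


def windowed_from_dict(d: dict) -> tuple[list[WindowedTrajectory], WindowSpec]:
    spec = WindowSpec.from_dict(d["spec"])
    wtrajs = [
        WindowedTrajectory(p["patient_id"], [frozenset(s) for s in p["window_sets"]])
        for p in d["patients"]
    ]
    return wtrajs, spec


def partition(
    pop: Population,
    spec: WindowSpec,
    *,
    vocabulary: FactorMap | Iterable[str] | None = None,
) -> list[WindowedTrajectory]:
    """Merge each patient's records into per-window factor sets.

    Patients with no in-range records are retained with all-empty window
    sets (they form the explicit "(none)" group downstream).  When
    ``vocabulary`` is given, watched factors are validated against it.
    With ``spec.carry_forward`` on, each window additionally inherits all
    diagnosis factors seen in earlier in-range windows (procedures, per the
    vocabulary, are never carried).
    """
    procedures: set[str] = set()
    if vocabulary is not None:
        if isinstance(vocabulary, FactorMap):
            known = set(vocabulary.factor_names) | {e.name for e in vocabulary.entries}
            procedures = vocabulary.procedure_factors
        else:
            known = set(vocabulary)
        if spec.watch is not None:
            for l, w in enumerate(spec.watch):
                unknown = set(w or ()) - known
                if unknown:
                    raise ValueError(
                        f"window {l}: unknown watched factor(s) {sorted(unknown)}"
                    )

    L = spec.n_windows
    out: list[WindowedTrajectory] = []
    for traj in pop.trajectories:
        sets: list[set[str]] = [set() for _ in range(L)]
        for fs, day in traj.records:
            l = spec.window_of(day)
            if l is not None:
                sets[l] |= fs
        if spec.carry_forward:
            carried: set[str] = set()
            for l in range(L):
                sets[l] |= carried
                carried |= sets[l] - procedures
        if spec.watch is not None:
            for l, w in enumerate(spec.watch):
                if w is not None:
                    sets[l] &= set(w)
        out.append(WindowedTrajectory(traj.patient_id, [frozenset(s) for s in sets]))
    return out
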
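"""Grouping patients within a time window into cohorts.

Two operators are provided, matching the two analysis styles:

* :func:`frequency_cluster` keeps every exact comorbidity combination whose
  patient count reaches a threshold and merges the rest into "others"
  groups (split by whether members carry the index factor).
* :func:`hierarchical_cluster` agglomerates the *unique* comorbidity sets
  under the Ochiai set similarity

      sim(s1, s2) = |s1 ∩ s2| / sqrt(|s1| |s2|)

  (the cosine similarity of indicator vectors), with distance 1 − sim,
  configurable linkage (average by default) and an explicit deterministic
  tie-break; patients inherit the cluster of their combination.

Cohort labels list the factors shared by *all* members; a trailing ``*``
marks that some member carries additional factors, and a bare ``*`` means
the members share no common factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .windows import EMPTY_KEY, WindowedTrajectory, comorbidity_key

__all__ = [
    "Cohort",
    "CohortSet",
    "ComorbidityGroup",
    "group_by_comorbidity",
    "frequency_cluster",
    "ochiai",
    "hierarchical_cluster",
    "label_cohort",
]

OTHERS_INDEX = "others-index"
OTHERS_NONINDEX = "others-nonindex"


@dataclass(frozen=True)
class ComorbidityGroup:
    """All patients sharing one exact factor combination at one window."""

    factors: frozenset[str]
    members: tuple[str, ...]

    @property
    def key(self) -> str:
        return comorbidity_key(self.factors)


@dataclass
class Cohort:
    """A node of the trajectory network: a patient group at one window."""

    window: int
    members: tuple[str, ...]
    common_factors: frozenset[str]
    partial: bool  # some member has factors beyond common_factors
    contains_index: bool
    kind: str = "comorbidity"  # comorbidity | others-index | others-nonindex
    custom_label: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cohort must have members")

    @property
    def label(self) -> str:
        return label_cohort(self)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CohortSet:
    """The disjoint cohorts covering the analysis population at one window."""

    window: int
    cohorts: list[Cohort]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.cohorts:
            overlap = seen.intersection(c.members)
            if overlap:
                raise ValueError(f"cohorts overlap on members {sorted(overlap)[:3]}")
            seen.update(c.members)

    @property
    def n_patients(self) -> int:
        return sum(len(c) for c in self.cohorts)

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "cohorts": [
                {
                    "members": list(c.members),
                    "common_factors": sorted(c.common_factors),
                    "partial": c.partial,
                    "contains_index": c.contains_index,
                    "kind": c.kind,
                    "custom_label": c.custom_label,
                    "label": c.label,
                }
                for c in self.cohorts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSet":
        return cls(
            d["window"],
            [
                Cohort(
                    d["window"],
                    tuple(cd["members"]),
                    frozenset(cd["common_factors"]),
                    cd["partial"],
                    cd["contains_index"],
                    cd.get("kind", "comorbidity"),
                    cd.get("custom_label"),
                )
                for cd in d["cohorts"]
            ],
        )


def label_cohort(c: Cohort) -> str:
    """Shared-factor label with ``*`` marking non-shared extras."""
    if c.custom_label is not None:
        return c.custom_label
    if not c.common_factors:
        return "*" if c.partial else EMPTY_KEY
    base = comorbidity_key(c.common_factors)
    return base + "*" if c.partial else base


def group_by_comorbidity(
    wtrajs: Sequence[WindowedTrajectory], window: int
) -> list[ComorbidityGroup]:
    """Patients grouped by their exact factor combination at one window.

    Groups are returned in deterministic order (by canonical key), members
    sorted; the empty combination forms its own "(none)" group.
    """
    buckets: dict[frozenset[str], list[str]] = {}
    for wt in wtrajs:
        buckets.setdefault(wt.window_sets[window], []).append(wt.patient_id)
    return [
        ComorbidityGroup(fs, tuple(sorted(members)))
        for fs, members in sorted(buckets.items(), key=lambda kv: comorbidity_key(kv[0]))
    ]


def _cohort_from_groups(
    window: int, groups: Sequence[ComorbidityGroup], index_factor: str, kind: str = "comorbidity"
) -> Cohort:
    members = tuple(sorted(m for g in groups for m in g.members))
    common = frozenset.intersection(*(g.factors for g in groups))
    partial = any(g.factors != common for g in groups)
    contains_index = any(index_factor in g.factors for g in groups)
    return Cohort(window, members, common, partial, contains_index, kind)


def frequency_cluster(
    groups: Sequence[ComorbidityGroup],
    threshold: int,
    *,
    window: int = 0,
    index_factor: str = "CKD",
    split_others_by_index: bool = True,
) -> CohortSet:
    """Keep combinations with ≥ ``threshold`` patients; merge the rest into "others".

    The merged remainder is split into at most two cohorts — one for
    combinations containing the index factor, one for the rest — unless
    ``split_others_by_index`` is off, in which case a single "others" cohort
    is produced.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = [g for g in groups if len(g.members) >= threshold]
    small = [g for g in groups if len(g.members) < threshold]

    cohorts = [_cohort_from_groups(window, [g], index_factor) for g in kept]
    if small:
        if split_others_by_index:
            with_idx = [g for g in small if index_factor in g.factors]
            without = [g for g in small if index_factor not in g.factors]
            if with_idx:
                c = _cohort_from_groups(window, with_idx, index_factor, OTHERS_INDEX)
                c.custom_label = f"others ({index_factor})"
                cohorts.append(c)
            if without:
                c = _cohort_from_groups(window, without, index_factor, OTHERS_NONINDEX)
                c.custom_label = "others"
                cohorts.append(c)
        else:
            c = _cohort_from_groups(window, small, index_factor, OTHERS_NONINDEX)
            c.custom_label = "others"
            cohorts.append(c)
    return CohortSet(window, cohorts)


def ochiai(s1: Iterable[str], s2: Iterable[str]) -> float:
    """Ochiai set similarity in [0, 1].

    Both sets empty is treated as identity (1.0); exactly one empty as
    complete dissimilarity (0.0) — the formula itself divides by zero there.
    """
    a, b = frozenset(s1), frozenset(s2)
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def hierarchical_cluster(
    groups: Sequence[ComorbidityGroup],
    k: int,
    *,
    window: int = 0,
    index_factor: str = "CKD",
    linkage: str = "average",
) -> CohortSet:
    """Agglomerate unique comorbidity sets to ``k`` cohorts under 1 − Ochiai.

    Clustering operates on the unique combinations (unweighted by their
    patient counts); every patient joins the cluster of its combination.
    Cluster distances follow the chosen linkage (average, single, complete)
    via Lance–Williams updates.  Merging is fully deterministic: at equal
    linkage distance the pair whose (lexicographically smallest member keys)
    sorts first is merged, so the k-cohort solution always refines the
    (k−1)-cohort one.
    """
    if linkage not in {"average", "single", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    u = len(groups)
    if not 1 <= k <= u:
        raise ValueError(f"k must be in [1, {u}], got {k}")
    keys = [g.key for g in groups]

    # active clusters keyed by id; pairwise distance matrix updated on merge
    members: dict[int, list[int]] = {i: [i] for i in range(u)}
    ckey = {i: keys[i] for i in range(u)}
    dist: dict[tuple[int, int], float] = {
        (i, j): 1.0 - ochiai(groups[i].factors, groups[j].factors)
        for i in range(u)
        for j in range(i + 1, u)
    }

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    active = list(range(u))
    while len(active) > k:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                cand = (d(a, b), *sorted((ckey[a], ckey[b])), a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, a, b = best
        na, nb = len(members[a]), len(members[b])
        for x in active:
            if x in (a, b):
                continue
            if linkage == "average":
                nd = (na * d(a, x) + nb * d(b, x)) / (na + nb)
            elif linkage == "single":
                nd = min(d(a, x), d(b, x))
            else:
                nd = max(d(a, x), d(b, x))
            dist[(a, x) if a < x else (x, a)] = nd
        members[a].extend(members[b])
        ckey[a] = min(ckey[a], ckey[b])
        del members[b]
        active.remove(b)

    clusters = sorted(members.values(), key=lambda c: min(keys[i] for i in c))
    cohorts = [
        _cohort_from_groups(window, [groups[i] for i in c], index_factor)
        for c in clusters
    ]
    return CohortSet(window, cohorts)
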
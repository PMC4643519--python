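"""The cohort-trajectory network: transitions, outcome entropy, filtering.

Nodes are cohorts at successive time windows; a directed edge links two
cohorts in consecutive windows whenever their member sets overlap.  Edge
weight is the overlap cardinality and its conditional probability is

    pb(c_{l+1,j} | c_{l,i}) = |c_{l,i} ∩ c_{l+1,j}| / |c_{l,i}|

A source cohort's *outcome entropy* measures how dispersed its members'
next-window destinations are: zero for a deterministic transition, maximal
when the outgoing probabilities are uniform.  The default is Shannon entropy
(natural log) over the outgoing probabilities; an ``as-printed`` mode
computing −Σ p·p is kept for fidelity with an alternative published form of
the same filter (it ranks transitions identically but is offset so that a
deterministic transition scores −1 rather than 0).  Edge filtering keeps
exactly the edges whose source entropy is at or below a threshold; nodes are
never removed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .clustering import Cohort, CohortSet
from .windows import WindowedTrajectory

__all__ = [
    "Edge",
    "CohortNetwork",
    "Highlight",
    "build_network",
    "outcome_entropy",
    "filter_edges",
    "highlight",
    "summarize",
]

ENTROPY_MODES = ("shannon", "as-printed")


def node_id(window: int, position: int) -> str:
    return f"w{window}:{position}"


@dataclass(frozen=True)
class Edge:
    source: str  # node id at window l
    target: str  # node id at window l+1
    members: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.members)

    @property
    def id(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class CohortNetwork:
    """All cohorts across windows plus the overlap edges between them."""

    cohort_sets: list[CohortSet]
    edges: list[Edge]
    entropy_mode: str = "shannon"

    def __post_init__(self) -> None:
        if self.entropy_mode not in ENTROPY_MODES:
            raise ValueError(f"entropy mode must be one of {ENTROPY_MODES}")

    # -- node access ---------------------------------------------------------
    @property
    def nodes(self) -> dict[str, Cohort]:
        return {
            node_id(cs.window, h): c
            for cs in self.cohort_sets
            for h, c in enumerate(cs.cohorts)
        }

    def out_edges(self, nid: str) -> list[Edge]:
        return [e for e in self.edges if e.source == nid]

    @property
    def probabilities(self) -> dict[str, float]:
        """pb(target | source) per edge id, denominator = source cardinality."""
        sizes = {nid: len(c) for nid, c in self.nodes.items()}
        return {e.id: e.cardinality / sizes[e.source] for e in self.edges}

    def entropies(self, mode: str | None = None) -> dict[str, float | None]:
        """Outcome entropy per node id; None flags nodes with no outgoing edge."""
        mode = mode or self.entropy_mode
        probs = self.probabilities
        by_source: dict[str, list[float]] = {}
        for e in self.edges:
            by_source.setdefault(e.source, []).append(probs[e.id])
        out: dict[str, float | None] = {}
        for nid, cohort in self.nodes.items():
            if nid in by_source:
                out[nid] = outcome_entropy(by_source[nid], mode=mode)
            else:
                out[nid] = None  # terminal window or full attrition: undefined
        return out

    def attrition_nodes(self, tol: float = 1e-9) -> set[str]:
        """Non-terminal nodes whose outgoing probabilities sum to < 1."""
        probs = self.probabilities
        sums: dict[str, float] = {}
        for e in self.edges:
            sums[e.source] = sums.get(e.source, 0.0) + probs[e.id]
        last = max((cs.window for cs in self.cohort_sets), default=0)
        flagged = set()
        for nid, c in self.nodes.items():
            if c.window == last:
                continue
            if sums.get(nid, 0.0) < 1.0 - tol:
                flagged.add(nid)
        return flagged

    def to_networkx(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        ent = self.entropies()
        for nid, c in self.nodes.items():
            g.add_node(nid, window=c.window, label=c.label, size=len(c), entropy=ent[nid])
        probs = self.probabilities
        for e in self.edges:
            g.add_edge(e.source, e.target, cardinality=e.cardinality, probability=probs[e.id])
        return g

    # -- JSON serialization ---------------------------------------------------
    def to_dict(self, *, include_members: bool = True) -> dict:
        ent = self.entropies()
        probs = self.probabilities
        return {
            "entropy_mode": self.entropy_mode,
            "windows": [
                {
                    "window": cs.window,
                    "cohorts": [
                        {
                            "id": node_id(cs.window, h),
                            "label": c.label,
                            "kind": c.kind,
                            "custom_label": c.custom_label,
                            "common_factors": sorted(c.common_factors),
                            "partial": c.partial,
                            "contains_index": c.contains_index,
                            "size": len(c),
                            "entropy": ent[node_id(cs.window, h)],
                            **({"members": list(c.members)} if include_members else {}),
                        }
                        for h, c in enumerate(cs.cohorts)
                    ],
                }
                for cs in self.cohort_sets
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "cardinality": e.cardinality,
                    "probability": probs[e.id],
                    **({"members": list(e.members)} if include_members else {}),
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortNetwork":
        cohort_sets = []
        for wd in d["windows"]:
            cohorts = [
                Cohort(
                    wd["window"],
                    tuple(cd["members"]),
                    frozenset(cd["common_factors"]),
                    cd["partial"],
                    cd["contains_index"],
                    cd.get("kind", "comorbidity"),
                    cd.get("custom_label"),
                )
                for cd in wd["cohorts"]
            ]
            cohort_sets.append(CohortSet(wd["window"], cohorts))
        edges = [
            Edge(ed["source"], ed["target"], tuple(ed["members"])) for ed in d["edges"]
        ]
        return cls(cohort_sets, edges, d.get("entropy_mode", "shannon"))


@dataclass
class Highlight:
    """Selection overlay: per-node and per-edge highlighted member counts."""

    patient_ids: frozenset[str]
    node_counts: dict[str, int]
    edge_counts: dict[str, int]


def build_network(
    cohort_sets: Sequence[CohortSet], *, entropy_mode: str = "shannon"
) -> CohortNetwork:
    """Connect consecutive-window cohorts whose member sets overlap."""
    if len(cohort_sets) < 2:
        raise ValueError("need cohorts for at least two windows")
    sets = sorted(cohort_sets, key=lambda cs: cs.window)
    edges: list[Edge] = []
    for left, right in zip(sets, sets[1:]):
        for i, ci in enumerate(left.cohorts):
            mi = set(ci.members)
            for j, cj in enumerate(right.cohorts):
                overlap = mi.intersection(cj.members)
                if overlap:
                    edges.append(
                        Edge(
                            node_id(left.window, i),
                            node_id(right.window, j),
                            tuple(sorted(overlap)),
                        )
                    )
    return CohortNetwork(list(sets), edges, entropy_mode)


def outcome_entropy(probabilities: Iterable[float], *, mode: str = "shannon") -> float:
    """Dispersion of a cohort's outgoing transition probabilities.

    ``shannon``: −Σ p ln p (0 for a single certain outcome, ln k at uniform).
    ``as-printed``: −Σ p·p (−1 for a single certain outcome, −1/k at uniform).
    """
    ps = [float(p) for p in probabilities]
    if not ps:
        raise ValueError("entropy of a node with no outgoing edges is undefined")
    if any(p <= 0 or p > 1 + 1e-12 for p in ps):
        raise ValueError("probabilities must lie in (0, 1]")
    if mode == "shannon":
        return -sum(p * math.log(p) for p in ps)
    if mode == "as-printed":
        return -sum(p * p for p in ps)
    raise ValueError(f"entropy mode must be one of {ENTROPY_MODES}")


def filter_edges(
    net: CohortNetwork, threshold: float, *, mode: str | None = None
) -> CohortNetwork:
    """Keep exactly the edges whose source-node entropy is ≤ ``threshold``.

    Filtering is all-or-none per source node (its outgoing edges share one
    entropy).  Nodes are never deleted.  At threshold 0 in Shannon mode only
    deterministic transitions — every member of the source flowing to a
    single target — survive.
    """
    mode = mode or net.entropy_mode
    if mode == "shannon" and threshold < 0:
        raise ValueError("Shannon entropy threshold must be >= 0")
    ent = net.entropies(mode)
    kept = [e for e in net.edges if ent[e.source] is not None and ent[e.source] <= threshold]
    return CohortNetwork(net.cohort_sets, kept, net.entropy_mode)


def _resolve_selection(
    net: CohortNetwork,
    selection: str | Iterable[str],
    wtrajs: Sequence[WindowedTrajectory] | None,
    vocabulary: Iterable[str] | None,
) -> frozenset[str]:
    nodes = net.nodes
    if not isinstance(selection, str):
        return frozenset(selection)
    if selection in nodes:
        return frozenset(nodes[selection].members)
    by_id = {e.id: e for e in net.edges}
    if selection in by_id:
        return frozenset(by_id[selection].members)
    # factor name: all patients carrying it in any window
    if wtrajs is not None:
        observed = {f for wt in wtrajs for ws in wt.window_sets for f in ws}
        if selection in observed or (vocabulary is not None and selection in set(vocabulary)):
            return frozenset(
                wt.patient_id
                for wt in wtrajs
                if any(selection in ws for ws in wt.window_sets)
            )
    raise KeyError(f"selection {selection!r} is not a node id, edge id or known factor")


def highlight(
    net: CohortNetwork,
    selection: str | Iterable[str],
    *,
    wtrajs: Sequence[WindowedTrajectory] | None = None,
    vocabulary: Iterable[str] | None = None,
) -> Highlight:
    """Overlay counts for a selection (node id, edge id, factor name, or ids).

    Factor selection requires the windowed trajectories and highlights every
    patient whose factor set contains the factor in any window; a vocabulary
    factor observed nowhere yields an all-zero overlay, while a string that
    is neither a node id, an edge id nor a known factor raises.  Selecting an
    explicit (possibly empty) iterable of patient ids is always allowed.
    """
    ids = _resolve_selection(net, selection, wtrajs, vocabulary)
    node_counts = {nid: len(ids.intersection(c.members)) for nid, c in net.nodes.items()}
    edge_counts = {e.id: len(ids.intersection(e.members)) for e in net.edges}
    return Highlight(ids, node_counts, edge_counts)


def summarize(
    patient_ids: Iterable[str],
    *,
    wtrajs: Sequence[WindowedTrajectory] | None = None,
    metadata: pd.DataFrame | None = None,
    index_year: Mapping[str, int] | None = None,
) -> dict:
    """Distributions of sex, age at index and factor prevalence for a selection.

    ``metadata`` needs a ``patient_id`` column plus optional ``sex`` and
    ``birth_year``; ages are computed against ``index_year`` (patient id →
    calendar year of the index event) when both are available.  Without
    metadata only factor prevalence is reported.
    """
    ids = set(patient_ids)
    out: dict = {"n": len(ids)}
    if not ids:
        return out
    if wtrajs is not None:
        counts: dict[str, int] = {}
        for wt in wtrajs:
            if wt.patient_id not in ids:
                continue
            for f in set().union(*wt.window_sets):
                counts[f] = counts.get(f, 0) + 1
        out["factor_prevalence"] = {
            f: counts[f] / len(ids) for f in sorted(counts)
        }
    if metadata is not None:
        md = metadata[metadata["patient_id"].isin(ids)]
        if "sex" in md.columns:
            out["sex_counts"] = md["sex"].value_counts().sort_index().to_dict()
        if "birth_year" in md.columns and index_year:
            ages = [
                index_year[pid] - by
                for pid, by in zip(md["patient_id"], md["birth_year"].astype(int))
                if pid in index_year
            ]
            if ages:
                s = pd.Series(ages)
                out["age_at_index"] = {
                    "mean": float(s.mean()),
                    "median": float(s.median()),
                    "min": int(s.min()),
                    "max": int(s.max()),
                }
    return out
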
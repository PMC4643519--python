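"""Vertical ordering and positioning of cohort nodes for the Sankey view.

The y-axis is nominal, so node order within each window is free; we choose
it to reduce weighted edge crossings (weight = product of the two edges'
cardinalities).  The optimizer sweeps back and forth across the windows,
pulling each node toward the cardinality-weighted barycenter of its
neighbours in adjacent windows, resolving overlaps by order-preserving
push-apart, and perturbing the targets with annealed noise so early sweeps
can escape poor initial orders.  The best (lowest-crossing) state seen —
including the initial one — is returned, so the result never degrades the
starting layout.  Everything is deterministic given (network, seed).

Edges are drawn back-to-front by descending cardinality ("z-order"), so
small flows stay visible on top of large ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import OTHERS_INDEX, OTHERS_NONINDEX
from .network import CohortNetwork, Edge
from .windows import EMPTY_KEY

__all__ = ["LayoutResult", "initial_order", "optimize_order", "count_crossings", "z_order"]


@dataclass
class LayoutResult:
    """Node order/positions per window plus the edge drawing sequence."""

    order: dict[int, list[str]]  # window -> node ids, top to bottom
    tops: dict[str, float]  # node id -> top coordinate (abstract units)
    heights: dict[str, float]  # node id -> height (∝ cardinality)
    window_x: dict[int, float]  # window -> x position
    edge_z: list[str]  # edge ids, first drawn (bottom) to last (top)
    crossings_initial: float = 0.0
    crossings_final: float = 0.0


def initial_order(net: CohortNetwork) -> dict[int, list[str]]:
    """Descending-cardinality order, "others"/"(none)" groups forced last."""
    order: dict[int, list[str]] = {}
    nodes = net.nodes
    for cs in net.cohort_sets:
        ids = [nid for nid, c in nodes.items() if c.window == cs.window]

        def sort_key(nid: str):
            c = nodes[nid]
            bottom = c.kind in (OTHERS_INDEX, OTHERS_NONINDEX) or c.label == EMPTY_KEY
            return (bottom, -len(c), c.label)

        order[cs.window] = sorted(ids, key=sort_key)
    return order


def count_crossings(net: CohortNetwork, order: dict[int, list[str]]) -> float:
    """Weighted crossings: Σ over interleaving same-gap edge pairs of w_e·w_f."""
    nodes = net.nodes
    rank = {nid: r for w, ids in order.items() for r, nid in enumerate(ids)}
    by_gap: dict[int, list[Edge]] = {}
    for e in net.edges:
        by_gap.setdefault(nodes[e.source].window, []).append(e)
    total = 0.0
    for gap_edges in by_gap.values():
        for i, e in enumerate(gap_edges):
            for f in gap_edges[i + 1 :]:
                ds = rank[e.source] - rank[f.source]
                dt = rank[e.target] - rank[f.target]
                if ds * dt < 0:
                    total += e.cardinality * f.cardinality
    return total


def z_order(edges: Sequence[Edge]) -> list[str]:
    """Drawing sequence: larger edges first (underneath), ties by labels."""
    return [
        e.id
        for e in sorted(edges, key=lambda e: (-e.cardinality, e.source, e.target))
    ]


def _stack(ids: list[str], heights: dict[str, float], gap: float) -> dict[str, float]:
    """Stack nodes in order from the top, returning top coordinates."""
    tops = {}
    y = 0.0
    for nid in ids:
        tops[nid] = y
        y += heights[nid] + gap
    return tops


def optimize_order(
    net: CohortNetwork,
    *,
    seed: int = 0,
    sweeps: int = 32,
    gap: float = 1.0,
    cooling: float = 0.98,
    unit_height: float = 1.0,
) -> LayoutResult:
    """Barycenter sweeps with annealed perturbation; returns the best-seen order.

    ``sweeps`` round trips (left→right then right→left) are performed.  At
    each visited window every node's target is the cardinality-weighted mean
    of its adjacent-window neighbours' centers, plus Gaussian noise scaled by
    the current temperature (starting at the mean node height, shrinking
    geometrically by ``cooling`` each half-sweep); nodes are then re-stacked
    in target order.  The move is kept if it does not worsen the weighted
    crossing count, otherwise accepted with Metropolis probability — and the
    best state ever seen is what is finally returned and positioned.
    """
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    heights = {nid: max(len(c), 1) * unit_height for nid, c in nodes.items()}
    windows = sorted({cs.window for cs in net.cohort_sets})
    order = initial_order(net)

    # adjacency: node -> [(neighbour, weight)], both directions
    neigh: dict[str, list[tuple[str, int]]] = {nid: [] for nid in nodes}
    for e in net.edges:
        neigh[e.source].append((e.target, e.cardinality))
        neigh[e.target].append((e.source, e.cardinality))

    def centers(o: dict[int, list[str]]) -> dict[str, float]:
        c = {}
        for w in windows:
            tops = _stack(o[w], heights, gap)
            for nid in o[w]:
                c[nid] = tops[nid] + heights[nid] / 2
        return c

    cost = count_crossings(net, order)
    initial_cost = cost
    best_order = {w: list(ids) for w, ids in order.items()}
    best_cost = cost

    mean_h = float(np.mean(list(heights.values()))) if heights else 1.0
    temp = mean_h

    for sweep in range(sweeps):
        for direction in (windows, list(reversed(windows))):
            cen = centers(order)
            for w in direction:
                ids = order[w]
                if len(ids) < 2:
                    continue
                targets = {}
                for nid in ids:
                    nb = neigh[nid]
                    if nb:
                        tot = sum(wt for _, wt in nb)
                        bary = sum(cen[m] * wt for m, wt in nb) / tot
                    else:
                        bary = cen[nid]
                    targets[nid] = bary + rng.normal(0.0, temp)
                proposal = sorted(ids, key=lambda nid: (targets[nid], nid))
                if proposal == ids:
                    continue
                trial = {k: (proposal if k == w else v) for k, v in order.items()}
                trial_cost = count_crossings(net, trial)
                delta = trial_cost - cost
                if delta <= 0 or (
                    temp > 0 and rng.random() < np.exp(-delta / (temp * mean_h))
                ):
                    order, cost = trial, trial_cost
                    cen = centers(order)
                if cost < best_cost:
                    best_cost = cost
                    best_order = {k: list(v) for k, v in order.items()}
            temp *= cooling

    tops = {}
    for w in windows:
        tops.update(_stack(best_order[w], heights, gap))
    return LayoutResult(
        order=best_order,
        tops=tops,
        heights=heights,
        window_x={w: float(i) for i, w in enumerate(windows)},
        edge_z=z_order(net.edges),
        crossings_initial=initial_cost,
        crossings_final=best_cost,
    )
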
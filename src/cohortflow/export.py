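"""Renderer-agnostic Sankey document export (JSON) and a static HTML view.

The JSON document is the contract between the analysis pipeline and any
renderer: nodes with window/position/size/color, links with gradient color
pairs, source entropy and z-index, plus an optional highlight overlay.  A
JSON Schema describing it ships with the package
(``cohortflow/data/sankey.schema.json``) and :func:`validate_doc` enforces
the same constraints structurally.  Output is byte-stable: keys sorted,
floats rounded to six significant digits.

The HTML export embeds a static inline-SVG rendering (heights proportional
to cardinality, per-comorbidity colors, gradient ribbons, asterisk labels,
red highlight regions, native hover tooltips) so the file can be opened
offline in any browser.
"""

from __future__ import annotations

import hashlib
import html
import json
from pathlib import Path
from typing import Mapping

from .clustering import OTHERS_INDEX, OTHERS_NONINDEX
from .layout import LayoutResult
from .network import CohortNetwork, Highlight
from .windows import EMPTY_KEY

__all__ = ["assign_colors", "export_json", "export_html", "validate_doc", "PALETTE"]

# fixed categorical palette (20 hues); collisions beyond 20 labels are accepted
PALETTE = [
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
    "#C49C94", "#F7B6D2", "#DBDB8D", "#9EDAE5", "#393B79",
]
OTHERS_INDEX_COLOR = "#F5C78E"  # light orange: below-threshold groups with index factor
OTHERS_NONINDEX_COLOR = "#BDE3BD"  # light green: below-threshold groups without it
NONE_COLOR = "#C4C4C4"  # neutral grey for the explicit empty combination
HIGHLIGHT_COLOR = "#D62828"


def _stable_index(label: str, modulus: int) -> int:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % modulus


def assign_colors(net: CohortNetwork) -> dict[str, str]:
    """Deterministic node-id → color mapping keyed on cohort labels.

    The same label always gets the same palette color (stable hash), across
    runs and regenerations; "others" groups use the two reserved tints and
    the empty combination a neutral grey.
    """
    colors: dict[str, str] = {}
    for nid, c in net.nodes.items():
        if c.kind == OTHERS_INDEX:
            colors[nid] = OTHERS_INDEX_COLOR
        elif c.kind == OTHERS_NONINDEX:
            colors[nid] = OTHERS_NONINDEX_COLOR
        elif c.label == EMPTY_KEY:
            colors[nid] = NONE_COLOR
        else:
            colors[nid] = PALETTE[_stable_index(c.label, len(PALETTE))]
    return colors


def _sig6(x: float) -> float:
    return float(f"{float(x):.6g}")


def build_doc(
    net: CohortNetwork,
    layout: LayoutResult,
    *,
    highlight: Highlight | None = None,
    meta: Mapping | None = None,
) -> dict:
    """Assemble the Sankey document dict (validated before return)."""
    colors = assign_colors(net)
    ent = net.entropies()
    probs = net.probabilities
    z_index = {eid: z for z, eid in enumerate(layout.edge_z)}
    nodes = []
    for nid, c in net.nodes.items():
        node = {
            "id": nid,
            "window": c.window,
            "label": c.label,
            "size": len(c),
            "x": _sig6(layout.window_x[c.window]),
            "y": _sig6(layout.tops[nid]),
            "height": _sig6(layout.heights[nid]),
            "color": colors[nid],
            "entropy": None if ent[nid] is None else _sig6(ent[nid]),
        }
        if highlight is not None:
            node["highlight"] = highlight.node_counts[nid]
        nodes.append(node)
    nodes.sort(key=lambda n: (n["window"], n["y"]))

    links = []
    for e in net.edges:
        link = {
            "id": e.id,
            "source": e.source,
            "target": e.target,
            "size": e.cardinality,
            "probability": _sig6(probs[e.id]),
            "entropy": None if ent[e.source] is None else _sig6(ent[e.source]),
            "colors": [colors[e.source], colors[e.target]],
            "z": z_index[e.id],
        }
        if highlight is not None:
            link["highlight"] = highlight.edge_counts[e.id]
        links.append(link)
    links.sort(key=lambda l: l["z"])

    doc = {
        "meta": dict(meta or {}),
        "nodes": nodes,
        "links": links,
    }
    doc["meta"].setdefault("entropy_mode", net.entropy_mode)
    validate_doc(doc)
    return doc


def validate_doc(doc: Mapping) -> None:
    """Structural validation of a Sankey document (schema contract).

    Raises ``ValueError`` on the first violation; used as an internal bug
    guard before writing and after reading.
    """
    for key in ("meta", "nodes", "links"):
        if key not in doc:
            raise ValueError(f"document missing {key!r}")
    ids = set()
    for n in doc["nodes"]:
        for key in ("id", "window", "label", "size", "x", "y", "height", "color"):
            if key not in n:
                raise ValueError(f"node missing {key!r}: {n}")
        if n["size"] <= 0 or n["height"] <= 0:
            raise ValueError(f"non-positive node size/height: {n['id']}")
        if "highlight" in n and not 0 <= n["highlight"] <= n["size"]:
            raise ValueError(f"node highlight exceeds size: {n['id']}")
        ids.add(n["id"])
    zs = []
    for l in doc["links"]:
        for key in ("id", "source", "target", "size", "colors", "z"):
            if key not in l:
                raise ValueError(f"link missing {key!r}: {l}")
        if l["source"] not in ids or l["target"] not in ids:
            raise ValueError(f"link endpoint not a node: {l['id']}")
        if "highlight" in l and not 0 <= l["highlight"] <= l["size"]:
            raise ValueError(f"link highlight exceeds size: {l['id']}")
        zs.append(l["z"])
    if sorted(zs) != list(range(len(zs))):
        raise ValueError("link z-indices must form a permutation 0..n-1")


def dumps_doc(doc: Mapping) -> str:
    """Canonical byte-stable serialization (sorted keys, 6-sig-digit floats)."""
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), allow_nan=False) + "\n"


def export_json(
    net: CohortNetwork,
    layout: LayoutResult,
    path: str | Path | None = None,
    *,
    highlight: Highlight | None = None,
    meta: Mapping | None = None,
) -> dict:
    """Write (optionally) and return the Sankey document for a laid-out network."""
    doc = build_doc(net, layout, highlight=highlight, meta=meta)
    if path is not None:
        Path(path).write_text(dumps_doc(doc))
    return doc


# --------------------------------------------------------------------------
# static HTML rendering
# --------------------------------------------------------------------------

_X_STEP = 260.0
_NODE_W = 22.0
_MARGIN = 40.0


def _scale(doc: Mapping) -> float:
    """One global pixels-per-unit constant so heights stay proportional."""
    max_extent = max((n["y"] + n["height"] for n in doc["nodes"]), default=1.0)
    return 620.0 / max(max_extent, 1e-9)


def _ribbon(x0, y0, x1, y1, h0, h1) -> str:
    cx = (x0 + x1) / 2
    return (
        f"M {x0:.2f} {y0:.2f} C {cx:.2f} {y0:.2f} {cx:.2f} {y1:.2f} {x1:.2f} {y1:.2f} "
        f"L {x1:.2f} {y1 + h1:.2f} C {cx:.2f} {y1 + h1:.2f} {cx:.2f} {y0 + h0:.2f} "
        f"{x0:.2f} {y0 + h0:.2f} Z"
    )


def render_svg(doc: Mapping) -> str:
    """Static SVG: gradient ribbons under node bars, red highlight regions."""
    s = _scale(doc)
    nodes = {n["id"]: n for n in doc["nodes"]}
    n_windows = len({n["window"] for n in doc["nodes"]}) or 1
    width = _MARGIN * 2 + _X_STEP * (n_windows - 1) + _NODE_W + 160
    height = 700.0

    def nx(n):  # left edge of node bar
        return _MARGIN + n["x"] * _X_STEP

    def ny(n):
        return _MARGIN + n["y"] * s

    # per-source running offsets so parallel ribbons stack within a node
    out_off = {nid: 0.0 for nid in nodes}
    in_off = {nid: 0.0 for nid in nodes}
    defs, ribbons = [], []
    for i, l in enumerate(sorted(doc["links"], key=lambda l: l["z"])):
        a, b = nodes[l["source"]], nodes[l["target"]]
        h = l["size"] / max(a["size"], 1) * a["height"] * s
        hb = l["size"] / max(b["size"], 1) * b["height"] * s
        y0 = ny(a) + out_off[l["source"]]
        y1 = ny(b) + in_off[l["target"]]
        out_off[l["source"]] += h
        in_off[l["target"]] += hb
        gid = f"grad{i}"
        c0, c1 = l["colors"]
        defs.append(
            f'<linearGradient id="{gid}" x1="0" y1="0" x2="1" y2="0">'
            f'<stop offset="0" stop-color="{c0}"/><stop offset="1" stop-color="{c1}"/>'
            f"</linearGradient>"
        )
        path = _ribbon(nx(a) + _NODE_W, y0, nx(b), y1, h, hb)
        ent = l.get("entropy")
        tip = (
            f"{l['source']} → {l['target']} | n={l['size']} "
            f"p={l.get('probability', '')} entropy={'' if ent is None else ent}"
        )
        ribbons.append(
            f'<path d="{path}" fill="url(#{gid})" fill-opacity="0.55">'
            f"<title>{html.escape(tip)}</title></path>"
        )
        hl = l.get("highlight", 0)
        if hl:
            hh = hl / l["size"]
            ribbons.append(
                f'<path d="{_ribbon(nx(a) + _NODE_W, y0, nx(b), y1, h * hh, hb * hh)}" '
                f'fill="{HIGHLIGHT_COLOR}" fill-opacity="0.8" class="highlight">'
                f"<title>{html.escape(tip)} (selected {hl})</title></path>"
            )

    bars, labels = [], []
    for n in doc["nodes"]:
        x, y, h = nx(n), ny(n), n["height"] * s
        ent = n.get("entropy")
        tip = f"{n['label']} | n={n['size']} entropy={'' if ent is None else ent}"
        bars.append(
            f'<rect x="{x:.2f}" y="{y:.2f}" width="{_NODE_W}" height="{max(h, 1.5):.2f}" '
            f'fill="{n["color"]}" stroke="#333" stroke-width="0.5">'
            f"<title>{html.escape(tip)}</title></rect>"
        )
        hl = n.get("highlight", 0)
        if hl:
            bars.append(
                f'<rect x="{x:.2f}" y="{y:.2f}" width="{_NODE_W}" '
                f'height="{max(h * hl / n["size"], 1.5):.2f}" fill="{HIGHLIGHT_COLOR}" '
                f'class="highlight"><title>{html.escape(tip)} (selected {hl})</title></rect>'
            )
        labels.append(
            f'<text x="{x + _NODE_W + 4:.2f}" y="{y + max(h, 1.5) / 2 + 4:.2f}" '
            f'font-size="11" font-family="sans-serif">{html.escape(n["label"])} '
            f"({n['size']})</text>"
        )

    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" height="{height:.0f}" '
        f'viewBox="0 0 {width:.0f} {height:.0f}">'
        f"<defs>{''.join(defs)}</defs>{''.join(ribbons)}{''.join(bars)}{''.join(labels)}</svg>"
    )


def export_html(doc: Mapping, path: str | Path | None = None) -> str:
    """Self-contained HTML page: embedded document JSON plus the SVG view."""
    validate_doc(doc)
    meta = doc.get("meta", {})
    title = html.escape(str(meta.get("title", "Cohort trajectory Sankey")))
    page = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>body{{font-family:sans-serif;margin:24px}}summary{{cursor:pointer}}</style>
</head>
<body>
<h1>{title}</h1>
{render_svg(doc)}
<details><summary>Sankey document (JSON)</summary>
<pre id="sankey-doc">{html.escape(dumps_doc(doc))}</pre>
</details>
</body>
</html>
"""
    if path is not None:
        Path(path).write_text(page)
    return page
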
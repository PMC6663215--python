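"""Interactive export: graph documents and standalone force-directed HTML.

A :class:`GraphDocument` is a versioned JSON-serializable record of an
annotated shape graph: nodes with member frames and per-category label
proportions, links, a category color legend, and provenance.
:func:`render_html` embeds the document verbatim in a self-contained HTML
page (no network access needed) with a force-directed layout, nodes drawn as
pie charts sized by member count, a hover box per node, and an info panel
with the legend and provenance.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass, field
from pathlib import Path

from .analysis import NodeAnnotation
from .mapper import ShapeGraph

__all__ = ["GraphDocument", "graph_to_document", "render_html",
           "save_document_json", "load_document_json", "DEFAULT_PALETTE"]

# fixed 12-color categorical palette; the rest category is rendered gray
DEFAULT_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78", "#98df8a",
]
REST_COLOR = "#999999"


@dataclass
class GraphDocument:
    """JSON-ready annotated shape graph (schema ``shapegraph-document/1``)."""

    nodes: list[dict]
    links: list[dict]
    legend: dict[str, str]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": "shapegraph-document/1",
            "nodes": self.nodes,
            "links": self.links,
            "legend": self.legend,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GraphDocument":
        return cls(doc["nodes"], doc["links"], doc["legend"], doc.get("meta", {}))


def graph_to_document(
    graph: ShapeGraph,
    annotation: NodeAnnotation,
    legend: dict[str, str] | None = None,
    images: dict[int, str] | None = None,
    source: str = "",
) -> GraphDocument:
    """Serialize an annotated shape graph losslessly into a GraphDocument.

    Categories are sorted lexicographically for stable pie-slice ordering;
    ``legend`` maps category -> color and defaults to the fixed palette with
    rest in gray.  ``images`` optionally attaches a per-node image reference
    (e.g., an activation-map snapshot) shown in the hover box.
    """
    node_ids = {nd.id for nd in graph.nodes}
    if set(annotation.proportions) != node_ids:
        raise ValueError("annotation does not match the graph's node ids")
    categories = sorted(
        {c for props in annotation.proportions.values() for c in props}
    )
    if legend is None:
        legend = {}
        i = 0
        for c in categories:
            if c == "rest":
                legend[c] = REST_COLOR
            else:
                legend[c] = DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
                i += 1
    missing = [c for c in categories if c not in legend]
    if missing:
        raise ValueError(f"legend missing colors for categories {missing}")
    nodes = []
    for nd in graph.nodes:
        rec = {
            "id": nd.id,
            "size": len(nd.members),
            "members": list(nd.members),
            "bin": list(nd.bin),
            "proportions": {
                c: annotation.proportions[nd.id].get(c, 0.0)
                for c in sorted(annotation.proportions[nd.id])
            },
        }
        if images and nd.id in images:
            rec["image"] = images[nd.id]
        nodes.append(rec)
    links = [{"source": a, "target": b} for a, b in graph.edges]
    meta = {"provenance": graph.provenance, "n_samples": graph.n_samples}
    if source:
        meta["source"] = source
    return GraphDocument(nodes, links, legend, meta)


def save_document_json(doc: GraphDocument, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc.to_dict(), indent=1, sort_keys=True))


def load_document_json(path: str | Path) -> GraphDocument:
    return GraphDocument.from_dict(json.loads(Path(path).read_text()))


def render_html(doc: GraphDocument, output_path: str | Path) -> Path:
    """Write a standalone interactive HTML page for a graph document.

    The document JSON is embedded verbatim in a ``<script id="graph-data">``
    block; a small dependency-free script runs a force simulation and draws
    pie-chart nodes on SVG with hover details and an info panel.
    """
    payload = json.dumps(doc.to_dict(), sort_keys=True)
    page = _TEMPLATE.replace("__GRAPH_DATA__", payload).replace(
        "__TITLE__", _html.escape(str(doc.meta.get("source", "shape graph")))
    )
    out = Path(output_path)
    out.write_text(page)
    return out


_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>shape graph — __TITLE__</title>
<style>
 body { margin:0; font:13px sans-serif; display:flex; height:100vh; }
 #panel { width:260px; padding:12px; border-right:1px solid #ccc; overflow:auto; }
 #view { flex:1; }
 #hover { position:fixed; display:none; background:#fff; border:1px solid #888;
          padding:6px 8px; pointer-events:none; max-width:260px; }
 .swatch { display:inline-block; width:11px; height:11px; margin-right:5px; }
 line.link { stroke:#bbb; stroke-width:1px; }
 pre { white-space:pre-wrap; font-size:11px; color:#555; }
</style>
</head>
<body>
<div id="panel">
 <h3>Shape graph</h3>
 <div id="stats"></div>
 <h4>Legend</h4>
 <div id="legend"></div>
 <h4>Provenance</h4>
 <pre id="prov"></pre>
</div>
<svg id="view"></svg>
<div id="hover"></div>
<script id="graph-data" type="application/json">__GRAPH_DATA__</script>
<script>
const doc = JSON.parse(document.getElementById('graph-data').textContent);
const svg = document.getElementById('view');
const W = svg.clientWidth || 800, H = svg.clientHeight || 600;
svg.setAttribute('viewBox', `0 0 ${W} ${H}`);
document.getElementById('stats').textContent =
  `${doc.nodes.length} nodes, ${doc.links.length} edges, ` +
  `${doc.meta.n_samples || '?'} samples`;
document.getElementById('prov').textContent =
  JSON.stringify(doc.meta.provenance || {}, null, 1);
const legendDiv = document.getElementById('legend');
for (const [cat, color] of Object.entries(doc.legend)) {
  const row = document.createElement('div');
  row.innerHTML = `<span class="swatch" style="background:${color}"></span>${cat}`;
  legendDiv.appendChild(row);
}
// simple force simulation: springs on links, repulsion, centering
const nodes = doc.nodes.map((n, i) => ({
  ...n, x: W/2 + 100*Math.cos(2*Math.PI*i/doc.nodes.length),
        y: H/2 + 100*Math.sin(2*Math.PI*i/doc.nodes.length), vx:0, vy:0 }));
const byId = new Map(nodes.map(n => [n.id, n]));
const links = doc.links.map(l => ({ s: byId.get(l.source), t: byId.get(l.target) }));
function step() {
  for (const l of links) {
    const dx = l.t.x - l.s.x, dy = l.t.y - l.s.y;
    const d = Math.hypot(dx, dy) || 1, f = 0.02 * (d - 40) / d;
    l.s.vx += f*dx; l.s.vy += f*dy; l.t.vx -= f*dx; l.t.vy -= f*dy;
  }
  for (const a of nodes) for (const b of nodes) {
    if (a === b) continue;
    const dx = b.x - a.x, dy = b.y - a.y;
    const d2 = dx*dx + dy*dy + 1, f = -600 / d2;
    a.vx += f*dx/Math.sqrt(d2); a.vy += f*dy/Math.sqrt(d2);
  }
  for (const n of nodes) {
    n.vx += 0.005*(W/2 - n.x); n.vy += 0.005*(H/2 - n.y);
    n.vx *= 0.85; n.vy *= 0.85; n.x += n.vx; n.y += n.vy;
  }
}
for (let i = 0; i < 300; i++) step();
const NS = 'http://www.w3.org/2000/svg';
for (const l of links) {
  const e = document.createElementNS(NS, 'line');
  e.setAttribute('class', 'link');
  e.setAttribute('x1', l.s.x); e.setAttribute('y1', l.s.y);
  e.setAttribute('x2', l.t.x); e.setAttribute('y2', l.t.y);
  svg.appendChild(e);
}
const hover = document.getElementById('hover');
for (const n of nodes) {
  const g = document.createElementNS(NS, 'g');
  const r = 4 + 2.5*Math.sqrt(n.size);
  let a0 = -Math.PI/2;
  const cats = Object.keys(n.proportions).sort();
  for (const c of cats) {
    const frac = n.proportions[c];
    if (frac <= 0) continue;
    const a1 = a0 + 2*Math.PI*frac;
    const p = document.createElementNS(NS, 'path');
    const large = (a1 - a0) > Math.PI ? 1 : 0;
    const x0 = n.x + r*Math.cos(a0), y0 = n.y + r*Math.sin(a0);
    const x1 = n.x + r*Math.cos(a1), y1 = n.y + r*Math.sin(a1);
    p.setAttribute('d', frac >= 0.9999
      ? `M ${n.x-r} ${n.y} a ${r} ${r} 0 1 0 ${2*r} 0 a ${r} ${r} 0 1 0 ${-2*r} 0`
      : `M ${n.x} ${n.y} L ${x0} ${y0} A ${r} ${r} 0 ${large} 1 ${x1} ${y1} Z`);
    p.setAttribute('fill', doc.legend[c] || '#000');
    g.appendChild(p);
    a0 = a1;
  }
  g.addEventListener('mousemove', ev => {
    hover.style.display = 'block';
    hover.style.left = (ev.clientX + 12) + 'px';
    hover.style.top = (ev.clientY + 12) + 'px';
    const props = cats.map(c => `${c}: ${(100*n.proportions[c]).toFixed(0)}%`).join(', ');
    hover.innerHTML = `<b>node ${n.id}</b> — ${n.size} frames<br>${props}` +
      (n.image ? `<br><img src="${n.image}" width="220">` : '');
  });
  g.addEventListener('mouseleave', () => { hover.style.display = 'none'; });
  svg.appendChild(g);
}
</script>
</body>
</html>
"""
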
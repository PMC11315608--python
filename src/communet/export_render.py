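"""Style, serialize and render laid-out community networks.

The styled document is the single exchange format consumed by all three
writers: GraphML (typed attributes, read back by any graph tool), Cytoscape
JSON (.cyjs, positions in screen convention with the y axis flipped), and a
static matplotlib figure (SVG or PNG). All outputs are deterministic:
elements are sorted by ID and no timestamps are embedded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .context import DEFAULT_WIDTH_RANGE, DirectionClass, EdgeContext
from .errors import ParameterError
from .layout import LayoutResult
from .reduction import ReducedNetwork

#: Direction-class colour semantics (default palette).
PALETTE = {
    DirectionClass.PRODUCTION: "#2ca02c",     # green
    DirectionClass.CONSUMPTION: "#d62728",    # red
    DirectionClass.BIDIRECTIONAL: "#9467bd",  # purple
    DirectionClass.INACTIVE: "#c7c7c7",
    None: "#999999",                          # uncontextualized
}

#: Colour-blind-safe variant (Okabe-Ito).
PALETTE_COLORBLIND = {
    DirectionClass.PRODUCTION: "#009e73",
    DirectionClass.CONSUMPTION: "#d55e00",
    DirectionClass.BIDIRECTIONAL: "#cc79a7",
    DirectionClass.INACTIVE: "#c7c7c7",
    None: "#999999",
}

MEMBER_COLOUR = "#1f77b4"
METABOLITE_COLOUR = "#8c8c8c"
METABOLITE_SIZE = 10.0
MEMBER_SIZE = 3.0 * METABOLITE_SIZE  # members drawn at 3x metabolite diameter
#: metabolite labels are dropped above this many visible metabolites
LABEL_DECLUTTER_LIMIT = 50

ARROWS = {
    DirectionClass.PRODUCTION: "source->target",    # member -> metabolite
    DirectionClass.CONSUMPTION: "target->source",   # metabolite -> member
    DirectionClass.BIDIRECTIONAL: "both",
    DirectionClass.INACTIVE: "none",
    None: "none",
}


@dataclass(frozen=True)
class StyledNode:
    id: str
    type: str  # "member" | "metabolite"
    label: str
    x: float
    y: float
    visible: bool
    circle: int
    colour: str
    size: float


@dataclass(frozen=True)
class StyledEdge:
    id: str
    reaction_id: str
    source: str  # member node
    target: str  # metabolite node
    direction_class: str
    width: float
    colour: str
    arrow: str
    visible: bool


@dataclass(frozen=True)
class StyledNetworkDocument:
    nodes: tuple[StyledNode, ...]
    edges: tuple[StyledEdge, ...]

    def visible_nodes(self) -> list[StyledNode]:
        return [n for n in self.nodes if n.visible]

    def visible_edges(self) -> list[StyledEdge]:
        return [e for e in self.edges if e.visible]


def style_document(
    network: ReducedNetwork,
    layout: LayoutResult,
    contexts: dict[str, EdgeContext] | None = None,
    colorblind: bool = False,
) -> StyledNetworkDocument:
    """Merge topology, positions, visibility and flux context into a document."""
    palette = PALETTE_COLORBLIND if colorblind else PALETTE
    nodes = []
    for nid, member in sorted(network.member_nodes):
        x, y = layout.positions[nid]
        nodes.append(
            StyledNode(
                id=nid, type="member", label=member, x=x, y=y,
                visible=network.is_visible(nid),
                circle=layout.circle_of[nid],
                colour=MEMBER_COLOUR, size=MEMBER_SIZE,
            )
        )
    for node in sorted(network.metabolite_nodes, key=lambda n: n.node_id):
        x, y = layout.positions[node.node_id]
        nodes.append(
            StyledNode(
                id=node.node_id, type="metabolite", label=node.display_name,
                x=x, y=y, visible=network.is_visible(node.node_id),
                circle=layout.circle_of[node.node_id],
                colour=METABOLITE_COLOUR, size=METABOLITE_SIZE,
            )
        )
    edges = []
    for edge in sorted(network.edges, key=lambda e: e.edge_id):
        ctx = (contexts or {}).get(edge.edge_id)
        klass = ctx.direction_class if ctx is not None else None
        edges.append(
            StyledEdge(
                id=edge.edge_id,
                reaction_id=edge.reaction_id,
                source=edge.member_node,
                target=edge.metabolite_node,
                direction_class=klass.name if klass is not None else "NONE",
                width=ctx.display_width if ctx is not None else DEFAULT_WIDTH_RANGE[0],
                colour=palette[klass],
                arrow=ARROWS[klass],
                visible=network.is_visible(edge.edge_id),
            )
        )
    return StyledNetworkDocument(nodes=tuple(nodes), edges=tuple(edges))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _document_graph(document: StyledNetworkDocument) -> nx.MultiDiGraph:
    graph = nx.MultiDiGraph()
    for n in sorted(document.nodes, key=lambda n: n.id):
        graph.add_node(
            n.id, type=n.type, label=n.label, x=float(n.x), y=float(n.y),
            visible=n.visible, circle=int(n.circle), colour=n.colour,
            size=float(n.size),
        )
    for e in sorted(document.edges, key=lambda e: e.id):
        graph.add_edge(
            e.source, e.target, key=e.id,
            reaction_id=e.reaction_id, direction_class=e.direction_class,
            width=float(e.width), colour=e.colour, arrow=e.arrow,
            visible=e.visible,
        )
    return graph


def write_graphml(document: StyledNetworkDocument, path: str | Path) -> Path:
    """Write the document as GraphML with typed attributes, sorted by ID."""
    path = Path(path)
    graph = _document_graph(document)
    nx.write_graphml(graph, path, named_key_ids=True, edge_id_from_attribute=None)
    return path


def read_graphml(path: str | Path) -> nx.MultiDiGraph:
    """Round-trip reader (thin wrapper, used by tests and the CLI)."""
    return nx.read_graphml(str(path), force_multigraph=True)


def write_cyjs(document: StyledNetworkDocument, path: str | Path) -> Path:
    """Write a Cytoscape JSON network; y is flipped to screen convention."""
    path = Path(path)
    payload = {
        "format_version": "1.0",
        "generated_by": "communet",
        "target_cytoscapejs_version": "~2.1",
        "data": {"name": "community exchange network"},
        "elements": {
            "nodes": [
                {
                    "data": {
                        "id": n.id, "name": n.label, "type": n.type,
                        "circle": int(n.circle), "colour": n.colour,
                        "size": float(n.size), "visible": n.visible,
                    },
                    "position": {"x": float(n.x), "y": -float(n.y)},
                }
                for n in sorted(document.nodes, key=lambda n: n.id)
            ],
            "edges": [
                {
                    "data": {
                        "id": e.id, "source": e.source, "target": e.target,
                        "reaction_id": e.reaction_id,
                        "direction_class": e.direction_class,
                        "width": float(e.width), "colour": e.colour,
                        "arrow": e.arrow, "visible": e.visible,
                    }
                }
                for e in sorted(document.edges, key=lambda e: e.id)
            ],
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# figure rendering
# ---------------------------------------------------------------------------

def _arrowhead(ax, tip, direction, colour, size, gid):
    """Draw one arrowhead triangle with an SVG group ID (countable in tests)."""
    from matplotlib.patches import Polygon

    dx, dy = direction
    norm = math.hypot(dx, dy) or 1.0
    ux, uy = dx / norm, dy / norm
    px, py = -uy, ux
    base = (tip[0] - ux * size, tip[1] - uy * size)
    pts = [
        tip,
        (base[0] + px * size * 0.5, base[1] + py * size * 0.5),
        (base[0] - px * size * 0.5, base[1] - py * size * 0.5),
    ]
    patch = Polygon(pts, closed=True, facecolor=colour, edgecolor="none", zorder=3)
    patch.set_gid(gid)
    ax.add_patch(patch)


def render_figure(
    document: StyledNetworkDocument,
    path: str | Path,
    format: str = "svg",
    legend: bool = True,
    dpi: int = 300,
) -> Path:
    """Render the visible part of the document to SVG (deterministic text)
    or PNG (rasterized at ``dpi``).

    Node and edge SVG groups carry ``gid`` attributes (``node-<id>``,
    ``edge-<id>``, ``arrow-<id>-*``), so the drawn element set is auditable.
    """
    if format not in {"svg", "png"}:
        raise ParameterError(f"unknown figure format {format!r} (svg or png)")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D

    with plt.rc_context({"svg.hashsalt": "communet"}):
        fig, ax = plt.subplots(figsize=(10, 10))
        ax.set_aspect("equal")
        ax.axis("off")

        pos = {n.id: (n.x, n.y) for n in document.nodes}
        size_of = {n.id: n.size for n in document.nodes}
        visible_nodes = document.visible_nodes()
        visible_ids = {n.id for n in visible_nodes}
        n_visible_metabolites = sum(1 for n in visible_nodes if n.type == "metabolite")

        for e in document.visible_edges():
            if e.source not in pos or e.target not in pos:
                continue
            (x1, y1), (x2, y2) = pos[e.source], pos[e.target]
            line = Line2D([x1, x2], [y1, y2], linewidth=e.width, color=e.colour,
                          zorder=1, solid_capstyle="round")
            line.set_gid(f"edge-{e.id}")
            ax.add_line(line)
            dx, dy = x2 - x1, y2 - y1
            dist = math.hypot(dx, dy) or 1.0
            head = 6.0 + 1.5 * e.width
            if e.arrow in {"source->target", "both"}:
                # tip just outside the target node circle
                f = max(0.0, 1.0 - (size_of[e.target] * 0.6) / dist)
                _arrowhead(ax, (x1 + dx * f, y1 + dy * f), (dx, dy),
                           e.colour, head, f"arrow-{e.id}-target")
            if e.arrow in {"target->source", "both"}:
                f = max(0.0, 1.0 - (size_of[e.source] * 0.6) / dist)
                _arrowhead(ax, (x2 - dx * f, y2 - dy * f), (-dx, -dy),
                           e.colour, head, f"arrow-{e.id}-source")

        for n in visible_nodes:
            circ = plt.Circle((n.x, n.y), radius=n.size * 0.5, facecolor=n.colour,
                              edgecolor="#333333", linewidth=0.8, zorder=2)
            circ.set_gid(f"node-{n.id}")
            ax.add_patch(circ)
            draw_label = n.type == "member" or n_visible_metabolites <= LABEL_DECLUTTER_LIMIT
            if draw_label:
                txt = ax.annotate(
                    n.label, (n.x, n.y),
                    xytext=(0, n.size * 0.5 + 3), textcoords="offset points",
                    ha="center", va="bottom",
                    fontsize=9 if n.type == "member" else 6,
                    fontweight="bold" if n.type == "member" else "normal",
                    zorder=4,
                )
                txt.set_gid(f"label-{n.id}")

        if legend:
            handles = [
                Line2D([], [], color=PALETTE[DirectionClass.PRODUCTION], lw=3,
                       label="production (member → metabolite)"),
                Line2D([], [], color=PALETTE[DirectionClass.CONSUMPTION], lw=3,
                       label="consumption (metabolite → member)"),
                Line2D([], [], color=PALETTE[DirectionClass.BIDIRECTIONAL], lw=3,
                       label="bidirectional"),
                Line2D([], [], color=PALETTE[None], lw=3, label="uncontextualized"),
            ]
            ax.legend(handles=handles, loc="lower left", fontsize=8, frameon=False)

        if visible_ids:
            ax.relim()
            ax.autoscale_view()
            ax.margins(0.08)
        path = Path(path)
        fig.savefig(path, format=format, dpi=dpi, metadata={"Date": None} if format == "svg" else None)
        plt.close(fig)
    return path
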
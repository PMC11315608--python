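"""Build the reduced community interaction network.

The full community model (thousands of species and reactions) is collapsed
to a strictly bipartite graph: one node per community member, one node per
exchange metabolite (a species of the shared compartment that some member
transports), and one edge per member transport reaction. Community boundary
exchanges (medium <-> environment) carry no member and are therefore stored
as attributes of the metabolite node rather than as edges.

Visibility toggling (used by the cross-feeding filter) never deletes
anything: nodes and edges keep their identity in ``hidden``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model_io import SHARED, CommunityModel, TransportReaction


@dataclass(frozen=True)
class MetaboliteNode:
    node_id: str
    species_id: str
    display_name: str
    has_boundary_exchange: bool
    boundary_reaction_ids: tuple[str, ...]


@dataclass(frozen=True)
class Edge:
    edge_id: str
    reaction_id: str
    member_node: str
    metabolite_node: str
    external_coefficient: float


@dataclass
class ReducedNetwork:
    """Bipartite member/metabolite graph with a visibility overlay."""

    member_nodes: tuple[tuple[str, str], ...]  # (node_id, member ID)
    metabolite_nodes: tuple[MetaboliteNode, ...]
    edges: tuple[Edge, ...]
    hidden: set[str] = field(default_factory=set)
    #: saved pre-toggle hidden set while the cross-feeding filter is active
    toggle_memo: set[str] | None = None

    # -- lookups ------------------------------------------------------------

    def member_node_ids(self) -> list[str]:
        return [nid for nid, _ in self.member_nodes]

    def metabolite_node_ids(self) -> list[str]:
        return [n.node_id for n in self.metabolite_nodes]

    def edges_of_metabolite(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.metabolite_node == node_id]

    def member_degree(self, node_id: str) -> int:
        """Distinct member neighbours over visible + hidden edges."""
        return len({e.member_node for e in self.edges if e.metabolite_node == node_id})

    def is_visible(self, element_id: str) -> bool:
        return element_id not in self.hidden

    def visible_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.edge_id not in self.hidden]

    def to_networkx(self) -> nx.MultiGraph:
        graph = nx.MultiGraph()
        for nid, member in self.member_nodes:
            graph.add_node(nid, kind="member", member=member)
        for node in self.metabolite_nodes:
            graph.add_node(
                nid := node.node_id,
                kind="metabolite",
                species_id=node.species_id,
                display_name=node.display_name,
                has_boundary_exchange=node.has_boundary_exchange,
            )
        for e in self.edges:
            graph.add_edge(
                e.member_node, e.metabolite_node, key=e.edge_id,
                reaction_id=e.reaction_id, external_coefficient=e.external_coefficient,
            )
        return graph


@dataclass(frozen=True)
class NetworkSummary:
    n_members: int
    n_metabolites: int
    n_edges: int
    n_boundary_reactions: int
    degree_histogram: dict[int, int]

    @property
    def n_reaction_records(self) -> int:
        """Edges plus boundary exchanges — both readings of 'reactions kept'."""
        return self.n_edges + self.n_boundary_reactions


def _display_name(species_id: str, name: str, shared: str) -> str:
    if name:
        return name
    suffix = "_" + shared
    if species_id.endswith(suffix) and len(species_id) > len(suffix):
        return species_id[: -len(suffix)]
    return species_id


def build_reduced_network(
    model: CommunityModel,
    transports: list[TransportReaction],
) -> ReducedNetwork:
    """Reduce a community model to its member/exchange-metabolite graph.

    Every model member gets a node even when isolated. A metabolite node is
    created per distinct external species appearing in a *member* transport;
    parallel transporters of the same member/metabolite pair stay as
    parallel edges because flux files key on reaction IDs. Boundary
    exchanges (``member == SHARED``) are attached to their metabolite node.
    """
    names = {s.species_id: s.name for s in model.species}
    member_transports = [t for t in transports if t.member != SHARED]
    boundary: dict[str, list[str]] = {}
    for t in transports:
        if t.member == SHARED:
            boundary.setdefault(t.external_species, []).append(t.reaction_id)

    member_nodes = tuple((m, m) for m in model.members)
    seen: dict[str, None] = {}
    for t in member_transports:
        seen.setdefault(t.external_species, None)
    metabolite_nodes = tuple(
        MetaboliteNode(
            node_id=sid,
            species_id=sid,
            display_name=_display_name(sid, names.get(sid, ""), model.shared_compartment),
            has_boundary_exchange=sid in boundary,
            boundary_reaction_ids=tuple(sorted(boundary.get(sid, ()))),
        )
        for sid in sorted(seen)
    )
    edges = tuple(
        Edge(
            edge_id=t.reaction_id,
            reaction_id=t.reaction_id,
            member_node=t.member,
            metabolite_node=t.external_species,
            external_coefficient=t.external_coefficient,
        )
        for t in member_transports
    )
    return ReducedNetwork(
        member_nodes=member_nodes,
        metabolite_nodes=metabolite_nodes,
        edges=edges,
    )


def network_summary(network: ReducedNetwork) -> NetworkSummary:
    """Counts and the metabolite-degree histogram; hiding does not change them."""
    histogram: dict[int, int] = {}
    for node in network.metabolite_nodes:
        d = network.member_degree(node.node_id)
        histogram[d] = histogram.get(d, 0) + 1
    return NetworkSummary(
        n_members=len(network.member_nodes),
        n_metabolites=len(network.metabolite_nodes),
        n_edges=len(network.edges),
        n_boundary_reactions=sum(
            len(n.boundary_reaction_ids) for n in network.metabolite_nodes
        ),
        degree_histogram=histogram,
    )
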
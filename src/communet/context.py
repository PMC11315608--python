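"""Contextualize the reduced network with flux data.

Every edge of the reduced network is a member transport reaction. Given an
FBA flux vector or FVA flux ranges, each edge is classified by its *signed
production* p = external_coefficient x flux: p > 0 means the member releases
the metabolite into the shared compartment, p < 0 means uptake. Edges whose
production magnitude stays within the zero-flux tolerance epsilon are
INACTIVE and dropped from the visualization.

Cross-feeding follows the community-modelling definition: a metabolite is
cross-fed when some member produces it and a *different* member takes it up
— more than two members may participate, and the metabolite's presence in
the growth medium is irrelevant. Under FVA the criterion is feasibility
(some flux state produces it / some consumes it); under FBA it is the single
realized state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction

from scipy import stats

from .errors import ParameterError
from .model_io import SHARED, FluxRanges, FluxVector, TransportReaction
from .reduction import ReducedNetwork

logger = logging.getLogger(__name__)

#: Default zero-flux tolerance, in flux units (solver-noise scale).
DEFAULT_EPSILON = 1e-6

#: Default edge-width range in drawing units.
DEFAULT_WIDTH_RANGE = (1.0, 10.0)


class DirectionClass(Enum):
    PRODUCTION = "production"
    CONSUMPTION = "consumption"
    BIDIRECTIONAL = "bidirectional"
    INACTIVE = "inactive"


class ContextMode(Enum):
    FBA = "fba"
    FVA = "fva"


@dataclass(frozen=True)
class EdgeContext:
    edge_id: str
    direction_class: DirectionClass
    #: realized signed production (FBA) — None in FVA mode
    production_rate: float | None = None
    #: feasible signed-production range (FVA) — None in FBA mode
    production_range: tuple[float, float] | None = None
    display_width: float = DEFAULT_WIDTH_RANGE[0]

    @property
    def magnitude(self) -> float:
        if self.production_range is not None:
            return max(abs(self.production_range[0]), abs(self.production_range[1]))
        return abs(self.production_rate or 0.0)


@dataclass(frozen=True)
class MetaboliteCrossFeeding:
    producers: frozenset[str]
    consumers: frozenset[str]

    @property
    def cross_fed(self) -> bool:
        return any(a != b for a in self.producers for b in self.consumers)


@dataclass(frozen=True)
class CrossFeedingReport:
    entries: dict[str, MetaboliteCrossFeeding]  # metabolite node -> record
    mode: ContextMode

    def cross_fed_metabolites(self) -> set[str]:
        return {nid for nid, e in self.entries.items() if e.cross_fed}


# ---------------------------------------------------------------------------
# signed production and classification
# ---------------------------------------------------------------------------

def signed_production(transport: TransportReaction, flux: float) -> float:
    """external_coefficient x flux: positive = release into the medium."""
    return transport.external_coefficient * flux


def production_range(
    transport: TransportReaction, flux_range: tuple[float, float]
) -> tuple[float, float]:
    """Signed-production interval for an FVA flux range, order-corrected for
    negative coefficients (an uptake-written reaction flips the interval)."""
    a = transport.external_coefficient * flux_range[0]
    b = transport.external_coefficient * flux_range[1]
    return (a, b) if a <= b else (b, a)


def _classify_point(p: float, epsilon: float) -> DirectionClass:
    if p > epsilon:
        return DirectionClass.PRODUCTION
    if p < -epsilon:
        return DirectionClass.CONSUMPTION
    return DirectionClass.INACTIVE


def _classify_range(pmin: float, pmax: float, epsilon: float) -> DirectionClass:
    if pmax <= epsilon and pmin >= -epsilon:
        return DirectionClass.INACTIVE
    if pmin > epsilon:
        return DirectionClass.PRODUCTION
    if pmax < -epsilon:
        return DirectionClass.CONSUMPTION
    if pmin < -epsilon and pmax > epsilon:
        return DirectionClass.BIDIRECTIONAL
    # one side within tolerance, the other active: the active side decides
    return DirectionClass.PRODUCTION if pmax > epsilon else DirectionClass.CONSUMPTION


def edge_width(
    magnitude: float,
    all_magnitudes: list[float],
    width_range: tuple[float, float] = DEFAULT_WIDTH_RANGE,
    log_scale: bool = True,
) -> float:
    """Map a production magnitude to a drawing width.

    Log-compressed by default because genome-scale fluxes span orders of
    magnitude: w = w_min + (w_max - w_min) * log10(1 + m/m_ref) /
    log10(1 + m_max/m_ref) with m_ref the smallest non-zero magnitude.
    Strictly monotone, w(0) = w_min, w(m_max) = w_max. A linear mode is
    available behind ``log_scale=False``.
    """
    w_min, w_max = width_range
    if magnitude < 0:
        raise ParameterError(f"magnitude must be >= 0, got {magnitude}")
    nonzero = [m for m in all_magnitudes if m > 0]
    if not nonzero:
        return w_min
    m_max = max(nonzero)
    if not log_scale:
        return w_min + (w_max - w_min) * magnitude / m_max
    m_ref = min(nonzero)
    return w_min + (w_max - w_min) * math.log10(1 + magnitude / m_ref) / math.log10(
        1 + m_max / m_ref
    )


def _transport_index(transports: list[TransportReaction]) -> dict[str, TransportReaction]:
    return {t.reaction_id: t for t in transports}


def _warn_unknown_ids(known: set[str], provided, label: str) -> None:
    unknown = sorted(set(provided) - known)
    if unknown:
        logger.warning(
            "%s contains %d reaction ID(s) absent from the model (ignored): %s%s",
            label, len(unknown), ", ".join(unknown[:5]),
            ", ..." if len(unknown) > 5 else "",
        )


def classify_edges_fba(
    network: ReducedNetwork,
    transports: list[TransportReaction],
    fluxes: FluxVector,
    epsilon: float = DEFAULT_EPSILON,
    width_range: tuple[float, float] = DEFAULT_WIDTH_RANGE,
    log_widths: bool = True,
) -> dict[str, EdgeContext]:
    """Classify every edge from one FBA flux vector.

    Edges whose reaction is absent from the flux file are INACTIVE with a
    warning; flux-file IDs absent from the model are ignored with a warning.
    """
    if epsilon < 0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    index = _transport_index(transports)
    all_rids = {t.reaction_id for t in transports}
    _warn_unknown_ids(all_rids, fluxes.values.keys(), "flux file")
    productions: dict[str, float] = {}
    missing: list[str] = []
    for e in network.edges:
        t = index[e.reaction_id]
        if e.reaction_id in fluxes:
            productions[e.edge_id] = signed_production(t, fluxes[e.reaction_id])
        else:
            productions[e.edge_id] = 0.0
            missing.append(e.reaction_id)
    if missing:
        logger.warning(
            "%d edge reaction(s) absent from the flux file, treated as inactive: %s%s",
            len(missing), ", ".join(missing[:5]), ", ..." if len(missing) > 5 else "",
        )
    magnitudes = [abs(p) for p in productions.values()]
    contexts = {}
    for e in network.edges:
        p = productions[e.edge_id]
        contexts[e.edge_id] = EdgeContext(
            edge_id=e.edge_id,
            direction_class=_classify_point(p, epsilon),
            production_rate=p,
            display_width=edge_width(abs(p), magnitudes, width_range, log_widths),
        )
    return contexts


def classify_edges_fva(
    network: ReducedNetwork,
    transports: list[TransportReaction],
    ranges: FluxRanges,
    epsilon: float = DEFAULT_EPSILON,
    width_range: tuple[float, float] = DEFAULT_WIDTH_RANGE,
    log_widths: bool = True,
) -> dict[str, EdgeContext]:
    """Classify every edge from FVA flux ranges.

    A range whose signed production spans beyond +-epsilon on both sides is
    BIDIRECTIONAL (both secretion and uptake are feasible states).
    """
    if epsilon < 0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    index = _transport_index(transports)
    all_rids = {t.reaction_id for t in transports}
    _warn_unknown_ids(all_rids, ranges.ranges.keys(), "FVA file")
    prod_ranges: dict[str, tuple[float, float]] = {}
    missing: list[str] = []
    for e in network.edges:
        t = index[e.reaction_id]
        if e.reaction_id in ranges:
            prod_ranges[e.edge_id] = production_range(t, ranges[e.reaction_id])
        else:
            prod_ranges[e.edge_id] = (0.0, 0.0)
            missing.append(e.reaction_id)
    if missing:
        logger.warning(
            "%d edge reaction(s) absent from the FVA file, treated as inactive: %s%s",
            len(missing), ", ".join(missing[:5]), ", ..." if len(missing) > 5 else "",
        )
    magnitudes = [max(abs(a), abs(b)) for a, b in prod_ranges.values()]
    contexts = {}
    for e in network.edges:
        pmin, pmax = prod_ranges[e.edge_id]
        contexts[e.edge_id] = EdgeContext(
            edge_id=e.edge_id,
            direction_class=_classify_range(pmin, pmax, epsilon),
            production_range=(pmin, pmax),
            display_width=edge_width(
                max(abs(pmin), abs(pmax)), magnitudes, width_range, log_widths
            ),
        )
    return contexts


def hide_inactive(
    network: ReducedNetwork, contexts: dict[str, EdgeContext]
) -> ReducedNetwork:
    """Hide INACTIVE edges and metabolite nodes left with no visible edge.

    Mutates and returns the network's visibility overlay; member nodes are
    never hidden by flux context.
    """
    for edge in network.edges:
        ctx = contexts.get(edge.edge_id)
        if ctx is not None and ctx.direction_class is DirectionClass.INACTIVE:
            network.hidden.add(edge.edge_id)
        else:
            network.hidden.discard(edge.edge_id)
    for node in network.metabolite_nodes:
        edges = network.edges_of_metabolite(node.node_id)
        if edges and all(e.edge_id in network.hidden for e in edges):
            network.hidden.add(node.node_id)
        else:
            network.hidden.discard(node.node_id)
    return network


# ---------------------------------------------------------------------------
# cross-feeding
# ---------------------------------------------------------------------------

def detect_cross_feeding(
    network: ReducedNetwork,
    edge_contexts: dict[str, EdgeContext],
    mode: ContextMode,
    epsilon: float = DEFAULT_EPSILON,
) -> CrossFeedingReport:
    """Per-metabolite producer/consumer member sets and the cross-fed flag.

    FBA mode reads the realized state (PRODUCTION / CONSUMPTION edges); FVA
    mode reads feasibility (max production > epsilon / min production <
    -epsilon, so a BIDIRECTIONAL edge makes its member both a potential
    producer and a potential consumer). Boundary-exchange status plays no
    role: cross-feeding is defined member-to-member.
    """
    entries: dict[str, MetaboliteCrossFeeding] = {}
    for node in network.metabolite_nodes:
        producers: set[str] = set()
        consumers: set[str] = set()
        for edge in network.edges_of_metabolite(node.node_id):
            ctx = edge_contexts.get(edge.edge_id)
            if ctx is None:
                continue
            if mode is ContextMode.FBA:
                if ctx.direction_class is DirectionClass.PRODUCTION:
                    producers.add(edge.member_node)
                elif ctx.direction_class is DirectionClass.CONSUMPTION:
                    consumers.add(edge.member_node)
            else:
                pmin, pmax = ctx.production_range or (0.0, 0.0)
                if pmax > epsilon:
                    producers.add(edge.member_node)
                if pmin < -epsilon:
                    consumers.add(edge.member_node)
        entries[node.node_id] = MetaboliteCrossFeeding(
            producers=frozenset(producers), consumers=frozenset(consumers)
        )
    return CrossFeedingReport(entries=entries, mode=mode)


def toggle_cross_feeding(
    network: ReducedNetwork, report: CrossFeedingReport
) -> ReducedNetwork:
    """Toggle the cross-feeding-only view (an involution on visibility).

    First call: hide every metabolite not cross-fed together with its edges
    (INACTIVE edges stay hidden regardless). Second call: restore exactly
    the visibility state before the first call.
    """
    if network.toggle_memo is not None:
        network.hidden = set(network.toggle_memo)
        network.toggle_memo = None
        return network
    network.toggle_memo = set(network.hidden)
    cross_fed = report.cross_fed_metabolites()
    for node in network.metabolite_nodes:
        if node.node_id not in cross_fed:
            network.hidden.add(node.node_id)
            for edge in network.edges_of_metabolite(node.node_id):
                network.hidden.add(edge.edge_id)
    return network


# ---------------------------------------------------------------------------
# bidirectionality statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BidirectionalityStats:
    """2x2 association between cross-fed status and FVA bidirectionality.

    The primary partition covers member transport reactions; the
    ``*_with_boundary`` fields repeat the tally with community boundary
    exchanges included, since either denominator is a defensible reading of
    "external reactions".
    """

    n_crossfed: int
    n_bidirectional_crossfed: int
    n_other: int
    n_bidirectional_other: int
    fraction_bidirectional_crossfed: Fraction | None
    fraction_bidirectional_other: Fraction | None
    p_value: float | None
    n_crossfed_with_boundary: int = 0
    n_bidirectional_crossfed_with_boundary: int = 0
    n_other_with_boundary: int = 0
    n_bidirectional_other_with_boundary: int = 0

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.n_bidirectional_crossfed, self.n_crossfed - self.n_bidirectional_crossfed),
            (self.n_bidirectional_other, self.n_other - self.n_bidirectional_other),
        )


def fisher_exact_two_sided(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact test of independence on a 2x2 count table."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bidirectionality_stats(
    transports: list[TransportReaction],
    ranges: FluxRanges,
    report: CrossFeedingReport,
    epsilon: float = DEFAULT_EPSILON,
) -> BidirectionalityStats:
    """Fractions of bidirectionally-feasible transports among cross-fed vs
    other metabolites, with a two-sided exact test of independence.

    A transport is bidirectional iff its signed-production FVA range strictly
    spans +-epsilon on both sides. Fractions are exact rationals; an empty
    group reports None and suppresses the test.
    """
    if report.mode is not ContextMode.FVA:
        raise ParameterError("bidirectionality statistics require an FVA-mode report")
    cross_fed = report.cross_fed_metabolites()

    def is_bidirectional(t: TransportReaction) -> bool:
        if t.reaction_id not in ranges:
            return False
        pmin, pmax = production_range(t, ranges[t.reaction_id])
        return _classify_range(pmin, pmax, epsilon) is DirectionClass.BIDIRECTIONAL

    counts = {True: [0, 0], False: [0, 0]}  # cross_fed -> [total, bidirectional]
    counts_wb = {True: [0, 0], False: [0, 0]}
    for t in transports:
        in_group = t.external_species in cross_fed
        bidi = is_bidirectional(t)
        if t.member != SHARED:
            counts[in_group][0] += 1
            counts[in_group][1] += int(bidi)
        counts_wb[in_group][0] += 1
        counts_wb[in_group][1] += int(bidi)

    n_cf, b_cf = counts[True][0], counts[True][1]
    n_ot, b_ot = counts[False][0], counts[False][1]
    frac_cf = Fraction(b_cf, n_cf) if n_cf else None
    frac_ot = Fraction(b_ot, n_ot) if n_ot else None
    p = None
    if n_cf and n_ot:
        p = fisher_exact_two_sided(((b_cf, n_cf - b_cf), (b_ot, n_ot - b_ot)))
    return BidirectionalityStats(
        n_crossfed=n_cf,
        n_bidirectional_crossfed=b_cf,
        n_other=n_ot,
        n_bidirectional_other=b_ot,
        fraction_bidirectional_crossfed=frac_cf,
        fraction_bidirectional_other=frac_ot,
        p_value=p,
        n_crossfed_with_boundary=counts_wb[True][0],
        n_bidirectional_crossfed_with_boundary=counts_wb[True][1],
        n_other_with_boundary=counts_wb[False][0],
        n_bidirectional_other_with_boundary=counts_wb[False][1],
    )
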
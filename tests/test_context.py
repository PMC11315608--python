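"""Flux contextualization: classification, widths, cross-feeding, stats."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from communet import (
    ContextMode,
    DirectionClass,
    FluxRanges,
    FluxVector,
    bidirectionality_stats,
    classify_edges_fba,
    classify_edges_fva,
    detect_cross_feeding,
    edge_width,
    hide_inactive,
    read_flux_tsv,
    read_fva_tsv,
    signed_production,
    toggle_cross_feeding,
)
from communet.context import _classify_range, production_range
from communet.errors import ParameterError
from communet.model_io import SHARED, TransportReaction

from conftest import make_bundle


def _t(rid="R", member="alpha", coeff=1.0):
    return TransportReaction(rid, member, "x_medium", coeff)


# ---------------------------------------------------------------------------
# signed production
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "coeff, flux, expected",
    [(1.0, 2.5, 2.5), (-1.0, 2.5, -2.5), (2.0, -3.0, -6.0)],
)
def test_signed_production(coeff, flux, expected):
    assert signed_production(_t(coeff=coeff), flux) == expected


@pytest.mark.parametrize(
    "coeff, rng, expected",
    [
        (1.0, (2.0, 5.0), (2.0, 5.0)),
        (-1.0, (2.0, 5.0), (-5.0, -2.0)),   # uptake-written: order corrected
        (1.0, (-3.0, 5.0), (-3.0, 5.0)),
        (-2.0, (-3.0, 5.0), (-10.0, 6.0)),
    ],
)
def test_production_range_order_correction(coeff, rng, expected):
    assert production_range(_t(coeff=coeff), rng) == expected


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_fba_classification_on_fixture_matches_planted(bundle):
    fluxes = read_flux_tsv(bundle.fba_path)
    contexts = classify_edges_fba(bundle.network, bundle.transports, fluxes)
    for rid, planted in bundle.truth.planted_fba.items():
        assert contexts[rid].direction_class.value == planted


def test_fba_classification_equals_bruteforce_rederivation(bundle):
    """Independent oracle: recompute signs straight from TSV x coefficient."""
    fluxes = read_flux_tsv(bundle.fba_path)
    contexts = classify_edges_fba(bundle.network, bundle.transports, fluxes)
    coeff = {t.reaction_id: t.external_coefficient for t in bundle.transports}
    eps = 1e-6
    for edge in bundle.network.edges:
        p = coeff[edge.reaction_id] * fluxes[edge.reaction_id]
        expected = (
            "production" if p > eps else "consumption" if p < -eps else "inactive"
        )
        assert contexts[edge.edge_id].direction_class.value == expected
        assert contexts[edge.edge_id].production_rate == pytest.approx(p)


def test_fva_classification_on_fixture_matches_planted(bundle):
    ranges = read_fva_tsv(bundle.fva_path)
    contexts = classify_edges_fva(bundle.network, bundle.transports, ranges)
    for rid, planted in bundle.truth.planted_fva.items():
        assert contexts[rid].direction_class.value == planted


@pytest.mark.parametrize(
    "coeff, rng, expected",
    [
        (1.0, (-3.0, 5.0), DirectionClass.BIDIRECTIONAL),
        (1.0, (0.0, 0.0), DirectionClass.INACTIVE),
        (-1.0, (2.0, 5.0), DirectionClass.CONSUMPTION),
        (1.0, (2.0, 5.0), DirectionClass.PRODUCTION),
    ],
)
def test_fva_sign_cases(coeff, rng, expected):
    pmin, pmax = production_range(_t(coeff=coeff), rng)
    assert _classify_range(pmin, pmax, 1e-6) is expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(-50, 50, allow_nan=False),
    st.floats(-2.0, 2.0).filter(lambda c: abs(c) > 1e-3),
    st.floats(0, 1e-3),
)
def test_fba_equals_degenerate_fva(flux, coeff, eps):
    """FBA classification of v must equal FVA classification of (v, v)."""
    t = _t(coeff=coeff)
    p = signed_production(t, flux)
    point = (
        DirectionClass.PRODUCTION if p > eps
        else DirectionClass.CONSUMPTION if p < -eps
        else DirectionClass.INACTIVE
    )
    pmin, pmax = production_range(t, (flux, flux))
    assert _classify_range(pmin, pmax, eps) is point


def test_classification_exhaustive_and_exclusive(bundle):
    ranges = read_fva_tsv(bundle.fva_path)
    contexts = classify_edges_fva(bundle.network, bundle.transports, ranges)
    assert set(contexts) == {e.edge_id for e in bundle.network.edges}
    for ctx in contexts.values():
        assert isinstance(ctx.direction_class, DirectionClass)


def test_missing_reaction_in_flux_file_is_inactive(bundle, caplog):
    fluxes = read_flux_tsv(bundle.fba_path)
    some_edge = bundle.network.edges[0].reaction_id
    values = {k: v for k, v in fluxes.values.items() if k != some_edge}
    values["not_in_model"] = 1.0
    with caplog.at_level("WARNING"):
        contexts = classify_edges_fba(bundle.network, bundle.transports, FluxVector(values))
    assert contexts[some_edge].direction_class is DirectionClass.INACTIVE
    assert "absent" in caplog.text


# ---------------------------------------------------------------------------
# widths
# ---------------------------------------------------------------------------

def test_edge_width_boundaries_and_monotonicity():
    mags = [0.0, 1.0, 10.0, 100.0]
    w_min, w_max = 1.0, 10.0
    widths = [edge_width(m, mags, (w_min, w_max)) for m in mags]
    assert widths[0] == pytest.approx(w_min)
    assert widths[-1] == pytest.approx(w_max)
    assert all(a < b for a, b in zip(widths, widths[1:]))
    # all-zero magnitudes: every width collapses to w_min
    assert edge_width(0.0, [0.0, 0.0], (w_min, w_max)) == w_min


def test_edge_width_linear_mode():
    assert edge_width(5.0, [0.0, 10.0], (0.0, 2.0), log_scale=False) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# cross-feeding
# ---------------------------------------------------------------------------

def brute_force_crossfeeding(network, contexts, mode, eps=1e-6):
    """Exhaustive oracle over the member x metabolite signed-production matrix."""
    out = {}
    for node in network.metabolite_nodes:
        producers, consumers = set(), set()
        for edge in network.edges:
            if edge.metabolite_node != node.node_id:
                continue
            ctx = contexts[edge.edge_id]
            if mode is ContextMode.FBA:
                p = ctx.production_rate
                if p > eps:
                    producers.add(edge.member_node)
                if p < -eps:
                    consumers.add(edge.member_node)
            else:
                pmin, pmax = ctx.production_range
                if pmax > eps:
                    producers.add(edge.member_node)
                if pmin < -eps:
                    consumers.add(edge.member_node)
        cross = any(a != b for a in producers for b in consumers)
        out[node.node_id] = (frozenset(producers), frozenset(consumers), cross)
    return out


@pytest.mark.parametrize("mode", [ContextMode.FBA, ContextMode.FVA])
def test_detect_cross_feeding_equals_bruteforce(bundle, mode):
    if mode is ContextMode.FBA:
        contexts = classify_edges_fba(
            bundle.network, bundle.transports, read_flux_tsv(bundle.fba_path)
        )
    else:
        contexts = classify_edges_fva(
            bundle.network, bundle.transports, read_fva_tsv(bundle.fva_path)
        )
    report = detect_cross_feeding(bundle.network, contexts, mode)
    oracle = brute_force_crossfeeding(bundle.network, contexts, mode)
    for nid, entry in report.entries.items():
        producers, consumers, cross = oracle[nid]
        assert entry.producers == producers
        assert entry.consumers == consumers
        assert entry.cross_fed == cross


def test_cross_feeding_matches_planted_sets(bundle):
    contexts = classify_edges_fba(
        bundle.network, bundle.transports, read_flux_tsv(bundle.fba_path)
    )
    report = detect_cross_feeding(bundle.network, contexts, ContextMode.FBA)
    for ext, (producers, consumers) in bundle.truth.crossfeeding_fba.items():
        assert report.entries[ext].producers == frozenset(producers)
        assert report.entries[ext].consumers == frozenset(consumers)


def test_same_member_production_and_uptake_is_not_cross_feeding(bundle):
    """A metabolite produced and consumed only by one member is not cross-fed."""
    from communet.context import MetaboliteCrossFeeding

    entry = MetaboliteCrossFeeding(frozenset({"alpha"}), frozenset({"alpha"}))
    assert not entry.cross_fed
    entry2 = MetaboliteCrossFeeding(frozenset({"alpha"}), frozenset({"alpha", "beta"}))
    assert entry2.cross_fed


def test_cross_feeding_is_label_equivariant(bundle):
    """Permuting member labels permutes the report and nothing else."""
    contexts = classify_edges_fva(
        bundle.network, bundle.transports, read_fva_tsv(bundle.fva_path)
    )
    report = detect_cross_feeding(bundle.network, contexts, ContextMode.FVA)
    members = [m for m, _ in bundle.network.member_nodes]
    perm = dict(zip(members, members[1:] + members[:1]))
    relabeled = bundle.network.__class__(
        member_nodes=tuple((perm[n], perm[m]) for n, m in bundle.network.member_nodes),
        metabolite_nodes=bundle.network.metabolite_nodes,
        edges=tuple(
            e.__class__(e.edge_id, e.reaction_id, perm[e.member_node],
                        e.metabolite_node, e.external_coefficient)
            for e in bundle.network.edges
        ),
    )
    report2 = detect_cross_feeding(relabeled, contexts, ContextMode.FVA)
    for nid, entry in report.entries.items():
        assert report2.entries[nid].producers == frozenset(perm[m] for m in entry.producers)
        assert report2.entries[nid].consumers == frozenset(perm[m] for m in entry.consumers)
        assert report2.entries[nid].cross_fed == entry.cross_fed


def test_toggle_hides_non_crossfed_and_is_involution(bundle):
    contexts = classify_edges_fba(
        bundle.network, bundle.transports, read_flux_tsv(bundle.fba_path)
    )
    hide_inactive(bundle.network, contexts)
    report = detect_cross_feeding(bundle.network, contexts, ContextMode.FBA)
    before = set(bundle.network.hidden)
    toggle_cross_feeding(bundle.network, report)
    cross_fed = report.cross_fed_metabolites()
    for node in bundle.network.metabolite_nodes:
        if node.node_id not in cross_fed:
            assert node.node_id in bundle.network.hidden
    # member nodes are never hidden
    for nid, _m in bundle.network.member_nodes:
        assert nid not in bundle.network.hidden
    toggle_cross_feeding(bundle.network, report)
    assert bundle.network.hidden == before


def test_hide_inactive_hides_orphan_metabolites(tmp_path):
    b = make_bundle(tmp_path, n_members=2, n_private=2, n_pair=1, n_core=0, seed=11)
    contexts = classify_edges_fba(b.network, b.transports, read_flux_tsv(b.fba_path))
    hide_inactive(b.network, contexts)
    for node in b.network.metabolite_nodes:
        edges = b.network.edges_of_metabolite(node.node_id)
        if all(contexts[e.edge_id].direction_class is DirectionClass.INACTIVE for e in edges):
            assert node.node_id in b.network.hidden
        else:
            assert node.node_id not in b.network.hidden


# ---------------------------------------------------------------------------
# bidirectionality statistics
# ---------------------------------------------------------------------------

def hypergeom_fisher_two_sided(table):
    """Independent two-sided exact test: enumerate the hypergeometric
    distribution of the top-left cell and sum probabilities <= observed."""
    (a, b), (c, d) = table
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    lo, hi = max(0, m1 - n2), min(m1, n1)

    def pmf(k):
        return (
            math.comb(n1, k) * math.comb(n2, m1 - k) / math.comb(n, m1)
        )

    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12)))


def test_stats_fractions_are_exact_rationals():
    from communet.context import fisher_exact_two_sided

    table = ((31, 9), (8, 91))
    assert Fraction(31, 40) == Fraction(775, 1000)
    assert Fraction(8, 99) != Fraction(81, 1000)  # approx 0.081
    p = fisher_exact_two_sided(table)
    assert p == pytest.approx(hypergeom_fisher_two_sided(table), abs=1e-9)


def test_stats_on_fixture(bundle):
    ranges = read_fva_tsv(bundle.fva_path)
    contexts = classify_edges_fva(bundle.network, bundle.transports, ranges)
    report = detect_cross_feeding(bundle.network, contexts, ContextMode.FVA)
    stats = bidirectionality_stats(bundle.transports, ranges, report)
    n_member_transports = sum(1 for t in bundle.transports if t.member != SHARED)
    assert stats.n_crossfed + stats.n_other == n_member_transports
    if stats.fraction_bidirectional_crossfed is not None:
        assert stats.fraction_bidirectional_crossfed == Fraction(
            stats.n_bidirectional_crossfed, stats.n_crossfed
        )
    if stats.p_value is not None:
        oracle = hypergeom_fisher_two_sided(stats.table)
        assert stats.p_value == pytest.approx(oracle, abs=1e-9)
    # including boundary exchanges, totals grow by the boundary count
    total_wb = stats.n_crossfed_with_boundary + stats.n_other_with_boundary
    assert total_wb == len(bundle.transports)


def test_stats_all_bidirectional_gives_p_one():
    transports = [
        _t("R1", "alpha"), _t("R2", "beta"),
        TransportReaction("R3", "alpha", "y_medium", 1.0),
        TransportReaction("R4", "beta", "y_medium", 1.0),
    ]
    ranges = FluxRanges({r: (-2.0, 2.0) for r in ("R1", "R2", "R3", "R4")})
    from communet.context import CrossFeedingReport, MetaboliteCrossFeeding

    report = CrossFeedingReport(
        entries={
            "x_medium": MetaboliteCrossFeeding(frozenset({"alpha"}), frozenset({"beta"})),
            "y_medium": MetaboliteCrossFeeding(frozenset(), frozenset()),
        },
        mode=ContextMode.FVA,
    )
    stats = bidirectionality_stats(transports, ranges, report)
    assert stats.fraction_bidirectional_crossfed == Fraction(1)
    assert stats.fraction_bidirectional_other == Fraction(1)
    assert stats.p_value == pytest.approx(1.0)


def test_stats_empty_partition_reports_none(bundle):
    ranges = read_fva_tsv(bundle.fva_path)
    contexts = classify_edges_fva(bundle.network, bundle.transports, ranges)
    report = detect_cross_feeding(bundle.network, contexts, ContextMode.FVA)
    # force every metabolite cross-fed: the "other" partition is empty
    from communet.context import CrossFeedingReport, MetaboliteCrossFeeding

    forced = CrossFeedingReport(
        entries={
            nid: MetaboliteCrossFeeding(frozenset({"alpha"}), frozenset({"beta"}))
            for nid in report.entries
        },
        mode=ContextMode.FVA,
    )
    stats = bidirectionality_stats(bundle.transports, ranges, forced)
    assert stats.n_other == 0
    assert stats.fraction_bidirectional_other is None
    assert stats.p_value is None


def test_stats_requires_fva_mode(bundle):
    from communet.context import CrossFeedingReport

    report = CrossFeedingReport(entries={}, mode=ContextMode.FBA)
    with pytest.raises(ParameterError):
        bidirectionality_stats(bundle.transports, FluxRanges({}), report)


def test_planted_association_p_value_matches_oracle():
    """50 random 2x2 tables: scipy's exact p equals the enumeration oracle."""
    from communet.context import fisher_exact_two_sided

    rng = np.random.default_rng(42)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        table = ((a, b), (c, d))
        if (a + b) == 0 or (c + d) == 0:
            continue
        assert fisher_exact_two_sided(table) == pytest.approx(
            hypergeom_fisher_two_sided(table), abs=1e-9
        )
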
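"""Concentric-circle layout for reduced community networks.

Nodes are placed on four circles, outermost to innermost:

1. metabolites exchanged with exactly one member (outermost, largest),
2. the community members themselves, evenly spaced,
3. metabolites exchanged by exactly two members, at the mid-angle of the
   shorter arc between them (directly between the pair when adjacent),
4. hub metabolites with three or more member partners (innermost).

The member ordering around circle 2 is chosen to maximize the number of
two-member metabolites whose pair ends up adjacent, so that circle-3 nodes
sit between their partners. The layout is fully deterministic and seed-free;
collisions are resolved by minimal angular nudging within each circle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .errors import ParameterError
from .reduction import ReducedNetwork

TWO_PI = 2.0 * math.pi

#: Default ring radii, outermost first (arbitrary length units).
DEFAULT_RADII = (400.0, 280.0, 180.0, 90.0)

#: Minimum angular separation between nodes sharing a circle (radians).
MIN_SEPARATION = math.radians(2.0)


@dataclass(frozen=True)
class LayoutResult:
    positions: dict[str, tuple[float, float]]
    circle_of: dict[str, int]
    angle_of: dict[str, float]
    radii: tuple[float, float, float, float]
    member_order: tuple[str, ...]


# ---------------------------------------------------------------------------
# member ordering
# ---------------------------------------------------------------------------

def pair_weights(network: ReducedNetwork) -> dict[frozenset[str], int]:
    """w(a, b) = number of metabolites connected to exactly the member pair {a, b}."""
    weights: dict[frozenset[str], int] = {}
    for node in network.metabolite_nodes:
        members = frozenset(
            e.member_node for e in network.edges if e.metabolite_node == node.node_id
        )
        if len(members) == 2:
            weights[members] = weights.get(members, 0) + 1
    return weights


def _adjacency_score(order: tuple[str, ...], weights: dict[frozenset[str], int]) -> int:
    m = len(order)
    if m < 2:
        return 0
    pairs = {frozenset((order[i], order[(i + 1) % m])) for i in range(m)}
    return sum(weights.get(p, 0) for p in pairs)


def _canonical(order: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical representative of a circular sequence up to rotation/reflection."""
    m = len(order)
    if m <= 1:
        return order
    variants = []
    for seq in (order, order[::-1]):
        k = seq.index(min(seq))
        variants.append(seq[k:] + seq[:k])
    return min(variants)


def order_members(network: ReducedNetwork) -> tuple[str, ...]:
    """Circular member order maximizing adjacency of two-member metabolite pairs.

    Exact by exhaustive search of circular permutations for up to 8 members
    (the typical visualized community size); greedy heaviest-pair path
    merging above that. Ties break lexicographically.
    """
    members = sorted(network.member_node_ids())
    m = len(members)
    if m <= 2:
        return tuple(members)
    weights = pair_weights(network)
    if m <= 8:
        best: tuple[int, tuple[str, ...]] | None = None
        first = members[0]
        for perm in itertools.permutations(members[1:]):
            order = _canonical((first, *perm))
            key = (-_adjacency_score(order, weights), order)
            if best is None or key < best:
                best = key
        assert best is not None
        return best[1]
    return _greedy_order(members, weights)


def _greedy_order(members: list[str], weights: dict[frozenset[str], int]) -> tuple[str, ...]:
    # heaviest-edge insertion: merge path fragments endpoint-to-endpoint
    ranked = sorted(
        weights.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )
    paths: dict[str, list[str]] = {m: [m] for m in members}  # endpoint -> path
    in_path = {m: m for m in members}  # member -> fragment key (first element)

    def fragment_of(x: str) -> list[str]:
        return paths[in_path[x]]

    for pair, _w in ranked:
        a, b = sorted(pair)
        fa, fb = fragment_of(a), fragment_of(b)
        if fa is fb:
            continue
        if fa[0] != a and fa[-1] != a:
            continue
        if fb[0] != b and fb[-1] != b:
            continue
        if fa[-1] != a:
            fa.reverse()
        if fb[0] != b:
            fb.reverse()
        merged = fa + fb
        for key in (in_path[fa[0]], in_path[fb[0]], in_path[fa[-1]], in_path[fb[-1]]):
            paths.pop(key, None)
        paths[merged[0]] = merged
        for x in merged:
            in_path[x] = merged[0]
    fragments = sorted(paths.values(), key=lambda p: p[0])
    order = tuple(x for frag in fragments for x in frag)
    return _canonical(order)


# ---------------------------------------------------------------------------
# circle assignment
# ---------------------------------------------------------------------------

def assign_circles(network: ReducedNetwork) -> dict[str, int]:
    """Member-degree -> circle: 1 partner -> 1, members -> 2, 2 -> 3, >=3 -> 4.

    Degree counts visible *and* hidden edges, so toggling visibility never
    reshuffles the geometry.
    """
    circles = {nid: 2 for nid in network.member_node_ids()}
    for node in network.metabolite_nodes:
        degree = network.member_degree(node.node_id)
        circles[node.node_id] = 1 if degree <= 1 else (3 if degree == 2 else 4)
    return circles


# ---------------------------------------------------------------------------
# angular helpers
# ---------------------------------------------------------------------------

def _wrap(angle: float) -> float:
    a = math.fmod(angle, TWO_PI)
    return a + TWO_PI if a < 0 else a


def _shorter_arc_midpoint(a: float, b: float) -> float:
    """Mid-angle of the shorter arc from a to b; antipodal ties (within 1e-9)
    pick the arc running counter-clockwise from a."""
    diff = _wrap(b - a)
    if abs(diff - math.pi) <= 1e-9:
        return _wrap(a + math.pi / 2.0)
    if diff < math.pi:
        return _wrap(a + diff / 2.0)
    return _wrap(b + (TWO_PI - diff) / 2.0)


def _isotonic(values: list[float]) -> list[float]:
    """Pool-adjacent-violators projection onto non-decreasing sequences (L2)."""
    blocks: list[tuple[float, int]] = []  # (mean, count)
    for v in values:
        mean, count = v, 1
        while blocks and blocks[-1][0] > mean:
            pm, pc = blocks.pop()
            mean = (pm * pc + mean * count) / (pc + count)
            count += pc
        blocks.append((mean, count))
    out: list[float] = []
    for mean, count in blocks:
        out.extend([mean] * count)
    return out


def _enforce_min_gap(
    targets: list[tuple[float, str]], delta: float
) -> dict[str, float]:
    """Nudge angles on one circle so consecutive nodes are >= delta apart.

    Deterministic and rotation-equivariant: the circle is cut at its largest
    angular gap (ties by the following node's ID), unwrapped, and the target
    angles projected onto the min-gap-feasible set by isotonic regression of
    ``angle - i*delta``. Falls back to even spacing when the circle cannot
    fit all nodes at the requested gap.
    """
    n = len(targets)
    if n == 0:
        return {}
    if n == 1:
        return {targets[0][1]: _wrap(targets[0][0])}
    ordered = sorted(((_wrap(a), nid) for a, nid in targets), key=lambda t: (t[0], t[1]))
    # cut at the largest gap; tie-break by smallest following node ID
    gaps = []
    for i in range(n):
        nxt = (i + 1) % n
        gap = _wrap(ordered[nxt][0] - ordered[i][0])
        if nxt == 0:
            gap = ordered[0][0] + TWO_PI - ordered[-1][0]
        gaps.append((-gap, ordered[nxt][1], nxt))
    _neg, _tid, cut = min(gaps)
    seq = ordered[cut:] + ordered[:cut]
    base = seq[0][0]
    if n * delta >= TWO_PI:  # cannot fit at the requested gap: even spacing
        return {nid: _wrap(base + i * TWO_PI / n) for i, (_a, nid) in enumerate(seq)}
    unwrapped = []
    prev = 0.0
    for a, nid in seq:
        rel = _wrap(a - base)
        if rel < prev - 1e-12:  # numeric wrap guard
            rel += TWO_PI
        unwrapped.append(rel)
        prev = rel
    shifted = [u - i * delta for i, u in enumerate(unwrapped)]
    fitted = _isotonic(shifted)
    angles = [f + i * delta for i, f in enumerate(fitted)]
    # wrap-around feasibility: last and first must also be delta apart
    if angles[-1] - angles[0] > TWO_PI - delta:
        span = TWO_PI / n
        angles = [i * span for i in range(n)]
    return {nid: _wrap(base + ang) for (_a, nid), ang in zip(seq, angles)}


# ---------------------------------------------------------------------------
# positions
# ---------------------------------------------------------------------------

def compute_positions(
    network: ReducedNetwork,
    order: tuple[str, ...] | None = None,
    radii: tuple[float, float, float, float] | None = None,
    min_separation: float = MIN_SEPARATION,
) -> LayoutResult:
    """Place every node of the network on its circle.

    ``order`` is the circular member sequence (default: :func:`order_members`);
    ``radii`` are the four ring radii, strictly decreasing outermost-first.
    Angles follow the mathematical convention (counter-clockwise from +x);
    screen-coordinate exporters flip the y axis.
    """
    if order is None:
        order = order_members(network)
    if radii is None:
        radii = DEFAULT_RADII
    r1, r2, r3, r4 = radii
    if not (r1 > r2 > r3 > r4 > 0):
        raise ParameterError(
            f"radii must be strictly decreasing and positive, got {radii}"
        )
    if set(order) != set(network.member_node_ids()):
        raise ParameterError("member order must contain each member node exactly once")

    circles = assign_circles(network)
    m = len(order)
    member_angle = {nid: TWO_PI * k / m for k, nid in enumerate(order)}

    metabolite_members = {
        node.node_id: sorted(
            {e.member_node for e in network.edges if e.metabolite_node == node.node_id}
        )
        for node in network.metabolite_nodes
    }

    targets: dict[int, list[tuple[float, str]]] = {1: [], 3: [], 4: []}
    # circle 1: spread each member's private metabolites evenly inside the
    # angular sector of half-width pi/m centred on the member
    privates: dict[str, list[str]] = {}
    for nid, circ in circles.items():
        if circ == 1:
            owner = metabolite_members[nid][0] if metabolite_members[nid] else None
            if owner is None:
                # orphan metabolite (all edges from one hidden member cannot
                # happen; degree >= 1 invariant): park at angle 0
                targets[1].append((0.0, nid))
                continue
            privates.setdefault(owner, []).append(nid)
    sector = TWO_PI / m
    for owner, nids in privates.items():
        centre = member_angle[owner]
        for j, nid in enumerate(sorted(nids)):
            offset = ((j + 1) / (len(nids) + 1) - 0.5) * sector
            targets[1].append((centre + offset, nid))

    # circle 3: mid-angle of the shorter arc between the pair
    for nid, circ in circles.items():
        if circ == 3:
            a, b = metabolite_members[nid]
            targets[3].append(
                (_shorter_arc_midpoint(member_angle[a], member_angle[b]), nid)
            )

    # circle 4: even spacing, slots anchored at the hubs' preferred angles
    hubs = sorted(nid for nid, circ in circles.items() if circ == 4)
    if hubs:
        prefs = {}
        for nid in hubs:
            angs = [member_angle[x] for x in metabolite_members[nid]]
            sx = sum(math.cos(a) for a in angs)
            sy = sum(math.sin(a) for a in angs)
            if math.hypot(sx, sy) > 1e-9:
                prefs[nid] = _wrap(math.atan2(sy, sx))
            else:
                prefs[nid] = member_angle[metabolite_members[nid][0]]
        phase = prefs[min(hubs)]
        slots = [_wrap(phase + i * TWO_PI / len(hubs)) for i in range(len(hubs))]
        ranked = sorted(hubs, key=lambda nid: (_wrap(prefs[nid] - phase), nid))
        for slot, nid in zip(slots, ranked):
            targets[4].append((slot, nid))

    angle_of: dict[str, float] = dict(member_angle)
    for circ in (1, 3, 4):
        angle_of.update(_enforce_min_gap(targets[circ], min_separation))

    radius_of = {1: r1, 2: r2, 3: r3, 4: r4}
    positions = {
        nid: (
            radius_of[circles[nid]] * math.cos(angle),
            radius_of[circles[nid]] * math.sin(angle),
        )
        for nid, angle in angle_of.items()
    }
    return LayoutResult(
        positions=positions,
        circle_of=circles,
        angle_of={nid: _wrap(a) for nid, a in angle_of.items()},
        radii=radii,
        member_order=tuple(order),
    )


def layout_network(network: ReducedNetwork, **kwargs) -> LayoutResult:
    """Convenience wrapper: order members, assign circles, compute positions."""
    return compute_positions(network, **kwargs)
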
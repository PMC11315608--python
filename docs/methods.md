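# Methods

## The reduction model

A community genome-scale metabolic model is one stoichiometric matrix
covering several organisms. Membership is encoded in identifiers: every
compartment and metabolite belonging to member *m* is prefixed `m_…`, and
one shared external compartment (default ID `medium`, overridable through
the SBML parameter `shared_compartment_id`) mediates all exchange. The
package assumes — and checks — two structural conventions:

1. every non-shared compartment ID parses as `member + "_" + suffix`;
2. a reaction crossing the medium wall moves exactly **one** medium
   metabolite (a *transport reaction*). Reactions moving several medium
   metabolites are excluded with a warning rather than rejected, so models
   with stray multi-metabolite transporters still visualize.

The reduced network keeps members and exchanged metabolites as nodes and
member transports as edges. Parallel transporters of the same
member/metabolite pair remain parallel edges: flux files key on reaction
IDs, and merging them would make contextualization ambiguous. Community
boundary exchanges have no member, so they become metabolite-node
attributes (`boundary_reaction_ids`) instead of edges; the summary reports
edge and edge+boundary totals separately so either notion of "reactions
kept" is available.

### Member inference

The member set is inferred from identifiers alone. Every underscore in a
compartment ID is a candidate member boundary; an assignment of one
candidate prefix per compartment is *valid* when each species in that
compartment has the shape `member + "_" + base + "_" + suffix` that the
prefixing convention produces (non-empty base, suffix = the compartment
suffix). Among valid assignments the minimal-cardinality member set wins,
preferring longer prefixes and finally lexicographic order for
determinism. This structural species constraint is what disambiguates
member names that themselves contain underscores (`m_x_c`, `m_y_c` with
species `m_x_glc__D_c` → members `{m_x, m_y}`, not `{m}`). If no
assignment satisfies the strict shape (species IDs that do not repeat the
compartment suffix), a relaxed tier requiring only the `member + "_"`
prefix is tried before failing with advice to pass `member_override`,
which always bypasses inference. Exhaustive search is capped at 2·10⁵
assignments (beyond that: greedy longest prefix per compartment).

SBML parameter values are numeric, so the `shared_compartment_id` override
carries the compartment ID in the parameter's **name** attribute; the
fixture generator writes the same encoding. FBC flux-bound parameters are
preferred for reaction bounds, falling back to (−1000, 1000) with a
warning, as bound dialects vary between exporters.

## Layout

Four concentric circles, default radii (400, 280, 180, 90) in arbitrary
drawing units (chosen so rings do not overlap at the default node sizes;
overridable). Circle membership is a pure function of *member-degree* (the
number of distinct member partners, counted over visible **and** hidden
edges so toggling never moves nodes): degree 1 → circle 1 (outermost),
members → circle 2, degree 2 → circle 3, degree ≥ 3 → circle 4.

Members are evenly spaced on circle 2. Their circular order maximizes
Σ w(a,b) over adjacent pairs, where w(a,b) counts metabolites connected to
exactly {a,b} — the only nodes whose placement benefits from adjacency.
The maximization is exact (exhaustive over circular permutations) up to 8
members, matching typical visualized community sizes, and a deterministic
heaviest-pair path-merging heuristic beyond that; ties break
lexicographically on the canonical rotation/reflection.

Target angles: circle-1 metabolites spread evenly inside the angular
sector of half-width π/m centred on their sole member; circle-3
metabolites sit at the mid-angle of the shorter arc between their two
members (for antipodal pairs, the counter-clockwise arc from the
lexicographically smaller member, decided within 1e-9 so the choice is
stable under rotation); circle-4 metabolites are evenly spaced on slots
anchored at the circular mean of their members' angles. Collisions are
resolved per circle with a minimum angular separation of 2°: the circle is
cut at its largest gap (ties: smallest following node ID) and the target
angles are projected onto the min-gap-feasible set by isotonic regression
(pool-adjacent-violators on `angle − i·δ`), which leaves already-separated
targets untouched, spreads exact ties symmetrically, and is
rotation-equivariant. If a circle cannot fit its nodes at 2°, it falls
back to even spacing. The layout is seed-free; rotating the member order
by k positions rotates every position by 2πk/m.

Coordinates are mathematical (x right, y up, counter-clockwise angles);
the Cytoscape JSON writer flips y to screen convention.

## Flux contextualization

For transport reaction r with external (medium-side) stoichiometric
coefficient c_r, the *signed production* of one flux value v is
p = c_r·v: positive releases the metabolite into the medium, negative
takes it up. This makes classification independent of whether the
transporter was written in secretion or uptake orientation. FVA ranges are
order-corrected the same way (a negative coefficient flips the interval).

Classes, with zero-flux tolerance ε (default 1e-6 flux units — LP solver
noise scale; the tolerance is configurable because it is a numerical, not
biological, constant):

* FBA: p > ε production, p < −ε consumption, else inactive;
* FVA on (p_min, p_max): inside [−ε, ε] inactive; p_min > ε production;
  p_max < −ε consumption; spanning beyond ε on both sides bidirectional.
  When one end lies inside the tolerance band and the other outside
  (e.g. p_min = 0, p_max ≫ ε), the active side decides — this keeps the
  classification exhaustive and makes FBA(v) coincide with FVA((v,v)) for
  every v.

Inactive edges are hidden, and metabolite nodes with no visible edge are
hidden with them; member nodes never are. Edge widths are log-compressed,
`w = w_min + (w_max − w_min)·log10(1 + m/m_ref)/log10(1 + m_max/m_ref)`
with m_ref the smallest non-zero magnitude, because genome-scale fluxes
span orders of magnitude and a linear map collapses all but the largest;
a linear mode sits behind `log_scale=False`. Colours: production green,
consumption red, bidirectional purple, uncontextualized grey, with an
Okabe-Ito colour-blind-safe variant.

## Cross-feeding and bidirectionality

A metabolite is cross-fed when ∃ a ∈ producers, b ∈ consumers with a ≠ b.
Under FBA, producers/consumers come from the realized state (edges
classified production/consumption); under FVA from feasibility (some
feasible state produces, some consumes — a bidirectional edge contributes
its member to both sets). Presence of the metabolite in the growth medium
is deliberately ignored. The cross-feeding toggle hides non-cross-fed
metabolites and their edges, remembers the previous visibility state, and
restores it exactly on the second call (an involution).

`bidirectionality_stats` partitions member transports by the cross-fed
status of their metabolite and reports, per group, the fraction whose FVA
production range strictly spans ±ε — as exact rationals — plus a
two-sided Fisher exact test of independence on the 2×2 table
(scipy's implementation; tests cross-check it against an independent
hypergeometric enumeration). Because "external reactions" can reasonably
include or exclude community boundary exchanges, both denominators are
reported. Empty groups yield `None` fractions and suppress the test.

## The synthetic generator

`fixtures.generate_toy_community` emulates the input conventions without
any download: per member an internal compartment `m_c`, a `medium`
compartment, species `m_<base>_c` / `<base>_medium`, one single-metabolite
transfer per (member, metabolite) incidence, one boundary exchange per
external metabolite, and per-species source/sink pseudo-reactions. The
sources and sinks provide stoichiometric feasibility only — the artifact
visualizes states, it does not simulate metabolism, so no biomass
reactions or realistic pathways are generated. Transfers of odd-indexed
members are written in uptake orientation so both sign conventions are
exercised. Bounds: (−1000, 1000) on transfers and exchanges, (0, 1000) on
sources/sinks.

Topology is a deterministic function of the counts (members, private
metabolites per member, metabolites per member pair, hub metabolites
shared by all members); the closed formulas for node and edge counts are
the reduction oracle. The seed only draws producer/consumer roles and
flux magnitudes. The default spec — 4 members, 3 private, 2 per pair,
1 hub — gives 25 metabolite nodes and 40 edges, a structured community of
the size typically visualized (a handful of organisms); flux magnitudes
are uniform in [1, 10]·flux_scale, far above ε.

Planted FBA states give every pair/hub metabolite one producer and ≥ 1
distinct consumers and close the medium mass balance through the boundary
exchange (Σ signed production = boundary export, exact by construction).
Planted FVA states make exactly `round(fraction·n)` transfers
bidirectional (default fraction 0.5) and label the rest. What passing
tests on these fixtures shows: the pipeline recovers planted structure
exactly under the stated conventions. What they do not show: robustness to
real-world deviations — non-convention identifiers, multi-metabolite
transporters beyond the warn-and-exclude path, thermodynamically
inconsistent ranges, or AGORA-scale model size.

## Applying to real communities (external recipe)

For a real study: merge the member reconstructions into one prefixed
community SBML (e.g. with PyCoMo), compute a community FBA solution or
FVA ranges with an LP solver (typical protocol: maximize community growth
at equal member abundance, constrain to ≥ 90 % of the optimum, then
min/max each transport), dump them to the two TSV dialects, and run
`communet run --model … --fva … --crossfeed`. Solving is out of scope for
this package.

## Numerical and testing choices

* Determinism everywhere: sorted element order in every writer, no
  timestamps (SVG written with a fixed hash salt and no date metadata),
  byte-identical re-runs.
* The acceptance sweep uses a 10-shape × 10-seed fixture matrix (100
  communities up to 6 members) and a 20-replicate recovery sweep in
  `scripts/acceptance.py`; these sizes exercise every degree class and
  both flux modes while keeping the whole suite in seconds.
* Known limitations: member inference is heuristic when species IDs do not
  follow the `member_base_suffix` shape (use `member_override`); circle-3
  placement of non-adjacent pairs can collide with other targets and is
  then nudged off the exact mid-angle; the greedy member ordering above 8
  members is not guaranteed optimal.
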
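"""Synthetic toy community models with known ground truth.

The generator emits a compartmentalized community model in SBML L3 + FBC
that follows the naming conventions the parser expects: one internal
compartment ``<member>_c`` per member, a shared ``medium`` compartment,
member-prefixed species IDs, single-metabolite transfer reactions between
each member and the medium, one community boundary exchange per external
metabolite, and per-member source/sink pseudo-reactions that make every
transfer stoichiometrically feasible. Alongside the model it emits flux
states (an FBA vector or FVA ranges) with *planted* edge classifications
and cross-feeding sets, plus a ground-truth record with closed-formula
node/edge counts — the independent oracle for the rest of the package.

Topology is fully determined by the counts; the seed only chooses which
members act as producers/consumers and the flux magnitudes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import libsbml
import numpy as np

from .errors import ParameterError

_MEMBER_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lam", "mu",
)

DEFAULT_TRANSFER_BOUNDS = (-1000.0, 1000.0)
DEFAULT_SOURCE_BOUNDS = (0.0, 1000.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic community.

    Defaults give a small but structured community: four members, three
    private metabolites each, two metabolites per member pair and one hub
    metabolite shared by everyone — the shape of a typical visualized
    community (a handful of organisms, tens of exchange metabolites).
    """

    n_members: int = 4
    n_private: int = 3
    n_pair: int = 2
    n_core: int = 1
    seed: int = 0
    flux_scale: float = 1.0
    #: fraction of member transfers planted as BIDIRECTIONAL in FVA mode
    fva_bidirectional_fraction: float = 0.5
    shared_compartment: str = "medium"

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ParameterError("n_members must be >= 1")
        if min(self.n_private, self.n_pair, self.n_core) < 0:
            raise ParameterError("metabolite counts must be >= 0")
        if self.n_core > 0 and self.n_members < 3:
            raise ParameterError("core metabolites require >= 3 members")
        if self.flux_scale <= 0:
            raise ParameterError("flux_scale must be positive")
        if not 0.0 <= self.fva_bidirectional_fraction <= 1.0:
            raise ParameterError("fva_bidirectional_fraction must be in [0, 1]")

    @property
    def members(self) -> tuple[str, ...]:
        if self.n_members <= len(_MEMBER_NAMES):
            return _MEMBER_NAMES[: self.n_members]
        return tuple(f"org{i:03d}" for i in range(self.n_members))

    @property
    def n_metabolite_nodes(self) -> int:
        return (
            self.n_members * self.n_private
            + math.comb(self.n_members, 2) * self.n_pair
            + self.n_core
        )

    @property
    def n_edges(self) -> int:
        """Member transfer reactions: one per (member, metabolite) incidence."""
        return (
            self.n_members * self.n_private
            + 2 * math.comb(self.n_members, 2) * self.n_pair
            + self.n_members * self.n_core
        )


@dataclass
class FixtureGroundTruth:
    spec: FixtureSpec
    members: tuple[str, ...]
    shared_compartment: str
    #: external species ID -> tuple of member IDs exchanging it
    metabolite_members: dict[str, tuple[str, ...]]
    #: transfer reaction ID -> (member, external species, external coefficient)
    transfers: dict[str, tuple[str, str, float]]
    #: external species ID -> boundary exchange reaction ID
    boundary_reactions: dict[str, str]
    n_species: int
    n_reactions: int
    n_metabolite_nodes: int
    n_edges: int
    n_boundary: int
    #: planted per-reaction direction classes ("production" etc.), per mode
    planted_fba: dict[str, str] = field(default_factory=dict)
    planted_fva: dict[str, str] = field(default_factory=dict)
    #: planted cross-feeding: external species -> (producers, consumers)
    crossfeeding_fba: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=dict)
    crossfeeding_fva: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=dict)

    def member_degree(self, species_id: str) -> int:
        return len(self.metabolite_members[species_id])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["spec"] = asdict(self.spec)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=list)
            fh.write("\n")
        return path


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def _external_metabolites(spec: FixtureSpec) -> list[tuple[str, tuple[str, ...]]]:
    """(base ID, members exchanging it), in deterministic order."""
    members = spec.members
    out: list[tuple[str, tuple[str, ...]]] = []
    for i, m in enumerate(members):
        for j in range(spec.n_private):
            out.append((f"prv{i}x{j}", (m,)))
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            for q in range(spec.n_pair):
                out.append((f"pair{i}x{j}x{q}", (members[i], members[j])))
    for q in range(spec.n_core):
        out.append((f"core{q}", tuple(members)))
    return out


def _transfer_id(member: str, base: str) -> str:
    return f"{member}_TF_{base}"


def _external_species_id(base: str, shared: str) -> str:
    return f"{base}_{shared}"


def _transfer_orientation(spec: FixtureSpec, member: str) -> float:
    """External coefficient of the member's transfers; odd members are
    written in uptake orientation so both sign conventions are exercised."""
    return 1.0 if spec.members.index(member) % 2 == 0 else -1.0


# ---------------------------------------------------------------------------
# SBML emission
# ---------------------------------------------------------------------------

def _check(value, message: str):
    if value is None or (isinstance(value, int) and value < 0):
        raise RuntimeError(f"libsbml call failed: {message}")
    return value


def _add_species(model: libsbml.Model, sid: str, compartment: str) -> None:
    sp = _check(model.createSpecies(), f"species {sid}")
    sp.setId(sid)
    sp.setCompartment(compartment)
    sp.setHasOnlySubstanceUnits(False)
    sp.setBoundaryCondition(False)
    sp.setConstant(False)
    sp.setInitialConcentration(0.0)


def _add_reaction(
    model: libsbml.Model,
    rid: str,
    stoich: dict[str, float],
    bounds: tuple[float, float],
    bound_params: dict[float, str],
) -> None:
    rxn = _check(model.createReaction(), f"reaction {rid}")
    rxn.setId(rid)
    rxn.setReversible(bounds[0] < 0)
    rxn.setFast(False)
    for sid, coeff in stoich.items():
        ref = rxn.createReactant() if coeff < 0 else rxn.createProduct()
        ref.setSpecies(sid)
        ref.setStoichiometry(abs(coeff))
        ref.setConstant(True)
    fbc = rxn.getPlugin("fbc")
    fbc.setLowerFluxBound(bound_params[bounds[0]])
    fbc.setUpperFluxBound(bound_params[bounds[1]])


def generate_toy_community(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, FixtureGroundTruth]:
    """Emit the toy community SBML file and its ground-truth record.

    Deterministic given the spec (including the seed): regenerating with the
    same spec produces byte-identical SBML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shared = spec.shared_compartment
    members = spec.members
    externals = _external_metabolites(spec)

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(f"toy_community_s{spec.seed}")
    model.getPlugin("fbc").setStrict(True)

    for comp_id in [f"{m}_c" for m in members] + [shared]:
        comp = model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    if shared != "medium":
        # the override convention: the parameter's name carries the ID
        param = model.createParameter()
        param.setId("shared_compartment_id")
        param.setName(shared)
        param.setValue(0.0)
        param.setConstant(True)

    bound_values = sorted(
        {*DEFAULT_TRANSFER_BOUNDS, *DEFAULT_SOURCE_BOUNDS}
    )
    bound_params: dict[float, str] = {}
    for value in bound_values:
        pid = f"bound_{str(value).replace('-', 'minus_').replace('.', '_')}"
        param = model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        bound_params[value] = pid

    # species: internal copies per incident member, one medium species each
    n_species = 0
    for base, incident in externals:
        for m in incident:
            _add_species(model, f"{m}_{base}_c", f"{m}_c")
            n_species += 1
        _add_species(model, _external_species_id(base, shared), shared)
        n_species += 1

    transfers: dict[str, tuple[str, str, float]] = {}
    boundary: dict[str, str] = {}
    n_reactions = 0
    for base, incident in externals:
        ext = _external_species_id(base, shared)
        for m in incident:
            internal = f"{m}_{base}_c"
            coeff = _transfer_orientation(spec, m)
            rid = _transfer_id(m, base)
            # coeff +1: internal -> medium (secretion-written); -1: reverse
            _add_reaction(
                model, rid, {internal: -coeff, ext: coeff},
                DEFAULT_TRANSFER_BOUNDS, bound_params,
            )
            transfers[rid] = (m, ext, coeff)
            n_reactions += 1
            _add_reaction(
                model, f"{m}_SRC_{base}", {internal: 1.0},
                DEFAULT_SOURCE_BOUNDS, bound_params,
            )
            _add_reaction(
                model, f"{m}_SNK_{base}", {internal: -1.0},
                DEFAULT_SOURCE_BOUNDS, bound_params,
            )
            n_reactions += 2
        ex_rid = f"EX_{ext}"
        _add_reaction(model, ex_rid, {ext: -1.0}, DEFAULT_TRANSFER_BOUNDS, bound_params)
        boundary[ext] = ex_rid
        n_reactions += 1

    sbml_path = out_dir / f"toy_community_s{spec.seed}.xml"
    if libsbml.writeSBMLToFile(doc, str(sbml_path)) != 1:
        raise RuntimeError(f"could not write SBML to {sbml_path}")

    truth = FixtureGroundTruth(
        spec=spec,
        members=members,
        shared_compartment=shared,
        metabolite_members={
            _external_species_id(base, shared): incident for base, incident in externals
        },
        transfers=transfers,
        boundary_reactions=boundary,
        n_species=n_species,
        n_reactions=n_reactions,
        n_metabolite_nodes=spec.n_metabolite_nodes,
        n_edges=spec.n_edges,
        n_boundary=len(boundary),
    )
    truth.write(out_dir / f"ground_truth_s{spec.seed}.json")
    return sbml_path, truth


# ---------------------------------------------------------------------------
# flux states
# ---------------------------------------------------------------------------

def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed * 1_000_003 + salt) % (2**31))


def generate_flux_state(
    spec: FixtureSpec,
    ground_truth: FixtureGroundTruth,
    mode: str,
    out_dir: str | Path,
) -> Path:
    """Write a planted FBA flux vector or FVA range TSV for the fixture.

    FBA mode plants, per pair/core metabolite, one producer and at least one
    distinct consumer, closing the medium mass balance with the boundary
    exchange; per-reaction classes and cross-feeding sets are recorded in the
    ground truth. FVA mode plants exactly
    ``round(fva_bidirectional_fraction * n_transfers)`` bidirectional ranges
    and labels the rest production/consumption/inactive.
    """
    mode = mode.lower()
    if mode not in {"fba", "fva"}:
        raise ParameterError(f"mode must be 'fba' or 'fva', got {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = ground_truth
    by_metabolite: dict[str, list[str]] = {}
    for rid, (member, ext, _c) in truth.transfers.items():
        by_metabolite.setdefault(ext, []).append(rid)
    for rids in by_metabolite.values():
        rids.sort()

    if mode == "fba":
        rng = _rng(spec, 1)
        fluxes: dict[str, float] = {}
        planted: dict[str, str] = {}
        crossfeeding: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
        for ext in sorted(by_metabolite):
            rids = by_metabolite[ext]
            incident = list(truth.metabolite_members[ext])
            production: dict[str, float] = {rid: 0.0 for rid in rids}
            if len(incident) >= 2:
                producer = incident[rng.integers(len(incident))]
                rest = [m for m in incident if m != producer]
                n_consumers = int(rng.integers(1, len(rest) + 1))
                consumers = sorted(
                    rng.choice(rest, size=n_consumers, replace=False).tolist()
                )
                s = float(np.round(spec.flux_scale * rng.uniform(1.0, 10.0), 6))
                uptake_total = float(np.round(s * rng.uniform(0.3, 1.0), 6))
                share = float(np.round(uptake_total / len(consumers), 6))
                for rid in rids:
                    member = truth.transfers[rid][0]
                    if member == producer:
                        production[rid] = s
                    elif member in consumers:
                        production[rid] = -share
                crossfeeding[ext] = (tuple([producer]), tuple(consumers))
            else:
                choice = rng.integers(3)  # 0 produce, 1 consume, 2 inactive
                s = float(np.round(spec.flux_scale * rng.uniform(1.0, 10.0), 6))
                p = s if choice == 0 else (-s if choice == 1 else 0.0)
                production[rids[0]] = p
                member = truth.transfers[rids[0]][0]
                crossfeeding[ext] = (
                    (member,) if p > 0 else (),
                    (member,) if p < 0 else (),
                )
            for rid in rids:
                coeff = truth.transfers[rid][2]
                fluxes[rid] = production[rid] / coeff
                planted[rid] = (
                    "production" if production[rid] > 0
                    else "consumption" if production[rid] < 0
                    else "inactive"
                )
            # medium balance: boundary exports the net production
            fluxes[truth.boundary_reactions[ext]] = sum(production.values())
        truth.planted_fba = planted
        truth.crossfeeding_fba = crossfeeding
        path = out_dir / f"flux_fba_s{spec.seed}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("reaction_id\tflux\n")
            for rid in sorted(fluxes):
                fh.write(f"{rid}\t{fluxes[rid]:.9g}\n")
        return path

    rng = _rng(spec, 2)
    transfer_ids = sorted(truth.transfers)
    n_bidi = round(spec.fva_bidirectional_fraction * len(transfer_ids))
    bidi_set = set(
        rng.choice(transfer_ids, size=n_bidi, replace=False).tolist()
    ) if transfer_ids else set()
    planted = {}
    ranges: dict[str, tuple[float, float]] = {}
    prod_ranges: dict[str, tuple[float, float]] = {}
    for rid in transfer_ids:
        coeff = truth.transfers[rid][2]
        if rid in bidi_set:
            lo = -float(np.round(spec.flux_scale * rng.uniform(0.5, 5.0), 6))
            hi = float(np.round(spec.flux_scale * rng.uniform(0.5, 5.0), 6))
            planted[rid] = "bidirectional"
        else:
            kind = rng.integers(3)  # 0 production, 1 consumption, 2 inactive
            if kind == 0:
                lo = float(np.round(spec.flux_scale * rng.uniform(0.1, 1.0), 6))
                hi = lo + float(np.round(spec.flux_scale * rng.uniform(0.5, 5.0), 6))
                planted[rid] = "production"
            elif kind == 1:
                hi = -float(np.round(spec.flux_scale * rng.uniform(0.1, 1.0), 6))
                lo = hi - float(np.round(spec.flux_scale * rng.uniform(0.5, 5.0), 6))
                planted[rid] = "consumption"
            else:
                lo = hi = 0.0
                planted[rid] = "inactive"
        prod_ranges[rid] = (lo, hi)
        vlo, vhi = lo / coeff, hi / coeff
        ranges[rid] = (min(vlo, vhi), max(vlo, vhi))
    crossfeeding = {}
    for ext, rids in by_metabolite.items():
        producers = sorted(
            {truth.transfers[rid][0] for rid in rids if prod_ranges[rid][1] > 0}
        )
        consumers = sorted(
            {truth.transfers[rid][0] for rid in rids if prod_ranges[rid][0] < 0}
        )
        crossfeeding[ext] = (tuple(producers), tuple(consumers))
    for ext, ex_rid in truth.boundary_reactions.items():
        active = any(planted[rid] != "inactive" for rid in by_metabolite[ext])
        span = 10.0 * spec.flux_scale
        ranges[ex_rid] = (-span, span) if active else (0.0, 0.0)
    truth.planted_fva = planted
    truth.crossfeeding_fva = crossfeeding
    path = out_dir / f"flux_fva_s{spec.seed}.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tmin_flux\tmax_flux\n")
        for rid in sorted(ranges):
            lo, hi = ranges[rid]
            fh.write(f"{rid}\t{lo:.9g}\t{hi:.9g}\n")
    return path
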
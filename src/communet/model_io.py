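"""Read community metabolic models (SBML L3 + FBC) and flux TSV files.

A *community* model packs several organisms ("members") into one
stoichiometric model. Each member keeps its own compartments, and all
members exchange metabolites through one shared external compartment
(conventionally ``medium``). Membership is encoded purely in identifiers:
every metabolite and compartment belonging to a member carries the member
ID as prefix, ``memberId_metaboliteId`` / ``memberId_compartmentId``.

This module parses such models into plain domain records, infers the member
set and shared compartment from the identifiers alone, and extracts the
*transport reactions* — reactions moving exactly one metabolite between a
member and the shared compartment — that become the edges of the reduced
interaction network.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import libsbml
import pandas as pd

from .errors import ConventionError, FormatError, SBMLParseError

logger = logging.getLogger(__name__)

#: Sentinel member ID for community-boundary exchange reactions and for
#: species living in the shared compartment. Chosen so it can never collide
#: with a member prefix (member IDs come from compartment IDs, which cannot
#: contain "<" in SBML SIds).
SHARED = "<shared>"

#: Default flux bounds applied when a reaction resolves no FBC bound.
DEFAULT_BOUNDS = (-1000.0, 1000.0)

#: SBML parameter whose *name* attribute overrides the shared compartment ID.
SHARED_COMPARTMENT_PARAMETER = "shared_compartment_id"

DEFAULT_SHARED_COMPARTMENT = "medium"


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRecord:
    """One species: ``member`` is :data:`SHARED` iff it sits in the medium."""

    species_id: str
    compartment: str
    member: str
    name: str = ""


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = DEFAULT_BOUNDS[0]
    upper_bound: float = DEFAULT_BOUNDS[1]

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.reaction_id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.reaction_id!r}: lower bound {self.lower_bound} "
                f"> upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class TransportReaction:
    """A reaction moving one metabolite across the shared-compartment wall.

    ``external_coefficient`` is the stoichiometric coefficient of the shared
    (medium) species: for positive flux, a positive coefficient means the
    reaction releases the metabolite into the medium. ``member`` is
    :data:`SHARED` for community boundary exchanges (medium <-> environment).
    """

    reaction_id: str
    member: str
    external_species: str
    external_coefficient: float
    lower_bound: float = DEFAULT_BOUNDS[0]
    upper_bound: float = DEFAULT_BOUNDS[1]

    @property
    def is_boundary(self) -> bool:
        return self.member == SHARED


@dataclass(frozen=True)
class CommunityModel:
    model_id: str
    members: tuple[str, ...]
    shared_compartment: str
    compartments: frozenset[str]
    species: tuple[SpeciesRecord, ...]
    reactions: tuple[ReactionRecord, ...]
    #: compartment ID -> owning member ID (shared compartment excluded)
    compartment_member: Mapping[str, str] = field(default_factory=dict)

    def species_by_id(self) -> dict[str, SpeciesRecord]:
        return {s.species_id: s for s in self.species}


@dataclass(frozen=True)
class FluxVector:
    """One FBA solution: reaction ID -> flux."""

    values: Mapping[str, float]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.values

    def __getitem__(self, reaction_id: str) -> float:
        return self.values[reaction_id]


@dataclass(frozen=True)
class FluxRanges:
    """FVA output: reaction ID -> (min_flux, max_flux)."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"reaction {rid!r}: min_flux {lo} > max_flux {hi}")

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.ranges

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]


# ---------------------------------------------------------------------------
# SBML reading
# ---------------------------------------------------------------------------

def _read_document(path: str | Path) -> libsbml.SBMLDocument:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        first = errors[0]
        raise SBMLParseError(
            f"{path}: malformed SBML at line {first.getLine()}: {first.getMessage().strip()}"
        )
    if doc.getModel() is None:
        raise SBMLParseError(f"{path}: SBML document contains no model")
    return doc


def detect_shared_compartment(document: libsbml.SBMLDocument) -> str:
    """Return the shared external compartment ID of a parsed SBML document.

    The override parameter ``shared_compartment_id`` wins when present (the
    compartment ID is carried in the parameter's *name* attribute, SBML
    parameter values being numeric); otherwise a compartment literally named
    ``medium`` is expected.
    """
    model = document.getModel()
    compartment_ids = {model.getCompartment(i).getId() for i in range(model.getNumCompartments())}
    param = model.getParameter(SHARED_COMPARTMENT_PARAMETER)
    if param is not None:
        shared = param.getName() or DEFAULT_SHARED_COMPARTMENT
        if shared not in compartment_ids:
            raise ConventionError(
                f"parameter {SHARED_COMPARTMENT_PARAMETER!r} names compartment "
                f"{shared!r}, which does not exist in the model"
            )
        return shared
    if DEFAULT_SHARED_COMPARTMENT in compartment_ids:
        return DEFAULT_SHARED_COMPARTMENT
    raise ConventionError(
        "no shared external compartment found: the model has neither a "
        f"{SHARED_COMPARTMENT_PARAMETER!r} parameter nor a compartment called "
        f"{DEFAULT_SHARED_COMPARTMENT!r}"
    )


def _prefix_candidates(compartment_id: str) -> list[str]:
    """All member-ID candidates for a compartment: every underscore boundary."""
    return [
        compartment_id[:i]
        for i, ch in enumerate(compartment_id)
        if ch == "_" and 0 < i < len(compartment_id)
    ]


def _assignment_valid(
    assignment: Mapping[str, str],
    species_by_compartment: Mapping[str, Sequence[str]],
    strict: bool,
) -> bool:
    """Check one compartment -> member assignment against the species IDs.

    Relaxed tier: every species in a member compartment starts with the
    member prefix + "_". Strict tier additionally requires the full
    ``member_base_suffix`` shape: the species ID must also end with
    "_" + the compartment suffix, with a non-empty base in between — the
    structure the member/metabolite prefixing convention produces.
    """
    for comp, member in assignment.items():
        suffix = comp[len(member) + 1:]
        if not suffix:
            return False
        for sid in species_by_compartment.get(comp, ()):
            head = member + "_"
            if not sid.startswith(head):
                return False
            if strict:
                tail = "_" + suffix
                # member + "_" + base + "_" + suffix with non-empty base
                if not sid.endswith(tail) or len(sid) <= len(head) + len(tail):
                    return False
    return True


def infer_members(
    compartment_ids: Iterable[str],
    species_ids: Iterable[tuple[str, str]] | Mapping[str, Sequence[str]],
    shared: str,
) -> tuple[str, ...]:
    """Infer the member ID set from compartment and species identifiers.

    ``species_ids`` maps compartment -> species IDs in it (or an iterable of
    ``(species_id, compartment)`` pairs). Every non-shared compartment must
    parse as ``member + "_" + suffix``; the minimal-cardinality prefix set
    consistent with the species IDs is chosen, preferring longer prefixes on
    ties, with a final lexicographic tie-break for determinism. Returns
    members in lexicographic order.
    """
    non_shared = sorted(c for c in set(compartment_ids) if c != shared)
    if not non_shared:
        raise ConventionError(
            f"no member compartments: the model has only the shared compartment {shared!r}"
        )
    if isinstance(species_ids, Mapping):
        species_by_compartment = {c: list(v) for c, v in species_ids.items()}
    else:
        species_by_compartment = {}
        for sid, comp in species_ids:
            species_by_compartment.setdefault(comp, []).append(sid)
    species_by_compartment.pop(shared, None)

    candidates = {c: _prefix_candidates(c) for c in non_shared}
    bad = sorted(c for c, cand in candidates.items() if not cand)
    if bad:
        raise ConventionError(
            "compartment(s) not attributable to any member (no underscore "
            f"boundary): {', '.join(bad)}; pass an explicit member_override"
        )

    n_assignments = math.prod(len(v) for v in candidates.values())
    for strict in (True, False):
        best: tuple[int, int, tuple[str, ...]] | None = None
        if n_assignments <= 200_000:
            pools = [candidates[c] for c in non_shared]
            for combo in itertools.product(*pools):
                assignment = dict(zip(non_shared, combo))
                if not _assignment_valid(assignment, species_by_compartment, strict):
                    continue
                members = tuple(sorted(set(combo)))
                key = (len(members), -sum(map(len, members)), members)
                if best is None or key < best:
                    best = key
        else:
            # too many combinations: greedy longest prefix per compartment
            combo = tuple(max(candidates[c], key=len) for c in non_shared)
            assignment = dict(zip(non_shared, combo))
            if _assignment_valid(assignment, species_by_compartment, strict):
                members = tuple(sorted(set(combo)))
                best = (len(members), -sum(map(len, members)), members)
        if best is not None:
            return best[2]
    raise ConventionError(
        "no consistent member-prefix assignment found for compartments "
        f"{', '.join(non_shared)}; pass an explicit member_override"
    )


def _resolve_bounds(model: libsbml.Model, reaction: libsbml.Reaction) -> tuple[float, float]:
    """FBC bound parameters when present, else (-1000, 1000) with a warning."""
    fbc = reaction.getPlugin("fbc")
    if fbc is not None:
        lo_id, hi_id = fbc.getLowerFluxBound(), fbc.getUpperFluxBound()
        if lo_id and hi_id:
            lo_p, hi_p = model.getParameter(lo_id), model.getParameter(hi_id)
            if lo_p is not None and hi_p is not None:
                return lo_p.getValue(), hi_p.getValue()
    logger.warning(
        "reaction %r: no resolvable FBC flux bounds, defaulting to (%g, %g)",
        reaction.getId(), *DEFAULT_BOUNDS,
    )
    return DEFAULT_BOUNDS


def _net_stoichiometry(reaction: libsbml.Reaction) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for i in range(reaction.getNumReactants()):
        ref = reaction.getReactant(i)
        stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
    for i in range(reaction.getNumProducts()):
        ref = reaction.getProduct(i)
        stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
    return stoich


def read_community_sbml(
    path: str | Path,
    member_override: Sequence[str] | None = None,
) -> CommunityModel:
    """Parse a community SBML file into a validated :class:`CommunityModel`.

    ``member_override`` bypasses member inference entirely; every non-shared
    compartment must then start with one of the given member IDs + "_".
    """
    doc = _read_document(path)
    model = doc.getModel()
    shared = detect_shared_compartment(doc)
    compartment_ids = [model.getCompartment(i).getId() for i in range(model.getNumCompartments())]

    species_pairs = [
        (model.getSpecies(i).getId(), model.getSpecies(i).getCompartment())
        for i in range(model.getNumSpecies())
    ]
    if member_override is not None:
        members = tuple(sorted(set(member_override)))
        if len(members) != len(list(member_override)):
            raise ConventionError("member_override contains duplicate member IDs")
        if any(not m for m in members):
            raise ConventionError("member_override contains an empty member ID")
    else:
        members = infer_members(compartment_ids, species_pairs, shared)

    compartment_member: dict[str, str] = {}
    unattributable: list[str] = []
    for comp in compartment_ids:
        if comp == shared:
            continue
        # longest matching member prefix wins (members may nest, e.g. m vs m_x)
        owners = [m for m in members if comp.startswith(m + "_")]
        if not owners:
            unattributable.append(comp)
            continue
        compartment_member[comp] = max(owners, key=len)
    if unattributable:
        raise ConventionError(
            f"compartment(s) not attributable to any member of {list(members)}: "
            f"{', '.join(sorted(unattributable))}"
        )

    species = tuple(
        SpeciesRecord(
            species_id=sid,
            compartment=comp,
            member=SHARED if comp == shared else compartment_member[comp],
            name=model.getSpecies(i).getName() or "",
        )
        for i, (sid, comp) in enumerate(species_pairs)
    )
    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        lo, hi = _resolve_bounds(model, rxn)
        reactions.append(
            ReactionRecord(
                reaction_id=rxn.getId(),
                stoichiometry=_net_stoichiometry(rxn),
                lower_bound=lo,
                upper_bound=hi,
            )
        )
    return CommunityModel(
        model_id=model.getId() or Path(path).stem,
        members=members,
        shared_compartment=shared,
        compartments=frozenset(compartment_ids),
        species=species,
        reactions=tuple(reactions),
        compartment_member=compartment_member,
    )


# ---------------------------------------------------------------------------
# transport extraction
# ---------------------------------------------------------------------------

def collect_transport_reactions(model: CommunityModel) -> list[TransportReaction]:
    """Gather reactions touching the shared compartment as transport records.

    One record per reaction with exactly one shared-compartment species.
    Reactions moving more than one medium metabolite violate the
    single-metabolite transport assumption and are excluded with a warning;
    a reaction whose member-side species belong to two different members is
    a convention violation and raises.
    """
    by_id = model.species_by_id()
    transports: list[TransportReaction] = []
    for rxn in model.reactions:
        shared_species = [
            (sid, coeff)
            for sid, coeff in rxn.stoichiometry.items()
            if by_id[sid].member == SHARED
        ]
        if not shared_species:
            continue
        if len(shared_species) > 1:
            logger.warning(
                "reaction %r moves %d shared-compartment metabolites "
                "(single-metabolite transport assumed): excluded",
                rxn.reaction_id, len(shared_species),
            )
            continue
        (ext_sid, ext_coeff), = shared_species
        if ext_coeff == 0:
            logger.warning(
                "reaction %r: shared species %r has net zero stoichiometry: excluded",
                rxn.reaction_id, ext_sid,
            )
            continue
        owner_members = {
            by_id[sid].member
            for sid in rxn.stoichiometry
            if by_id[sid].member != SHARED
        }
        if len(owner_members) > 1:
            raise ConventionError(
                f"reaction {rxn.reaction_id!r} spans members "
                f"{sorted(owner_members)}: cannot attribute the transport"
            )
        member = owner_members.pop() if owner_members else SHARED
        transports.append(
            TransportReaction(
                reaction_id=rxn.reaction_id,
                member=member,
                external_species=ext_sid,
                external_coefficient=ext_coeff,
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
            )
        )
    return transports


# ---------------------------------------------------------------------------
# flux TSV files
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (header row mandatory)") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    extra = [c for c in frame.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, extra)
    dupes = frame["reaction_id"][frame["reaction_id"].duplicated()]
    if not dupes.empty:
        raise FormatError(
            f"{path}: duplicate reaction_id(s): {sorted(dupes.unique())}"
        )
    return frame[list(required)]


def _parse_numeric(frame: pd.DataFrame, column: str, path: Path) -> pd.Series:
    parsed = pd.to_numeric(frame[column], errors="coerce")
    bad = parsed.isna() & frame[column].notna() | frame[column].isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(
            f"{path}: non-numeric {column} value {frame[column][bad.idxmax()]!r} "
            f"in row {row}"
        )
    return parsed.astype(float)


def read_flux_tsv(path: str | Path) -> FluxVector:
    """Read an FBA flux vector TSV with columns ``reaction_id`` and ``flux``."""
    path = Path(path)
    frame = _read_tsv(path, ("reaction_id", "flux"))
    flux = _parse_numeric(frame, "flux", path)
    return FluxVector(values=dict(zip(frame["reaction_id"], flux)))


def read_fva_tsv(path: str | Path) -> FluxRanges:
    """Read an FVA TSV with columns ``reaction_id``, ``min_flux``, ``max_flux``."""
    path = Path(path)
    frame = _read_tsv(path, ("reaction_id", "min_flux", "max_flux"))
    lo = _parse_numeric(frame, "min_flux", path)
    hi = _parse_numeric(frame, "max_flux", path)
    for rid, a, b in zip(frame["reaction_id"], lo, hi):
        if a > b:
            raise FormatError(f"{path}: reaction {rid!r}: min_flux {a} > max_flux {b}")
    return FluxRanges(ranges=dict(zip(frame["reaction_id"], zip(lo, hi))))
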
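"""Shared fixtures: synthetic community bundles and a seeded fixture matrix."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pytest

from communet import (
    CommunityModel,
    ReducedNetwork,
    TransportReaction,
    build_reduced_network,
    collect_transport_reactions,
    read_community_sbml,
)
from communet.fixtures import (
    FixtureGroundTruth,
    FixtureSpec,
    generate_flux_state,
    generate_toy_community,
)


@dataclass
class Bundle:
    """One generated toy community with everything derived from it."""

    spec: FixtureSpec
    sbml_path: Path
    truth: FixtureGroundTruth
    fba_path: Path
    fva_path: Path
    model: CommunityModel
    transports: list[TransportReaction]
    network: ReducedNetwork


def make_bundle(out_dir: Path, **spec_kwargs) -> Bundle:
    spec = FixtureSpec(**spec_kwargs)
    sbml_path, truth = generate_toy_community(spec, out_dir)
    fba_path = generate_flux_state(spec, truth, "fba", out_dir)
    fva_path = generate_flux_state(spec, truth, "fva", out_dir)
    model = read_community_sbml(sbml_path)
    transports = collect_transport_reactions(model)
    network = build_reduced_network(model, transports)
    return Bundle(spec, sbml_path, truth, fba_path, fva_path, model, transports, network)


@pytest.fixture
def bundle(tmp_path) -> Bundle:
    """Default four-member community (3 private, 2 per pair, 1 core)."""
    return make_bundle(tmp_path, seed=1)


#: (n_members, n_private, n_pair, n_core) shapes covering degenerate and
#: structured communities; crossed with seeds to form the fixture matrix.
MATRIX_SHAPES = [
    (1, 0, 0, 0),
    (1, 2, 0, 0),
    (2, 1, 1, 0),
    (2, 0, 3, 0),
    (3, 2, 1, 1),
    (3, 0, 0, 2),
    (4, 3, 2, 1),
    (4, 0, 1, 0),
    (5, 1, 1, 1),
    (6, 2, 0, 2),
]

MATRIX_SEEDS = list(range(10))


def matrix_specs() -> list[FixtureSpec]:
    """100 seeded fixture specs (10 shapes x 10 seeds)."""
    return [
        FixtureSpec(n_members=m, n_private=p, n_pair=q, n_core=c, seed=s)
        for (m, p, q, c) in MATRIX_SHAPES
        for s in MATRIX_SEEDS
    ]


@pytest.fixture(scope="session")
def fixture_matrix(tmp_path_factory) -> list[Bundle]:
    """The full 100-fixture matrix, generated once per session."""
    root = tmp_path_factory.mktemp("matrix")
    bundles = []
    for i, spec in enumerate(matrix_specs()):
        d = root / f"f{i:03d}"
        sbml_path, truth = generate_toy_community(spec, d)
        fba_path = generate_flux_state(spec, truth, "fba", d)
        fva_path = generate_flux_state(spec, truth, "fva", d)
        model = read_community_sbml(sbml_path)
        transports = collect_transport_reactions(model)
        network = build_reduced_network(model, transports)
        bundles.append(
            Bundle(spec, sbml_path, truth, fba_path, fva_path, model, transports, network)
        )
    return bundles
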
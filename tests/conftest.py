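"""Shared fixtures: tiny deterministic networks and random-network helpers."""

from __future__ import annotations

import numpy as np
import pytest

from rwdir.hetnet import HeteroNetwork, Label, LabelAssignment, RNAType
from rwdir.synthetic import FixtureSpec, generate_hetnet


@pytest.fixture
def three_vertex_net() -> HeteroNetwork:
    """g1, g2 mRNA; mi1 miRNA; edges g1-g2 and g1-mi1."""
    return HeteroNetwork.from_members(
        {"g1": RNAType.MRNA, "g2": RNAType.MRNA, "mi1": RNAType.MIRNA},
        [("g1", "g2"), ("g1", "mi1")],
    )


@pytest.fixture
def tiny_fixture():
    """Seeded 12-vertex planted-homophily network with labels."""
    from rwdir.synthetic import tiny_spec

    return generate_hetnet(tiny_spec(rng_seed=0))


def random_fixture_spec(seed: int, h_scale: str = "small") -> FixtureSpec:
    """A randomized but valid spec drawn from ``seed``.

    Densities keep within-class edges dominant so the transfer-parameter
    budgets hold; sizes vary with the seed.
    """
    rng = np.random.default_rng(seed)
    if h_scale == "small":
        sizes = (int(rng.integers(5, 10)), int(rng.integers(3, 6)), int(rng.integers(3, 6)))
    else:
        sizes = (int(rng.integers(15, 25)), int(rng.integers(5, 10)), int(rng.integers(5, 10)))
    within = tuple(float(rng.uniform(0.5, 0.8)) for _ in range(3))
    cross = tuple(float(rng.uniform(0.02, 0.12)) for _ in range(3))
    h = sum(sizes)
    n_related = int(rng.integers(2, max(3, h // 4)))
    n_irrelevant = int(rng.integers(2, max(3, h // 4)))
    return FixtureSpec(
        sizes=sizes,
        within_density=within,
        cross_density=cross,
        n_related=n_related,
        n_irrelevant=n_irrelevant,
        n_unlabeled_community=int(rng.integers(0, 3)),
        homophily=float(rng.uniform(1.0, 3.0)),
        rng_seed=seed,
    )


def random_network(seed: int, h_scale: str = "small"):
    """A random fixture constrained to the transfer-parameter validity domain.

    Small random blocks occasionally yield cross/within edge-count ratios
    outside [0, 1] or over the per-class budget, where the block transition
    matrix is undefined by construction; such draws are resampled from a
    shifted seed so every returned network supports the full walk.
    """
    from rwdir.hetnet import build_adjacency
    from rwdir.transition import ParameterError, transfer_parameters

    attempt = seed
    while True:
        net, labels = generate_hetnet(random_fixture_spec(attempt, h_scale))
        try:
            transfer_parameters(build_adjacency(net))
        except ParameterError:
            attempt += 100_000
            continue
        return net, labels


def labels_list(net: HeteroNetwork, assignment: LabelAssignment) -> list[Label]:
    return assignment.resolve(net)
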
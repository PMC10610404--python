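"""Shared fixtures and independent oracles for the test-suite.

The oracles here are deliberately naive: exact integer combinatorics and
literal draw enumeration for the hypergeometric tail, the textbook
step-up formula for Benjamini–Hochberg, and a brute-force double loop for
the directed network intersection. They share no code with the
implementation paths they check.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pytest
from hypothesis import settings

from cernet.model import (
    CoexpressionNetwork,
    ModulePartition,
    RegulatoryNetwork,
    undirected_key,
)

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles


def hypergeom_tail_exact(k: int, a: int, b: int, n: int) -> float:
    """P(X >= k) by exact integer combinatorics (no scipy)."""
    num = sum(comb(a, x) * comb(n - a, b - x) for x in range(k, min(a, b) + 1))
    return num / comb(n, b)


def hypergeom_tail_enumerate(k: int, a: int, b: int, n: int) -> float:
    """P(X >= k) by literally enumerating all C(n, b) draws."""
    universe = range(n)
    in_a = set(range(a))
    hits = sum(
        1 for draw in itertools.combinations(universe, b)
        if len(in_a.intersection(draw)) >= k
    )
    return hits / comb(n, b)


def bh_stepup(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg by the direct formula q_(i) = min_{j>=i} m*p_(j)/j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = running
    return adjusted


def brute_force_merge(
    grn_edges: Dict[Tuple[str, str], float],
    coexp_edges: Dict[Tuple[str, str], float],
) -> Set[Tuple[str, str]]:
    """All GRN edges whose unordered pair is co-expressed (double loop)."""
    kept = set()
    for (tf, tg) in grn_edges:
        for (a, b) in coexp_edges:
            if (tf, tg) == (a, b) or (tf, tg) == (b, a):
                kept.add((tf, tg))
    return kept


# --------------------------------------------------------------- builders


def make_coexp(
    pairs: Dict[Tuple[str, str], float],
    partition: Dict[str, str] | None = None,
    condition: str = "test",
) -> CoexpressionNetwork:
    if partition is None:
        partition = {}
        for a, b in pairs:
            partition.setdefault(a, "blue")
            partition.setdefault(b, "blue")
    return CoexpressionNetwork(
        dict(pairs), ModulePartition(partition, condition), condition
    )


def random_network_pair(
    rng: np.random.Generator, max_nodes: int = 200
) -> Tuple[RegulatoryNetwork, CoexpressionNetwork]:
    """A random GRN + co-expression network over a shared gene universe."""
    n = int(rng.integers(4, max_nodes + 1))
    genes = [f"AT1G{i:05d}" for i in range(1, n + 1)]
    n_coexp = int(rng.integers(0, 3 * n))
    coexp: Dict[Tuple[str, str], float] = {}
    for _ in range(n_coexp):
        a, b = rng.choice(genes, size=2, replace=False)
        coexp[undirected_key(str(a), str(b))] = float(rng.uniform(0, 1))
    n_grn = int(rng.integers(0, 3 * n))
    grn: Dict[Tuple[str, str], float] = {}
    for _ in range(n_grn):
        tf, tg = rng.choice(genes, size=2, replace=False)
        grn[(str(tf), str(tg))] = float(rng.uniform(0, 10))
    partition = {g: "blue" for g in genes}
    net = CoexpressionNetwork(coexp, ModulePartition(partition, "x"), "x")
    return RegulatoryNetwork(grn, "x"), net


@pytest.fixture(scope="session")
def small_study():
    """Default-condition synthetic study, generated once per session."""
    from cernet.synthetic import SimulationConfig, generate_study

    return generate_study(SimulationConfig(seed=7))
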
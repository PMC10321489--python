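from __future__ import annotations

import numpy as np
import pytest

from paramotif.netio import (
    InteractionNetwork,
    ParalogPairTable,
    RegulatoryNetwork,
)


def random_case(seed: int, n_nodes: int = 30, edge_p: float = 0.08, n_pairs: int = 25):
    """A small random GRN + PPI + paralog table for oracle comparisons.

    Nodes double as regulators and targets (no bipartite constraint), so the
    finders are exercised on arbitrary directed structure including
    within-pair edges and overlapping roles.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    dir_edges = set()
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_p:
                dir_edges.add((nodes[i], nodes[j]))
    und_edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_p:
                und_edges.add((nodes[i], nodes[j]))
    pairs = []
    seen = set()
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        key = frozenset((nodes[i], nodes[j]))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(tuple(sorted((nodes[i], nodes[j]))))
    grn = RegulatoryNetwork.from_edges((r, t, 1.0) for r, t in dir_edges)
    ppi = InteractionNetwork.from_edges((a, b, 1.0) for a, b in und_edges)
    table = ParalogPairTable.from_records(
        [(a, b, "WGD" if k % 2 == 0 else "SSD") for k, (a, b) in enumerate(pairs)]
    )
    return grn, ppi, table, dir_edges, und_edges, pairs


@pytest.fixture
def tiny_grn() -> RegulatoryNetwork:
    return RegulatoryNetwork.from_edges(
        [("T1", "g1", 0.9), ("T2", "g1", 0.8), ("T1", "g2", 0.7), ("T2", "g2", 0.6)]
    )


@pytest.fixture
def tiny_ppi() -> InteractionNetwork:
    return InteractionNetwork.from_edges(
        [("p1", "x", 0.9), ("p2", "x", 0.8), ("T1", "T2", 0.7)]
    )


@pytest.fixture
def tiny_pairs() -> ParalogPairTable:
    return ParalogPairTable.from_records(
        [("T1", "T2", "WGD", 0.2, 0.05), ("g1", "g2", "SSD", 1.1, 0.3),
         ("p1", "p2", "WGD", 0.3, 0.1)]
    )
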
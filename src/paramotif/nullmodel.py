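"""Degree-preserving null models and Z-scores for motif frequencies.

Observed motif frequencies are compared against an ensemble of null
networks obtained by *node-label permutation*: the graph structure is held
fixed and node identities are shuffled, so every in-, out- and undirected
degree sequence is preserved exactly. Labels permute within role strata —
regulators among regulators, pure targets among targets, PPI-only proteins
among themselves — which preserves the bipartite role structure of inferred
regulatory networks. By default one shared relabeling per permutation is
applied jointly to the regulatory and interaction networks, so motifs that
span both (delta) keep their cross-network degree coupling in the null.

The standard protocol is 1000 permutations; a motif stratum is called
significant when Z = (observed - null mean) / null sd >= 2, and a Z-score
below 2 is reported as not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import MOTIF_TYPES, count_strata
from .netio import InteractionNetwork, ParalogPairTable, RegulatoryNetwork

__all__ = [
    "NullEnsemble",
    "permutation_mapping",
    "permute_labels",
    "generate_nulls",
    "calculate_z",
]

#: Z-score threshold for significance.
Z_THRESHOLD = 2.0


@dataclass
class NullEnsemble:
    """Per-stratum vectors of motif counts over permuted networks.

    ``counts`` maps (motif_type, mode, age_group) to an integer vector of
    length ``n_permutations``. Strata are the cross product of requested
    motif types with the (mode, age_group) combinations present in the pair
    table; a stratum whose count was zero in every permutation still has its
    (all-zero) vector.
    """

    n_permutations: int
    seed: int
    counts: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (motif_type, mode, age_group, permutation, count)."""
        rows = []
        for (motif, mode, age), vec in sorted(self.counts.items()):
            for i, c in enumerate(vec):
                rows.append((motif, mode, age, i, int(c)))
        return pd.DataFrame(
            rows, columns=["motif_type", "mode", "age_group", "permutation", "count"]
        )


def _strata_nodes(
    grn: RegulatoryNetwork, ppi: InteractionNetwork
) -> tuple[list[str], list[str], list[str]]:
    """Partition nodes into permutation strata.

    Regulator-role nodes (out-degree >= 1 in the GRN) permute among
    themselves, pure-target nodes among themselves, and PPI-only nodes among
    themselves, so node roles — and hence every degree sequence — are
    preserved.
    """
    regs = sorted(grn.regulators)
    tgts = sorted(grn.targets - grn.regulators)
    grn_nodes = grn.nodes
    ppi_only = sorted(ppi.nodes - grn_nodes)
    return regs, tgts, ppi_only


def permutation_mapping(
    grn: RegulatoryNetwork,
    ppi: InteractionNetwork,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Draw one within-strata node-label permutation over both networks."""
    mapping: dict[str, str] = {}
    for stratum in _strata_nodes(grn, ppi):
        if len(stratum) > 1:
            perm = rng.permutation(len(stratum))
            mapping.update({stratum[i]: stratum[j] for i, j in enumerate(perm)})
        elif stratum:
            mapping[stratum[0]] = stratum[0]
    return mapping


def permute_labels(
    grn: RegulatoryNetwork,
    ppi: InteractionNetwork,
    seed: int,
    shared_relabeling: bool = True,
) -> tuple[RegulatoryNetwork, InteractionNetwork]:
    """Return degree-preserving relabeled copies of both networks.

    With ``shared_relabeling`` (default) a single gene→gene permutation is
    applied to both networks; otherwise the interaction network draws an
    independent permutation (restricted to its own nodes, same strata rule).
    """
    rng = np.random.default_rng(seed)
    mapping = permutation_mapping(grn, ppi, rng)
    grn_perm = grn.relabel(mapping)
    if shared_relabeling:
        ppi_perm = ppi.relabel(mapping)
    else:
        # restrict an independent draw to a bijection of the PPI node set
        sub = _restrict_bijection(permutation_mapping(grn, ppi, rng), ppi.nodes)
        ppi_perm = ppi.relabel(sub)
    return grn_perm, ppi_perm


def _restrict_bijection(mapping: dict[str, str], nodes: frozenset[str]) -> dict[str, str]:
    """Close a within-strata permutation onto `nodes` by cycle-following.

    Following each cycle of the full permutation and keeping only the visits
    to `nodes` yields a permutation of `nodes` that still respects strata.
    """
    out: dict[str, str] = {}
    seen: set[str] = set()
    for start in mapping:
        if start in seen or start not in nodes:
            continue
        cycle_member = start
        prev_in_nodes = start
        seen.add(start)
        cur = mapping[start]
        while cur != start:
            if cur in nodes:
                out[prev_in_nodes] = cur
                prev_in_nodes = cur
                seen.add(cur)
            cur = mapping[cur]
        out[prev_in_nodes] = start
    return out


def _mapped_pair_list(
    pairs: ParalogPairTable, inverse: dict[str, str]
) -> list[tuple[str, str, str, str]]:
    """Compose the inverse permutation with pair endpoints.

    Counting motifs for pair (a, b) on the relabeled network equals counting
    for (sigma^-1(a), sigma^-1(b)) on the original network; pairs with a gene
    outside both networks contribute zero motifs either way and are dropped.
    """
    out = []
    for (g1, g2), (mode, age) in pairs.pair_info.items():
        if g1 in inverse and g2 in inverse:
            out.append((inverse[g1], inverse[g2], mode, age))
    return out


def _pair_strata(pairs: ParalogPairTable) -> list[tuple[str, str]]:
    return sorted({(r.mode, r.age_group) for r in pairs.df.itertuples(index=False)})


def generate_nulls(
    grn: RegulatoryNetwork,
    ppi: InteractionNetwork,
    pairs: ParalogPairTable,
    n_permutations: int = 1000,
    seed: int = 0,
    motif_types: tuple[str, ...] = MOTIF_TYPES,
    require_target_paralogy: bool = True,
    delta_topology: str = "v_plus_regulator_ppi",
) -> NullEnsemble:
    """Motif-count ensemble over degree-preserving label permutations.

    The paralog-pair table is held fixed while node identities move, which
    is implemented by composing each permutation with the pair endpoints
    (identical in distribution to relabeling the networks, and cheap). One
    integer seed expands deterministically into per-permutation child seeds.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    strata = [
        (motif, mode, age)
        for motif in motif_types
        for mode, age in _pair_strata(pairs)
    ]
    vectors = {key: np.zeros(n_permutations, dtype=np.int64) for key in strata}
    children = np.random.SeedSequence(seed).spawn(n_permutations)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        mapping = permutation_mapping(grn, ppi, rng)
        inverse = {v: k for k, v in mapping.items()}
        pair_list = _mapped_pair_list(pairs, inverse)
        counts = count_strata(
            grn, ppi, pair_list,
            motif_types=motif_types,
            require_target_paralogy=require_target_paralogy,
            delta_topology=delta_topology,
        )
        for key, n in counts.items():
            if key in vectors:
                vectors[key][i] = n
    return NullEnsemble(n_permutations=n_permutations, seed=seed, counts=vectors)


def calculate_z(observed: pd.DataFrame, nulls: NullEnsemble) -> pd.DataFrame:
    """Z-scores of observed motif frequencies against the null ensemble.

    `observed` is a (motif_type, mode, age_group, observed_count) table as
    produced by :func:`paramotif.motifs.count_motifs`; strata present in the
    ensemble but absent from `observed` score an observed count of zero.
    An observed stratum missing from the ensemble is an error. A stratum
    with null sd = 0 gets Z = NaN and a degenerate-null flag (never
    +/- infinity). ``significant`` follows the Z >= 2 rule.
    """
    obs = {
        (r.motif_type, r.mode, r.age_group): int(r.observed_count)
        for r in observed.itertuples(index=False)
    }
    missing = sorted(set(obs) - set(nulls.counts))
    if missing:
        raise ValueError(f"observed strata missing from null ensemble: {missing}")
    rows = []
    for key in sorted(nulls.counts):
        vec = nulls.counts[key]
        o = obs.get(key, 0)
        mean = float(np.mean(vec))
        sd = float(np.std(vec, ddof=1)) if len(vec) > 1 else 0.0
        if sd > 0:
            z = (o - mean) / sd
            degenerate = False
        else:
            z = math.nan
            degenerate = True
        significant = (not degenerate) and z >= Z_THRESHOLD
        rows.append((*key, o, mean, sd, z, significant, degenerate))
    return pd.DataFrame(
        rows,
        columns=[
            "motif_type", "mode", "age_group", "observed",
            "null_mean", "null_sd", "z", "significant", "degenerate",
        ],
    )
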
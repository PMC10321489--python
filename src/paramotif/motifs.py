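"""Enumeration of the five paralog-containing network motif types.

Every motif here is licensed by a paralogous gene pair (a duplicate pair
from the :class:`~paramotif.netio.ParalogPairTable`):

- **V**: two paralogous regulators share a target gene.
- **PPI V**: two paralogous proteins share a physical interaction partner.
- **lambda**: two paralogous target genes are regulated by the same regulator.
- **delta**: a V motif whose two paralogous regulators additionally interact
  physically (default topology; see :func:`find_delta` for the alternative).
- **bifan**: two paralogous regulators regulate the same pair of target
  genes; by default the target pair must itself be paralogous.

All motif members are distinct genes, instances are identified by the
unordered licensing pair plus partner set (never double-counted for the two
orderings of a pair), and a pair whose genes are absent from the network
simply contributes no motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import pandas as pd

from .netio import (
    InteractionNetwork,
    ParalogPairTable,
    RegulatoryNetwork,
    ValidationError,
)

__all__ = [
    "MOTIF_TYPES",
    "MotifInstance",
    "find_v",
    "find_ppi_v",
    "find_lambda",
    "find_delta",
    "find_bifan",
    "count_motifs",
]

MOTIF_TYPES = ("V", "PPI_V", "LAMBDA", "DELTA", "BIFAN")

#: delta topology readings (the second is two paralogous targets of a shared
#: regulator whose protein products interact).
DELTA_TOPOLOGIES = ("v_plus_regulator_ppi", "lambda_plus_target_ppi")


@dataclass(frozen=True)
class MotifInstance:
    """One motif occurrence.

    ``pair`` is the licensing paralog pair in canonical order; ``partners``
    holds the remaining member genes (one shared target / regulator /
    interactor, or the two targets of a bifan, sorted). ``mode`` and
    ``age_group`` are those of the licensing pair. For bifans whose target
    pair is itself in the pair table, ``target_pair_mode`` records the target
    pair's duplication mode and ``mixed`` flags a mode disagreement between
    the two pairs.
    """

    motif_type: str
    pair: tuple[str, str]
    partners: tuple[str, ...]
    mode: str
    age_group: str
    target_pair_mode: Optional[str] = None
    mixed: bool = False


def _iter_pairs_in(pairs: ParalogPairTable, adj: dict[str, set]) -> Iterator[tuple]:
    """Yield (g1, g2, mode, age_group) for pairs whose both genes have entries in adj."""
    for (g1, g2), (mode, age) in pairs.pair_info.items():
        if g1 in adj and g2 in adj:
            yield g1, g2, mode, age


def find_v(grn: RegulatoryNetwork, pairs: ParalogPairTable) -> list[MotifInstance]:
    """V motifs: paralogous regulators (g1, g2) sharing a target outside the pair."""
    out = []
    adj = grn.out_adj
    for g1, g2, mode, age in _iter_pairs_in(pairs, adj):
        shared = (adj[g1] & adj[g2]) - {g1, g2}
        for tgt in sorted(shared):
            out.append(MotifInstance("V", (g1, g2), (tgt,), mode, age))
    return out


def find_ppi_v(ppi: InteractionNetwork, pairs: ParalogPairTable) -> list[MotifInstance]:
    """PPI V motifs: paralogous proteins sharing a third interaction partner.

    A direct interaction between the two pair members is not a PPI V; the
    shared partner must be a distinct third protein.
    """
    out = []
    nb = ppi.neighbors
    for g1, g2, mode, age in _iter_pairs_in(pairs, nb):
        shared = (nb[g1] & nb[g2]) - {g1, g2}
        for p in sorted(shared):
            out.append(MotifInstance("PPI_V", (g1, g2), (p,), mode, age))
    return out


def find_lambda(grn: RegulatoryNetwork, pairs: ParalogPairTable) -> list[MotifInstance]:
    """Lambda motifs: paralogous targets (g1, g2) regulated by a shared regulator."""
    out = []
    adj = grn.in_adj
    for g1, g2, mode, age in _iter_pairs_in(pairs, adj):
        shared = (adj[g1] & adj[g2]) - {g1, g2}
        for reg in sorted(shared):
            out.append(MotifInstance("LAMBDA", (g1, g2), (reg,), mode, age))
    return out


def find_delta(
    grn: RegulatoryNetwork,
    ppi: InteractionNetwork,
    pairs: ParalogPairTable,
    topology: str = "v_plus_regulator_ppi",
) -> list[MotifInstance]:
    """Delta motifs, under a switchable topology predicate.

    Default (``v_plus_regulator_ppi``): a V motif whose paralogous regulators
    additionally share a PPI edge. Alternative (``lambda_plus_target_ppi``):
    a lambda motif whose paralogous targets share a PPI edge. Only the
    licensing-pair predicate differs; enumeration is shared.
    """
    if topology not in DELTA_TOPOLOGIES:
        raise ValueError(f"topology must be one of {DELTA_TOPOLOGIES}")
    base = find_v if topology == "v_plus_regulator_ppi" else find_lambda
    out = []
    for inst in base(grn, pairs):
        if ppi.has_edge(*inst.pair):
            out.append(
                MotifInstance("DELTA", inst.pair, inst.partners, inst.mode, inst.age_group)
            )
    return out


def _bifan_regpair_shared(
    grn: RegulatoryNetwork, pairs: ParalogPairTable
) -> Iterator[tuple[str, str, str, str, set[str]]]:
    adj = grn.out_adj
    for g1, g2, mode, age in _iter_pairs_in(pairs, adj):
        shared = (adj[g1] & adj[g2]) - {g1, g2}
        if len(shared) >= 2:
            yield g1, g2, mode, age, shared


def iter_bifan(
    grn: RegulatoryNetwork,
    pairs: ParalogPairTable,
    require_target_paralogy: bool = True,
) -> Iterator[MotifInstance]:
    """Stream bifan instances without materializing all target pairs at once.

    For each paralogous regulator pair with shared-target set ``S``, every
    unordered target pair from ``S`` is a bifan; with
    ``require_target_paralogy`` (the default) only target pairs that are
    themselves in the paralog table count. One instance per
    (regulator pair, target pair) subgraph.
    """
    info = pairs.pair_info
    for g1, g2, mode, age, shared in _bifan_regpair_shared(grn, pairs):
        if require_target_paralogy:
            for (t1, t2), (tmode, _tage) in info.items():
                if (t1, t2) != (g1, g2) and t1 in shared and t2 in shared:
                    yield MotifInstance(
                        "BIFAN", (g1, g2), (t1, t2), mode, age,
                        target_pair_mode=tmode, mixed=(tmode != mode),
                    )
        else:
            ordered = sorted(shared)
            for i, t1 in enumerate(ordered):
                for t2 in ordered[i + 1:]:
                    tmode = info.get((t1, t2), (None,))[0]
                    yield MotifInstance(
                        "BIFAN", (g1, g2), (t1, t2), mode, age,
                        target_pair_mode=tmode,
                        mixed=(tmode is not None and tmode != mode),
                    )


def find_bifan(
    grn: RegulatoryNetwork,
    pairs: ParalogPairTable,
    require_target_paralogy: bool = True,
    count_only: bool = False,
):
    """Bifan motifs: paralogous regulators regulating the same pair of targets.

    Returns a list of :class:`MotifInstance`, or, with ``count_only``, a
    stratified count table computed without materializing instances
    (closed form ``C(|S|, 2)`` per regulator pair when target paralogy is
    not required).
    """
    if not count_only:
        return list(iter_bifan(grn, pairs, require_target_paralogy))
    counts: dict[tuple[str, str], int] = {}
    info = pairs.pair_info
    for g1, g2, mode, age, shared in _bifan_regpair_shared(grn, pairs):
        if require_target_paralogy:
            n = sum(
                1
                for (t1, t2) in info
                if (t1, t2) != (g1, g2) and t1 in shared and t2 in shared
            )
        else:
            n = len(shared) * (len(shared) - 1) // 2
        if n:
            counts[(mode, age)] = counts.get((mode, age), 0) + n
    rows = [
        ("BIFAN", mode, age, n) for (mode, age), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["motif_type", "mode", "age_group", "observed_count"])


def count_motifs(
    instances: list[MotifInstance], pairs: ParalogPairTable
) -> pd.DataFrame:
    """Stratify motif instances by (motif_type, mode, age_group).

    The stratum is that of the licensing pair as recorded in `pairs` (so an
    age assignment applied after enumeration takes effect); an instance whose
    pair is absent from the table is an error. Returns a table with an
    ``observed_count`` column; strata with zero instances are omitted.
    """
    info = pairs.pair_info
    counts: dict[tuple[str, str, str], int] = {}
    for inst in instances:
        if inst.pair not in info:
            raise ValidationError(
                f"motif instance references pair {inst.pair} absent from the paralog table"
            )
        mode, age = info[inst.pair]
        key = (inst.motif_type, mode, age)
        counts[key] = counts.get(key, 0) + 1
    rows = [(*key, n) for key, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["motif_type", "mode", "age_group", "observed_count"])


def count_strata(
    grn: RegulatoryNetwork,
    ppi: InteractionNetwork,
    pair_list: list[tuple[str, str, str, str]],
    motif_types: tuple[str, ...] = MOTIF_TYPES,
    require_target_paralogy: bool = True,
    delta_topology: str = "v_plus_regulator_ppi",
) -> dict[tuple[str, str, str], int]:
    """Count motifs per (motif_type, mode, age_group) without materializing instances.

    `pair_list` rows are ``(gene1, gene2, mode, age_group)``. This is the hot
    path of the permutation null model; it must agree exactly with the
    ``find_*`` enumerators (asserted in the test suite).
    """
    out_adj, in_adj, nb = grn.out_adj, grn.in_adj, ppi.neighbors
    pair_keys = {(g1, g2) if g1 <= g2 else (g2, g1) for g1, g2, _, _ in pair_list}
    counts: dict[tuple[str, str, str], int] = {}

    def bump(motif: str, mode: str, age: str, n: int) -> None:
        if n:
            key = (motif, mode, age)
            counts[key] = counts.get(key, 0) + n

    delta_on_v = delta_topology == "v_plus_regulator_ppi"
    for g1, g2, mode, age in pair_list:
        if "V" in motif_types or "DELTA" in motif_types or "BIFAN" in motif_types:
            if g1 in out_adj and g2 in out_adj:
                shared = (out_adj[g1] & out_adj[g2]) - {g1, g2}
                n_shared = len(shared)
                if "V" in motif_types:
                    bump("V", mode, age, n_shared)
                if "DELTA" in motif_types and delta_on_v and ppi.has_edge(g1, g2):
                    bump("DELTA", mode, age, n_shared)
                if "BIFAN" in motif_types and n_shared >= 2:
                    if require_target_paralogy:
                        n = sum(
                            1
                            for (t1, t2) in pair_keys
                            if t1 in shared and t2 in shared
                        )
                    else:
                        n = n_shared * (n_shared - 1) // 2
                    bump("BIFAN", mode, age, n)
        if "LAMBDA" in motif_types or ("DELTA" in motif_types and not delta_on_v):
            if g1 in in_adj and g2 in in_adj:
                n_shared = len((in_adj[g1] & in_adj[g2]) - {g1, g2})
                if "LAMBDA" in motif_types:
                    bump("LAMBDA", mode, age, n_shared)
                if "DELTA" in motif_types and not delta_on_v and ppi.has_edge(g1, g2):
                    bump("DELTA", mode, age, n_shared)
        if "PPI_V" in motif_types and g1 in nb and g2 in nb:
            bump("PPI_V", mode, age, len((nb[g1] & nb[g2]) - {g1, g2}))
    return counts


def instances_to_frame(instances: list[MotifInstance]) -> pd.DataFrame:
    """Flatten instances for TSV output."""
    rows = [
        (
            i.motif_type, i.pair[0], i.pair[1], ";".join(i.partners),
            i.mode, i.age_group,
            i.target_pair_mode if i.target_pair_mode is not None else "NA",
            "mixed" if i.mixed else "NA",
        )
        for i in instances
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "motif_type", "gene1", "gene2", "partners",
            "mode", "age_group", "target_pair_mode", "flag",
        ],
    )
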
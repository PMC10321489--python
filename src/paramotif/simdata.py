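"""Synthetic data with exported ground truth.

Every analysis in this package can be exercised without downloads:

- :func:`simulate_networks` grows a directed bipartite regulatory network
  whose regulator degrees are heavy-tailed under preferential attachment
  (uniform attachment gives the Poisson-like contrast case), plus a uniform
  random protein–protein interaction graph.
- :func:`plant_motifs` inserts node-disjoint motif instances with known
  per-stratum counts. Planted instances use fresh nodes, so finder counts
  on the planted part equal the recorded truth exactly; implied secondary
  motifs (a planted delta is also a V; a planted bifan contributes two V
  and, through its paralogous target pair, two lambda instances) are part
  of the recorded expectation.
- :func:`simulate_pairs` draws duplicate pairs whose Ks follows a Gaussian
  mixture (truncated at 0) and whose Ka lies on a Michaelis–Menten curve
  plus noise, optionally with the WGD group's saturation level scaled down
  (slower divergence of WGD-derived pairs).
- :func:`simulate_full_study` composes all of the above into one coherent
  data set that carries the qualitative effects the analyses are meant to
  detect: more motifs on recent-WGD pairs than ancient-WGD pairs, higher
  interaction similarity for WGD pairs, and a lower divergence asymptote
  for WGD pairs.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .netio import (
    UNASSIGNED,
    AnnotationTable,
    InteractionNetwork,
    ParalogPairTable,
    RegulatoryNetwork,
)
from .motifs import MOTIF_TYPES

__all__ = [
    "SimulationTruth",
    "simulate_networks",
    "plant_motifs",
    "simulate_pairs",
    "simulate_full_study",
]


@dataclass
class SimulationTruth:
    """Ground truth exported next to generated data; JSON-serializable."""

    seed: int
    planted_counts: dict = field(default_factory=dict)
    expected_counts: dict = field(default_factory=dict)
    mixture: Optional[list] = None
    mm: Optional[dict] = None
    similarity_effect: Optional[dict] = None
    components: Optional[dict] = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(d: dict) -> dict:
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
                    for k, v in d.items()}

        payload = {
            "seed": self.seed,
            "planted_counts": enc(self.planted_counts),
            "expected_counts": enc(self.expected_counts),
            "mixture": self.mixture,
            "mm": self.mm,
            "similarity_effect": self.similarity_effect,
            "components": enc(self.components) if self.components else None,
            "extras": self.extras,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def simulate_networks(
    n_regulators: int,
    n_targets: int,
    grn_attachment: str = "preferential",
    ppi_density: float = 0.02,
    seed: int = 0,
    edges_per_target: int = 3,
    ppi_nodes: Optional[Sequence[str]] = None,
    hub_weights: bool = False,
) -> tuple[RegulatoryNetwork, InteractionNetwork, SimulationTruth]:
    """Grow a directed bipartite GRN and a uniform random PPI graph.

    Each of ``n_targets`` target genes receives ``edges_per_target`` incoming
    edges; under ``preferential`` attachment a regulator is chosen with
    probability proportional to its current out-degree + 1 (rich-get-richer,
    heavy-tailed out-degrees), under ``uniform`` uniformly at random. Edge
    weights are Uniform(0, 1); with ``hub_weights`` they are additionally
    scaled by the regulator's relative connectivity, so high-weight edge
    quantiles are hub-dominated (as importance scores of GRN inference tend
    to be). The PPI graph is Erdős–Rényi with ``ppi_density`` over
    ``ppi_nodes`` (default: all GRN nodes), scores Uniform(0.5, 1).
    """
    if n_regulators < 10 or n_targets < 10:
        raise ValueError("need >= 10 regulators and >= 10 targets")
    if not 0.0 <= ppi_density <= 1.0:
        raise ValueError("ppi_density must be in [0, 1]")
    if grn_attachment not in ("preferential", "uniform"):
        raise ValueError("grn_attachment must be 'preferential' or 'uniform'")
    rng = np.random.default_rng(seed)
    regs = [f"R{i:04d}" for i in range(n_regulators)]
    tgts = [f"G{i:04d}" for i in range(n_targets)]
    out_deg = np.zeros(n_regulators)
    m = min(edges_per_target, n_regulators)
    edges = []
    for t in tgts:
        if grn_attachment == "preferential":
            p = (out_deg + 1.0) / (out_deg + 1.0).sum()
            chosen = rng.choice(n_regulators, size=m, replace=False, p=p)
        else:
            chosen = rng.choice(n_regulators, size=m, replace=False)
        for j in chosen:
            out_deg[j] += 1
            edges.append((regs[j], t, float(rng.uniform(0.0, 1.0))))
    if hub_weights:
        rel = out_deg / out_deg.max() if out_deg.max() > 0 else out_deg
        scale = {regs[j]: 0.2 + 0.8 * math.sqrt(rel[j]) for j in range(n_regulators)}
        edges = [(r, t, w * scale[r]) for r, t, w in edges]
    grn = RegulatoryNetwork.from_edges(edges)

    nodes = list(ppi_nodes) if ppi_nodes is not None else regs + tgts
    ppi_edges = []
    if ppi_density > 0 and len(nodes) > 1:
        n = len(nodes)
        # vectorized Bernoulli over the upper triangle
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < ppi_density
        scores = rng.uniform(0.5, 1.0, size=int(keep.sum()))
        for (i, j), s in zip(zip(iu[keep], ju[keep]), scores):
            ppi_edges.append((nodes[i], nodes[j], float(s)))
    ppi = InteractionNetwork.from_edges(ppi_edges, min_score=0.0)
    truth = SimulationTruth(seed=seed, extras={
        "grn_attachment": grn_attachment,
        "n_regulators": n_regulators,
        "n_targets": n_targets,
        "ppi_density": ppi_density,
    })
    return grn, ppi, truth


def _implied_counts(spec: dict) -> dict:
    """Per-finder expected counts for node-disjoint plantings.

    A delta plant is also one V; a bifan plant (with paralogous targets)
    contributes one bifan, two V for the regulator pair, and two lambda for
    the target pair, all in the same stratum.
    """
    expected: dict[tuple[str, str, str], int] = {}

    def bump(motif, mode, age, n):
        key = (motif, mode, age)
        expected[key] = expected.get(key, 0) + n

    for (motif, mode, age), n in spec.items():
        if motif not in MOTIF_TYPES:
            raise ValueError(f"unknown motif type {motif!r}")
        bump(motif, mode, age, n)
        if motif == "DELTA":
            bump("V", mode, age, n)
        elif motif == "BIFAN":
            bump("V", mode, age, 2 * n)
            bump("LAMBDA", mode, age, 2 * n)
    return {k: v for k, v in expected.items() if v}


def plant_motifs(
    grn: RegulatoryNetwork,
    ppi: InteractionNetwork,
    motif_spec: dict,
    seed: int = 0,
    prefix: str = "PL",
) -> tuple[RegulatoryNetwork, InteractionNetwork, ParalogPairTable, SimulationTruth]:
    """Insert node-disjoint motif instances with known per-stratum counts.

    ``motif_spec`` maps (motif_type, mode, age_group) to the number of
    instances to plant. Every instance is built from fresh nodes (never
    reusing background or previously planted nodes), so the planted
    contribution to each finder's count is exact and recorded in
    ``truth.expected_counts``.
    """
    existing = set(grn.nodes) | set(ppi.nodes)
    counter = [0]

    def fresh(tag: str) -> str:
        while True:
            name = f"{prefix}{counter[0]:05d}{tag}"
            counter[0] += 1
            if name not in existing:
                existing.add(name)
                return name

    grn_edges = list(grn.edges)
    ppi_edges = list(ppi.edges)
    pair_rows = []
    for (motif, mode, age), n in sorted(motif_spec.items()):
        if n < 0:
            raise ValueError("negative planted count")
        for _ in range(n):
            if motif == "V":
                a, b, t = fresh("a"), fresh("b"), fresh("t")
                grn_edges += [(a, t, 1.0), (b, t, 1.0)]
                pair_rows.append((a, b, mode, None, None, age))
            elif motif == "PPI_V":
                a, b, x = fresh("a"), fresh("b"), fresh("x")
                ppi_edges += [(a, x, 1.0), (b, x, 1.0)]
                pair_rows.append((a, b, mode, None, None, age))
            elif motif == "LAMBDA":
                r, a, b = fresh("r"), fresh("a"), fresh("b")
                grn_edges += [(r, a, 1.0), (r, b, 1.0)]
                pair_rows.append((a, b, mode, None, None, age))
            elif motif == "DELTA":
                a, b, t = fresh("a"), fresh("b"), fresh("t")
                grn_edges += [(a, t, 1.0), (b, t, 1.0)]
                ppi_edges += [(a, b, 1.0)]
                pair_rows.append((a, b, mode, None, None, age))
            elif motif == "BIFAN":
                a, b, t1, t2 = fresh("a"), fresh("b"), fresh("t"), fresh("t")
                grn_edges += [(a, t1, 1.0), (a, t2, 1.0), (b, t1, 1.0), (b, t2, 1.0)]
                pair_rows.append((a, b, mode, None, None, age))
                pair_rows.append((t1, t2, mode, None, None, age))
            else:
                raise ValueError(f"unknown motif type {motif!r}")
    pairs = ParalogPairTable.from_records(pair_rows)
    truth = SimulationTruth(
        seed=seed,
        planted_counts=dict(motif_spec),
        expected_counts=_implied_counts(motif_spec),
    )
    return (
        RegulatoryNetwork.from_edges(grn_edges),
        InteractionNetwork.from_edges(ppi_edges, min_score=ppi.min_score),
        pairs,
        truth,
    )


DEFAULT_MIXTURE = [(0.15, 0.05, 0.6), (1.10, 0.20, 0.4)]
DEFAULT_MM = (0.5, 0.4, 0.02)


def _truncated_normal(rng, mean, sd, size):
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_pairs(
    n_pairs_per_group: int = 500,
    mixture: Sequence[tuple[float, float, float]] = tuple(DEFAULT_MIXTURE),
    mm: tuple[float, float, float] = DEFAULT_MM,
    wgd_vmax_scale: float = 1.0,
    seed: int = 0,
    gene_prefix: str = "dup",
) -> tuple[ParalogPairTable, SimulationTruth]:
    """Draw WGD and SSD duplicate pairs with mixture Ks and Michaelis–Menten Ka.

    Ks is drawn from the Gaussian mixture (components selected by weight,
    values truncated at 0); Ka = Vmax·Ks/(Km + Ks) + Normal(0, noise_sd),
    floored at 0, with the WGD group's Vmax multiplied by
    ``wgd_vmax_scale`` (< 1 plants the slower-divergence contrast).
    ``truth.components`` records each pair's generating mixture component
    (1-based, youngest first).
    """
    weights = np.array([w for _, _, w in mixture], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mixture weights must sum to 1")
    means = np.array([m for m, _, _ in mixture])
    sds = np.array([s for _, s, _ in mixture])
    order = np.argsort(means)
    vmax, km, noise_sd = mm
    rng = np.random.default_rng(seed)
    rows = []
    components = {}
    idx = 0
    for mode in ("WGD", "SSD"):
        scale = wgd_vmax_scale if mode == "WGD" else 1.0
        comp = rng.choice(len(means), size=n_pairs_per_group, p=weights)
        for c in comp:
            ks = float(_truncated_normal(rng, means[c], sds[c], 1)[0])
            ka = max(0.0, scale * vmax * ks / (km + ks) + float(rng.normal(0, noise_sd)))
            g1 = f"{gene_prefix}A{idx:05d}"
            g2 = f"{gene_prefix}B{idx:05d}"
            idx += 1
            rows.append((g1, g2, mode, ks, ka, UNASSIGNED))
            # component index after sorting means, 1-based (youngest = 1)
            components[(g1, g2) if g1 <= g2 else (g2, g1)] = int(np.where(order == c)[0][0]) + 1
    pairs = ParalogPairTable.from_records(rows)
    truth = SimulationTruth(
        seed=seed,
        mixture=[list(map(float, t)) for t in mixture],
        mm={"vmax": vmax, "km": km, "noise_sd": noise_sd, "wgd_vmax_scale": wgd_vmax_scale},
        components=components,
    )
    return pairs, truth


def simulate_full_study(
    seed: int = 0,
    n_regulators: int = 80,
    n_targets: int = 300,
    n_pairs_per_stratum: int = 40,
    planted_v: dict = None,
    wgd_vmax_scale: float = 0.6,
    wgd_shared_partners: int = 4,
    ssd_shared_partners: int = 1,
    private_partners: int = 2,
) -> dict:
    """One coherent synthetic study with all planted effects.

    Produces a weighted GRN (preferential attachment, hub-dominated
    weights), a PPI network, a paralog-pair table with two Ks age
    components (recent ≈ 0.15, ancient ≈ 1.10), planted motif instances
    concentrated on recent-WGD pairs, a planted interaction-similarity
    advantage for WGD pairs, a planted divergence contrast
    (Vmax_WGD = ``wgd_vmax_scale`` × Vmax_SSD), and an annotation table in
    which WGD-pair genes are preferentially labelled ``dosage_sensitive``.

    Returns a dict with keys ``grn, ppi, pairs, annotations, truth``.
    """
    if planted_v is None:
        planted_v = {
            ("V", "WGD", "1"): 30, ("V", "WGD", "2"): 8,
            ("V", "SSD", "1"): 15, ("V", "SSD", "2"): 8,
            ("PPI_V", "WGD", "1"): 12, ("PPI_V", "WGD", "2"): 4,
            ("LAMBDA", "WGD", "1"): 10, ("LAMBDA", "WGD", "2"): 3,
            ("DELTA", "WGD", "1"): 8, ("DELTA", "WGD", "2"): 2,
            ("BIFAN", "WGD", "1"): 6, ("BIFAN", "WGD", "2"): 2,
        }
    rng = np.random.default_rng(seed)
    sub = np.random.SeedSequence(seed).spawn(4)
    grn, ppi, _ = simulate_networks(
        n_regulators, n_targets,
        grn_attachment="preferential", ppi_density=0.01,
        seed=int(sub[0].generate_state(1)[0] % (2**31)),
        hub_weights=True,
    )
    grn, ppi, planted_pairs, plant_truth = plant_motifs(
        grn, ppi, planted_v, seed=int(sub[1].generate_state(1)[0] % (2**31))
    )

    # background pairs over network nodes (degree-stratified: regulators with
    # regulators, targets with targets) so null Z-scores stay calibrated
    regs = sorted(grn.regulators)
    tgts = sorted(grn.targets - grn.regulators)
    bg_rows = []
    for stratum_nodes in (regs, tgts):
        chosen = rng.choice(len(stratum_nodes), size=(n_pairs_per_stratum, 2))
        for i, j in chosen:
            if i == j:
                continue
            mode = "WGD" if rng.random() < 0.5 else "SSD"
            age = "1" if rng.random() < 0.5 else "2"
            bg_rows.append((stratum_nodes[i], stratum_nodes[j], mode, None, None, age))
    bg_pairs = ParalogPairTable.from_records(bg_rows)

    # merge planted + background; drop background rows colliding with planted
    merged = ParalogPairTable.from_records(
        [tuple(r) for r in planted_pairs.df.itertuples(index=False)]
        + [tuple(r) for r in bg_pairs.df.itertuples(index=False)]
    )

    # Ks per pair from its age component, Ka from the Michaelis-Menten curve
    mixture = list(DEFAULT_MIXTURE)
    vmax, km, noise_sd = DEFAULT_MM
    comp_params = {"1": mixture[0], "2": mixture[1]}
    df = merged.df.copy()
    ks_vals, ka_vals = [], []
    for r in df.itertuples(index=False):
        mean, sd, _ = comp_params.get(r.age_group, mixture[0])
        ks = float(_truncated_normal(rng, mean, sd, 1)[0])
        scale = wgd_vmax_scale if r.mode == "WGD" else 1.0
        ka = max(0.0, scale * vmax * ks / (km + ks) + float(rng.normal(0, noise_sd)))
        ks_vals.append(ks)
        ka_vals.append(ka)
    df["ks"] = ks_vals
    df["ka"] = ka_vals
    true_groups = dict(zip(zip(df["gene1"], df["gene2"]), df["age_group"]))
    # the pipeline re-derives age groups from Ks peaks; ship them unassigned
    df["age_group"] = UNASSIGNED
    pairs = ParalogPairTable(df.reset_index(drop=True))

    # similarity effect: WGD pairs share more PPI partners than SSD pairs
    ppi_edges = list(ppi.edges)
    counter = [0]

    def fresh_partner() -> str:
        counter[0] += 1
        return f"PX{counter[0]:05d}"

    for r in pairs.df.itertuples(index=False):
        n_shared = wgd_shared_partners if r.mode == "WGD" else ssd_shared_partners
        for _ in range(n_shared):
            x = fresh_partner()
            ppi_edges += [(r.gene1, x, 1.0), (r.gene2, x, 1.0)]
        for g in (r.gene1, r.gene2):
            for _ in range(private_partners):
                ppi_edges.append((g, fresh_partner(), 1.0))
    ppi = InteractionNetwork.from_edges(ppi_edges, min_score=ppi.min_score)

    # annotations: WGD-pair genes preferentially dosage-sensitive
    wgd_genes = pairs.genes_by_mode("WGD")
    ann_rows = []
    for g in sorted(grn.nodes | ppi.nodes):
        if g in wgd_genes:
            if rng.random() < 0.7:
                ann_rows.append((g, "dosage_sensitive", "process"))
        elif rng.random() < 0.1:
            ann_rows.append((g, "dosage_sensitive", "process"))
        if rng.random() < 0.3:
            ann_rows.append((g, "housekeeping", "process"))
    annotations = AnnotationTable.from_records(ann_rows)

    truth = SimulationTruth(
        seed=seed,
        planted_counts=plant_truth.planted_counts,
        expected_counts=plant_truth.expected_counts,
        mixture=[list(map(float, t)) for t in mixture],
        mm={"vmax": vmax, "km": km, "noise_sd": noise_sd,
            "wgd_vmax_scale": wgd_vmax_scale},
        similarity_effect={
            "wgd_shared_partners": wgd_shared_partners,
            "ssd_shared_partners": ssd_shared_partners,
            "private_partners": private_partners,
        },
        components={k: v for k, v in true_groups.items()},
    )
    return {"grn": grn, "ppi": ppi, "pairs": pairs, "annotations": annotations, "truth": truth}
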
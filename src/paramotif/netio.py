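"""Data model and TSV readers/writers for networks, paralog pairs, and annotations.

All downstream analyses consume the container types defined here:

- :class:`RegulatoryNetwork` — directed, weighted regulator→target edges
  (a gene regulatory network, e.g. the ranked edge list produced by a
  GRN-inference tool such as GENIE3).
- :class:`InteractionNetwork` — undirected, scored protein–protein
  interaction edges (e.g. a STRING-style export).
- :class:`ParalogPairTable` — duplicate gene pairs labelled by duplication
  mode (whole-genome duplication, WGD, vs. small-scale duplication, SSD)
  with optional synonymous (Ks) and nonsynonymous (Ka) substitution rates
  and an assigned age group.
- :class:`AnnotationTable` — many-to-many gene → functional-term mapping
  used for enrichment tests.

Gene identifiers are opaque, case-sensitive strings. Loading is
canonicalizing: self-edges are dropped with a warning, duplicate edges keep
the maximum weight/score, and unordered pairs are stored with a canonical
endpoint order, so the loaded structures are invariant to input row order.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "MODES",
    "UNASSIGNED",
    "ParseError",
    "ValidationError",
    "RegulatoryNetwork",
    "InteractionNetwork",
    "ParalogPairTable",
    "AnnotationTable",
    "read_grn",
    "read_ppi",
    "read_pairs",
    "read_annotations",
    "write_grn",
    "write_ppi",
    "write_pairs",
]

#: Allowed duplication-mode labels.
MODES = ("WGD", "SSD")

#: Age-group label for pairs outside every Ks-peak interval.
UNASSIGNED = "unassigned"

_HEADER_TOKENS = {
    "regulator", "target", "weight",
    "genea", "geneb", "score", "protein1", "protein2",
    "gene1", "gene2", "mode", "ks", "ka", "age_group",
    "gene", "term", "namespace",
}


class ParseError(ValueError):
    """A malformed input file (wrong column count, non-numeric field, empty file)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


@dataclass
class RegulatoryNetwork:
    """Directed weighted gene regulatory network.

    Parameters
    ----------
    edges
    tuple of ``(regulator, target, weight)`` triples in canonical
        (regulator, target) sort order. Invariants: no self-edges, no
        duplicate (regulator, target) pairs, every weight >= 0.
    """

    edges: tuple[tuple[str, str, float], ...]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        dedupe: bool = True,
    ) -> "RegulatoryNetwork":
        """Build a network from raw edges, applying the canonicalization rules.

        Self-edges are dropped with a warning; duplicate (regulator, target)
        pairs keep the maximum weight; edges are stored sorted.
        """
        best: dict[tuple[str, str], float] = {}
        n_self = 0
        n_dup = 0
        for reg, tgt, w in edges:
            w = float(w)
            if w < 0:
                raise ValidationError(f"negative edge weight {w!r} on ({reg}, {tgt})")
            if not math.isfinite(w):
                raise ValidationError(f"non-finite edge weight on ({reg}, {tgt})")
            if reg == tgt:
                n_self += 1
                continue
            key = (reg, tgt)
            if key in best:
                n_dup += 1
                if not dedupe:
                    raise ValidationError(f"duplicate edge {key}")
                if w > best[key]:
                    best[key] = w
            else:
                best[key] = w
        if n_self:
            warnings.warn(f"dropped {n_self} self-edge(s) from regulatory network")
        if n_dup:
            warnings.warn(
                f"collapsed {n_dup} duplicate edge(s) in regulatory network (kept max weight)"
            )
        return cls(tuple((r, t, best[(r, t)]) for r, t in sorted(best)))

    @cached_property
    def out_adj(self) -> dict[str, set[str]]:
        """regulator → set of targets."""
        adj: dict[str, set[str]] = {}
        for r, t, _ in self.edges:
            adj.setdefault(r, set()).add(t)
        return adj

    @cached_property
    def in_adj(self) -> dict[str, set[str]]:
        """target → set of regulators."""
        adj: dict[str, set[str]] = {}
        for r, t, _ in self.edges:
            adj.setdefault(t, set()).add(r)
        return adj

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(self.out_adj)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self.in_adj)

    @property
    def nodes(self) -> frozenset[str]:
        return self.regulators | self.targets

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def relabel(self, mapping: dict[str, str]) -> "RegulatoryNetwork":
        """Apply a node relabeling; identifiers absent from `mapping` are kept."""
        return RegulatoryNetwork.from_edges(
            (mapping.get(r, r), mapping.get(t, t), w) for r, t, w in self.edges
        )

    def out_degree(self, gene: str) -> int:
        return len(self.out_adj.get(gene, ()))

    def in_degree(self, gene: str) -> int:
        return len(self.in_adj.get(gene, ()))

    def total_degrees(self) -> dict[str, int]:
        """in-degree + out-degree for every node."""
        return {g: self.out_degree(g) + self.in_degree(g) for g in self.nodes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "weight"])


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionNetwork:
    """Undirected scored protein–protein interaction network.

    Edges are stored with a canonical endpoint order (``a <= b``), so
    ``(a, b)`` and ``(b, a)`` denote the same interaction. ``min_score`` is
    the confidence threshold already applied to the stored edges.
    """

    edges: tuple[tuple[str, str, float], ...]
    min_score: float = 0.0

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        min_score: float = 0.0,
    ) -> "InteractionNetwork":
        best: dict[tuple[str, str], float] = {}
        n_self = 0
        n_below = 0
        for a, b, s in edges:
            s = float(s)
            if not math.isfinite(s):
                raise ValidationError(f"non-finite interaction score on ({a}, {b})")
            if a == b:
                n_self += 1
                continue
            if s < min_score:
                n_below += 1
                continue
            key = _canon_pair(a, b)
            if key not in best or s > best[key]:
                best[key] = s
        if n_self:
            warnings.warn(f"dropped {n_self} self-interaction(s)")
        return cls(
            tuple((a, b, best[(a, b)]) for a, b in sorted(best)),
            min_score=min_score,
        )

    @cached_property
    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b, _ in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    @cached_property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, b, _ in self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _canon_pair(a, b) in self.edge_set

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.neighbors)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def relabel(self, mapping: dict[str, str]) -> "InteractionNetwork":
        return InteractionNetwork.from_edges(
            ((mapping.get(a, a), mapping.get(b, b), s) for a, b, s in self.edges),
            min_score=self.min_score,
        )

    def degree(self, gene: str) -> int:
        return len(self.neighbors.get(gene, ()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["geneA", "geneB", "score"])


@dataclass
class ParalogPairTable:
    """Duplicate gene pairs with duplication mode, substitution rates, and age group.

    Backed by a DataFrame with columns ``gene1, gene2, mode, ks, ka,
    age_group``. Pairs are unordered and stored with ``gene1 <= gene2``;
    ``mode`` is one of ``WGD``/``SSD``; ``ks``/``ka`` are non-negative or NaN;
    ``age_group`` is a 1-based peak index (youngest first) or ``"unassigned"``.
    """

    df: pd.DataFrame

    COLUMNS = ("gene1", "gene2", "mode", "ks", "ka", "age_group")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
    ) -> "ParalogPairTable":
        """Build from ``(gene1, gene2, mode[, ks[, ka[, age_group]]])`` tuples."""
        rows = []
        seen: set[tuple[str, str]] = set()
        bad_mode: list[str] = []
        n_dup = 0
        for rec in records:
            rec = tuple(rec)
            g1, g2, mode = rec[0], rec[1], rec[2]
            ks = float(rec[3]) if len(rec) > 3 and rec[3] is not None else math.nan
            ka = float(rec[4]) if len(rec) > 4 and rec[4] is not None else math.nan
            age = rec[5] if len(rec) > 5 and rec[5] is not None else UNASSIGNED
            if g1 == g2:
                raise ValidationError(f"pair with identical genes: {g1}")
            if mode not in MODES:
                bad_mode.append(f"({g1}, {g2}): {mode!r}")
                continue
            for name, val in (("Ks", ks), ("Ka", ka)):
                if not math.isnan(val) and (val < 0 or math.isinf(val)):
                    raise ValidationError(f"{name}={val} for pair ({g1}, {g2}) must be finite and >= 0")
            key = _canon_pair(g1, g2)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            rows.append((*key, mode, ks, ka, str(age)))
        if bad_mode:
            raise ValidationError(
                "mode must be one of %s; offending rows: %s" % (MODES, "; ".join(bad_mode))
            )
        if n_dup:
            warnings.warn(f"dropped {n_dup} duplicate paralog pair(s) (kept first occurrence)")
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        df = df.sort_values(["gene1", "gene2"], kind="stable").reset_index(drop=True)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    @cached_property
    def pair_info(self) -> dict[tuple[str, str], tuple[str, str]]:
        """(gene1, gene2) → (mode, age_group) lookup, canonical key order."""
        return {
            (r.gene1, r.gene2): (r.mode, r.age_group)
            for r in self.df.itertuples(index=False)
        }

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.pair_info)

    def genes_by_mode(self, mode: str) -> set[str]:
        """All genes that are a member of at least one pair of the given mode."""
        sub = self.df[self.df["mode"] == mode]
        return set(sub["gene1"]) | set(sub["gene2"])

    def with_age_groups(self, assignment: dict[tuple[str, str], str]) -> "ParalogPairTable":
        """Return a copy with age_group replaced per the canonical-pair mapping."""
        df = self.df.copy()
        df["age_group"] = [
            str(assignment.get((r.gene1, r.gene2), r.age_group))
            for r in df.itertuples(index=False)
        ]
        return ParalogPairTable(df)

    def subset(self, mask) -> "ParalogPairTable":
        return ParalogPairTable(self.df[mask].reset_index(drop=True))


@dataclass
class AnnotationTable:
    """Many-to-many gene → term mapping (``gene, term, namespace`` columns)."""

    df: pd.DataFrame

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "AnnotationTable":
        rows = []
        for rec in records:
            rec = tuple(rec)
            gene, term = rec[0], rec[1]
            ns = rec[2] if len(rec) > 2 and rec[2] is not None else "NA"
            rows.append((gene, term, ns))
        df = pd.DataFrame(rows, columns=["gene", "term", "namespace"])
        df = df.drop_duplicates(["gene", "term"]).reset_index(drop=True)
        return cls(df)

    @cached_property
    def genes_by_term(self) -> dict[str, set[str]]:
        return {t: set(g["gene"]) for t, g in self.df.groupby("term")}


# ---------------------------------------------------------------------------
# TSV parsing


def _read_rows(path, min_cols: int, max_cols: int, what: str) -> list[tuple[int, list[str]]]:
    """Read TSV rows, skipping an optional header (detected by known column
    names or a non-numeric third field in row 1). Returns (lineno, fields)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        raw = [(i + 1, row) for i, row in enumerate(csv.reader(fh, delimiter="\t")) if row]
    if not raw:
        raise ParseError(f"{path}: empty {what} file")
    first = raw[0][1]
    has_header = any(f.strip().lower() in _HEADER_TOKENS for f in first)
    if not has_header and len(first) >= 3 and not _is_number(first[2]) and what != "paralog-pair":
        has_header = True
    rows = raw[1:] if has_header else raw
    if not rows:
        raise ParseError(f"{path}: {what} file has a header but no data rows")
    out = []
    for lineno, fields in rows:
        if not (min_cols <= len(fields) <= max_cols):
            raise ParseError(
                f"{path}:{lineno}: expected {min_cols}-{max_cols} columns, got {len(fields)}"
            )
        out.append((lineno, [f.strip() for f in fields]))
    return out


def _parse_float(path, lineno: int, text: str, name: str) -> float:
    if text in ("", "NA", "NaN", "nan"):
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric {name} {text!r}") from None


def read_grn(path, dedupe: bool = True) -> RegulatoryNetwork:
    """Read a regulatory network from a ``regulator  target  [weight]`` TSV.

    A missing weight column defaults to 1.0. Self-edges are dropped with a
    warning; duplicate (regulator, target) rows keep the maximum weight.
    """
    edges = []
    for lineno, fields in _read_rows(path, 2, 3, "regulatory-network"):
        w = _parse_float(path, lineno, fields[2], "weight") if len(fields) == 3 else 1.0
        if math.isnan(w):
            raise ParseError(f"{path}:{lineno}: missing edge weight")
        edges.append((fields[0], fields[1], w))
    return RegulatoryNetwork.from_edges(edges, dedupe=dedupe)


def read_ppi(path, min_score: float = 0.5) -> InteractionNetwork:
    """Read a protein–protein interaction network from a ``geneA  geneB  [score]`` TSV.

    Edges below ``min_score`` are discarded at load time (STRING-style
    confidence filtering; the conventional threshold is 0.5). A missing score
    column defaults to 1.0.
    """
    edges = []
    for lineno, fields in _read_rows(path, 2, 3, "interaction-network"):
        s = _parse_float(path, lineno, fields[2], "score") if len(fields) == 3 else 1.0
        if math.isnan(s):
            raise ParseError(f"{path}:{lineno}: missing interaction score")
        edges.append((fields[0], fields[1], s))
    return InteractionNetwork.from_edges(edges, min_score=min_score)


def read_pairs(path) -> ParalogPairTable:
    """Read a paralog-pair table from a ``gene1  gene2  mode  [Ks  [Ka  [age_group]]]`` TSV."""
    records = []
    for lineno, fields in _read_rows(path, 3, 6, "paralog-pair"):
        ks = _parse_float(path, lineno, fields[3], "Ks") if len(fields) > 3 else math.nan
        ka = _parse_float(path, lineno, fields[4], "Ka") if len(fields) > 4 else math.nan
        age = fields[5] if len(fields) > 5 and fields[5] != "NA" else UNASSIGNED
        records.append((fields[0], fields[1], fields[2], ks, ka, age))
    return ParalogPairTable.from_records(records)


def read_annotations(path) -> AnnotationTable:
    """Read a ``gene  term  [namespace]`` annotation TSV."""
    records = []
    for _, fields in _read_rows(path, 2, 3, "annotation"):
        records.append(tuple(fields))
    return AnnotationTable.from_records(records)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_grn(net: RegulatoryNetwork, path) -> None:
    _write_tsv(net.to_frame(), path)


def write_ppi(net: InteractionNetwork, path) -> None:
    _write_tsv(net.to_frame(), path)


def write_pairs(pairs: ParalogPairTable, path) -> None:
    df = pairs.df.rename(columns={"ks": "Ks", "ka": "Ka"})
    _write_tsv(df, path)
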
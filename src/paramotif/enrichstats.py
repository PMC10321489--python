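"""Fisher's-exact-test enrichment with Benjamini–Hochberg correction.

Two uses: overrepresentation of functional terms (or TF families) among a
gene set against a background, and the association between duplication mode
and network membership (are WGD-derived genes overrepresented among the
genes with protein–protein interactions?). Both reduce to 2×2 exact tests;
p-values across terms are adjusted by the Benjamini–Hochberg step-up
procedure.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netio import AnnotationTable, ParalogPairTable, ValidationError

__all__ = ["fisher_enrichment", "mode_membership_test"]

_COLUMNS = [
    "term", "a", "b", "c", "d", "odds_ratio", "p_value", "p_adjusted", "enriched",
]


def _fisher(a: int, b: int, c: int, d: int, alternative: str) -> tuple[float, float]:
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    return float(odds), float(p)


def fisher_enrichment(
    genes: set[str],
    background: set[str],
    annotations: AnnotationTable,
    alternative: str = "greater",
    alpha: float = 0.05,
    min_annotated: int = 2,
) -> pd.DataFrame:
    """Term overrepresentation in `genes` relative to `background`.

    For each term annotated in at least ``min_annotated`` background genes
    and at least one gene of the query set, the 2×2 table is

    ===============  ============  ===================
    .                with term     without term
    ===============  ============  ===================
    query set        a             b
    rest of backgr.  c             d
    ===============  ============  ===================

    scored by Fisher's exact test (default alternative "greater", i.e.
    enrichment), with Benjamini–Hochberg adjustment across all tested
    terms; ``enriched`` flags adjusted p below ``alpha``.
    """
    genes = set(genes)
    background = set(background)
    stray = genes - background
    if stray:
        raise ValidationError(f"genes not in background: {sorted(stray)[:10]}")
    if not background:
        raise ValidationError("background is empty")
    n_set = len(genes)
    n_bg = len(background)
    rows = []
    for term in sorted(annotations.genes_by_term):
        with_term = annotations.genes_by_term[term] & background
        if len(with_term) < min_annotated:
            continue
        a = len(with_term & genes)
        if a == 0:
            continue
        b = n_set - a
        c = len(with_term) - a
        d = (n_bg - n_set) - c
        odds, p = _fisher(a, b, c, d, alternative)
        rows.append((term, a, b, c, d, odds, p))
    if not rows:
        return pd.DataFrame(columns=_COLUMNS)
    df = pd.DataFrame(rows, columns=_COLUMNS[:7])
    _, p_adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["enriched"] = df["p_adjusted"] < alpha
    return df


def mode_membership_test(
    network_genes: set[str],
    all_genes: set[str],
    pairs: ParalogPairTable,
    alternative: str = "greater",
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Association between WGD derivation and network membership.

    Builds the 2×2 table (WGD-derived vs not) × (in network vs not) over
    ``all_genes``, where "WGD-derived" means member of at least one WGD
    pair. A gene in both a WGD and an SSD pair counts as WGD-derived
    (WGD precedence) unless ``drop_ambiguous`` removes it from the universe.
    Returns a one-row table in the same layout as :func:`fisher_enrichment`
    (a = WGD-derived genes in the network).
    """
    network_genes = set(network_genes)
    all_genes = set(all_genes)
    stray = network_genes - all_genes
    if stray:
        raise ValidationError(f"network genes not in universe: {sorted(stray)[:10]}")
    wgd = pairs.genes_by_mode("WGD") & all_genes
    if drop_ambiguous:
        ambiguous = wgd & pairs.genes_by_mode("SSD")
        all_genes = all_genes - ambiguous
        network_genes = network_genes - ambiguous
        wgd = wgd - ambiguous
    a = len(wgd & network_genes)
    b = len(wgd - network_genes)
    c = len(network_genes - wgd)
    d = len(all_genes) - a - b - c
    odds, p = _fisher(a, b, c, d, alternative)
    return pd.DataFrame(
        [("WGD_in_network", a, b, c, d, odds, p, p, p < 0.05)],
        columns=_COLUMNS,
    )
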
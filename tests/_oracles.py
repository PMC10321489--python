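"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops over node triples
and quadruples, direct set arithmetic, direct tail summation — and shares
no code with the package's implementations.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_v(dir_edges: set, pairs: list) -> dict:
    """Count V motifs per pair by looping over every candidate target node."""
    nodes = {x for e in dir_edges for x in e}
    out = {}
    for a, b in pairs:
        n = 0
        for t in nodes:
            if t in (a, b):
                continue
            if (a, t) in dir_edges and (b, t) in dir_edges:
                n += 1
        out[(a, b)] = n
    return out


def brute_lambda(dir_edges: set, pairs: list) -> dict:
    nodes = {x for e in dir_edges for x in e}
    out = {}
    for a, b in pairs:
        n = 0
        for r in nodes:
            if r in (a, b):
                continue
            if (r, a) in dir_edges and (r, b) in dir_edges:
                n += 1
        out[(a, b)] = n
    return out


def brute_ppi_v(und_edges: set, pairs: list) -> dict:
    und = {frozenset(e) for e in und_edges}
    nodes = {x for e in und_edges for x in e}
    out = {}
    for a, b in pairs:
        n = 0
        for x in nodes:
            if x in (a, b):
                continue
            if frozenset((a, x)) in und and frozenset((b, x)) in und:
                n += 1
        out[(a, b)] = n
    return out


def brute_delta(dir_edges: set, und_edges: set, pairs: list) -> dict:
    und = {frozenset(e) for e in und_edges}
    v = brute_v(dir_edges, pairs)
    return {p: (n if frozenset(p) in und else 0) for p, n in v.items()}


def brute_bifan(dir_edges: set, pairs: list, require_target_paralogy: bool) -> dict:
    """Quadruple loop: regulator pair x unordered target pair."""
    nodes = {x for e in dir_edges for x in e}
    pair_keys = {frozenset(p) for p in pairs}
    out = {}
    for a, b in pairs:
        n = 0
        for t1, t2 in combinations(sorted(nodes), 2):
            if {t1, t2} & {a, b}:
                continue
            if not all(
                (r, t) in dir_edges for r in (a, b) for t in (t1, t2)
            ):
                continue
            if require_target_paralogy and frozenset((t1, t2)) not in pair_keys:
                continue
            n += 1
        out[(a, b)] = n
    return out


def dice(a: set, b: set) -> float:
    denom = len(a) + len(b)
    return 2.0 * len(a & b) / denom if denom else math.nan


def hypergeom_tail_greater(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table with fixed margins, by direct summation."""
    row1 = a + b
    col1 = a + c
    n = a + b + c + d

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    denom = log_comb(n, col1)
    total = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        total += math.exp(
            log_comb(row1, k) + log_comb(n - row1, col1 - k) - denom
        )
    return min(total, 1.0)


def mwu_pair_counting(x, y) -> float:
    """Mann-Whitney U of sample x: concordant pairs with half credit for ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def ols_r_squared(x, y) -> tuple[float, float]:
    """Textbook OLS slope and R^2."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    r2 = sxy**2 / (sxx * syy)
    return slope, r2
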
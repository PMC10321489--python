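"""Duplicate-pair age groups from Ks peaks and Ka–Ks divergence curves.

Synonymous substitutions (Ks) accumulate roughly neutrally, so the Ks value
of a duplicate pair is a proxy for its age, and peaks in a whole-paranome Ks
distribution mark bursts of duplication — typically whole-genome duplication
(WGD) events. This module:

1. fits a univariate Gaussian mixture with a user-fixed number of
   components to the Ks values (:func:`fit_ks_peaks`) — mixture models tend
   to overestimate the number of Ks peaks, so the component count is an
   explicit input, not model-selected;
2. defines an *age group* per peak as the interval mean ± 2 sd (floored at
   zero) and assigns each pair to a group (:func:`split_pairs_by_peak`);
3. fits a saturating Michaelis–Menten curve Ka = Vmax·Ks/(Km + Ks) to the
   Ka-vs-Ks scatter of a duplication-mode group (:func:`fit_mm_divergence`)
   — nonsynonymous divergence saturates at high Ks, so a linear model is
   inadequate; Vmax is the divergence asymptote and Km the Ks at
   half-saturation.

The expectation–maximization loop is implemented here directly so that the
log-likelihood trajectory is exposed and its monotone non-decrease is
asserted on every fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .netio import (
    UNASSIGNED,
    InteractionNetwork,
    ParalogPairTable,
    ValidationError,
)

__all__ = ["KsPeak", "MMFit", "fit_ks_peaks", "split_pairs_by_peak", "fit_mm_divergence"]


@dataclass(frozen=True)
class KsPeak:
    """One component of the Ks mixture, in Ks units.

    ``index`` is 1-based, ordered by mean (1 = youngest peak). ``interval``
    is [mean - 2 sd, mean + 2 sd] with the lower bound floored at 0; pairs
    whose Ks falls inside it belong to this peak's age group.
    """

    index: int
    mean: float
    sd: float
    weight: float

    @property
    def interval(self) -> tuple[float, float]:
        return (max(0.0, self.mean - 2.0 * self.sd), self.mean + 2.0 * self.sd)

    def contains(self, ks: float) -> bool:
        lo, hi = self.interval
        return lo <= ks <= hi

    def standardized_distance(self, ks: float) -> float:
        return abs(ks - self.mean) / self.sd


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis–Menten divergence curve Ka(Ks) = Vmax·Ks/(Km + Ks).

    ``Vmax`` (Ka units) is the saturation asymptote of nonsynonymous
    divergence; ``Km`` (Ks units) is the half-saturation constant; the
    initial slope of the curve is Vmax/Km.
    """

    vmax: float
    km: float
    residual_sd: float
    n_points: int
    group: str

    def predict(self, ks):
        ks = np.asarray(ks, dtype=float)
        return self.vmax * ks / (self.km + ks)


class FitError(RuntimeError):
    """A fit failed to converge or the data are degenerate."""


# ---------------------------------------------------------------------------
# Univariate Gaussian mixture via EM

_MIN_SD = 1e-4  # variance floor, in Ks units, to keep components from collapsing


def _em_1d(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """EM for a univariate Gaussian mixture; returns params + LL trajectory."""
    n = x.size
    ll_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        log_dens = stats.norm.logpdf(x[:, None], means[None, :], sds[None, :])
        log_weighted = log_dens + np.log(weights)[None, :]
        log_norm = np.logaddexp.reduce(log_weighted, axis=1)
        ll = float(np.sum(log_norm))
        if ll_trace and ll < ll_trace[-1] - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_trace[-1]} -> {ll}"
            )
        ll_trace.append(ll)
        resp = np.exp(log_weighted - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, _MIN_SD**2))
        weights = nk / n
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            return means, sds, weights, ll_trace, True
        prev_ll = ll
    return means, sds, weights, ll_trace, False


def fit_ks_peaks(
    pairs: ParalogPairTable,
    n_peaks: int,
    ks_max: float = 5.0,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[KsPeak]:
    """Fit an ``n_peaks``-component Gaussian mixture to the Ks distribution.

    Ks values outside (0, ``ks_max``] are excluded (Ks saturates and becomes
    unreliable beyond ~5). EM is run from ``n_restarts`` seeded
    initializations (quantile-spread means, k-means-style) and the best
    log-likelihood solution is kept. Peaks are returned sorted by mean,
    youngest first, with 1-based indices.

    Raises
    ------
    ValidationError
        if fewer than ``10 * n_peaks`` usable Ks values remain.
    FitError
        if no restart converges.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    ks = pairs.df["ks"].to_numpy(dtype=float)
    x = ks[np.isfinite(ks) & (ks > 0) & (ks <= ks_max)]
    if x.size < 10 * n_peaks:
        raise ValidationError(
            f"need >= {10 * n_peaks} pairs with Ks in (0, {ks_max}], got {x.size}"
        )
    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for r in range(n_restarts):
        # quantile-anchored means with jitter; first restart is deterministic
        q = (np.arange(n_peaks) + 0.5) / n_peaks
        means0 = np.quantile(x, q)
        if r > 0:
            means0 = np.sort(rng.choice(x, size=n_peaks, replace=False))
        sd0 = max(float(np.std(x)) / n_peaks, _MIN_SD)
        sds0 = np.full(n_peaks, sd0)
        w0 = np.full(n_peaks, 1.0 / n_peaks)
        try:
            means, sds, wts, trace, converged = _em_1d(
                x, means0.astype(float), sds0, w0, tol=tol, max_iter=max_iter
            )
        except AssertionError:
            raise
        if converged:
            if best is None or trace[-1] > best[3][-1]:
                best = (means, sds, wts, trace)
        diagnostics.append((r, trace[-1], converged))
    if best is None:
        raise FitError(f"EM failed to converge in {n_restarts} restarts: {diagnostics}")
    means, sds, wts, _ = best
    order = np.argsort(means)
    return [
        KsPeak(index=i + 1, mean=float(means[j]), sd=float(sds[j]), weight=float(wts[j]))
        for i, j in enumerate(order)
    ]


def assign_age_group(ks: float, peaks: list[KsPeak]) -> str:
    """Age group for one Ks value per the mean ± 2 sd rule.

    Inside exactly one peak interval → that peak's index. Inside several
    (overlapping intervals) → the peak with the smallest standardized
    distance |Ks - mean| / sd, ties to the younger peak. Outside all →
    ``"unassigned"``.
    """
    if ks is None or not math.isfinite(ks):
        return UNASSIGNED
    hits = [p for p in peaks if p.contains(ks)]
    if not hits:
        return UNASSIGNED
    if len(hits) == 1:
        return str(hits[0].index)
    best = min(hits, key=lambda p: (p.standardized_distance(ks), p.index))
    return str(best.index)


def split_pairs_by_peak(pairs: ParalogPairTable, peaks: list[KsPeak]) -> ParalogPairTable:
    """Assign every pair to a Ks-peak age group (deterministic, idempotent).

    Pairs lacking a finite Ks are left ``"unassigned"`` (counted in a
    warning).
    """
    if not peaks:
        raise ValueError("peaks must be non-empty")
    if [p.index for p in peaks] != sorted(p.index for p in peaks):
        raise ValueError("peaks must be ordered by index")
    assignment = {}
    n_missing = 0
    for r in pairs.df.itertuples(index=False):
        ks = float(r.ks)
        if not math.isfinite(ks):
            n_missing += 1
        assignment[(r.gene1, r.gene2)] = assign_age_group(ks, peaks)
    if n_missing:
        warnings.warn(f"{n_missing} pair(s) lack Ks and remain unassigned")
    return pairs.with_age_groups(assignment)


# ---------------------------------------------------------------------------
# Michaelis–Menten divergence fit


def _interacting_mask(pairs: ParalogPairTable, ppi: InteractionNetwork, direct_only: bool):
    """Pairs whose proteins interact directly or share >= 1 PPI partner."""
    nb = ppi.neighbors
    mask = []
    for r in pairs.df.itertuples(index=False):
        direct = ppi.has_edge(r.gene1, r.gene2)
        if direct_only:
            mask.append(direct)
            continue
        shared = (nb.get(r.gene1, set()) & nb.get(r.gene2, set())) - {r.gene1, r.gene2}
        mask.append(direct or bool(shared))
    return np.asarray(mask, dtype=bool)


def fit_mm_divergence(
    pairs: ParalogPairTable,
    group: str,
    interacting_only: bool = False,
    ppi: Optional[InteractionNetwork] = None,
    direct_only: bool = False,
    min_points: int = 20,
) -> MMFit:
    """Least-squares Michaelis–Menten fit of Ka against Ks for one mode group.

    With ``interacting_only`` the fit is restricted to pairs whose two
    proteins interact directly or share at least one interaction partner in
    `ppi` (``direct_only`` restricts to direct interactions). Initialization
    is Vmax0 = max(Ka), Km0 = median(Ks); parameters are constrained
    positive.
    """
    df = pairs.df[pairs.df["mode"] == group]
    sub = ParalogPairTable(df.reset_index(drop=True))
    if interacting_only:
        if ppi is None:
            raise ValueError("interacting_only requires a PPI network")
        sub = sub.subset(_interacting_mask(sub, ppi, direct_only))
    ks = sub.df["ks"].to_numpy(dtype=float)
    ka = sub.df["ka"].to_numpy(dtype=float)
    ok = np.isfinite(ks) & np.isfinite(ka)
    ks, ka = ks[ok], ka[ok]
    if ks.size < min_points:
        raise ValidationError(
            f"need >= {min_points} pairs with finite Ka and Ks in group {group}, got {ks.size}"
        )
    if np.allclose(ks, ks[0]):
        raise FitError("degenerate data: all Ks values are equal")

    def mm(k, vmax, km):
        return vmax * k / (km + k)

    p0 = (max(float(np.max(ka)), 1e-6), max(float(np.median(ks)), 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            mm, ks, ka, p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-10, ftol=1e-10, maxfev=500 * 10,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    resid = ka - mm(ks, *popt)
    dof = max(ks.size - 2, 1)
    return MMFit(
        vmax=float(popt[0]),
        km=float(popt[1]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=int(ks.size),
        group=group,
    )
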
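import math

import numpy as np
import pytest

from paramotif.dupes_age import (
    FitError,
    KsPeak,
    MMFit,
    _em_1d,
    assign_age_group,
    fit_ks_peaks,
    fit_mm_divergence,
    split_pairs_by_peak,
)
from paramotif.netio import InteractionNetwork, ParalogPairTable, ValidationError
from paramotif.simdata import simulate_pairs


def pairs_from_ks(ks, mode="WGD", ka=None):
    ka = ka if ka is not None else [None] * len(ks)
    return ParalogPairTable.from_records(
        [(f"a{i}", f"b{i}", mode, k, kav) for i, (k, kav) in enumerate(zip(ks, ka))]
    )


class TestKsPeaks:
    def test_single_component_is_sample_moments(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 0.3, size=400)
        x = x[(x > 0) & (x <= 5.0)]
        peaks = fit_ks_peaks(pairs_from_ks(x), n_peaks=1, seed=0)
        assert peaks[0].mean == pytest.approx(float(np.mean(x)), abs=1e-6)
        assert peaks[0].sd == pytest.approx(float(np.std(x)), abs=1e-5)
        assert peaks[0].weight == pytest.approx(1.0)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(42)
        n = 3000
        comp = rng.random(n) < 0.6
        x = np.where(comp, rng.normal(0.15, 0.05, n), rng.normal(1.10, 0.20, n))
        x = np.abs(x)
        peaks = fit_ks_peaks(pairs_from_ks(x), n_peaks=2, seed=42)
        assert peaks[0].mean == pytest.approx(0.15, abs=0.05)
        assert peaks[1].mean == pytest.approx(1.10, abs=0.05)
        assert peaks[0].index == 1 and peaks[1].index == 2
        assert peaks[0].weight + peaks[1].weight == pytest.approx(1.0)

    def test_agrees_with_sklearn_mixture(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.3, 0.08, 800), rng.normal(1.5, 0.25, 600)])
        x = x[(x > 0) & (x <= 5)]
        peaks = fit_ks_peaks(pairs_from_ks(x), n_peaks=2, seed=1)
        gm = sklearn.GaussianMixture(2, covariance_type="full", n_init=5,
                                     random_state=0, tol=1e-7).fit(x[:, None])
        ref_means = np.sort(gm.means_.ravel())
        assert peaks[0].mean == pytest.approx(ref_means[0], abs=0.02)
        assert peaks[1].mean == pytest.approx(ref_means[1], abs=0.02)

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(3)
        x = np.abs(np.concatenate([rng.normal(0.2, 0.05, 300), rng.normal(1.0, 0.3, 300)]))
        means, sds, w, trace, conv = _em_1d(
            x, np.array([0.1, 2.0]), np.array([0.5, 0.5]), np.array([0.5, 0.5])
        )
        assert conv
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_too_few_points_errors(self):
        with pytest.raises(ValidationError, match=">= 20"):
            fit_ks_peaks(pairs_from_ks([0.1, 0.2, 0.3, 0.4, 0.5]), n_peaks=2)

    def test_ks_max_excludes_saturated_values(self):
        x = list(np.linspace(0.05, 0.5, 30)) + [12.0, 30.0]
        peaks = fit_ks_peaks(pairs_from_ks(x), n_peaks=1, ks_max=5.0)
        assert peaks[0].mean < 1.0


class TestSplitByPeak:
    PEAK = KsPeak(index=1, mean=0.2, sd=0.05, weight=1.0)

    def test_interval_rule(self):
        assert self.PEAK.interval == pytest.approx((0.1, 0.3))
        assert assign_age_group(0.25, [self.PEAK]) == "1"
        assert assign_age_group(0.35, [self.PEAK]) == "unassigned"

    def test_interval_floored_at_zero(self):
        p = KsPeak(index=1, mean=0.05, sd=0.1, weight=1.0)
        assert p.interval[0] == 0.0

    def test_overlap_resolved_by_standardized_distance(self):
        peaks = [
            KsPeak(index=1, mean=0.2, sd=0.05, weight=0.5),
            KsPeak(index=2, mean=0.5, sd=0.15, weight=0.5),
        ]
        # Ks=0.28: distances 1.6 vs ~1.467 -> older peak wins
        assert assign_age_group(0.28, peaks) == "2"
        # equidistant point -> tie goes to the younger peak
        d = KsPeak(index=1, mean=0.2, sd=0.1, weight=0.5)
        e = KsPeak(index=2, mean=0.4, sd=0.1, weight=0.5)
        assert assign_age_group(0.3, [d, e]) == "1"

    def test_missing_ks_unassigned_with_warning(self):
        tbl = ParalogPairTable.from_records(
            [("a", "b", "WGD", 0.25), ("c", "d", "SSD")]
        )
        with pytest.warns(UserWarning, match="lack Ks"):
            out = split_pairs_by_peak(tbl, [self.PEAK])
        assert out.df["age_group"].tolist() == ["1", "unassigned"]

    def test_idempotent(self):
        tbl = ParalogPairTable.from_records([("a", "b", "WGD", 0.22)])
        once = split_pairs_by_peak(tbl, [self.PEAK])
        twice = split_pairs_by_peak(once, [self.PEAK])
        assert once.df.equals(twice.df)

    def test_separated_mixture_assignment_accuracy(self):
        pairs, truth = simulate_pairs(n_pairs_per_group=400, seed=5)
        peaks = fit_ks_peaks(pairs, n_peaks=2, seed=5)
        out = split_pairs_by_peak(pairs, peaks)
        hits = 0
        total = 0
        for r in out.df.itertuples(index=False):
            true_comp = str(truth.components[(r.gene1, r.gene2)])
            if r.age_group != "unassigned":
                total += 1
                hits += r.age_group == true_comp
        assert total > 0.8 * len(out.df)
        assert hits / total >= 0.9


class TestMMDivergence:
    def test_noise_free_exact_recovery(self):
        ks = np.linspace(0.05, 3.0, 60)
        ka = 0.5 * ks / (0.4 + ks)
        fit = fit_mm_divergence(pairs_from_ks(ks, ka=ka), "WGD")
        assert fit.vmax == pytest.approx(0.5, abs=1e-6)
        assert fit.km == pytest.approx(0.4, abs=1e-6)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_10_percent(self):
        rng = np.random.default_rng(7)
        ks = rng.uniform(1e-3, 3.0, 1000)
        ka = np.maximum(0, 0.5 * ks / (0.4 + ks) + rng.normal(0, 0.02, 1000))
        fit = fit_mm_divergence(pairs_from_ks(ks, ka=ka), "WGD")
        assert abs(fit.vmax - 0.5) / 0.5 < 0.10
        assert abs(fit.km - 0.4) / 0.4 < 0.10

    def test_linear_limit_matches_origin_ols(self):
        """For Ks << Km the curve is linear with slope Vmax/Km."""
        rng = np.random.default_rng(11)
        km_true, vmax_true = 2.0, 0.8
        ks = rng.uniform(1e-4, 0.05 * km_true, 400)
        ka = vmax_true * ks / (km_true + ks) + rng.normal(0, 1e-5, 400)
        fit = fit_mm_divergence(pairs_from_ks(ks, ka=ka), "WGD")
        ols_slope = float(np.sum(ks * ka) / np.sum(ks * ks))
        assert abs(fit.vmax / fit.km - ols_slope) / ols_slope < 0.05

    def test_interacting_only_filter(self):
        ks = np.linspace(0.05, 3.0, 40)
        ka = 0.5 * ks / (0.4 + ks)
        tbl = pairs_from_ks(ks, ka=ka)
        # give only half of the pairs a shared partner
        edges = []
        for i in range(20):
            edges += [(f"a{i}", f"x{i}", 1.0), (f"b{i}", f"x{i}", 1.0)]
        ppi = InteractionNetwork.from_edges(edges)
        fit = fit_mm_divergence(tbl, "WGD", interacting_only=True, ppi=ppi)
        assert fit.n_points == 20
        with pytest.raises(ValueError, match="PPI"):
            fit_mm_divergence(tbl, "WGD", interacting_only=True)

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(ValidationError):
            fit_mm_divergence(pairs_from_ks([0.1] * 5, ka=[0.1] * 5), "WGD")
        ks = [1.0] * 25
        with pytest.raises(FitError, match="degenerate"):
            fit_mm_divergence(pairs_from_ks(ks, ka=[0.2] * 25), "WGD")

    def test_residual_sd_grows_with_noise(self):
        rng = np.random.default_rng(2)
        ks = rng.uniform(0.01, 3.0, 600)

        def fit_sd(noise):
            ka = np.maximum(0, 0.5 * ks / (0.4 + ks) + rng.normal(0, noise, 600))
            return fit_mm_divergence(pairs_from_ks(ks, ka=ka), "WGD").residual_sd

        assert fit_sd(0.01) < fit_sd(0.08)

    def test_wgd_contrast_direction(self):
        pairs, _ = simulate_pairs(n_pairs_per_group=300, wgd_vmax_scale=0.6, seed=9)
        wgd = fit_mm_divergence(pairs, "WGD")
        ssd = fit_mm_divergence(pairs, "SSD")
        assert wgd.vmax < ssd.vmax
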
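import math

import networkx as nx
import numpy as np
import pytest

from _oracles import dice, mwu_pair_counting, ols_r_squared
from paramotif.netio import (
    InteractionNetwork,
    ParalogPairTable,
    RegulatoryNetwork,
    ValidationError,
)
from paramotif.topology import (
    FilterError,
    degree_compare,
    filter_grn,
    scale_free_fit,
    sd_similarity,
)


def power_law_degrees(gamma=2.0, kmax=100):
    """Degree k appears proportionally to k^-gamma, k = 1..kmax."""
    degs = []
    for k in range(1, kmax + 1):
        degs += [k] * max(1, round(1e6 * k ** (-gamma) / 1.0))
    return degs


class TestScaleFreeFit:
    def test_exact_power_law(self):
        fit = scale_free_fit(power_law_degrees())
        assert fit.r_squared > 0.98
        assert fit.slope == pytest.approx(-2.0, abs=0.3)
        assert fit.slope < 0

    def test_regular_graph_degenerate(self):
        fit = scale_free_fit([4] * 50)
        assert fit.degenerate and math.isnan(fit.r_squared)

    def test_r_squared_matches_textbook_ols(self):
        """Recompute the binned regression from scratch and compare to 1e-10."""
        rng = np.random.default_rng(5)
        degs = rng.geometric(0.2, size=500)
        n_bins = 10
        fit = scale_free_fit(degs, n_bins=n_bins)
        k = np.asarray([d for d in degs if d >= 1], dtype=float)
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                xs.append(math.log10(k[sel].mean()))
                ys.append(math.log10(sel.sum() / k.size))
        slope, r2 = ols_r_squared(xs, ys)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)
        assert fit.slope == pytest.approx(slope, abs=1e-10)

    def test_preferential_vs_uniform_ordering(self):
        for seed in range(3):
            ba = nx.barabasi_albert_graph(2000, 2, seed=seed)
            er = nx.gnm_random_graph(2000, ba.number_of_edges(), seed=seed)
            r2_ba = scale_free_fit([d for _, d in ba.degree()]).r_squared
            r2_er = scale_free_fit([d for _, d in er.degree()]).r_squared
            assert r2_ba > r2_er

    def test_too_few_nodes(self):
        with pytest.raises(ValidationError):
            scale_free_fit([1, 2, 3])


def hub_skeleton_network(seed=0, n_noise=300):
    """Top-weight quarter of edges is a hub-dominated star forest; the rest
    is uniform noise among fresh nodes."""
    rng = np.random.default_rng(seed)
    edges = []
    for h in range(5):
        for i in range(20):
            edges.append((f"hub{h}", f"leaf{h}_{i}", float(rng.uniform(0.8, 1.0))))
    for i in range(n_noise):
        edges.append((f"u{i}", f"v{i}", float(rng.uniform(0.0, 0.5))))
    return RegulatoryNetwork.from_edges(edges)


class TestFilterGrn:
    def test_full_network_returned_when_always_scale_free(self):
        degs_net = []
        rng = np.random.default_rng(1)
        # BA graph oriented arbitrarily: every subnetwork stays heavy-tailed
        ba = nx.barabasi_albert_graph(800, 3, seed=4)
        edges = [(f"n{a}", f"n{b}", float(rng.uniform(0, 1))) for a, b in ba.edges()]
        net = RegulatoryNetwork.from_edges(edges)
        sub, diag = filter_grn(net, n_steps=5, r2_threshold=0.0)
        assert sub.n_edges == net.n_edges
        assert diag["step"].iloc[-1] == 5

    def test_selected_step_matches_exhaustive_scan(self):
        net = hub_skeleton_network()
        sub, diag = filter_grn(net, n_steps=20, r2_threshold=0.75)
        passing = diag[diag["r_squared"] > 0.75]
        assert not passing.empty
        best_step = int(passing["step"].max())
        assert sub.n_edges == int(diag.loc[diag["step"] == best_step, "n_edges"].iloc[0])
        assert sub.n_edges < net.n_edges  # a proper subnetwork was chosen

    def test_subnetwork_sizes_are_quantile_fractions(self):
        net = hub_skeleton_network(seed=2)
        _, diag = filter_grn(net, n_steps=20, r2_threshold=0.75)
        n = net.n_edges
        for r in diag.itertuples(index=False):
            assert r.n_edges == math.ceil(r.step * n / 20)

    def test_all_equal_weights_deterministic(self):
        edges = [(f"R{i}", f"G{j}", 0.5) for i in range(10) for j in range(20)]
        net = RegulatoryNetwork.from_edges(edges)
        try:
            sub1, d1 = filter_grn(net, n_steps=20, r2_threshold=-1.0)
            sub2, d2 = filter_grn(net, n_steps=20, r2_threshold=-1.0)
            assert sub1.edges == sub2.edges
        except FilterError:
            pytest.fail("threshold -1 must always pass")

    def test_no_pass_raises_with_diagnostics(self):
        edges = [(f"R{i}", f"G{i}", float(i % 7) / 10) for i in range(100)]
        net = RegulatoryNetwork.from_edges(edges)
        with pytest.raises(FilterError) as exc:
            filter_grn(net, n_steps=10, r2_threshold=1.01)
        assert len(exc.value.diagnostics) == 10


class TestSimilarity:
    def make_ppi(self, partner_map):
        edges = []
        for g, partners in partner_map.items():
            for p in partners:
                edges.append((g, p, 1.0))
        return InteractionNetwork.from_edges(edges)

    def test_closed_forms(self):
        ppi = self.make_ppi({"a": ["x", "y"], "b": ["x", "z"]})
        tbl = ParalogPairTable.from_records([("a", "b", "WGD")])
        s = sd_similarity(ppi, tbl)["similarity"].iloc[0]
        assert s == pytest.approx(0.5)
        ppi2 = self.make_ppi({"a": ["x", "y"], "b": ["x", "y"]})
        assert sd_similarity(ppi2, tbl)["similarity"].iloc[0] == pytest.approx(1.0)
        ppi3 = self.make_ppi({"a": ["x"], "b": ["z"]})
        assert sd_similarity(ppi3, tbl)["similarity"].iloc[0] == pytest.approx(0.0)

    def test_no_partners_is_nan(self):
        ppi = self.make_ppi({"c": ["d"]})
        tbl = ParalogPairTable.from_records([("a", "b", "WGD")])
        assert math.isnan(sd_similarity(ppi, tbl)["similarity"].iloc[0])

    def test_direct_interaction_excluded_from_partner_sets(self):
        ppi = self.make_ppi({"a": ["b", "x"], "b": ["x"]})
        tbl = ParalogPairTable.from_records([("a", "b", "WGD")])
        row = sd_similarity(ppi, tbl).iloc[0]
        assert row["n_partners_1"] == 1 and row["n_partners_2"] == 1
        assert row["similarity"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_set_arithmetic_on_random_ppi(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"p{i}" for i in range(200)]
        edges = set()
        while len(edges) < 1200:
            i, j = rng.integers(0, 200, 2)
            if i != j:
                edges.add((nodes[min(i, j)], nodes[max(i, j)]))
        ppi = InteractionNetwork.from_edges((a, b, 1.0) for a, b in edges)
        pairs = []
        while len(pairs) < 50:
            i, j = rng.integers(0, 200, 2)
            if i != j and tuple(sorted((nodes[i], nodes[j]))) not in pairs:
                pairs.append(tuple(sorted((nodes[i], nodes[j]))))
        tbl = ParalogPairTable.from_records([(a, b, "WGD") for a, b in pairs])
        out = sd_similarity(ppi, tbl)
        nb = ppi.neighbors
        for r in out.itertuples(index=False):
            a = nb.get(r.gene1, set()) - {r.gene1, r.gene2}
            b = nb.get(r.gene2, set()) - {r.gene1, r.gene2}
            expected = dice(a, b)
            if math.isnan(expected):
                assert math.isnan(r.similarity)
            else:
                assert abs(r.similarity - expected) < 1e-12

    def test_grn_auto_role(self):
        net = RegulatoryNetwork.from_edges(
            [("a", "x", 1.0), ("b", "x", 1.0), ("a", "y", 1.0), ("r", "g1", 1.0),
             ("r", "g2", 1.0)]
        )
        tbl = ParalogPairTable.from_records([("a", "b", "WGD"), ("g1", "g2", "SSD")])
        out = sd_similarity(net, tbl).set_index("gene1")
        # regulators compared by targets: {x,y} vs {x} -> 2/3
        assert out.loc["a", "similarity"] == pytest.approx(2 / 3)
        # targets compared by regulators: {r} vs {r} -> 1
        assert out.loc["g1", "similarity"] == pytest.approx(1.0)


class TestDegreeCompare:
    def make(self, wgd_degs, ssd_degs):
        edges = []
        pairs = []
        idx = 0
        for mode, degs in (("WGD", wgd_degs), ("SSD", ssd_degs)):
            for d in degs:
                g1, g2 = f"{mode}a{idx}", f"{mode}b{idx}"
                idx += 1
                for k in range(d):
                    edges.append((g1, f"x{idx}_{k}", 1.0))
                    edges.append((g2, f"y{idx}_{k}", 1.0))
                pairs.append((g1, g2, mode))
        return (
            InteractionNetwork.from_edges(edges),
            ParalogPairTable.from_records(pairs),
        )

    def test_identical_samples_zero_effect(self):
        net, tbl = self.make([3, 3, 3], [3, 3, 3])
        res = degree_compare(net, tbl)
        assert res["rank_biserial"] == pytest.approx(0.0, abs=1e-9)

    def test_separated_samples_extreme_effect(self):
        net, tbl = self.make([10, 11, 12], [2, 3, 4])
        res = degree_compare(net, tbl)
        assert abs(res["rank_biserial"]) == pytest.approx(1.0)

    def test_u_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        wgd = rng.integers(1, 8, 12).tolist()
        ssd = rng.integers(1, 8, 15).tolist()
        net, tbl = self.make(wgd, ssd)
        res = degree_compare(net, tbl)
        x = sorted(wgd * 2)  # both pair genes carry degree d
        y = sorted(ssd * 2)
        assert res["U"] == pytest.approx(mwu_pair_counting(x, y))

    def test_mode_with_too_few_genes_errors(self):
        net = InteractionNetwork.from_edges([("a", "x", 1.0)])
        tbl = ParalogPairTable.from_records([("a", "b", "WGD"), ("c", "d", "SSD")])
        with pytest.raises(ValidationError):
            degree_compare(net, tbl)
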
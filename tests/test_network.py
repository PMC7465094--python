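"""Network assembly, interaction typing, hubness, degree distribution."""

import itertools

import networkx as nx
import numpy as np
import pytest

from idopnet.benchmarks import embedded_network_truth
from idopnet.network import (
    IdopNetwork,
    assemble,
    classify_pair,
    degree_powerlaw_check,
    hubness,
    hubness_table,
    interaction_table,
)
from idopnet.qdode import NetworkModelConfig, _System, _fit_target, fit_group_qdode
from idopnet.simulate import generate_cohort


@pytest.fixture(scope="module")
def fitted_system():
    truth, nodes = embedded_network_truth(0)
    coh = generate_cohort(truth, seed=1000)
    ds = coh.dataset.group("high")
    fits = fit_group_qdode(
        ds.subset_genes(nodes), NetworkModelConfig(), group="high", ei=ds.ei
    )
    return truth, fits


class TestAssemble:
    def test_regulator_free_fits_give_edgeless_network(self):
        truth, nodes = embedded_network_truth(1, regulated=())
        coh = generate_cohort(truth, seed=2)
        ds = coh.dataset.group("high")
        sub = ds.subset_genes(nodes)
        sys_ = _System(
            sub.values.to_numpy(), ds.ei.to_numpy(), sub.gene_ids, NetworkModelConfig()
        )
        fits = {n: _fit_target(sys_, n, []) for n in nodes}
        net = assemble(fits, group="high")
        assert net.graph.number_of_edges() == 0
        for n in nodes:
            assert net.node_value(n) == pytest.approx(
                float(fits[n].P_ind.mean()), rel=1e-12
            )

    def test_two_ei_values_share_topology_but_not_weights(self, fitted_system):
        truth, fits = fitted_system
        any_fit = next(iter(fits.values()))
        e1 = float(any_fit.ei[len(any_fit.ei) // 3])
        e2 = float(any_fit.ei[2 * len(any_fit.ei) // 3])
        n1 = assemble(fits, at=e1, eps_w=0.0)
        n2 = assemble(fits, at=e2, eps_w=0.0)
        assert set(n1.graph.edges) == set(n2.graph.edges)
        w1 = [n1.graph.edges[e]["weight"] for e in n1.graph.edges]
        w2 = [n2.graph.edges[e]["weight"] for e in n2.graph.edges]
        assert not np.allclose(w1, w2)

    def test_out_of_grid_ei_clamped_with_warning(self, fitted_system, caplog):
        truth, fits = fitted_system
        with caplog.at_level("WARNING"):
            net = assemble(fits, at=1e9)
        assert any("clamping" in r.message for r in caplog.records)
        assert isinstance(net, IdopNetwork)

    def test_edge_recovery_against_truth(self, fitted_system):
        truth, fits = fitted_system
        net = assemble(fits, group="high")
        true_edges = {(r.regulator, r.target) for r in truth.regulations}
        found = set(net.graph.edges)
        assert true_edges <= found
        for r in truth.regulations:
            assert net.graph.edges[r.regulator, r.target]["sign"] == r.sign

    def test_no_self_loops(self, fitted_system):
        truth, fits = fitted_system
        net = assemble(fits, group="high")
        assert all(u != v for u, v in net.graph.edges)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "ab,ba,expected",
        [
            (0.5, 0.3, "synergism"),
            (-0.5, -0.3, "antagonism"),
            (0.5, 0.0, "directional synergism"),
            (0.0, 0.5, "directional synergism"),
            (-0.5, 0.0, "directional antagonism"),
            (0.0, -0.5, "directional antagonism"),
            (0.5, -0.3, "altruism/aggression"),
            (-0.5, 0.3, "altruism/aggression"),
            (0.0, 0.0, "none"),
        ],
    )
    def test_rule_table(self, ab, ba, expected):
        assert classify_pair(ab, ba, eps=0.0) == expected

    def test_enumeration_oracle_over_all_sign_patterns(self):
        """Exhaustive enumeration of the 9 sign patterns against a
        straight reimplementation of the rule."""

        def oracle(sa, sb):
            pair = {sa, sb}
            if pair == {1}:
                return "synergism"
            if pair == {-1}:
                return "antagonism"
            if pair == {1, 0}:
                return "directional synergism"
            if pair == {-1, 0}:
                return "directional antagonism"
            if pair == {1, -1}:
                return "altruism/aggression"
            return "none"

        for sa, sb in itertools.product((-1, 0, 1), repeat=2):
            assert classify_pair(float(sa), float(sb), eps=0.0) == oracle(sa, sb)

    def test_eps_thresholds_small_effects(self):
        assert classify_pair(0.5, 1e-9, eps=1e-6) == "directional synergism"
        assert classify_pair(1e-9, -1e-9, eps=1e-6) == "none"

    def test_symmetry_under_pair_swap(self):
        for ab, ba in [(0.5, 0.3), (0.5, -0.3), (0.0, 0.4), (-0.2, 0.0)]:
            assert classify_pair(ab, ba) == classify_pair(ba, ab)

    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(1.0, 1.0, eps=-1.0)


class TestHubness:
    def _star(self):
        G = nx.DiGraph()
        for i in range(5):
            G.add_edge("hub", f"leaf{i}", weight=1.0, sign=1)
        return IdopNetwork(G, group="high", context="grid-mean")

    def test_star_center_and_leaf(self):
        net = self._star()
        assert hubness(net, "hub") == (5.0, 0.0)
        assert hubness(net, "leaf0") == (0.0, 1.0)

    def test_total_out_strength_equals_total_in_strength(self, fitted_system):
        truth, fits = fitted_system
        net = assemble(fits, group="high")
        table = hubness_table(net)
        assert table["out_strength"].sum() == pytest.approx(
            table["in_strength"].sum(), rel=1e-12
        )

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            hubness(self._star(), "nope")


class TestInteractionTable:
    def test_pair_types_are_valid_and_true_edges_directional(self, fitted_system):
        truth, fits = fitted_system
        net = assemble(fits, group="high")
        table = interaction_table(net)
        assert set(table["type"]) <= {
            "synergism",
            "antagonism",
            "directional synergism",
            "directional antagonism",
            "altruism/aggression",
            "none",
        }
        # the promoting true edge is one-sided in truth
        row = table[
            (table["node_a"] == "m1g0") & (table["node_b"] == "m2g0")
        ].iloc[0]
        assert row["type"] == "directional synergism"


class TestDegreePowerlaw:
    def test_exact_inverse_square_degrees(self):
        # build a graph whose degree frequencies follow d**-2 exactly
        G = nx.DiGraph()
        node = 0
        for d in range(1, 9):
            count = max(1, round(512 / d**2))
            for _ in range(count):
                for k in range(d):
                    G.add_edge(f"n{node}", f"aux{node}_{k}", weight=1.0, sign=1)
                node += 1
        net = IdopNetwork(G, group="x", context="grid-mean")
        res = degree_powerlaw_check(net)
        assert not res.inconclusive

    def test_log_log_regression_matches_numpy_oracle(self):
        rng = np.random.default_rng(0)
        G = nx.DiGraph()
        node = 0
        for d in (1, 2, 3, 4, 6, 8):
            for _ in range(max(1, int(100 / d**2))):
                targets = rng.choice(1000, size=d, replace=False)
                for t in targets:
                    G.add_edge(f"hub{node}", f"t{t}", weight=1.0, sign=1)
                node += 1
        net = IdopNetwork(G, group="x", context="grid-mean")
        res = degree_powerlaw_check(net)
        deg = np.array([G.in_degree(n) + G.out_degree(n) for n in G.nodes])
        deg = deg[deg > 0]
        vals, counts = np.unique(deg, return_counts=True)
        slope, intercept = np.polyfit(np.log(vals), np.log(counts), 1)
        assert res.exponent == pytest.approx(-slope, abs=1e-10)

    def test_regular_graph_is_inconclusive(self):
        G = nx.DiGraph()
        for i in range(6):
            G.add_edge(f"a{i}", f"b{i}", weight=1.0, sign=1)
        net = IdopNetwork(G, group="x", context="grid-mean")
        assert degree_powerlaw_check(net).inconclusive


class TestExport:
    def test_graphml_and_csv_roundtrip(self, fitted_system, tmp_path):
        truth, fits = fitted_system
        net = assemble(fits, group="high")
        gml = tmp_path / "net.graphml"
        net.write_graphml(gml)
        back = nx.read_graphml(gml)
        assert back.number_of_edges() == net.graph.number_of_edges()
        csv = tmp_path / "edges.csv"
        net.write_edges_csv(csv)
        import pandas as pd

        df = pd.read_csv(csv)
        assert set(df.columns) >= {"regulator", "target", "weight", "sign"}
        assert len(df) == net.graph.number_of_edges()
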
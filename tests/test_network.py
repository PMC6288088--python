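import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coocnet.io_tables import TaxaCountTable
from coocnet.network import (
    NetworkConfig,
    abundance_ratio,
    build_network,
    export_network,
)


def _toy(rng, K=5, n_cil=3, n_gut=2):
    counts = rng.integers(1, 200, size=(K, n_cil + n_gut))
    table = TaxaCountTable(
        [f"t{i}" for i in range(K)],
        [f"c{j}" for j in range(n_cil)] + [f"g{j}" for j in range(n_gut)],
        counts,
    )
    metadata = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "group": ["ciliate"] * n_cil + ["gut"] * n_gut,
            "species_label": ["sp"] * (n_cil + n_gut),
            "country": ["x"] * (n_cil + n_gut),
        }
    )
    return table, metadata


class TestAbundanceRatio:
    def test_equal_group_means_give_one(self):
        counts = np.array([[10, 10, 10, 10], [90, 90, 90, 90]])
        table = TaxaCountTable(["a", "b"], ["c1", "c2", "g1", "g2"], counts)
        md = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "group": ["ciliate", "ciliate", "gut", "gut"],
                "species_label": ["s"] * 4,
                "country": ["x"] * 4,
            }
        )
        assert np.allclose(abundance_ratio(table, md), 1.0)

    def test_taxon_absent_from_gut_stays_finite(self):
        counts = np.array([[10, 10, 0, 0], [90, 90, 100, 100]])
        table = TaxaCountTable(["a", "b"], ["c1", "c2", "g1", "g2"], counts)
        md = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "group": ["ciliate", "ciliate", "gut", "gut"],
                "species_label": ["s"] * 4,
                "country": ["x"] * 4,
            }
        )
        r = abundance_ratio(table, md)
        assert np.isfinite(r).all()
        assert r[0] > 1_000  # present only in ciliate samples

    def test_hand_computed_means_ratio(self):
        counts = np.array([[20, 40, 10, 10], [80, 60, 90, 90]])
        table = TaxaCountTable(["a", "b"], ["c1", "c2", "g1", "g2"], counts)
        md = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "group": ["ciliate", "ciliate", "gut", "gut"],
                "species_label": ["s"] * 4,
                "country": ["x"] * 4,
            }
        )
        eps = 1e-6
        expected = (0.3 + eps) / (0.1 + eps)  # taxon a: mean(0.2, 0.4) vs mean(0.1, 0.1)
        assert abundance_ratio(table, md)[0] == pytest.approx(expected, rel=1e-9)

    def test_missing_group_rejected(self, rng):
        table, md = _toy(rng)
        md["group"] = "ciliate"
        with pytest.raises(ValueError, match="non-empty"):
            abundance_ratio(table, md)


class TestBuildNetwork:
    def test_all_insignificant_gives_no_edges(self, rng):
        table, md = _toy(rng)
        rho = np.full((5, 5), 0.9)
        np.fill_diagonal(rho, 1.0)
        net = build_network(rho, np.ones((5, 5)), table, md, {})
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 5  # isolated nodes retained

    def test_threshold_boundary_is_strict(self, rng):
        table, md = _toy(rng)
        rho = np.eye(5)
        rho[0, 1] = rho[1, 0] = 0.5       # exactly at the threshold: excluded
        rho[2, 3] = rho[3, 2] = 0.5001    # strictly above: included
        p = np.full((5, 5), 0.001)
        net = build_network(rho, p, table, md, {})
        assert not net.has_edge("t0", "t1")
        assert net.has_edge("t2", "t3")

    def test_matches_brute_force_pair_scan(self, rng):
        table, md = _toy(rng)
        m = rng.uniform(-1, 1, size=(5, 5))
        rho = (m + m.T) / 2
        np.fill_diagonal(rho, 1.0)
        p = rng.uniform(0, 0.2, size=(5, 5))
        p = (p + p.T) / 2
        cfg = NetworkConfig(r_threshold=0.4, p_threshold=0.05)
        net = build_network(rho, p, table, md, {}, cfg)
        expected = {
            (f"t{i}", f"t{j}")
            for i in range(5)
            for j in range(i + 1, 5)
            if abs(rho[i, j]) > 0.4 and p[i, j] < 0.05
        }
        assert {tuple(sorted(e)) for e in net.edges} == expected

    def test_edge_count_monotone_in_thresholds(self, rng):
        table, md = _toy(rng, K=10)
        m = rng.uniform(-1, 1, size=(10, 10))
        rho = (m + m.T) / 2
        np.fill_diagonal(rho, 1.0)
        p = rng.uniform(0, 1, size=(10, 10))
        p = (p + p.T) / 2
        edges = [
            build_network(
                rho, p, table, md, {}, NetworkConfig(r_threshold=r, p_threshold=pt)
            ).number_of_edges()
            for r, pt in [(0.1, 0.8), (0.3, 0.8), (0.5, 0.8), (0.5, 0.4), (0.5, 0.1)]
        ]
        assert edges == sorted(edges, reverse=True)

    def test_node_attributes_filled(self, rng):
        table, md = _toy(rng)
        taxonomy = {"t0": "Proteobacteria"}
        net = build_network(np.eye(5), np.ones((5, 5)), table, md, taxonomy)
        assert net.nodes["t0"]["phylum"] == "Proteobacteria"
        assert net.nodes["t1"]["phylum"] == "Unclassified"
        assert 0 < net.nodes["t0"]["abundance"] < 1
        assert "group_ratio" in net.nodes["t0"]

    def test_misaligned_matrices_rejected(self, rng):
        table, md = _toy(rng)
        with pytest.raises(ValueError, match="misaligned"):
            build_network(np.eye(4), np.ones((4, 4)), table, md, {})


class TestExportNetwork:
    def test_graphml_round_trip(self, rng, tmp_path):
        table, md = _toy(rng)
        rho = np.eye(5)
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            rho[i, j] = rho[j, i] = 0.8 if i != 3 else -0.8
        p = np.full((5, 5), 0.001)
        net = build_network(rho, p, table, md, {"t0": "Bacteroidetes"})
        gml = tmp_path / "net.graphml"
        tsv = tmp_path / "edges.tsv"
        export_network(net, gml, tsv)
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == net.number_of_nodes()
        assert back.number_of_edges() == net.number_of_edges() == 3
        assert back.nodes["t0"]["phylum"] == "Bacteroidetes"
        edges = pd.read_csv(tsv, sep="\t")
        assert len(edges) == 3
        rhos = {
            tuple(sorted((r.taxon_a, r.taxon_b))): r.rho for r in edges.itertuples()
        }
        assert rhos[("t3", "t4")] == pytest.approx(-0.8)

    def test_empty_network_exports_cleanly(self, rng, tmp_path):
        table, md = _toy(rng)
        net = build_network(np.eye(5), np.ones((5, 5)), table, md, {})
        gml = tmp_path / "empty.graphml"
        export_network(net, gml)
        back = nx.read_graphml(gml)
        assert back.number_of_edges() == 0
        assert back.number_of_nodes() == 5
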
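"""File formats, configuration validation, and the pipeline driver."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from miconet import PipelineConfig
from miconet.io import (
    mni_to_graph,
    read_biom_json,
    read_count_table,
    read_network,
    write_biom_json,
    write_count_table,
    write_network,
)
from miconet.pipeline import run_pipeline
from miconet.population import MniNetwork
from miconet.tables import TableValidationError


class TestCountTableIO:
    def test_tsv_round_trip(self, small_table, tmp_path):
        c, m = tmp_path / "c.tsv", tmp_path / "m.tsv"
        write_count_table(small_table, c, m)
        back = read_count_table(c, m)
        assert back.counts.equals(small_table.counts)
        assert back == small_table

    def test_negative_count_rejected_with_cell_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tt1\tt2\ns1\t5\t-3\n")
        with pytest.raises(TableValidationError, match=r"s1.*t2"):
            read_count_table(p)

    def test_non_integer_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tt1\ns1\t2.5\n")
        with pytest.raises(TableValidationError, match="non-integer"):
            read_count_table(p)

    def test_metadata_must_cover_every_sample(self, small_table, tmp_path):
        c, m = tmp_path / "c.tsv", tmp_path / "m.tsv"
        write_count_table(small_table, c, m)
        meta = pd.read_csv(m, sep="\t", index_col=0).iloc[:-1]
        meta.to_csv(m, sep="\t")
        with pytest.raises(TableValidationError, match="missing"):
            read_count_table(c, m)

    def test_biom_json_round_trip(self, small_table, tmp_path):
        p = tmp_path / "table.biom.json"
        write_biom_json(small_table, p)
        back = read_biom_json(p)
        assert back.counts.equals(small_table.counts)
        assert list(back.metadata["timepoint"]) == list(
            small_table.metadata["timepoint"].astype(str)
        )


class TestNetworkIO:
    def _net(self):
        g = nx.Graph()
        g.add_nodes_from(["c", "a", "b"])
        g.add_edge("b", "a", weight=0.123456789012, stability=0.9)
        g.add_edge("c", "b", weight=-0.5, stability=1.0)
        return g

    def test_graphml_round_trip_preserves_weights(self, tmp_path):
        p = tmp_path / "net.graphml"
        write_network(self._net(), p)
        back = read_network(p)
        assert set(back.nodes) == {"a", "b", "c"}
        assert back.edges["a", "b"]["weight"] == pytest.approx(
            0.123456789012, abs=1e-12
        )

    def test_identical_networks_serialize_identically(self, tmp_path):
        g1 = self._net()
        g2 = nx.Graph()
        g2.add_edge("c", "b", weight=-0.5, stability=1.0)
        g2.add_edge("a", "b", weight=0.123456789012, stability=0.9)
        p1, p2 = tmp_path / "1.graphml", tmp_path / "2.graphml"
        write_network(g1, p1)
        write_network(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_network_valid_graphml(self, tmp_path):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        p = tmp_path / "empty.graphml"
        write_network(g, p)
        back = read_network(p)
        assert set(back.nodes) == {"x", "y"} and back.number_of_edges() == 0

    def test_edgelist_sorted_pairs(self, tmp_path):
        p = tmp_path / "net.tsv"
        write_network(self._net(), p)
        write_network(self._net(), p, format="edgelist_tsv")
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "taxonA\ttaxonB\tweight"
        pairs = [tuple(l.split("\t")[:2]) for l in lines[1:]]
        assert pairs == sorted(pairs)
        assert all(a < b for a, b in pairs)

    def test_mni_edges_carry_status(self, tmp_path):
        mni = MniNetwork(
            sample_id="s1",
            gained={("a", "b"): 0.4},
            lost={("b", "c"): 0.1},
            delta_weights={("c", "d"): 0.2},
            nodes=["a", "b", "c", "d"],
        )
        p = tmp_path / "mni.graphml"
        write_network(mni, p)
        back = read_network(p)
        statuses = {tuple(sorted((u, v))): d["status"] for u, v, d in back.edges(data=True)}
        assert statuses == {
            ("a", "b"): "gained",
            ("b", "c"): "lost",
            ("c", "d"): "changed",
        }
        assert mni_to_graph(mni).number_of_nodes() == 4


class TestConfig:
    def test_defaults_are_study_settings(self):
        cfg = PipelineConfig()
        assert cfg.rel_abund_min == 1e-4
        assert cfg.prevalence_min == 0.37
        assert cfg.rarefaction_depth == 50_000
        assert cfg.bootstrap_n == 1000
        assert cfg.bootstrap_fraction == 0.8

    def test_invalid_threshold_rejected_before_running(self):
        with pytest.raises(ValueError):
            PipelineConfig(prevalence_min=1.1)

    def test_yaml_round_trip_and_stable_hash(self, tmp_path):
        cfg = PipelineConfig(seed=7, n_subsamples=13)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = PipelineConfig.from_yaml(p)
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()
        assert PipelineConfig().config_hash() != cfg.config_hash()

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("not_a_setting: 1\n")
        with pytest.raises(ValueError, match="unknown"):
            PipelineConfig.from_yaml(p)


class TestPipeline:
    def test_full_run_writes_all_stages(self, small_table, tmp_path):
        cfg = PipelineConfig(seed=11, n_subsamples=10, out_dir=str(tmp_path / "run"))
        manifest = run_pipeline(small_table, cfg)
        names = [s["stage"] for s in manifest.stages]
        assert names == ["input", "mnp", "mni", "metrics", "compare"]
        out = tmp_path / "run"
        for f in ("mnp.graphml", "mni_metrics.csv", "group_comparison.csv", "manifest.json"):
            assert (out / f).exists()
        saved = json.loads((out / "manifest.json").read_text())
        assert saved["config_hash"] == cfg.config_hash()
        metrics = pd.read_csv(out / "mni_metrics.csv")
        assert len(metrics) == small_table.n_samples

    def test_rerun_reproduces_checksums(self, small_table, tmp_path):
        def run(d):
            cfg = PipelineConfig(seed=11, n_subsamples=10, out_dir=str(d))
            return run_pipeline(small_table, cfg)

        m1 = run(tmp_path / "a")
        m2 = run(tmp_path / "b")
        for s1, s2 in zip(m1.stages, m2.stages):
            c1 = {k.split("/")[-1]: v for k, v in s1["outputs"].items()}
            c2 = {k.split("/")[-1]: v for k, v in s2["outputs"].items()}
            assert c1 == c2
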
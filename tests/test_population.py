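"""Population networks, leave-one-out single-sample networks, bootstrap
ensembles."""

import numpy as np
import pandas as pd
import pytest

from miconet import CohortDesign, PipelineConfig, clr_transform, compute_all_mnis, compute_mni, compute_mnp
from miconet.inference import neighborhood_fit
from miconet.population import bootstrap_mnp, subtract_networks
from miconet.synthetic import make_true_model, sample_counts
from miconet.tables import CountTable


def _edges(g):
    return {tuple(sorted(e)) for e in g.edges}


def _weights(g):
    return {tuple(sorted((u, v))): d["weight"] for u, v, d in g.edges(data=True)}


class TestComputeMnp:
    def test_pipeline_composition_and_determinism(self, small_table, fast_config):
        r1 = compute_mnp(small_table, fast_config)
        r2 = compute_mnp(small_table, fast_config)
        assert set(r1.network.nodes) == set(r1.filtered.taxon_ids)
        assert _edges(r1.network) == _edges(r2.network)
        assert _weights(r1.network) == _weights(r2.network)
        assert r1.stars.selected_lambda == r2.stars.selected_lambda

    def test_too_few_samples_rejected(self, small_table, fast_config):
        tiny = small_table.select_samples(small_table.sample_ids[:3])
        with pytest.raises(ValueError):
            compute_mnp(tiny, fast_config)

    def test_duplicated_table_same_point_fit_at_fixed_lambda(self, small_table):
        """Duplicating every sample leaves standardized moments unchanged, so
        the point estimate at a fixed penalty is identical."""
        clr = clr_transform(small_table)
        doubled = CountTable(
            counts=pd.concat(
                [small_table.counts, small_table.counts.set_axis(
                    [s + "_dup" for s in small_table.sample_ids])]
            ),
            metadata=pd.concat(
                [small_table.metadata, small_table.metadata.set_axis(
                    [s + "_dup" for s in small_table.sample_ids])]
            ),
        )
        clr2 = clr_transform(doubled)
        lam = 0.3
        b1 = neighborhood_fit(clr, lam)
        b2 = neighborhood_fit(clr2, lam)
        assert np.allclose(b1, b2, atol=1e-6)


class TestMni:
    def test_reconstruction_identity_for_every_sample(self, small_table, fast_config):
        """MNP(all \\ i) patched with MNI_i reproduces MNP(all) exactly on
        edge sets and to 1e-8 on weights, for all 20 samples."""
        mnp = compute_mnp(small_table, fast_config)
        from miconet.population import _loo_network

        for sid in small_table.sample_ids:
            mni = compute_mni(small_table, sid, fast_config, mnp=mnp)
            loo = _loo_network(mnp, sid, fast_config)
            patched = mni.patch(loo)
            assert _edges(patched) == _edges(mnp.network)
            w_p, w_f = _weights(patched), _weights(mnp.network)
            assert all(abs(w_p[e] - w_f[e]) < 1e-8 for e in w_f)

    def test_gained_and_lost_disjoint(self, small_table, fast_config):
        mni = compute_mni(small_table, small_table.sample_ids[0], fast_config)
        assert not (set(mni.gained) & set(mni.lost))

    def test_absent_sample_rejected(self, small_table, fast_config):
        with pytest.raises(KeyError):
            compute_mni(small_table, "nope", fast_config)

    def test_one_mni_per_sample(self, small_table, fast_config):
        mnis = compute_all_mnis(small_table, fast_config)
        assert sorted(mnis) == sorted(small_table.sample_ids)
        assert all(m.sample_id == s for s, m in mnis.items())

    def test_duplicate_samples_have_identical_mnis(self, fast_config):
        """Removing either copy of a duplicated sample leaves the same data,
        so the two MNIs coincide exactly (pinned-lambda mode)."""
        model = make_true_model(12, "erdos_renyi", edge_density=0.12, seed=5)
        design = CohortDesign(
            n_baseline=6, n_post=6,
            depth_mean=50_000, depth_min=50_000, depth_max=50_000, seed=5,
        )
        table = sample_counts(model, design)
        dup = table.counts.iloc[[0]].set_axis(["dup"])
        counts = pd.concat([table.counts, dup])
        meta = pd.concat(
            [table.metadata, table.metadata.iloc[[0]].set_axis(["dup"])]
        )
        tdup = CountTable(counts=counts, metadata=meta)
        mnp = compute_mnp(tdup, fast_config)
        mni_a = compute_mni(tdup, table.sample_ids[0], fast_config, mnp=mnp)
        mni_b = compute_mni(tdup, "dup", fast_config, mnp=mnp)
        assert set(mni_a.gained) == set(mni_b.gained)
        assert set(mni_a.lost) == set(mni_b.lost)
        for e in mni_a.delta_weights:
            assert mni_a.delta_weights[e] == pytest.approx(
                mni_b.delta_weights[e], abs=1e-8
            )

    def test_leave_one_out_networks_population_dominated(self, fast_config):
        """With n >= 50 samples the MNP barely moves when one sample is
        dropped: median Jaccard similarity of edge sets > 0.5."""
        model = make_true_model(15, "erdos_renyi", edge_density=0.15, seed=8)
        design = CohortDesign(
            n_baseline=25, n_post=25,
            depth_mean=50_000, depth_min=50_000, depth_max=50_000, seed=8,
        )
        table = sample_counts(model, design)
        mnp = compute_mnp(table, fast_config)
        from miconet.population import _loo_network

        full = _edges(mnp.network)
        jac = []
        for sid in table.sample_ids[:8]:
            loo = _edges(_loo_network(mnp, sid, fast_config))
            union = full | loo
            jac.append(len(full & loo) / len(union) if union else 1.0)
        assert np.median(jac) > 0.5

    def test_summary_graph_statuses(self, small_table, fast_config):
        mni = compute_mni(small_table, small_table.sample_ids[1], fast_config)
        g = mni.summary_graph()
        statuses = {d["status"] for _, _, d in g.edges(data=True)}
        assert statuses <= {"gained", "lost", "changed"}


class TestSubtraction:
    def test_subtract_networks_partition(self):
        import networkx as nx

        full = nx.Graph()
        full.add_edge("a", "b", weight=0.5)
        full.add_edge("b", "c", weight=0.2)
        reduced = nx.Graph()
        reduced.add_edge("b", "c", weight=0.1)
        reduced.add_edge("c", "d", weight=0.3)
        mni = subtract_networks(full, reduced, "s")
        assert set(mni.gained) == {("a", "b")}
        assert set(mni.lost) == {("c", "d")}
        assert mni.delta_weights[("b", "c")] == pytest.approx(0.1)
        patched = mni.patch(reduced)
        assert _edges(patched) == _edges(full)
        assert _weights(patched)[("b", "c")] == pytest.approx(0.2)


class TestBootstrap:
    def test_replicate_count_and_subset_size(self, small_table, fast_config):
        ens = bootstrap_mnp(small_table, n_networks=10, subsample_fraction=0.8,
                            config=fast_config)
        assert ens.n_networks == 10
        assert len(ens.values("edge_number")) == 10

    def test_full_fraction_gives_zero_variance(self, small_table, fast_config):
        ens = bootstrap_mnp(small_table, n_networks=5, subsample_fraction=1.0,
                            config=fast_config)
        for metric in ("mean_degree", "edge_number", "robustness"):
            assert np.var(ens.values(metric)) == 0.0

    def test_same_seed_identical_ensembles(self, small_table, fast_config):
        e1 = bootstrap_mnp(small_table, n_networks=6, config=fast_config)
        e2 = bootstrap_mnp(small_table, n_networks=6, config=fast_config)
        pd.testing.assert_frame_equal(e1.metrics, e2.metrics)

    def test_sample_order_does_not_change_metric_multiset(self, small_table, fast_config):
        shuffled = small_table.select_samples(small_table.sample_ids[::-1])
        e1 = bootstrap_mnp(small_table, n_networks=8, config=fast_config)
        e2 = bootstrap_mnp(shuffled, n_networks=8, config=fast_config)
        v1 = sorted(e1.values("edge_number"))
        v2 = sorted(e2.values("edge_number"))
        assert v1 == v2
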
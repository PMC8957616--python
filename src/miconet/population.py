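"""Population-level (MNP) and single-sample (MNI) networks.

The microbiome network of the population (MNP) is the full pipeline —
taxon filtering, optional rarefaction, CLR, neighbourhood lasso with StARS
selection — applied to all samples of a group. The microbiome network of an
individual (MNI) is the signed difference between the MNP of the whole set
and the MNP re-fitted with that individual's sample removed: edges gained,
edges lost, and weight changes on shared edges. By default the leave-one-out
fit is pinned to the full-data selected penalty so an MNI reflects the
removed sample rather than re-selection noise.

A bootstrap ensemble re-infers the network on random 80% subsets of
samples and records a MetricSet per replicate, supporting distributional
comparison of network metrics between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import child_rng
from .config import PipelineConfig
from .inference import StarsResult, infer_network, stars_select
from .metrics import MetricSet, basic_metrics, fragility_curve, metric_set, natural_connectivity, robustness_auc
from .preprocess import clr_transform, filter_taxa, rarefy
from .tables import ClrMatrix, CountTable

Edge = tuple[str, str]

#: weight changes below this are numerical noise, not a "changed" edge
DELTA_TOL = 1e-8


def _edge(u, v) -> Edge:
    return (u, v) if str(u) <= str(v) else (v, u)


def _edge_weights(g: nx.Graph) -> dict[Edge, float]:
    return {_edge(u, v): float(d.get("weight", 0.0)) for u, v, d in g.edges(data=True)}


@dataclass
class MnpResult:
    """MNP with the intermediate products needed for leave-one-out fits."""

    network: nx.Graph
    stars: StarsResult
    clr: ClrMatrix
    filtered: CountTable


@dataclass
class MniNetwork:
    """Signed difference MNP(all) - MNP(all \\ sample)."""

    sample_id: str
    gained: dict[Edge, float]        # in MNP(all), absent from the LOO fit
    lost: dict[Edge, float]          # in the LOO fit, absent from MNP(all)
    delta_weights: dict[Edge, float]  # w_all - w_loo on shared edges
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.gained) & set(self.lost):
            raise ValueError("gained and lost edge sets must be disjoint")

    def summary_graph(self, tol: float = DELTA_TOL) -> nx.Graph:
        """Perturbation graph for metric comparisons.

        Edges are the gained/lost support plus shared edges whose weight
        moved by more than ``tol``; weights are |delta| (for gained/lost,
        the full weight in the parent where the edge exists). Nodes are
        the incident taxa only.
        """
        g = nx.Graph()
        for e, w in self.gained.items():
            g.add_edge(*e, weight=abs(w), status="gained", delta_weight=float(w))
        for e, w in self.lost.items():
            g.add_edge(*e, weight=abs(w), status="lost", delta_weight=float(-w))
        for e, d in self.delta_weights.items():
            if abs(d) > tol:
                g.add_edge(*e, weight=abs(d), status="changed", delta_weight=float(d))
        return g

    def metric_set(
        self,
        ordering: str = "betweenness_then_degree",
        response: str = "lcc_fraction",
        tol: float = DELTA_TOL,
    ) -> MetricSet:
        """Per-sample summary metrics of the perturbation.

        Degree/edge/node counts are taken on the perturbation support
        (taxa incident to a gained/lost/changed edge), while robustness and
        natural connectivity are assessed over the full taxon set (isolated
        taxa included): connectivity robustness is a community-level
        property, and judging it on the support alone would reward small
        concentrated perturbations over large ones.
        """
        support = self.summary_graph(tol=tol)
        ms = basic_metrics(support)
        community = support.copy()
        community.add_nodes_from(self.nodes)
        ms.natural_connectivity_initial = natural_connectivity(community)
        if community.number_of_nodes() >= 2:
            curve = fragility_curve(community, ordering=ordering)
            ms.robustness = robustness_auc(curve, response=response)
            ms.fragility = 1.0 - ms.robustness
        else:
            ms.robustness, ms.fragility = 0.0, 1.0
        return ms

    def patch(self, loo_network: nx.Graph) -> nx.Graph:
        """Reconstruct MNP(all) from the leave-one-out network and this MNI."""
        g = loo_network.copy()
        for e, w in self.lost.items():
            g.remove_edge(*e)
        for e, w in self.gained.items():
            g.add_edge(*e, weight=w)
        for e, d in self.delta_weights.items():
            g.edges[e]["weight"] = g.edges[e]["weight"] + d
        return g


def preprocess_for_inference(
    table: CountTable, config: PipelineConfig
) -> tuple[CountTable, ClrMatrix]:
    """filter -> (optional rarefy) -> CLR, per the configuration."""
    filtered = filter_taxa(
        table,
        rel_abund_min=config.rel_abund_min,
        prevalence_min=config.prevalence_min,
        abundance_stat=config.abundance_stat,
    )
    if config.rarefy_enabled:
        filtered = rarefy(filtered, depth=config.rarefaction_depth, seed=config.seed)
    return filtered, clr_transform(filtered, pseudocount=config.pseudocount)


def compute_mnp(table: CountTable, config: PipelineConfig | None = None) -> MnpResult:
    """Full-pipeline population network; deterministic given config.seed."""
    config = config or PipelineConfig()
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for population inference")
    filtered, clr = preprocess_for_inference(table, config)
    stars = stars_select(
        clr,
        n_subsamples=config.n_subsamples,
        subsample_fraction=config.subsample_fraction,
        stability_threshold=config.stars_threshold,
        seed=config.seed,
        symmetrization=config.symmetrization,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    net = infer_network(clr, stars=stars, symmetrization=config.symmetrization)
    return MnpResult(network=net, stars=stars, clr=clr, filtered=filtered)


def _loo_network(
    mnp: MnpResult, sample_id: str, config: PipelineConfig
) -> nx.Graph:
    """Leave-one-out fit, on the full-data taxon set.

    In pinned mode (default) the full-data selected lambda is reused and
    the fit is a deterministic point estimate; in free mode StARS re-selects
    on the reduced sample set.
    """
    loo_table = mnp.filtered.drop_sample(sample_id)
    clr = clr_transform(loo_table, pseudocount=config.pseudocount)
    if config.mni_lambda_mode == "pinned":
        return infer_network(
            clr, lam=mnp.stars.selected_lambda, symmetrization=config.symmetrization
        )
    stars = stars_select(
        clr,
        n_subsamples=config.n_subsamples,
        subsample_fraction=config.subsample_fraction,
        stability_threshold=config.stars_threshold,
        seed=config.seed,
        symmetrization=config.symmetrization,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    return infer_network(clr, stars=stars, symmetrization=config.symmetrization)


def subtract_networks(
    full: nx.Graph, reduced: nx.Graph, sample_id: str
) -> MniNetwork:
    """Signed difference full - reduced as an MniNetwork."""
    w_full = _edge_weights(full)
    w_red = _edge_weights(reduced)
    gained = {e: w for e, w in w_full.items() if e not in w_red}
    lost = {e: w for e, w in w_red.items() if e not in w_full}
    shared = set(w_full) & set(w_red)
    delta = {e: w_full[e] - w_red[e] for e in sorted(shared)}
    nodes = sorted(set(full.nodes) | set(reduced.nodes))
    return MniNetwork(
        sample_id=sample_id, gained=gained, lost=lost, delta_weights=delta, nodes=nodes
    )


def compute_mni(
    table: CountTable,
    sample_id: str,
    config: PipelineConfig | None = None,
    mnp: MnpResult | None = None,
) -> MniNetwork:
    """MNI for one sample: MNP(all) minus MNP(all without the sample)."""
    config = config or PipelineConfig()
    if sample_id not in table.sample_ids:
        raise KeyError(f"sample {sample_id!r} not in table")
    if table.n_samples - 1 < 4:
        raise ValueError("need at least 4 remaining samples")
    if mnp is None:
        mnp = compute_mnp(table, config)
    reduced = _loo_network(mnp, sample_id, config)
    return subtract_networks(mnp.network, reduced, sample_id)


def compute_all_mnis(
    table: CountTable,
    config: PipelineConfig | None = None,
    mnp: MnpResult | None = None,
) -> dict[str, MniNetwork]:
    """One MNI per sample, sharing a single full-data MNP fit."""
    config = config or PipelineConfig()
    if mnp is None:
        mnp = compute_mnp(table, config)
    return {
        s: compute_mni(table, s, config, mnp=mnp) for s in table.sample_ids
    }


@dataclass
class BootstrapEnsemble:
    """Per-replicate network metrics on random sample subsets."""

    n_networks: int
    subsample_fraction: float
    seed: int
    metrics: pd.DataFrame  # long format: replicate, metric, value

    def values(self, metric: str) -> np.ndarray:
        sel = self.metrics[self.metrics["metric"] == metric]
        return sel.sort_values("replicate")["value"].to_numpy()


def bootstrap_mnp(
    table: CountTable,
    n_networks: int = 1000,
    subsample_fraction: float = 0.8,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> BootstrapEnsemble:
    """Metric distribution over networks re-inferred on random 80% subsets.

    Subsets are drawn without replacement from the (sorted) sample ids, so
    the ensemble is invariant to sample order. In pinned mode each replicate
    is a point fit at the full-data StARS lambda; free mode re-runs StARS
    per replicate.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    n = table.n_samples
    m = int(np.floor(subsample_fraction * n))
    if m < 4:
        raise ValueError("subsample size must be >= 4")
    # canonical sample order: the ensemble is invariant to row permutations
    sample_ids = sorted(table.sample_ids)
    table = table.select_samples(sample_ids)
    mnp = compute_mnp(table, config)
    rows = []
    for r in range(n_networks):
        rng = child_rng(seed, "bootstrap", r)
        chosen = [sample_ids[i] for i in rng.choice(n, size=m, replace=False)]
        sub = mnp.filtered.select_samples(chosen)
        clr = clr_transform(sub, pseudocount=config.pseudocount)
        if config.bootstrap_lambda_mode == "pinned":
            net = infer_network(
                clr, lam=mnp.stars.selected_lambda, symmetrization=config.symmetrization
            )
        else:
            stars = stars_select(
                clr,
                n_subsamples=config.n_subsamples,
                subsample_fraction=config.subsample_fraction,
                stability_threshold=config.stars_threshold,
                seed=int(rng.integers(2**31 - 1)),
                symmetrization=config.symmetrization,
                n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            net = infer_network(clr, stars=stars, symmetrization=config.symmetrization)
        ms = metric_set(
            net, ordering=config.attack_ordering, response=config.attack_response
        )
        for k, v in ms.as_dict().items():
            rows.append({"replicate": r, "metric": k, "value": v})
    return BootstrapEnsemble(
        n_networks=n_networks,
        subsample_fraction=subsample_fraction,
        seed=seed,
        metrics=pd.DataFrame(rows),
    )
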
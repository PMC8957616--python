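"""Connectivity, targeted-attack fragility, and robustness scoring.

Metrics are computed on the unweighted topology. Natural connectivity is
the spectral robustness measure NC = ln( (1/n) sum_i exp(mu_i) ) over the
adjacency eigenvalues mu_i; it is 0 for an empty graph and strictly
increases whenever an edge is added. Fragility is simulated by deleting
nodes in decreasing centrality order (betweenness, ties by degree, then
node id) computed once on the intact graph; robustness is the trapezoidal
AUC of the normalized response (largest-connected-component fraction by
default, natural connectivity as an alternative) against the fraction of
nodes removed, and fragility is reported as 1 - robustness. The LCC
response is the default because it makes complete graphs provably maximal:
after k removals any graph is a subgraph of K_{n-k}.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import logsumexp

ORDERINGS = ("betweenness", "degree", "betweenness_then_degree")
RESPONSES = ("natural_connectivity", "lcc_fraction")


@dataclass
class MetricSet:
    """Summary metrics of one network."""

    mean_degree: float
    edge_number: int
    node_number: int
    robustness: float = float("nan")
    fragility: float = float("nan")
    natural_connectivity_initial: float = float("nan")
    flag: str | None = None

    def as_dict(self) -> dict:
        return {
            "mean_degree": self.mean_degree,
            "edge_number": self.edge_number,
            "node_number": self.node_number,
            "robustness": self.robustness,
            "fragility": self.fragility,
            "natural_connectivity_initial": self.natural_connectivity_initial,
        }


@dataclass
class FragilityCurve:
    """Targeted-attack trajectory; step 0 describes the intact graph."""

    removal_order: list
    fraction_removed: np.ndarray
    lcc_size: np.ndarray
    natural_connectivity: np.ndarray
    ordering: str = "betweenness_then_degree"

    def __post_init__(self) -> None:
        if (np.diff(self.lcc_size) > 0).any():
            raise ValueError("largest-component size must be non-increasing")
        if (np.diff(self.fraction_removed) <= 0).any():
            raise ValueError("fraction_removed must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.fraction_removed)

    @property
    def n_nodes(self) -> int:
        return len(self.removal_order)

    def response(self, which: str) -> np.ndarray:
        if which == "natural_connectivity":
            return self.natural_connectivity
        if which == "lcc_fraction":
            # fraction of ALL nodes in the largest component: 1 iff the
            # intact graph is connected; disconnected graphs start lower
            return self.lcc_size / self.n_nodes
        raise ValueError(f"unknown response {which!r}")


def basic_metrics(net: nx.Graph) -> MetricSet:
    """Node count (isolates included), edge count, and mean degree 2E/N."""
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return MetricSet(0.0, 0, 0, flag="empty node set")
    return MetricSet(mean_degree=2.0 * e / n, edge_number=e, node_number=n)


def natural_connectivity(net: nx.Graph) -> float:
    """NC = ln(mean(exp(eigenvalues))) of the unweighted adjacency.

    Computed via logsumexp for numerical stability; an empty graph (all
    eigenvalues 0) gives exactly 0.
    """
    n = net.number_of_nodes()
    if n == 0:
        return 0.0
    if net.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(net, weight=None)
    eigs = np.linalg.eigvalsh(a)
    return float(logsumexp(eigs) - np.log(n))


def _lcc_size(net: nx.Graph) -> int:
    if net.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(net))


def _attack_key(net: nx.Graph, ordering: str) -> dict:
    betw = nx.betweenness_centrality(net) if "betweenness" in ordering else {}
    deg = dict(net.degree())
    if ordering == "betweenness":
        return {v: (betw[v],) for v in net.nodes}
    if ordering == "degree":
        return {v: (deg[v],) for v in net.nodes}
    if ordering == "betweenness_then_degree":
        return {v: (betw[v], deg[v]) for v in net.nodes}
    raise ValueError(f"unknown ordering {ordering!r}; one of {ORDERINGS}")


def fragility_curve(
    net: nx.Graph,
    ordering: str = "betweenness_then_degree",
    recompute: bool = False,
) -> FragilityCurve:
    """Targeted attack: delete nodes in decreasing centrality order.

    By default the ranking keys are computed once on the intact graph
    (static attack); with ``recompute=True`` the keys are re-evaluated
    after every removal. Ties break by the secondary key, then by node id
    ascending. The curve records the largest-component size and natural
    connectivity after each removal, ending at the empty graph.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("fragility needs at least 2 nodes")
    g = net.copy()
    order: list = []
    lcc = [_lcc_size(g)]
    ncs = [natural_connectivity(g)]
    if not recompute:
        keys = _attack_key(g, ordering)
        ranked = sorted(g.nodes, key=lambda v: (tuple(-k for k in keys[v]), str(v)))
    for step in range(n):
        if recompute:
            keys = _attack_key(g, ordering)
            victim = sorted(
                g.nodes, key=lambda v: (tuple(-k for k in keys[v]), str(v))
            )[0]
        else:
            victim = ranked[step]
        g.remove_node(victim)
        order.append(victim)
        lcc.append(_lcc_size(g))
        ncs.append(natural_connectivity(g))
    return FragilityCurve(
        removal_order=order,
        fraction_removed=np.arange(n + 1) / n,
        lcc_size=np.array(lcc),
        natural_connectivity=np.array(ncs),
        ordering=ordering,
    )


def robustness_auc(
    curve: FragilityCurve, response: str = "lcc_fraction"
) -> float:
    """Trapezoidal AUC of the normalized attack response vs fraction removed.

    The LCC response is already a fraction of the node count (for a
    connected graph this equals step-0 normalization, and a disconnected
    graph is rightly scored less robust); natural connectivity is
    normalized by its intact-graph value and returns 0 when that value is
    0 (no edges to lose). AUC lies in [0, 1] for non-increasing responses.
    """
    if curve.n_steps < 2:
        raise ValueError("curve needs at least 2 steps")
    y = curve.response(response).astype(float)
    if response == "natural_connectivity":
        if y[0] == 0:
            return 0.0
        y = y / y[0]
    return float(np.trapezoid(y, curve.fraction_removed))


def metric_set(
    net: nx.Graph,
    ordering: str = "betweenness_then_degree",
    response: str = "lcc_fraction",
) -> MetricSet:
    """Full MetricSet: degree/edge/node counts plus attack robustness."""
    ms = basic_metrics(net)
    ms.natural_connectivity_initial = natural_connectivity(net)
    if net.number_of_nodes() >= 2:
        curve = fragility_curve(net, ordering=ordering)
        ms.robustness = robustness_auc(curve, response=response)
        ms.fragility = 1.0 - ms.robustness
    else:
        ms.robustness = 0.0
        ms.fragility = 1.0
        ms.flag = ms.flag or "fewer than 2 nodes; robustness undefined"
    return ms
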
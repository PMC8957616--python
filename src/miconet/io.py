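"""File I/O: count tables (TSV, BIOM-style JSON), networks (GraphML,
edge-list TSV), metrics and curves (CSV).

All writers emit deterministically ordered output so identical objects
serialize byte-for-byte identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .metrics import FragilityCurve, MetricSet
from .population import MniNetwork
from .tables import CountTable, TableValidationError


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, counts_path, metadata_path) -> None:
    """TSV: first column 'sample_id', remaining columns taxa; metadata TSV
    with sample_id, subject, timepoint."""
    df = table.counts.copy()
    df.index.name = "sample_id"
    df.to_csv(counts_path, sep="\t")
    meta = table.metadata.loc[table.counts.index, ["subject", "timepoint"]].copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_count_table(counts_path, metadata_path=None, format: str = "tsv") -> CountTable:
    """Parse and validate a count table; errors name the offending cell."""
    if format == "biom_json":
        return read_biom_json(counts_path, metadata_path)
    if format != "tsv":
        raise ValueError("format must be 'tsv' or 'biom_json'")
    try:
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableValidationError(f"cannot parse {counts_path}: {exc}") from exc
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(
            {"subject": df.index, "timepoint": "unknown"}, index=df.index
        )
    return CountTable(counts=df, metadata=meta)


def write_biom_json(table: CountTable, path) -> None:
    """Minimal dense BIOM-style JSON (rows = taxa, columns = samples)."""
    payload = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "type": "OTU table",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [table.n_taxa, table.n_samples],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [
            {
                "id": s,
                "metadata": {
                    "subject": str(table.metadata.loc[s, "subject"]),
                    "timepoint": str(table.metadata.loc[s, "timepoint"]),
                },
            }
            for s in table.sample_ids
        ],
        "data": table.counts.to_numpy().T.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_biom_json(path, metadata_path=None) -> CountTable:
    payload = json.loads(Path(path).read_text())
    taxa = [r["id"] for r in payload["rows"]]
    samples = [c["id"] for c in payload["columns"]]
    if payload.get("matrix_type") == "dense":
        data = np.asarray(payload["data"]).T
    else:  # sparse: [row, col, value] triplets
        data = np.zeros((len(samples), len(taxa)))
        for r, c, v in payload["data"]:
            data[c, r] = v
    counts = pd.DataFrame(data.astype(np.int64), index=samples, columns=taxa)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(
            {
                "subject": [
                    (c.get("metadata") or {}).get("subject", c["id"])
                    for c in payload["columns"]
                ],
                "timepoint": [
                    (c.get("metadata") or {}).get("timepoint", "unknown")
                    for c in payload["columns"]
                ],
            },
            index=samples,
        )
    return CountTable(counts=counts, metadata=meta)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _canonical_graph(net: nx.Graph) -> nx.Graph:
    """Copy with nodes and edges in sorted order for stable serialization."""
    g = nx.Graph(**net.graph)
    for v in sorted(net.nodes, key=str):
        g.add_node(v, **net.nodes[v])
    for u, v in sorted(
        (tuple(sorted((str(a), str(b)))) for a, b in net.edges), key=lambda e: e
    ):
        g.add_edge(u, v, **net.edges[u, v])
    return g


def mni_to_graph(mni: MniNetwork) -> nx.Graph:
    """MNI as a graph with status in {gained, lost, changed} per edge."""
    g = mni.summary_graph()
    g.add_nodes_from(mni.nodes)
    g.graph["sample_id"] = mni.sample_id
    return g


def write_network(net: nx.Graph | MniNetwork, path, format: str = "graphml") -> None:
    if isinstance(net, MniNetwork):
        net = mni_to_graph(net)
    g = _canonical_graph(net)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path, infer_numeric_types=True)
    elif format == "edgelist_tsv":
        with open(path, "w") as fh:
            fh.write("taxonA\ttaxonB\tweight\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.12g}\n")
    else:
        raise ValueError("format must be 'graphml' or 'edgelist_tsv'")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# metrics and curves
# ---------------------------------------------------------------------------

def write_metric_set(ms: MetricSet, path) -> None:
    Path(path).write_text(json.dumps(ms.as_dict(), sort_keys=True, indent=2))


def write_fragility_curve(curve: FragilityCurve, path) -> None:
    rows = {
        "step": np.arange(curve.n_steps),
        "node_removed": [""] + [str(v) for v in curve.removal_order],
        "fraction_removed": curve.fraction_removed,
        "lcc_size": curve.lcc_size,
        "natural_connectivity": curve.natural_connectivity,
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def write_adjacency(adjacency: np.ndarray, taxon_ids, path, format: str = "edgelist_tsv") -> None:
    """Ground-truth adjacency as GraphML or edge-list TSV."""
    g = nx.Graph()
    g.add_nodes_from(taxon_ids)
    iu, ju = np.triu_indices(len(taxon_ids), k=1)
    for i, j in zip(iu, ju):
        if adjacency[i, j]:
            g.add_edge(taxon_ids[i], taxon_ids[j], weight=1.0)
    write_network(g, path, format=format)
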
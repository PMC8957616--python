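"""Pipeline driver: chains every stage reproducibly and writes a manifest.

Stages: read -> filter (-> rarefy) -> CLR -> MNP -> per-sample MNIs ->
metrics -> group comparison. Every output embeds the configuration hash;
the manifest records per-stage outputs with checksums so a re-run with the
same config and inputs is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import write_count_table, write_fragility_curve, write_metric_set, write_network
from .metrics import fragility_curve, metric_set
from .population import bootstrap_mnp, compute_all_mnis, compute_mnp
from .stats import bootstrap_mean_test
from .tables import CountTable

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    stages: list[dict] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add_stage(self, name: str, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {str(p): _sha256(p) for p in outputs},
                "time": time.time(),
            }
        )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "software_version": self.software_version,
                    "started": self.started,
                    "finished": self.finished,
                    "stages": self.stages,
                },
                indent=2,
            )
        )


def run_pipeline(
    table: CountTable,
    config: PipelineConfig | None = None,
    bootstrap: bool = False,
) -> RunManifest:
    """Run the full analysis on a count table and write all outputs.

    Group comparison uses the metadata ``timepoint`` labels; MNI summary
    metrics per sample are compared between timepoints with the bootstrap
    mean test. The optional metric bootstrap (1000 networks by default) is
    off unless requested, being by far the most expensive stage.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), software_version=__version__
    )
    manifest.started = time.time()
    config.to_yaml(out / "config.yaml")

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.add_stage(name, outputs)

    state: dict = {}

    def s_input():
        p1, p2 = out / "input_counts.tsv", out / "input_metadata.tsv"
        write_count_table(table, p1, p2)
        return [p1, p2]

    def s_mnp():
        state["mnp"] = compute_mnp(table, config)
        p1, p2 = out / "mnp.graphml", out / "mnp_filtered_counts.tsv"
        write_network(state["mnp"].network, p1)
        write_count_table(state["mnp"].filtered, p2, out / "mnp_filtered_metadata.tsv")
        stars = state["mnp"].stars
        p3 = out / "stars.json"
        p3.write_text(
            json.dumps(
                {
                    "lambdas": stars.path.lambdas.tolist(),
                    "instability": stars.instability.tolist(),
                    "selected_lambda": stars.selected_lambda,
                    "no_stable_lambda": stars.no_stable_lambda,
                },
                indent=2,
            )
        )
        return [p1, p2, p3]

    def s_mni():
        mnis = compute_all_mnis(table, config, mnp=state["mnp"])
        state["mnis"] = mnis
        paths = []
        for sid, mni in mnis.items():
            p = out / f"mni_{sid}.graphml"
            write_network(mni, p)
            paths.append(p)
        return paths

    def s_metrics():
        rows = []
        for sid, mni in state["mnis"].items():
            ms = mni.metric_set(
                ordering=config.attack_ordering,
                response=config.attack_response,
            )
            row = {"sample_id": sid, **ms.as_dict()}
            row["timepoint"] = table.metadata.loc[sid, "timepoint"]
            rows.append(row)
        df = pd.DataFrame(rows)
        state["mni_metrics"] = df
        p1 = out / "mni_metrics.csv"
        df.to_csv(p1, index=False)
        mnp_ms = metric_set(
            state["mnp"].network,
            ordering=config.attack_ordering,
            response=config.attack_response,
        )
        p2 = out / "mnp_metrics.json"
        write_metric_set(mnp_ms, p2)
        p3 = out / "mnp_fragility_curve.csv"
        if state["mnp"].network.number_of_nodes() >= 2:
            write_fragility_curve(
                fragility_curve(state["mnp"].network, ordering=config.attack_ordering), p3
            )
        else:
            p3.write_text("")
        return [p1, p2, p3]

    def s_compare():
        df = state["mni_metrics"]
        groups = sorted(df["timepoint"].unique())
        rows = []
        if len(groups) == 2:
            g1, g2 = groups
            for metric in (
                "mean_degree",
                "edge_number",
                "node_number",
                "robustness",
            ):
                a = df.loc[df["timepoint"] == g2, metric].to_numpy()
                b = df.loc[df["timepoint"] == g1, metric].to_numpy()
                res = bootstrap_mean_test(a, b, seed=config.seed)
                rows.append(
                    {
                        "metric": metric,
                        "group_high": g2,
                        "group_low": g1,
                        "mean_diff": res.statistic,
                        "p_value": res.p_value,
                        "method": res.method,
                    }
                )
        p = out / "group_comparison.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        return [p]

    def s_bootstrap():
        ens = bootstrap_mnp(
            table,
            n_networks=config.bootstrap_n,
            subsample_fraction=config.bootstrap_fraction,
            config=config,
        )
        p = out / "bootstrap_metrics.csv"
        ens.metrics.to_csv(p, index=False)
        return [p]

    stage("input", s_input)
    stage("mnp", s_mnp)
    stage("mni", s_mni)
    stage("metrics", s_metrics)
    stage("compare", s_compare)
    if bootstrap:
        stage("bootstrap", s_bootstrap)

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
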
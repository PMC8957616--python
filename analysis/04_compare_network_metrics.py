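#!/usr/bin/env python
"""Compare network metrics between baseline and post-intervention arms.

Two comparisons, mirroring the study's analysis plan:
  (a) population level — a bootstrap ensemble of networks re-inferred on
      random 80% sample subsets per arm, with the bootstrap hypothesis
      test on each metric's ensemble mean (the population-level contrast
      is expected to be weak);
  (b) individual level — per-sample single-sample-network (MNI) metrics
      compared with the bootstrap test (the better-powered contrast).

Writes results/metric_comparison.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import study_cohort, study_config  # noqa: E402

from miconet import bootstrap_mean_test  # noqa: E402
from miconet.population import bootstrap_mnp  # noqa: E402

METRICS = ("mean_degree", "edge_number", "node_number", "robustness")
N_BOOT_NETWORKS = 200  # per arm; the study used 1000


def main() -> None:
    table, _, _ = study_cohort()
    config = study_config()
    rows = []

    ensembles = {}
    for arm in ("baseline", "post"):
        sub = table.select_samples(table.samples_for_timepoint(arm))
        ensembles[arm] = bootstrap_mnp(
            sub, n_networks=N_BOOT_NETWORKS, subsample_fraction=0.8, config=config
        )
    for metric in METRICS:
        res = bootstrap_mean_test(
            ensembles["post"].values(metric),
            ensembles["baseline"].values(metric),
            seed=config.seed,
        )
        rows.append(
            {"level": "population_bootstrap", "metric": metric,
             "mean_diff_post_minus_baseline": res.statistic, "p_value": res.p_value}
        )

    mni_path = Path("results/mni_metrics.csv")
    if not mni_path.exists():
        print("results/mni_metrics.csv missing -- run 03_single_sample_networks.py first")
        sys.exit(1)
    df = pd.read_csv(mni_path)
    for metric in METRICS:
        post = df.loc[df["timepoint"] == "post", metric].to_numpy()
        base = df.loc[df["timepoint"] == "baseline", metric].to_numpy()
        res = bootstrap_mean_test(post, base, seed=config.seed)
        rows.append(
            {"level": "single_sample", "metric": metric,
             "mean_diff_post_minus_baseline": res.statistic, "p_value": res.p_value}
        )

    out = pd.DataFrame(rows)
    out.to_csv("results/metric_comparison.csv", index=False)
    print(out.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
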
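#!/usr/bin/env python
"""Recompute the lipid summary statistics from the study's printed means.

Inputs are the printed per-class ceramide means (baseline and week 5), the
total ceramide, total free fatty acid and cholesterol means. Outputs fold
changes per ceramide class, the total-ceramide percent change, and the
baseline FFA:ceramide and cholesterol:ceramide molar ratios, written to
results/lipid_summaries.csv.
"""

from pathlib import Path

import pandas as pd

from miconet import change_summary

# per-class ceramide means, pmol/ug protein (baseline, week 5)
CERAMIDE_CLASSES = {
    "AdS": (0.23, 0.31),
    "AH": (0.39, 0.54),
    "AP": (0.25, 0.35),
    "AS": (0.16, 0.22),
    "EOH": (0.17, 0.25),
    "EOS": (0.23, 0.28),
    "NdS": (0.30, 0.36),
    "NH": (0.47, 0.63),
    "NP": (0.35, 0.45),
    "NS": (0.28, 0.38),
}
TOTAL_CERAMIDE = (2.85, 3.80)
TOTAL_FFA_BASELINE = 51.06
CHOLESTEROL_BASELINE = 29.85


def main() -> None:
    Path("results").mkdir(exist_ok=True)
    rows = []
    for cls, (b, f) in CERAMIDE_CLASSES.items():
        cs = change_summary(b, f)
        rows.append(
            {"quantity": f"ceramide_{cls}_fold_change", "value": cs.fold_change_2dp}
        )
    total = change_summary(*TOTAL_CERAMIDE)
    rows.append(
        {"quantity": "total_ceramide_percent_change", "value": total.percent_change_int}
    )
    rows.append(
        {
            "quantity": "baseline_ffa_to_ceramide_ratio",
            "value": round(TOTAL_FFA_BASELINE / TOTAL_CERAMIDE[0], 1),
        }
    )
    rows.append(
        {
            "quantity": "baseline_cholesterol_to_ceramide_ratio",
            "value": round(CHOLESTEROL_BASELINE / TOTAL_CERAMIDE[0], 1),
        }
    )
    df = pd.DataFrame(rows)
    df.to_csv("results/lipid_summaries.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nmolar ratio ceramide : FFA : cholesterol ~= 1 : "
        f"{TOTAL_FFA_BASELINE / TOTAL_CERAMIDE[0]:.0f} : "
        f"{CHOLESTEROL_BASELINE / TOTAL_CERAMIDE[0]:.0f}"
    )


if __name__ == "__main__":
    main()
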
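#!/usr/bin/env python
"""Score recognition and recall behavior and check coder reliability.

Reads the cohort written by 01_simulate_cohort.py, computes per-participant
signal-detection rates by valence, reconciles the two coders' recall
codings, estimates Krippendorff's alpha per week, and writes the scored
tables under results/.
"""

import json
from pathlib import Path

import pandas as pd

from emobias import (
    compute_recognition_rates,
    bootstrap_alpha_ci,
    reconcile_coders,
    tally_recall,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    trials = pd.read_csv(ROOT / "cohort" / "recognition.csv")
    codings = pd.read_csv(ROOT / "cohort" / "recall_coding.csv")

    rates = compute_recognition_rates(trials)
    rates.to_csv(ROOT / "recognition_rates.csv", index=False)
    summary = rates.groupby("valence")[["hit_rate", "fa_rate", "corrected_recognition"]].mean()
    print("mean recognition rates by valence:")
    print(summary.round(3).to_string())

    valence_map = (trials.query("status == 'old'")
                   .drop_duplicates("item_id").set_index("item_id")["valence"].to_dict())
    reliability = {}
    counts_all = []
    for week, wdf in codings.groupby("week"):
        coders = sorted(wdf["coder_id"].unique())
        disc, merged = reconcile_coders(
            wdf[wdf["coder_id"] == coders[0]], wdf[wdf["coder_id"] == coders[1]]
        )
        mat = wdf.pivot_table(index="coder_id",
                              columns=["participant_id", "item_id"], values="code")
        rel = bootstrap_alpha_ci(mat, n_boot=1000, seed=seed + week)
        reliability[str(week)] = rel.to_dict()
        print(f"week {week}: {len(disc)} coder discrepancies, "
              f"alpha = {rel.alpha:.3f} [{rel.ci_low:.3f}, {rel.ci_high:.3f}]")
        counts = tally_recall(merged, valence_map)
        counts["week"] = week
        counts_all.append(counts)
    pd.concat(counts_all, ignore_index=True).to_csv(ROOT / "recall_counts.csv", index=False)
    (ROOT / "reliability.json").write_text(json.dumps(reliability, indent=2) + "\n")


if __name__ == "__main__":
    main()
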
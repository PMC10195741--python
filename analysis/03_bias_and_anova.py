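#!/usr/bin/env python
"""Build the positive emotional memory bias composite and run the ANOVAs.

The composite combines Week-5 false-alarm rates and Week-5 correct recall
(positive minus negative, each z-scored across participants).  The 2x2
between-subjects ANOVA on the composite asks whether the biofeedback arms
differ in bias; the mixed ANOVAs on false alarms and recall mirror the
standard condition x age x valence (x week) analyses.
"""

from pathlib import Path

import pandas as pd

from emobias import compute_bias_scores, fit_mixed_anova

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rates = pd.read_csv(ROOT / "recognition_rates.csv")
    counts = pd.read_csv(ROOT / "recall_counts.csv")
    participants = pd.read_csv(ROOT / "cohort" / "participants.csv")

    fa = rates.pivot(index="participant_id", columns="valence", values="fa_rate")
    rec5 = counts.query("week == 5").set_index("participant_id")
    bias = compute_bias_scores(
        fa["positive"], fa["negative"],
        rec5.loc[fa.index, "correct_positive"].astype(float),
        rec5.loc[fa.index, "correct_negative"].astype(float),
    )
    bias.index.name = "participant_id"
    bias.reset_index().to_csv(ROOT / "bias_scores.csv", index=False)

    meta = participants.set_index("participant_id")[["condition", "age_group"]]
    long = bias.join(meta).reset_index().rename(columns={"bias": "dv"})
    tab = fit_mixed_anova(long, between=["condition", "age_group"])
    print("bias 2x2 ANOVA:")
    print(tab[["effect", "df_effect", "df_error", "F", "p", "partial_eta_sq"]]
          .round(4).to_string(index=False))
    cond_means = long.groupby("condition")["dv"].mean()
    print(f"\nmean bias: Osc+ {cond_means.get('OscPlus', float('nan')):+.3f}, "
          f"Osc- {cond_means.get('OscMinus', float('nan')):+.3f}")

    fa_long = rates.merge(meta.reset_index(), on="participant_id").rename(
        columns={"fa_rate": "dv"})
    tab_fa = fit_mixed_anova(fa_long, between=["condition", "age_group"],
                             within=["valence"])
    tab_fa.insert(0, "measure", "fa_rate")
    tab.insert(0, "measure", "bias")
    pd.concat([tab, tab_fa], ignore_index=True).to_csv(
        ROOT / "anova_tables.csv", index=False)
    print("\nfalse-alarm 2x2x3 mixed ANOVA written to anova_tables.csv")


if __name__ == "__main__":
    main()
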
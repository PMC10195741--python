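#!/usr/bin/env python
"""Does post-intervention connectivity mediate the condition effect on bias?

Single-mediator model with condition (Osc+ = 0, Osc- = 1) as exposure,
post-intervention amygdala-mPFC connectivity as mediator, and the bias
composite as outcome, always controlling for pre-intervention
connectivity; mood-change and RMSSD-change variants follow.  10,000
case-resampling bootstrap replicates; percentile intervals.
"""

import json
from pathlib import Path

import pandas as pd

from emobias import fit_model4

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    bias = pd.read_csv(ROOT / "bias_scores.csv").set_index("participant_id")
    participants = pd.read_csv(ROOT / "cohort" / "participants.csv").set_index("participant_id")
    conn = pd.read_csv(ROOT / "cohort" / "connectivity.csv").set_index("participant_id")
    cov = pd.read_csv(ROOT / "cohort" / "covariates.csv").set_index("participant_id")
    df = bias.join(participants).join(conn).join(cov).dropna()

    x = (df["condition"] == "OscMinus").astype(float).to_numpy()
    out = {}
    for extra in ([], ["mood_change"], ["rmssd_change"]):
        names = ["pre_beta", *extra]
        res = fit_model4(x, df["post_beta"].to_numpy(), df["bias"].to_numpy(),
                         covariates=df[names].to_numpy(), covariate_names=names,
                         n_boot=10_000, seed=seed)
        out["+".join(names)] = res.to_dict()
        lo, hi = res.ci_ab
        verdict = "significant" if (hi < 0 or lo > 0) else "not significant"
        print(f"covariates {names}: ab = {res.ab:+.3f} 95% CI [{lo:+.3f}, {hi:+.3f}] "
              f"({verdict}); c = {res.c:+.3f}, c' = {res.c_prime:+.3f}")
    (ROOT / "mediation.json").write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
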
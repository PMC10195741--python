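"""Calibration studies on synthetic cohorts with known ground truth.

These routines quantify how well the estimation machinery recovers the
generator's truth: bootstrap CI coverage for the indirect effect,
point-estimate recovery, agreement between Sobel and bootstrap verdicts,
and sign recovery through the full behavioral pipeline.

Two outcome configurations are used:

* **linear**: the outcome is the generator's latent bias trait itself, so
  the slope-scale true indirect effect is exactly ``true_a * true_b`` and
  coverage/recovery are well defined;
* **behavioral**: the outcome is the bias composite computed from the
  generated recognition and recall tables, where the latent trait passes
  through binomial/Poisson readouts and cross-participant z-scoring, so
  only the sign of the indirect effect is comparable to truth.
"""

from __future__ import annotations

import numpy as np

from .bias import compute_bias_scores
from .cohort import CohortSpec, generate_cohort, item_valence_map
from .mediation import fit_model4, sobel
from .scoring import compute_recognition_rates, reconcile_coders, tally_recall

__all__ = [
    "mediation_inputs_linear",
    "mediation_inputs_behavioral",
    "coverage_study",
    "recovery_study",
    "sobel_concordance_study",
    "pipeline_sign_recovery",
]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def mediation_inputs_linear(cohort):
    """(x, m, y, pre) with the latent trait as a linear outcome."""
    x = (cohort.participants["condition"] == "OscMinus").to_numpy(float)
    m = cohort.connectivity["post_beta"].to_numpy()
    pre = cohort.connectivity["pre_beta"].to_numpy()
    y = cohort.latent.to_numpy()
    return x, m, y, pre


def mediation_inputs_behavioral(cohort):
    """(x, m, y, pre) with y = bias composite scored from behavior."""
    x = (cohort.participants["condition"] == "OscMinus").to_numpy(float)
    m = cohort.connectivity["post_beta"].to_numpy()
    pre = cohort.connectivity["pre_beta"].to_numpy()
    rates = compute_recognition_rates(cohort.recognition_trials)
    fa = rates.pivot(index="participant_id", columns="valence", values="fa_rate")
    wk5 = cohort.recall_codings.query("week == 5")
    a = wk5[wk5["coder_id"] == "coderA"]
    b = wk5[wk5["coder_id"] == "coderB"]
    _, merged = reconcile_coders(a, b)
    counts = tally_recall(merged, item_valence_map()).set_index("participant_id")
    pid = cohort.participants["participant_id"]
    bias = compute_bias_scores(
        fa.loc[pid, "positive"], fa.loc[pid, "negative"],
        counts.loc[pid, "correct_positive"].astype(float),
        counts.loc[pid, "correct_negative"].astype(float),
    )
    return x, m, bias["bias"].to_numpy(), pre


def coverage_study(
    n_reps: int = 200,
    n_per_cell: int = 60,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    **spec_kwargs,
) -> dict:
    """Empirical coverage of the bootstrap CI for ab under linear truth."""
    seeds = _spawn_seeds(seed, 2 * n_reps)
    covered = 0
    for r in range(n_reps):
        spec = CohortSpec(n_per_cell=n_per_cell, seed=int(seeds[2 * r]), **spec_kwargs)
        cohort = generate_cohort(spec)
        x, m, y, pre = mediation_inputs_linear(cohort)
        res = fit_model4(x, m, y, covariates=pre, n_boot=n_boot, level=level,
                         seed=int(seeds[2 * r + 1]))
        truth = spec.true_a * spec.true_b
        lo, hi = res.ci_ab
        covered += lo <= truth <= hi
    return {"coverage": covered / n_reps, "n_reps": n_reps,
            "n": 4 * n_per_cell, "n_boot": n_boot}


def recovery_study(
    n_reps: int = 100,
    n_per_cell: int = 250,
    true_a: float = 0.5,
    true_b: float = 0.6,
    rel_tol: float = 0.25,
    seed: int = 0,
    **spec_kwargs,
) -> dict:
    """Fraction of replicates whose ab estimate falls within ``rel_tol`` of truth."""
    seeds = _spawn_seeds(seed, n_reps)
    truth = true_a * true_b
    hits = 0
    for r in range(n_reps):
        spec = CohortSpec(n_per_cell=n_per_cell, seed=int(seeds[r]),
                          true_a=true_a, true_b=true_b, **spec_kwargs)
        cohort = generate_cohort(spec)
        x, m, y, pre = mediation_inputs_linear(cohort)
        res = fit_model4(x, m, y, covariates=pre, n_boot=0)
        hits += abs(res.ab - truth) <= rel_tol * abs(truth)
    return {"recovery_rate": hits / n_reps, "n_reps": n_reps,
            "n": 4 * n_per_cell, "true_ab": truth}


def sobel_concordance_study(
    n_reps: int = 200,
    n_per_cell: int = 150,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    **spec_kwargs,
) -> dict:
    """Agreement of Sobel p < alpha with the bootstrap CI excluding zero."""
    seeds = _spawn_seeds(seed, 2 * n_reps)
    agree = 0
    for r in range(n_reps):
        spec = CohortSpec(n_per_cell=n_per_cell, seed=int(seeds[2 * r]), **spec_kwargs)
        cohort = generate_cohort(spec)
        x, m, y, pre = mediation_inputs_linear(cohort)
        res = fit_model4(x, m, y, covariates=pre, n_boot=n_boot,
                         level=1 - alpha, seed=int(seeds[2 * r + 1]))
        _, p = sobel(res.a, res.se_a, res.b, res.se_b)
        boot_sig = not (res.ci_ab[0] <= 0.0 <= res.ci_ab[1])
        agree += (p < alpha) == boot_sig
    return {"concordance": agree / n_reps, "n_reps": n_reps, "n": 4 * n_per_cell}


def pipeline_sign_recovery(
    n_reps: int = 100,
    n_per_cell: int = 250,
    seed: int = 0,
    **spec_kwargs,
) -> dict:
    """Sign agreement of the full behavioral pipeline's ab with the truth."""
    seeds = _spawn_seeds(seed, n_reps)
    hits = 0
    truth_sign = None
    for r in range(n_reps):
        spec = CohortSpec(n_per_cell=n_per_cell, seed=int(seeds[r]), **spec_kwargs)
        truth_sign = np.sign(spec.true_a * spec.true_b)
        cohort = generate_cohort(spec)
        x, m, y, pre = mediation_inputs_behavioral(cohort)
        res = fit_model4(x, m, y, covariates=pre, n_boot=0)
        hits += np.sign(res.ab) == truth_sign
    return {"sign_agreement": hits / n_reps, "n_reps": n_reps,
            "n": 4 * n_per_cell, "truth_sign": float(truth_sign)}
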
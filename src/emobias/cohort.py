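"""Synthetic randomized-trial cohorts with known ground-truth mediation paths.

Emulates a two-arm (Osc+ biofeedback vs. Osc- active control), two
age-group (younger/older adult) trial in which the intervention shifts
resting amygdala-mPFC functional connectivity, which in turn shifts a
latent positive-memory-bias trait that expresses itself in valence-specific
recognition and recall behavior:

* condition code ``x``: Osc+ = 0, Osc- = 1;
* pre-intervention connectivity ``pre ~ Normal(0, 1)``;
* post-intervention connectivity
  ``post = rho_pre*pre + true_a*x + Normal(0, sigma_m)``;
* latent bias ``latent = true_c_prime*x + true_b*post + Normal(0, sigma_y)``,
  so the slope-scale true indirect effect is ``true_a * true_b``;
* per valence, hit and false-alarm probabilities are shifted by
  ``+/- bias_gain * latent`` on the logit scale (positive valence up,
  negative down, neutral unshifted) and expected recall counts by the same
  amount on the log scale; recognition outcomes are binomial over 12 items
  per valence x old/new cell, recall counts Poisson truncated at 12.

Each participant receives 72 recognition trials (36 old, 36 new; 12 per
valence per status).  Recall is coded at two time points by two coders;
the second coder's code for each item is flipped with probability
``coder_disagreement``.  The ``latent`` trait is retained on the cohort so
calibration studies can run the mediation on a linear outcome with a known
slope-scale truth, bypassing the nonlinear behavioral readout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .scoring import AGE_GROUPS, CONDITIONS, INCORRECT_PREFIX, VALENCES

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "item_valence_map"]

N_PER_CELL_ITEMS = 12  # pictures per valence per old/new status


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort.

    Defaults reflect a mid-sized trial cell (n=36 per condition x age
    group, total N=144) with path coefficients ``true_a=-0.4`` and
    ``true_b=0.38`` (indirect effect -0.152 under Osc+=0/Osc-=1 coding,
    i.e. the Osc+ arm raises connectivity and a positive bias),
    false-alarm and hit base rates of 0.05 and 0.87, Week-5 recall of
    about 1.8 pictures per valence (Week 4 richer at 4.0), and a 2.5%
    coder disagreement rate.
    """

    n_per_cell: int = 36
    true_a: float = -0.4
    true_b: float = 0.38
    true_c_prime: float = -0.28
    rho_pre: float = 0.5
    sigma_m: float = 1.0
    sigma_y: float = 1.0
    base_fa: float = 0.05
    base_hit: float = 0.87
    base_recall_rate: float = 1.8
    base_recall_rate_week4: float = 4.0
    bias_gain: float = 0.35
    coder_disagreement: float = 0.025
    cov_mood_sd: float = 1.0
    cov_rmssd_sd: float = 1.0
    seed: int = 0
    # secondary knobs
    p_remember_hit: float = 0.65
    p_remember_fa: float = 0.25
    p_code2: float = 0.01
    incorrect_recall_rate: float = 1.8
    age_offset_post: float = 0.0
    age_offset_latent: float = 0.0

    def __post_init__(self):
        checks = [
            ("n_per_cell", self.n_per_cell >= 2),
            ("sigma_m", self.sigma_m > 0),
            ("sigma_y", self.sigma_y > 0),
            ("rho_pre", 0.0 <= self.rho_pre <= 1.0),
            ("base_fa", 0.0 < self.base_fa < 1.0),
            ("base_hit", 0.0 < self.base_hit < 1.0),
            ("base_recall_rate", 0.0 <= self.base_recall_rate <= N_PER_CELL_ITEMS),
            ("base_recall_rate_week4", 0.0 <= self.base_recall_rate_week4 <= N_PER_CELL_ITEMS),
            ("coder_disagreement", 0.0 <= self.coder_disagreement < 1.0),
            ("p_remember_hit", 0.0 <= self.p_remember_hit <= 1.0),
            ("p_remember_fa", 0.0 <= self.p_remember_fa <= 1.0),
            ("p_code2", 0.0 <= self.p_code2 < 1.0),
            ("incorrect_recall_rate", self.incorrect_recall_rate >= 0.0),
            ("cov_mood_sd", self.cov_mood_sd > 0),
            ("cov_rmssd_sd", self.cov_rmssd_sd > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise SchemaError(f"invalid CohortSpec field: {name} = {getattr(self, name)!r}")


@dataclass
class SyntheticCohort:
    """Generated tables plus the spec (and latent trait) that produced them."""

    participants: pd.DataFrame
    recognition_trials: pd.DataFrame
    recall_codings: pd.DataFrame  # long: coder_id, week, participant_id, item_id, code
    connectivity: pd.DataFrame
    covariates: pd.DataFrame
    truth: CohortSpec
    latent: pd.Series = field(repr=False, default=None)

    def write(self, outdir) -> dict:
        """Write the cohort as the pipeline's CSV schemas plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("participants", self.participants),
            ("recognition", self.recognition_trials),
            ("recall_coding", self.recall_codings),
            ("connectivity", self.connectivity),
            ("covariates", self.covariates),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(asdict(self.truth), indent=2) + "\n")
        paths["truth"] = truth_path
        return paths


def item_valence_map() -> dict:
    """item_id -> valence for the 36 old (studied) pictures."""
    return {
        f"{val}_old_{i:02d}": val
        for val in VALENCES
        for i in range(1, N_PER_CELL_ITEMS + 1)
    }


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


_VALENCE_SIGN = {"neutral": 0.0, "positive": 1.0, "negative": -1.0}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a complete synthetic cohort from ``spec``.

    Deterministic: the same spec (including seed) reproduces the same
    tables byte-for-byte when written to CSV.
    """
    rng = np.random.default_rng(spec.seed)
    n = 4 * spec.n_per_cell
    cells = [(c, a) for c in CONDITIONS for a in AGE_GROUPS]
    condition = np.repeat([c for c, _ in cells], spec.n_per_cell)
    age_group = np.repeat([a for _, a in cells], spec.n_per_cell)
    pid = np.array([f"P{i:04d}" for i in range(1, n + 1)])
    x = (condition == "OscMinus").astype(float)  # Osc+ = 0, Osc- = 1
    oa = (age_group == "OA").astype(float)

    age = np.where(
        oa == 1,
        rng.integers(55, 81, size=n),
        rng.integers(18, 36, size=n),
    )
    sex = rng.choice(["F", "M"], size=n)
    years_education = np.clip(np.round(rng.normal(16, 2, size=n)), 12, 25).astype(int)

    pre = rng.normal(0.0, 1.0, size=n)
    post = (
        spec.rho_pre * pre
        + spec.true_a * x
        + spec.age_offset_post * oa
        + rng.normal(0.0, spec.sigma_m, size=n)
    )
    latent = (
        spec.true_c_prime * x
        + spec.true_b * post
        + spec.age_offset_latent * oa
        + rng.normal(0.0, spec.sigma_y, size=n)
    )

    # ---- recognition: 12 old + 12 new items per valence ----
    rec_rows = []
    for val in VALENCES:
        s = _VALENCE_SIGN[val]
        p_hit = _sigmoid(_logit(spec.base_hit) + s * spec.bias_gain * latent)
        p_fa = _sigmoid(_logit(spec.base_fa) + s * spec.bias_gain * latent)
        for status, p_old in (("old", p_hit), ("new", p_fa)):
            called = rng.random((n, N_PER_CELL_ITEMS)) < p_old[:, None]
            p_rem = spec.p_remember_hit if status == "old" else spec.p_remember_fa
            remember = rng.random((n, N_PER_CELL_ITEMS)) < p_rem
            resp = np.where(called, np.where(remember, "remember", "know"), "new")
            for i in range(N_PER_CELL_ITEMS):
                rec_rows.append(pd.DataFrame({
                    "participant_id": pid,
                    "item_id": f"{val}_{status}_{i + 1:02d}",
                    "valence": val,
                    "status": status,
                    "response": resp[:, i],
                }))
    recognition = (
        pd.concat(rec_rows, ignore_index=True)
        .sort_values(["participant_id", "item_id"], kind="stable")
        .reset_index(drop=True)
    )

    # ---- recall codings at Weeks 4 and 5, two coders ----
    coding_rows = []
    for week, base_rate in ((4, spec.base_recall_rate_week4), (5, spec.base_recall_rate)):
        codes_a = {}
        for val in VALENCES:
            s = _VALENCE_SIGN[val]
            lam = base_rate * np.exp(s * spec.bias_gain * latent)
            k = np.minimum(rng.poisson(lam), N_PER_CELL_ITEMS)
            # choose which k of the 12 studied items were recalled
            order = np.argsort(rng.random((n, N_PER_CELL_ITEMS)), axis=1)
            recalled = order < k[:, None]
            codes = recalled.astype(int)
            # occasional double-match: a recalled item coded 2
            codes[recalled & (rng.random((n, N_PER_CELL_ITEMS)) < spec.p_code2)] = 2
            codes_a[val] = codes
        n_incorrect = rng.poisson(spec.incorrect_recall_rate, size=n)
        for coder in ("coderA", "coderB"):
            for val in VALENCES:
                codes = codes_a[val]
                if coder == "coderB" and spec.coder_disagreement > 0:
                    flip = rng.random((n, N_PER_CELL_ITEMS)) < spec.coder_disagreement
                    flipped = np.where(codes == 1, 0, 1)  # 0->1, 1->0, 2->1
                    codes = np.where(flip, flipped, codes)
                for i in range(N_PER_CELL_ITEMS):
                    coding_rows.append(pd.DataFrame({
                        "coder_id": coder,
                        "week": week,
                        "participant_id": pid,
                        "item_id": f"{val}_old_{i + 1:02d}",
                        "code": codes[:, i],
                    }))
            # sentinel entries for descriptions matching no picture
            max_inc = int(n_incorrect.max()) if n else 0
            for j in range(max_inc):
                has = n_incorrect > j
                if not has.any():
                    break
                coding_rows.append(pd.DataFrame({
                    "coder_id": coder,
                    "week": week,
                    "participant_id": pid[has],
                    "item_id": f"{INCORRECT_PREFIX}_{j + 1:02d}",
                    "code": 1,
                }))
    recall_codings = (
        pd.concat(coding_rows, ignore_index=True)
        .sort_values(["week", "coder_id", "participant_id", "item_id"], kind="stable")
        .reset_index(drop=True)
    )

    participants = pd.DataFrame({
        "participant_id": pid,
        "condition": condition,
        "age_group": age_group,
        "age": age,
        "sex": sex,
        "years_education": years_education,
    })
    connectivity = pd.DataFrame({
        "participant_id": pid,
        "pre_beta": pre,
        "post_beta": post,
    })
    covariates = pd.DataFrame({
        "participant_id": pid,
        "mood_change": rng.normal(0.0, spec.cov_mood_sd, size=n),
        "rmssd_change": rng.normal(0.0, spec.cov_rmssd_sd, size=n),
        "rmssd_baseline": np.clip(rng.normal(45.0, 12.0, size=n), 5.0, None),
    })

    return SyntheticCohort(
        participants=participants,
        recognition_trials=recognition,
        recall_codings=recall_codings,
        connectivity=connectivity,
        covariates=covariates,
        truth=spec,
        latent=pd.Series(latent, index=pid, name="latent"),
    )
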
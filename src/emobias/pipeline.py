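"""End-to-end orchestration from CSV tables to a results bundle.

Stages: validate inputs -> recognition rates -> coder reconciliation +
reliability -> recall tallies -> bias composite -> ANOVAs -> mediation
(one model per configured covariate set).  Every stage logs participant
counts in and out; listwise exclusions are recorded with reason codes in
the run manifest.

CSV schemas (column names are part of the contract):

* ``participants``: participant_id, condition, age_group, age, sex, years_education
* ``recognition``: participant_id, item_id, valence, status, response
* ``recall_coding``: coder_id, week, participant_id, item_id, code
* ``connectivity``: participant_id, pre_beta, post_beta
* ``covariates``: participant_id, mood_change, rmssd_change, rmssd_baseline

Exposure coding for mediation: Osc+ = 0, Osc- = 1, so a negative total or
indirect effect means the Osc+ arm shows the higher positive-memory bias.
Pre-intervention connectivity is always a covariate; mood change and RMSSD
change can be added per model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import scoring
from .anova import fit_mixed_anova
from .exceptions import SchemaError
from .mediation import fit_model4
from .reliability import bootstrap_alpha_ci

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]

logger = logging.getLogger("emobias")

FILE_NAMES = ("participants", "recognition", "recall_coding", "connectivity", "covariates")

_SCHEMAS = {
    "participants": ["participant_id", "condition", "age_group", "age", "sex", "years_education"],
    "recognition": ["participant_id", "item_id", "valence", "status", "response"],
    "recall_coding": ["coder_id", "week", "participant_id", "item_id", "code"],
    "connectivity": ["participant_id", "pre_beta", "post_beta"],
    "covariates": ["participant_id", "mood_change", "rmssd_change", "rmssd_baseline"],
}

_OPTIONAL_MEDIATION_COVARIATES = ("mood_change", "rmssd_change")


@dataclass
class PipelineConfig:
    """Paths and analysis settings for one pipeline run."""

    data_dir: Path | str | None = None
    paths: dict = field(default_factory=dict)  # overrides per FILE_NAMES key
    out_dir: Path | str = "results"
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    covariate_sets: list = field(
        default_factory=lambda: [[], ["mood_change"], ["rmssd_change"]]
    )
    reconcile_rule: str = "max"
    n_boot_alpha: int = 1000

    def resolved_paths(self) -> dict:
        out = {}
        for name in FILE_NAMES:
            if name in self.paths:
                out[name] = Path(self.paths[name])
            elif self.data_dir is not None:
                out[name] = Path(self.data_dir) / f"{name}.csv"
            else:
                raise SchemaError(f"no path for input table {name!r}")
        return out

    def validate(self) -> None:
        if self.n_boot < 100:
            raise SchemaError(f"n_boot must be >= 100, got {self.n_boot}")
        if not 0.0 < self.ci_level < 1.0:
            raise SchemaError(f"ci_level must be in (0, 1), got {self.ci_level}")
        for cs in self.covariate_sets:
            bad = set(cs) - set(_OPTIONAL_MEDIATION_COVARIATES)
            if bad:
                raise SchemaError(
                    f"unknown mediation covariates {sorted(bad)}; "
                    f"choose from {_OPTIONAL_MEDIATION_COVARIATES} (pre_beta is always included)"
                )
        for name, p in self.resolved_paths().items():
            if not p.exists():
                raise SchemaError(f"input file for {name!r} not found: {p}")


def _check_table(name: str, df: pd.DataFrame) -> str | None:
    """Return an error message (naming the first offending row) or None."""
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        return f"missing columns: {missing}"

    def first_bad(mask, what):
        i = int(np.flatnonzero(mask.to_numpy())[0])
        return f"{what} at row {i}: {df.iloc[i].to_dict()}"

    if name == "participants":
        bad = ~df["condition"].isin(scoring.CONDITIONS)
        if bad.any():
            return first_bad(bad, "invalid condition")
        bad = ~df["age_group"].isin(scoring.AGE_GROUPS)
        if bad.any():
            return first_bad(bad, "invalid age_group")
        bad = df["age"] < 18
        if bad.any():
            return first_bad(bad, "age < 18")
        if df["participant_id"].duplicated().any():
            return first_bad(df["participant_id"].duplicated(), "duplicate participant_id")
    elif name == "recognition":
        for col, allowed in (
            ("valence", scoring.VALENCES),
            ("status", scoring.STATUSES),
            ("response", scoring.RESPONSES),
        ):
            bad = ~df[col].isin(allowed)
            if bad.any():
                return first_bad(bad, f"invalid {col}")
        dup = df.duplicated(["participant_id", "item_id"])
        if dup.any():
            return first_bad(dup, "duplicate (participant_id, item_id)")
    elif name == "recall_coding":
        bad = ~df["code"].isin([0, 1, 2])
        if bad.any():
            return first_bad(bad, "invalid code")
        bad = ~df["week"].isin([4, 5])
        if bad.any():
            return first_bad(bad, "invalid week")
        for week, wdf in df.groupby("week"):
            sets = {
                coder: set(zip(cdf["participant_id"], cdf["item_id"]))
                for coder, cdf in wdf.groupby("coder_id")
            }
            coders = sorted(sets)
            if len(coders) < 2:
                return f"week {week}: need >= 2 coders, found {coders}"
            ref = sets[coders[0]]
            for coder in coders[1:]:
                diff = ref ^ sets[coder]
                if diff:
                    return (
                        f"week {week}: coder index mismatch between {coders[0]} and "
                        f"{coder}; first differing keys: {sorted(diff)[:3]}"
                    )
    else:  # connectivity, covariates
        num_cols = [c for c in _SCHEMAS[name] if c not in ("participant_id",)]
        arr = df[num_cols].to_numpy(dtype=float)
        bad = ~np.isfinite(arr).all(axis=1)
        if bad.any():
            return f"non-finite values at row {int(np.flatnonzero(bad)[0])}"
    return None


def validate_inputs(paths: dict) -> pd.DataFrame:
    """Schema report per input file: pass/fail with the first offending row."""
    rows = []
    for name in FILE_NAMES:
        p = Path(paths[name])
        if not p.exists():
            rows.append({"file": name, "path": str(p), "passed": False,
                         "message": "file not found"})
            continue
        df = pd.read_csv(p)
        msg = _check_table(name, df)
        rows.append({"file": name, "path": str(p), "passed": msg is None,
                     "message": msg or "ok"})
    return pd.DataFrame(rows)


def _condition_code(condition: pd.Series) -> pd.Series:
    """Osc+ = 0, Osc- = 1."""
    return condition.map({"OscPlus": 0.0, "OscMinus": 1.0})


def _alpha_matrix(week_codings: pd.DataFrame) -> pd.DataFrame:
    """coders x (participant, item) matrix for reliability."""
    return week_codings.pivot_table(
        index="coder_id", columns=["participant_id", "item_id"], values="code",
        aggfunc="first",
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the results bundle under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    config.validate()
    paths = config.resolved_paths()
    report = validate_inputs(paths)
    if not report["passed"].all():
        bad = report[~report["passed"]].iloc[0]
        raise SchemaError(f"input validation failed for {bad['file']}: {bad['message']}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {name: pd.read_csv(paths[name]) for name in FILE_NAMES}
    participants = tables["participants"]
    manifest: dict = {
        "config": {
            "paths": {k: str(v) for k, v in paths.items()},
            "out_dir": str(out_dir),
            "n_boot": config.n_boot,
            "ci_level": config.ci_level,
            "seed": config.seed,
            "covariate_sets": config.covariate_sets,
            "reconcile_rule": config.reconcile_rule,
        },
        "stages": {},
        "exclusions": [],
    }
    seed_pool = iter(np.random.SeedSequence(config.seed).generate_state(32) % (2**31))

    # ---- stage: recognition rates ----
    rates = scoring.compute_recognition_rates(tables["recognition"])
    n_recog = rates["participant_id"].nunique()
    logger.info("recognition: %d participants scored", n_recog)
    manifest["stages"]["recognition"] = {"n_in": participants.shape[0], "n_out": int(n_recog)}

    # ---- stage: recall reconciliation, reliability, tallies ----
    valence_map = (
        tables["recognition"].query("status == 'old'")
        .drop_duplicates("item_id").set_index("item_id")["valence"].to_dict()
    )
    recall_counts = {}
    reliability = {}
    discrepancy_counts = {}
    for week, wdf in tables["recall_coding"].groupby("week"):
        coders = sorted(wdf["coder_id"].unique())
        a = wdf[wdf["coder_id"] == coders[0]]
        b = wdf[wdf["coder_id"] == coders[1]]
        discrepancies, merged = scoring.reconcile_coders(a, b, rule=config.reconcile_rule)
        discrepancy_counts[int(week)] = int(len(discrepancies))
        rel = bootstrap_alpha_ci(
            _alpha_matrix(wdf), n_boot=config.n_boot_alpha,
            level=config.ci_level, seed=int(next(seed_pool)),
        )
        reliability[int(week)] = rel
        recall_counts[int(week)] = scoring.tally_recall(merged, valence_map)
        logger.info("recall week %s: %d participants, %d discrepancies, alpha=%.3f",
                    week, recall_counts[int(week)]["participant_id"].nunique(),
                    len(discrepancies), rel.alpha)
    manifest["stages"]["recall"] = {
        int(w): {"n_out": int(recall_counts[w]["participant_id"].nunique()),
                 "discrepancies": discrepancy_counts[w]}
        for w in recall_counts
    }
    (out_dir / "reliability.json").write_text(json.dumps(
        {str(w): r.to_dict() for w, r in reliability.items()}, indent=2, sort_keys=True
    ) + "\n")

    # ---- stage: bias composite (Week-5 false alarms + Week-5 recall) ----
    r5 = recall_counts.get(5)
    if r5 is None:
        raise SchemaError("no Week-5 recall codings; bias composite needs Week 5")
    fa = rates.pivot(index="participant_id", columns="valence", values="fa_rate")
    rec5 = r5.set_index("participant_id")
    common = fa.index.intersection(rec5.index)
    dropped = sorted(set(fa.index).symmetric_difference(rec5.index))
    for pid in dropped:
        manifest["exclusions"].append(
            {"participant_id": str(pid), "stage": "bias",
             "reason": "missing_recognition_or_week5_recall"}
        )
    bias_df = bias_mod.compute_bias_scores(
        fa.loc[common, "positive"], fa.loc[common, "negative"],
        rec5.loc[common, "correct_positive"].astype(float),
        rec5.loc[common, "correct_negative"].astype(float),
    )
    bias_df.index.name = "participant_id"
    bias_df.reset_index().to_csv(out_dir / "bias_scores.csv", index=False)
    manifest["stages"]["bias"] = {"n_in": int(len(fa)), "n_out": int(len(bias_df))}
    logger.info("bias: %d participants in composite", len(bias_df))

    # ---- stage: ANOVAs ----
    meta = participants.set_index("participant_id")[["condition", "age_group"]]
    anova_rows = []

    bias_long = bias_df.join(meta).reset_index()
    tab = fit_mixed_anova(bias_long.rename(columns={"bias": "dv"}),
                          between=["condition", "age_group"])
    tab.insert(0, "measure", "bias")
    anova_rows.append(tab)

    rates_long = rates.merge(meta.reset_index(), on="participant_id")
    for measure in ("fa_rate", "hit_rate", "corrected_recognition"):
        tab = fit_mixed_anova(
            rates_long.rename(columns={measure: "dv"}),
            between=["condition", "age_group"], within=["valence"],
        )
        tab.insert(0, "measure", measure)
        anova_rows.append(tab)

    both_weeks = sorted(recall_counts)
    if set(both_weeks) >= {4, 5}:
        long_recall = []
        for w in (4, 5):
            d = recall_counts[w].melt(
                id_vars=["participant_id"],
                value_vars=["correct_neutral", "correct_positive", "correct_negative"],
                var_name="valence", value_name="dv",
            )
            d["valence"] = d["valence"].str.removeprefix("correct_")
            d["week"] = w
            long_recall.append(d)
        recall_long = pd.concat(long_recall, ignore_index=True)
        complete = (
            recall_long.groupby("participant_id")["dv"].size() == 6
        )
        keep = complete[complete].index
        for pid in sorted(set(recall_long["participant_id"]) - set(keep)):
            manifest["exclusions"].append(
                {"participant_id": str(pid), "stage": "recall_anova",
                 "reason": "missing_week"}
            )
        recall_long = recall_long[recall_long["participant_id"].isin(keep)]
        recall_long = recall_long.merge(meta.reset_index(), on="participant_id")
        tab = fit_mixed_anova(recall_long, between=["condition", "age_group"],
                              within=["valence", "week"])
        tab.insert(0, "measure", "recall_count")
        anova_rows.append(tab)

    anova_tables = pd.concat(anova_rows, ignore_index=True)
    anova_tables.to_csv(out_dir / "anova_tables.csv", index=False)
    manifest["stages"]["anova"] = {"n_tables": int(len(anova_rows))}

    # ---- stage: mediation ----
    med_base = (
        bias_df[["bias"]]
        .join(meta)
        .join(tables["connectivity"].set_index("participant_id"))
        .join(tables["covariates"].set_index("participant_id"))
    )
    n_before = len(med_base)
    incomplete = med_base.index[med_base.isna().any(axis=1)]
    for pid in incomplete:
        manifest["exclusions"].append(
            {"participant_id": str(pid), "stage": "mediation",
             "reason": "missing_connectivity_or_covariates"}
        )
    med = med_base.dropna()
    mediation_out = {}
    for cov_set in config.covariate_sets:
        names = ["pre_beta", *cov_set]
        res = fit_model4(
            x=_condition_code(med["condition"]).to_numpy(),
            m=med["post_beta"].to_numpy(),
            y=med["bias"].to_numpy(),
            covariates=med[names].to_numpy(),
            covariate_names=names,
            n_boot=config.n_boot,
            level=config.ci_level,
            seed=int(next(seed_pool)),
        )
        mediation_out["+".join(names)] = res.to_dict()
        logger.info("mediation [%s]: ab=%.4f CI=%s", "+".join(names), res.ab, res.ci_ab)
    (out_dir / "mediation.json").write_text(
        json.dumps(mediation_out, indent=2, sort_keys=True) + "\n"
    )
    manifest["stages"]["mediation"] = {"n_in": int(n_before), "n_out": int(len(med))}

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
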
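"""Behavioral memory scoring: recognition rates and recall tallies.

Recognition follows the Remember/Know convention: an item is "called old"
iff the response is ``remember`` or ``know``.  Per participant and valence
we report hit rate (old items called old), false-alarm rate (new items
called old), corrected recognition (hits minus false alarms), and the
Remember/Know split of both rates.

Recall codings arrive per coder as (participant, item) -> code maps with
codes 0 (not recalled), 1 (recalled), and occasionally 2 (two recalled
descriptions matched the same picture).  Dual codings are reconciled by a
configurable rule (default: elementwise maximum, favouring "reported") and
tallied into per-valence correct counts plus an incorrect-recall count;
incorrect recalls are carried as sentinel items whose id starts with
``incorrect``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "VALENCES",
    "STATUSES",
    "RESPONSES",
    "CONDITIONS",
    "AGE_GROUPS",
    "INCORRECT_PREFIX",
    "compute_recognition_rates",
    "reconcile_coders",
    "tally_recall",
]

VALENCES = ("neutral", "positive", "negative")
STATUSES = ("old", "new")
RESPONSES = ("remember", "know", "new")
CONDITIONS = ("OscPlus", "OscMinus")
AGE_GROUPS = ("YA", "OA")

#: item_id prefix marking a recalled description that matched no study picture
INCORRECT_PREFIX = "incorrect"

_TRIAL_COLS = ["participant_id", "item_id", "valence", "status", "response"]
_CODING_COLS = ["participant_id", "item_id", "code"]


def compute_recognition_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x valence signal-detection rates from trial responses.

    Parameters
    ----------
    trials
        Long table with columns ``participant_id, item_id, valence, status,
        response``; one row per recognition trial.

    Returns
    -------
    DataFrame with one row per participant x valence and columns
    ``hit_rate, fa_rate, corrected_recognition, remember_hit_rate,
    know_hit_rate, remember_fa_rate, know_fa_rate, n_old, n_new``.

    Raises
    ------
    SchemaError
        On unknown labels, duplicate (participant, item) pairs, or an empty
        participant x valence x status cell (the message names it).
    """
    missing = [c for c in _TRIAL_COLS if c not in trials.columns]
    if missing:
        raise SchemaError(f"recognition table missing columns: {missing}")
    bad_resp = set(trials["response"]) - set(RESPONSES)
    if bad_resp:
        raise SchemaError(f"unknown response labels: {sorted(bad_resp)}")
    bad_val = set(trials["valence"]) - set(VALENCES)
    if bad_val:
        raise SchemaError(f"unknown valence labels: {sorted(bad_val)}")
    bad_stat = set(trials["status"]) - set(STATUSES)
    if bad_stat:
        raise SchemaError(f"unknown status labels: {sorted(bad_stat)}")
    if trials.duplicated(["participant_id", "item_id"]).any():
        dup = trials[trials.duplicated(["participant_id", "item_id"])].iloc[0]
        raise SchemaError(
            f"duplicate (participant_id, item_id): ({dup.participant_id}, {dup.item_id})"
        )

    t = trials.copy()
    t["called_old"] = t["response"].isin(["remember", "know"])
    t["remember"] = t["response"].eq("remember")
    t["know"] = t["response"].eq("know")

    g = t.groupby(["participant_id", "valence", "status"], sort=True, observed=True)
    agg = g.agg(n=("response", "size"),
                called_old=("called_old", "sum"),
                remember=("remember", "sum"),
                know=("know", "sum"))

    # every participant must have both statuses in every valence
    participants = t["participant_id"].unique()
    for pid in participants:
        for val in VALENCES:
            for st in STATUSES:
                if (pid, val, st) not in agg.index:
                    raise SchemaError(
                        f"empty recognition cell: participant {pid!r}, "
                        f"valence {val!r}, status {st!r}"
                    )

    wide = agg.unstack("status")
    rows = pd.DataFrame(index=wide.index)
    n_old = wide[("n", "old")]
    n_new = wide[("n", "new")]
    rows["hit_rate"] = wide[("called_old", "old")] / n_old
    rows["fa_rate"] = wide[("called_old", "new")] / n_new
    rows["corrected_recognition"] = rows["hit_rate"] - rows["fa_rate"]
    rows["remember_hit_rate"] = wide[("remember", "old")] / n_old
    rows["know_hit_rate"] = wide[("know", "old")] / n_old
    rows["remember_fa_rate"] = wide[("remember", "new")] / n_new
    rows["know_fa_rate"] = wide[("know", "new")] / n_new
    rows["n_old"] = n_old.astype(int)
    rows["n_new"] = n_new.astype(int)
    return rows.reset_index()


def reconcile_coders(
    coding_a: pd.DataFrame,
    coding_b: pd.DataFrame,
    rule: str = "max",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare two coders' recall codings and produce a merged coding.

    Where the coders agree the merged code is their common value; where
    they disagree the configured rule applies.  ``"max"`` (default) keeps
    the elementwise maximum, favouring "reported"; ``"a"`` defers to coder
    A.  The rule is an automated stand-in for the human adjudication step
    of dual-coding protocols.

    Returns
    -------
    (discrepancies, merged)
        ``discrepancies`` lists every (participant_id, item_id) with
        unequal codes plus both codes; ``merged`` has the coding columns
        of coder A with the resolved ``code``.

    Raises
    ------
    SchemaError
        If the two coders' (participant, item) index sets differ (the
        message lists missing keys).
    """
    for name, c in (("coding_a", coding_a), ("coding_b", coding_b)):
        missing = [col for col in _CODING_COLS if col not in c.columns]
        if missing:
            raise SchemaError(f"{name} missing columns: {missing}")
        bad = set(c["code"]) - {0, 1, 2}
        if bad:
            raise SchemaError(f"{name} contains invalid codes: {sorted(bad)}")
    key = ["participant_id", "item_id"]
    a = coding_a.set_index(key)["code"].sort_index()
    b = coding_b.set_index(key)["code"].sort_index()
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise SchemaError(
            "coder index sets differ; "
            f"missing from B: {list(only_a[:5])}, missing from A: {list(only_b[:5])}"
        )
    if rule not in ("max", "a"):
        raise ValueError(f"unknown resolution rule {rule!r}")

    disagree = a != b
    discrepancies = pd.DataFrame({
        "code_a": a[disagree],
        "code_b": b[disagree],
    }).reset_index()
    merged_code = np.maximum(a, b) if rule == "max" else a
    merged = merged_code.rename("code").reset_index()
    # carry week through when both coders agree on it
    if "week" in coding_a.columns:
        merged["week"] = coding_a["week"].iloc[0]
    return discrepancies, merged


def tally_recall(
    merged: pd.DataFrame,
    valence_map: dict | pd.Series,
    incorrect_prefix: str = INCORRECT_PREFIX,
) -> pd.DataFrame:
    """Sum merged recall codes into per-participant, per-valence counts.

    Codes are summed (a code 2 contributes 2), so a valence count can
    exceed the number of pictures only through code-2 entries.  Items
    whose id starts with ``incorrect_prefix`` are sentinel entries for
    recalled descriptions that matched no picture; their codes sum into
    the ``incorrect`` column.

    Raises
    ------
    SchemaError
        If a non-sentinel item_id is absent from ``valence_map``.
    """
    if isinstance(valence_map, pd.Series):
        valence_map = valence_map.to_dict()
    m = merged.copy()
    is_sentinel = m["item_id"].astype(str).str.startswith(incorrect_prefix)
    unmapped = set(m.loc[~is_sentinel, "item_id"]) - set(valence_map)
    if unmapped:
        raise SchemaError(f"items missing from valence map: {sorted(unmapped)[:5]}")
    m["valence"] = np.where(
        is_sentinel, "incorrect", m["item_id"].map(valence_map)
    )
    bad_val = set(m.loc[~is_sentinel, "valence"]) - set(VALENCES)
    if bad_val:
        raise SchemaError(f"valence map contains unknown valences: {sorted(bad_val)}")

    pivot = (
        m.pivot_table(index="participant_id", columns="valence", values="code",
                      aggfunc="sum", fill_value=0)
        .reindex(columns=list(VALENCES) + ["incorrect"], fill_value=0)
    )
    out = pd.DataFrame({
        "participant_id": pivot.index,
        "correct_neutral": pivot["neutral"].to_numpy(),
        "correct_positive": pivot["positive"].to_numpy(),
        "correct_negative": pivot["negative"].to_numpy(),
        "incorrect": pivot["incorrect"].to_numpy(),
    }).reset_index(drop=True)
    if "week" in merged.columns:
        out["week"] = merged["week"].iloc[0]
    return out
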
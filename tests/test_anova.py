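"""Mixed ANOVA against cell-means/split-plot oracles and reference libraries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emobias import (
    DegenerateInputError,
    DesignError,
    fit_mixed_anova,
    partial_eta_squared,
    welch_or_student_t,
)


def _long(Y, groups, within_name="valence", between_name="condition"):
    """Y: subjects x within-levels matrix; groups: subject group labels."""
    n, w = Y.shape
    rows = []
    for s in range(n):
        for j in range(w):
            rows.append({
                "participant_id": f"S{s}", between_name: groups[s],
                within_name: f"w{j}", "dv": Y[s, j],
            })
    return pd.DataFrame(rows)


def splitplot_oracle(Y, groups):
    """Balanced one-between one-within split-plot by direct cell-mean sums."""
    n, w = Y.shape
    levels = sorted(set(groups))
    g = len(levels)
    npg = n // g
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = {lv: Y[[i for i in range(n) if groups[i] == lv]].mean() for lv in levels}
    w_means = Y.mean(axis=0)
    cell = {lv: Y[[i for i in range(n) if groups[i] == lv]].mean(axis=0) for lv in levels}

    ss_between_subj = w * sum((sm - grand) ** 2 for sm in subj_means)
    ss_group = npg * w * sum((group_means[lv] - grand) ** 2 for lv in levels)
    ss_subj_within = ss_between_subj - ss_group
    ss_w = n * sum((wm - grand) ** 2 for wm in w_means)
    ss_gw = npg * sum(
        (cell[lv][j] - group_means[lv] - w_means[j] + grand) ** 2
        for lv in levels for j in range(w)
    )
    ss_total = ((Y - grand) ** 2).sum()
    ss_err_w = ss_total - ss_between_subj - ss_w - ss_gw
    return {
        "group": (ss_group, g - 1, ss_subj_within, g * (npg - 1)),
        "within": (ss_w, w - 1, ss_err_w, g * (npg - 1) * (w - 1)),
        "interaction": (ss_gw, (g - 1) * (w - 1), ss_err_w, g * (npg - 1) * (w - 1)),
    }


def test_balanced_two_by_three_matches_cell_means_oracle(rng):
    Y = rng.normal(size=(8, 3))
    groups = ["A"] * 4 + ["B"] * 4
    tab = fit_mixed_anova(_long(Y, groups), between=["condition"], within=["valence"])
    tab = tab.set_index("effect")
    oracle = splitplot_oracle(Y, groups)
    mapping = {"condition": "group", "valence": "within", "condition:valence": "interaction"}
    for effect, key in mapping.items():
        ss, dfe, ss_err, dferr = oracle[key]
        row = tab.loc[effect]
        assert row["ss"] == pytest.approx(ss, abs=1e-8)
        assert row["df_effect"] == dfe
        assert row["ss_error"] == pytest.approx(ss_err, abs=1e-8)
        assert row["df_error"] == dferr
        F = (ss / dfe) / (ss_err / dferr)
        assert row["F"] == pytest.approx(F, abs=1e-8)
        assert row["p"] == pytest.approx(stats.f.sf(F, dfe, dferr), abs=1e-10)


def test_agrees_with_pingouin_mixed_anova(rng):
    """Independent-library cross-check on a balanced design.

    (On unbalanced designs this engine reports Type III, unweighted-means
    within-subject effects, which legitimately differ from pingouin's
    weighted-means sums of squares; the unbalanced between-subjects path
    is cross-checked against statsmodels Type III below.)
    """
    pg = pytest.importorskip("pingouin")
    Y = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
    groups = ["A"] * 6 + ["B"] * 6
    data = _long(Y, groups)
    ours = fit_mixed_anova(data, between=["condition"], within=["valence"]).set_index("effect")
    ref = pg.mixed_anova(data=data, dv="dv", within="valence", subject="participant_id",
                         between="condition").set_index("Source")
    assert ours.loc["condition", "F"] == pytest.approx(ref.loc["condition", "F"], rel=1e-6)
    assert ours.loc["valence", "F"] == pytest.approx(ref.loc["valence", "F"], rel=1e-6)
    assert ours.loc["condition:valence", "F"] == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-6)
    assert ours.loc["valence", "df_error"] == ref.loc["valence", "DF2"]
    assert ours.loc["valence", "partial_eta_sq"] == pytest.approx(
        ref.loc["valence", "np2"], rel=1e-6)


def test_between_only_two_by_two_agrees_with_statsmodels_type3(rng):
    """2x2 between-subjects Type III SS vs statsmodels with sum coding."""
    smf = pytest.importorskip("statsmodels.formula.api")
    from statsmodels.stats.anova import anova_lm

    n = 37  # deliberately unbalanced
    df = pd.DataFrame({
        "participant_id": [f"S{i}" for i in range(n)],
        "condition": rng.choice(["A", "B"], size=n, p=[0.6, 0.4]),
        "age_group": rng.choice(["Y", "O"], size=n),
        "dv": rng.normal(size=n),
    })
    ours = fit_mixed_anova(df, between=["condition", "age_group"]).set_index("effect")
    model = smf.ols("dv ~ C(condition, Sum) * C(age_group, Sum)", data=df).fit()
    ref = anova_lm(model, typ=3)
    assert ours.loc["condition", "ss"] == pytest.approx(
        ref.loc["C(condition, Sum)", "sum_sq"], rel=1e-8)
    assert ours.loc["age_group", "ss"] == pytest.approx(
        ref.loc["C(age_group, Sum)", "sum_sq"], rel=1e-8)
    assert ours.loc["condition:age_group", "ss"] == pytest.approx(
        ref.loc["C(condition, Sum):C(age_group, Sum)", "sum_sq"], rel=1e-8)
    assert ours.loc["condition", "F"] == pytest.approx(
        ref.loc["C(condition, Sum)", "F"], rel=1e-8)


def test_two_within_factors_df_structure(rng):
    """2 between x 2 between x 3 within x 2 within: df bookkeeping."""
    n = 24
    groups_c = ["A"] * 12 + ["B"] * 12
    groups_a = (["Y"] * 6 + ["O"] * 6) * 2
    rows = []
    for s in range(n):
        for v in ("neu", "pos", "neg"):
            for t in (4, 5):
                rows.append({
                    "participant_id": f"S{s}", "condition": groups_c[s],
                    "age_group": groups_a[s], "valence": v, "week": t,
                    "dv": rng.normal(),
                })
    tab = fit_mixed_anova(pd.DataFrame(rows), between=["condition", "age_group"],
                          within=["valence", "week"]).set_index("effect")
    err_between = n - 4
    assert tab.loc["condition", ("df_error")] == err_between
    assert tab.loc["valence", "df_effect"] == 2
    assert tab.loc["valence", "df_error"] == 2 * err_between
    assert tab.loc["week", "df_effect"] == 1
    assert tab.loc["week", "df_error"] == err_between
    assert tab.loc["valence:week", "df_effect"] == 2
    assert tab.loc["valence:week", "df_error"] == 2 * err_between
    assert tab.loc["condition:age_group:valence:week", "df_effect"] == 2
    # all 15 effects present (3 between + 4 strata x 3)
    assert len(tab) == 15


def test_within_only_agrees_with_anovarm(rng):
    """No between factors: matches statsmodels repeated-measures ANOVA."""
    from statsmodels.stats.anova import AnovaRM

    n = 10
    rows = []
    for s in range(n):
        for v in ("a", "b", "c", "d"):
            rows.append({"participant_id": f"S{s}", "valence": v, "dv": rng.normal()})
    df = pd.DataFrame(rows)
    ours = fit_mixed_anova(df, within=["valence"]).set_index("effect")
    ref = AnovaRM(df, depvar="dv", subject="participant_id", within=["valence"]).fit()
    assert ours.loc["valence", "F"] == pytest.approx(
        ref.anova_table.loc["valence", "F Value"], rel=1e-8)
    assert ours.loc["valence", "df_error"] == ref.anova_table.loc["valence", "Den DF"]


def test_shift_invariance_of_F(rng):
    Y = rng.normal(size=(10, 3))
    groups = ["A"] * 5 + ["B"] * 5
    t1 = fit_mixed_anova(_long(Y, groups), between=["condition"], within=["valence"])
    t2 = fit_mixed_anova(_long(Y + 100.0, groups), between=["condition"], within=["valence"])
    np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-9)


def test_participant_label_permutation_invariance(rng):
    Y = rng.normal(size=(10, 3))
    groups = ["A"] * 5 + ["B"] * 5
    data = _long(Y, groups)
    relabel = {f"S{i}": f"Z{99 - i}" for i in range(10)}
    shuffled = data.assign(participant_id=data["participant_id"].map(relabel))
    shuffled = shuffled.sample(frac=1.0, random_state=3).reset_index(drop=True)
    t1 = fit_mixed_anova(data, between=["condition"], within=["valence"]).set_index("effect")
    t2 = fit_mixed_anova(shuffled, between=["condition"], within=["valence"]).set_index("effect")
    np.testing.assert_allclose(t1["F"], t2.loc[t1.index, "F"], rtol=1e-9)


def test_constant_dv_flags_degenerate(rng):
    Y = np.full((8, 3), 2.5)
    groups = ["A"] * 4 + ["B"] * 4
    tab = fit_mixed_anova(_long(Y, groups), between=["condition"], within=["valence"])
    assert (tab["ss"] == 0).all()
    assert (tab["F"] == 0).all()
    assert (tab["partial_eta_sq"] == 0).all()
    assert tab["degenerate"].all()


def test_missing_within_cell_lists_participant(rng):
    Y = rng.normal(size=(8, 3))
    data = _long(Y, ["A"] * 4 + ["B"] * 4)
    data = data[~((data.participant_id == "S2") & (data.valence == "w1"))]
    with pytest.raises(DesignError, match="S2"):
        fit_mixed_anova(data, between=["condition"], within=["valence"])


def test_partial_eta_squared_values():
    assert partial_eta_squared(0.0, 5.0) == 0.0
    assert partial_eta_squared(5.0, 0.0) == 1.0
    assert partial_eta_squared(2.0, 6.0) == 0.25
    with pytest.raises(DegenerateInputError):
        partial_eta_squared(0.0, 0.0)


def test_t_statistic_identical_groups():
    t, df, p = welch_or_student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)
    assert df == 4


def test_t_statistic_separated_groups():
    t, df, p = welch_or_student_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    assert abs(t) > 50 and p < 1e-6


def test_t_matches_scipy_oracle(rng):
    a = rng.normal(size=5)
    b = rng.normal(1.0, 2.0, size=5)
    t, df, p = welch_or_student_t(a, b)
    ref = stats.ttest_ind(a, b, equal_var=True)
    assert t == pytest.approx(ref.statistic, abs=1e-12)
    assert p == pytest.approx(ref.pvalue, abs=1e-12)
    tw, dfw, pw = welch_or_student_t(a, b, welch=True)
    refw = stats.ttest_ind(a, b, equal_var=False)
    assert tw == pytest.approx(refw.statistic, abs=1e-12)
    assert pw == pytest.approx(refw.pvalue, abs=1e-12)


def test_zero_variance_rejected():
    with pytest.raises(DegenerateInputError):
        welch_or_student_t([1.0, 1.0, 1.0], [1.0, 1.0])
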
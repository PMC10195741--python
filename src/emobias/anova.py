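"""Mixed-design factorial ANOVA with partial eta-squared.

Supports up to two between-subjects and two within-subjects factors on
long-format data where every participant contributes exactly one
observation per within-subject cell (a split-plot design).  Effects are
tested against the error stratum they belong to:

* between-subjects effects against subjects-within-groups error, computed
  from an OLS fit to each subject's mean across within cells;
* each within-subjects effect (and its interactions with between factors)
  against its own effect-by-subjects-within-groups error, computed by
  projecting each subject's within-cell profile onto an orthonormal
  contrast basis for that effect and regressing the contrast scores on the
  between design.

Between-subjects sums of squares are Type III via sum-to-zero (effects)
coding with the full factorial model, matching the default of the major
commercial packages, so unequal group sizes are handled.  No sphericity
correction is applied (integer degrees of freedom are reported).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DesignError

__all__ = ["fit_mixed_anova", "partial_eta_squared", "welch_or_student_t"]

_ZERO_TOL = 1e-12


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size ``SS_effect / (SS_effect + SS_error)``."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise DegenerateInputError("both sums of squares are zero; eta_p^2 undefined")
    return ss_effect / (ss_effect + ss_error)


def welch_or_student_t(group_a, group_b, welch: bool = False):
    """Two-sample t test; pooled-variance by default, Welch on request.

    Returns ``(t, df, p)`` with a two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            raise DegenerateInputError("zero variance in both groups")
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0.0:
            raise DegenerateInputError("zero pooled variance")
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _effects_code(levels: pd.Series, level_order: list) -> np.ndarray:
    """Sum-to-zero coding: k levels -> k-1 columns; last level codes -1."""
    k = len(level_order)
    idx = levels.map({lv: i for i, lv in enumerate(level_order)}).to_numpy()
    X = np.zeros((len(levels), k - 1))
    for j in range(k - 1):
        X[idx == j, j] = 1.0
    X[idx == k - 1, :] = -1.0
    return X


def _between_design(subjects: pd.DataFrame, between: list[str]):
    """Full-factorial effects-coded design over the between factors.

    Returns ``(X, terms)`` where ``terms`` maps term name -> column slice.
    """
    n = len(subjects)
    cols = [np.ones((n, 1))]
    terms: dict[str, slice] = {"Intercept": slice(0, 1)}
    start = 1
    level_orders = {}
    mains = {}
    for f in between:
        order = list(pd.unique(subjects[f]))
        if len(order) < 2:
            raise DesignError(f"between factor {f!r} has fewer than 2 levels")
        level_orders[f] = order
        Xf = _effects_code(subjects[f], order)
        mains[f] = Xf
        cols.append(Xf)
        terms[f] = slice(start, start + Xf.shape[1])
        start += Xf.shape[1]
    if len(between) == 2:
        f1, f2 = between
        X1, X2 = mains[f1], mains[f2]
        inter = np.einsum("ni,nj->nij", X1, X2).reshape(n, -1)
        cols.append(inter)
        terms[f"{f1}:{f2}"] = slice(start, start + inter.shape[1])
        start += inter.shape[1]
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("between-subjects design is rank deficient (empty cell?)")
    return X, terms


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _type3_ss(X: np.ndarray, terms: dict[str, slice], Y: np.ndarray):
    """Type III SS per term, summed over response columns of ``Y``.

    Returns ``(ss_terms, rss_full)``; the intercept's SS is the drop-one
    test of the constant, which in a contrast-score regression is the test
    of the within-subject effect itself.
    """
    if Y.ndim == 1:
        Y = Y[:, None]
    rss_full = sum(_rss(X, Y[:, j]) for j in range(Y.shape[1]))
    ss = {}
    for name, sl in terms.items():
        keep = np.ones(X.shape[1], bool)
        keep[sl] = False
        Xr = X[:, keep]
        rss_red = sum(_rss(Xr, Y[:, j]) for j in range(Y.shape[1]))
        ss[name] = max(rss_red - rss_full, 0.0)
    return ss, rss_full


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis orthogonal to the constant vector."""
    A = np.hstack([np.ones((k, 1)) / np.sqrt(k), np.eye(k)[:, : k - 1]])
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:k]


def _within_bases(within_levels: dict[str, list]):
    """Orthonormal contrast matrix per within term over the within-cell grid.

    Cells are ordered as the cartesian product of the factor level lists.
    """
    factors = list(within_levels)
    sizes = [len(within_levels[f]) for f in factors]
    ones = [np.ones((s, 1)) / np.sqrt(s) for s in sizes]
    H = [_orthonormal_contrasts(s) for s in sizes]
    bases: dict[str, np.ndarray] = {}
    if len(factors) >= 1:
        parts = [H[0]] + ones[1:]
        bases[factors[0]] = _kron_all(parts)
    if len(factors) == 2:
        bases[factors[1]] = _kron_all([ones[0], H[1]])
        bases[f"{factors[0]}:{factors[1]}"] = _kron_all([H[0], H[1]])
    return bases


def _kron_all(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def fit_mixed_anova(
    data: pd.DataFrame,
    dv: str = "dv",
    subject: str = "participant_id",
    between: list[str] | tuple[str, ...] = (),
    within: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mixed-design factorial ANOVA table.

    Parameters
    ----------
    data
        Long format: one row per subject x within-cell observation, with
        the dependent variable in column ``dv`` and factor level columns.
    between, within
        Factor column names; up to 2 of each.  ``within=()`` gives a
        purely between-subjects factorial ANOVA.

    Returns
    -------
    DataFrame with one row per effect: ``effect, ss, df_effect, ss_error,
    df_error, F, p, partial_eta_sq, degenerate``.  ``degenerate`` flags
    effects whose error stratum has (numerically) zero sum of squares, in
    which case F is reported as 0.

    Raises
    ------
    DesignError
        On missing within-cells (listing offending participants), empty
        between-cells, or fewer than 2 subjects in a between cell.
    """
    between = list(between)
    within = list(within)
    if len(between) > 2 or len(within) > 2:
        raise DesignError("at most 2 between and 2 within factors are supported")
    for col in [dv, subject, *between, *within]:
        if col not in data.columns:
            raise DesignError(f"column {col!r} not in data")

    within_levels = {f: list(pd.unique(data[f])) for f in within}
    cell_cols = within if within else []
    if cell_cols:
        grid = list(product(*[within_levels[f] for f in within]))
        pv = data.pivot_table(index=subject, columns=cell_cols, values=dv,
                              aggfunc="size", fill_value=0)
        counts = data.groupby([subject, *cell_cols], observed=True)[dv].size()
        if (counts != 1).any():
            bad = counts[counts != 1].index.get_level_values(0).unique().tolist()
            raise DesignError(
                f"each participant needs exactly one observation per within-cell; "
                f"offending participants: {bad[:10]}"
            )
        full = data.pivot_table(index=subject, columns=cell_cols, values=dv)
        if full.isna().any().any():
            bad = full.index[full.isna().any(axis=1)].tolist()
            raise DesignError(f"participants missing within-cells: {bad[:10]}")
        # order columns as the cartesian product of level lists
        if len(within) == 1:
            full = full.reindex(columns=[g[0] for g in grid])
        else:
            full = full.reindex(columns=pd.MultiIndex.from_tuples(grid))
        Y = full.to_numpy()
        subj_index = full.index
    else:
        counts = data.groupby(subject, observed=True)[dv].size()
        if (counts != 1).any():
            bad = counts[counts != 1].index.tolist()
            raise DesignError(
                f"purely between design needs one row per participant; duplicated: {bad[:10]}"
            )
        Y = data.set_index(subject)[dv].to_frame().to_numpy()
        subj_index = data.set_index(subject).index

    subjects = (
        data.drop_duplicates(subject).set_index(subject).loc[subj_index].reset_index()
    )
    for f in between:
        per_subj = data.groupby(subject, observed=True)[f].nunique()
        if (per_subj > 1).any():
            raise DesignError(f"between factor {f!r} varies within a participant")
    if between:
        cell_n = subjects.groupby(between, observed=True)[subject].size()
        if (cell_n < 2).any():
            raise DesignError(
                f"between cells need >= 2 participants; sizes: {cell_n.to_dict()}"
            )

    n_subj, W = Y.shape
    X, terms = _between_design(subjects, between)
    p_full = X.shape[1]
    rows = []

    ss_floor = _ZERO_TOL * max(1.0, float(np.abs(Y).max()) ** 2) * Y.size

    def add_row(effect, ss_eff, df_eff, ss_err, df_err):
        # clamp numerical dust from RSS differencing to an exact zero
        if ss_eff <= ss_floor:
            ss_eff = 0.0
        if ss_err <= ss_floor:
            ss_err = 0.0
        degenerate = ss_err == 0.0
        if degenerate:
            F = 0.0
            p = 1.0
        else:
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            F = ms_eff / ms_err
            p = float(stats.f.sf(F, df_eff, df_err))
        if ss_eff <= _ZERO_TOL and ss_err <= _ZERO_TOL:
            eta = 0.0
        else:
            eta = partial_eta_squared(max(ss_eff, 0.0), max(ss_err, 0.0))
        rows.append({
            "effect": effect, "ss": ss_eff, "df_effect": df_eff,
            "ss_error": ss_err, "df_error": df_err, "F": F, "p": p,
            "partial_eta_sq": eta, "degenerate": degenerate,
        })

    # ---- between stratum: subject means, SS rescaled to the dv scale ----
    ybar = Y.mean(axis=1)
    ss_b, rss_b = _type3_ss(X, terms, ybar)
    df_err_b = n_subj - p_full
    for name, sl in terms.items():
        if name == "Intercept":
            continue
        df_eff = sl.stop - sl.start
        add_row(name, W * ss_b[name], df_eff, W * rss_b, df_err_b)

    # ---- within strata: one per within term ----
    if within:
        bases = _within_bases(within_levels)
        for wterm, C in bases.items():
            S = Y @ C  # n_subj x q contrast scores
            q = C.shape[1]
            ss_w, rss_w = _type3_ss(X, terms, S)
            df_err = q * (n_subj - p_full)
            for bname, sl in terms.items():
                if bname == "Intercept":
                    effect = wterm
                    df_b = 1
                else:
                    effect = f"{bname}:{wterm}"
                    df_b = sl.stop - sl.start
                add_row(effect, ss_w[bname], df_b * q, rss_w, df_err)

    return pd.DataFrame(rows)
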
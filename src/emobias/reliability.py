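"""Krippendorff's alpha inter-rater reliability with a unit-resampling bootstrap.

Agreement between coders over units (here, participant x picture pairs with
recall-match codes 0/1/2) is summarised as ``alpha = 1 - Do/De``, where
``Do`` is the observed disagreement computed over all pairs of codings
within each unit (each unit's pairs weighted by ``1/(m_u - 1)``) and
``De`` is the disagreement expected by chance from the marginal code
frequencies.  Missing codings are allowed and excluded per-unit; units
with fewer than two codings contribute nothing.

The default nominal metric treats codes as unordered categories (a match
code of 2 is "matched twice", not "twice as matched"); an interval metric
is available for genuinely ordered codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .mediation import percentile_ci

__all__ = ["ReliabilityResult", "krippendorff_alpha", "bootstrap_alpha_ci"]


def _as_matrix(codes) -> np.ndarray:
    """Coerce a coders x units code matrix to float with NaN for missing."""
    if isinstance(codes, pd.DataFrame):
        codes = codes.to_numpy()
    arr = np.asarray(codes, dtype=float)
    if arr.ndim != 2:
        raise ValueError("codes must be a 2-D coders x units matrix")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 coders")
    return arr


def _delta_sq(values: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise squared-difference matrix for the chosen metric."""
    if metric == "nominal":
        return 1.0 - np.eye(values.size)
    if metric == "interval":
        d = values[:, None] - values[None, :]
        return d * d
    raise ValueError(f"unknown metric {metric!r}; use 'nominal' or 'interval'")


def krippendorff_alpha(codes, metric: str = "nominal") -> float:
    """Point estimate of Krippendorff's alpha.

    Parameters
    ----------
    codes
        ``(n_coders, n_units)`` array or DataFrame; NaN marks a missing
        coding (excluded per-unit).
    metric
        ``"nominal"`` (default) or ``"interval"``.

    Raises
    ------
    DegenerateInputError
        If every pairable coding is the same single value: expected
        disagreement is zero and alpha is undefined (not silently 1.0).
    """
    arr = _as_matrix(codes)
    m_u = np.sum(~np.isnan(arr), axis=0)  # codings per unit
    usable = m_u >= 2
    if not usable.any():
        raise ValueError("need at least one unit with >= 2 codings")
    arr = arr[:, usable]
    m_u = m_u[usable]

    values = np.unique(arr[~np.isnan(arr)])
    if values.size < 2:
        raise DegenerateInputError(
            "all pairable codings share a single value; expected disagreement "
            "is zero and alpha is undefined"
        )
    delta = _delta_sq(values, metric)

    # per-unit value counts -> coincidence-matrix contributions
    v_index = {v: i for i, v in enumerate(values)}
    n_vals = values.size
    n_units = arr.shape[1]
    counts = np.zeros((n_units, n_vals))
    for i, v in enumerate(values):
        counts[:, i] = np.sum(arr == v, axis=0)

    # observed disagreement: ordered within-unit pairs weighted 1/(m_u-1)
    pair_disagree = np.einsum("uc,uk,ck->u", counts, counts, delta)
    Do_num = np.sum(pair_disagree / (m_u - 1))
    n_pairable = float(m_u.sum())
    Do = Do_num / n_pairable

    n_c = counts.sum(axis=0)
    De = np.einsum("c,k,ck->", n_c, n_c, delta) / (n_pairable * (n_pairable - 1.0))
    if De == 0.0:
        raise DegenerateInputError("expected disagreement is zero; alpha undefined")
    return float(1.0 - Do / De)


@dataclass
class ReliabilityResult:
    """Alpha with a bootstrap percentile interval over resampled units."""

    alpha: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int | None
    n_degenerate: int = 0
    replicates: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "level": self.level,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
        }


def bootstrap_alpha_ci(
    codes,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    metric: str = "nominal",
) -> ReliabilityResult:
    """Nonparametric bootstrap CI for alpha: resample units with replacement.

    Replicates in which the resampled matrix is degenerate (a single
    distinct code) are skipped and counted in ``n_degenerate``; if every
    replicate is degenerate an error is raised.
    """
    arr = _as_matrix(codes)
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: interval will be unstable", stacklevel=2)
    point = krippendorff_alpha(arr, metric=metric)
    rng = np.random.default_rng(seed)
    n_units = arr.shape[1]
    reps = []
    n_degenerate = 0
    for _ in range(n_boot):
        cols = rng.integers(0, n_units, size=n_units)
        try:
            reps.append(krippendorff_alpha(arr[:, cols], metric=metric))
        except DegenerateInputError:
            n_degenerate += 1
    if not reps:
        raise DegenerateInputError("all bootstrap replicates were degenerate")
    reps = np.asarray(reps)
    if reps.size >= 100:
        lo, hi = percentile_ci(reps, level)
    else:
        lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
        lo, hi = float(lo), float(hi)
    return ReliabilityResult(
        alpha=point, ci_low=lo, ci_high=hi, n_boot=n_boot, level=level,
        seed=seed, n_degenerate=n_degenerate, replicates=reps,
    )
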
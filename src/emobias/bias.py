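"""Positive emotional memory bias composite.

The composite contrasts memory for positive versus negative material using
the two retrieval-bias-sensitive measures: false-alarm rates from the
recognition test (differential false alarms to new items indicate a
response bias toward a valence) and correct free-recall counts.  Each of
the four inputs is z-scored across participants and combined as::

    bias = (z_fa_pos - z_fa_neg) + (z_rec_pos - z_rec_neg)

so false recognition and recall contribute equally, and a higher score
means memory tilted toward positive material.  By construction the sample
mean of the composite is zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SchemaError

__all__ = ["standardize", "compute_bias_scores"]


def standardize(values) -> np.ndarray:
    """Z-score a vector: subtract the mean, divide by the sample SD (ddof=1).

    Raises
    ------
    DegenerateInputError
        On fewer than 2 values, zero spread, or missing values (missing
        data must be handled listwise upstream, never silently here).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need a 1-D vector with at least 2 values")
    if np.isnan(x).any():
        raise DegenerateInputError(
            "missing values present; apply listwise exclusion before z-scoring"
        )
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("constant input has zero spread; z-scores undefined")
    return (x - x.mean()) / sd


_COLS = ("fa_pos", "fa_neg", "rec_pos", "rec_neg")


def compute_bias_scores(
    fa_pos: pd.Series,
    fa_neg: pd.Series,
    rec_pos: pd.Series,
    rec_neg: pd.Series,
) -> pd.DataFrame:
    """Composite positive-memory-bias score per participant.

    All four series must be indexed by the same participant set
    (listwise-complete); z-scores are computed on that intersection-free
    common sample.

    Returns
    -------
    DataFrame indexed by participant with columns ``z_fa_pos, z_fa_neg,
    z_rec_pos, z_rec_neg, bias``.
    """
    series = dict(zip(_COLS, (fa_pos, fa_neg, rec_pos, rec_neg)))
    base_index = fa_pos.index
    for name, s in series.items():
        if not isinstance(s, pd.Series):
            raise SchemaError(f"{name} must be a pandas Series indexed by participant")
        if len(s.index.symmetric_difference(base_index)):
            raise SchemaError(
                f"{name} index does not match fa_pos index; "
                "inputs must be listwise-complete over one participant set"
            )
    out = pd.DataFrame(index=base_index)
    for name, s in series.items():
        try:
            out[f"z_{name}"] = standardize(s.reindex(base_index).to_numpy())
        except DegenerateInputError as e:
            raise DegenerateInputError(f"column {name}: {e}") from e
    out["bias"] = (out["z_fa_pos"] - out["z_fa_neg"]) + (out["z_rec_pos"] - out["z_rec_neg"])
    return out
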
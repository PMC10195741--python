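"""Single-mediator mediation with covariates and percentile-bootstrap inference.

Implements the product-of-coefficients decomposition for one exposure ``x``,
one mediator ``m``, and one outcome ``y``::

    m = i_1 + a*x           (+ covariates)
    y = i_2 + c'*x + b*m    (+ covariates)
    y = i_3 + c*x           (+ covariates)

The indirect effect is ``ab = a*b`` and the OLS identity ``c = c' + a*b``
holds exactly whenever all three regressions share the same sample and
covariate set.  Inference for every path uses a case-resampling bootstrap
(participant rows resampled with replacement, all regressions refit) with
percentile intervals; the analytic Sobel test is provided as a cross-check.

Covariates enter all three regressions, mirroring the semantics of a
standard single-mediator macro (PROCESS Model 4).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, DesignError

__all__ = [
    "OLSFit",
    "MediationResult",
    "ols",
    "fit_model4",
    "percentile_ci",
    "sobel",
]


@dataclass(frozen=True)
class OLSFit:
    """Coefficients and classical standard errors of a least-squares fit."""

    coef: np.ndarray
    se: np.ndarray
    resid_var: float  # unbiased estimate, SSR / (n - p)
    df_resid: int
    fitted: np.ndarray
    residuals: np.ndarray


def ols(design: np.ndarray, response: np.ndarray) -> OLSFit:
    """Ordinary least squares on an explicit design matrix.

    Parameters
    ----------
    design
        ``(n, p)`` matrix including any intercept column the caller wants.
    response
        ``(n,)`` vector.

    Raises
    ------
    DesignError
        If ``n <= p`` or the design is rank deficient (the message names
        the columns involved in the collinearity).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2:
        raise DesignError("design must be a 2-D matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise DesignError(f"response length {y.shape} does not match design rows {n}")
    if n <= p:
        raise DesignError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns whose removal restores full rank
        culprits = [
            j for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DesignError(
            f"design is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {culprits}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    df_resid = n - p
    resid_var = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(resid_var * np.diag(XtX_inv), 0.0, None))
    return OLSFit(coef=coef, se=se, resid_var=resid_var, df_resid=df_resid,
                  fitted=fitted, residuals=resid)


def percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval of a vector of bootstrap replicates.

    Uses linear interpolation between order statistics (``numpy.quantile``
    default) so intervals are reproducible across platforms.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or draws.size < 100:
        raise DegenerateInputError(
            f"need at least 100 replicate draws for a percentile interval, got {draws.size}"
        )
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    lo, hi = np.quantile(draws, [(1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0])
    return float(lo), float(hi)


def sobel(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel first-order test of the indirect effect ``a*b``.

    Returns ``(z, p)`` with ``z = ab / sqrt(b^2 se_a^2 + a^2 se_b^2)`` and a
    two-sided normal p-value.  Serves as an analytic cross-check of the
    bootstrap interval; the bootstrap is the primary inference.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    if denom == 0.0:
        return 0.0, 1.0
    z = (a * b) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class MediationResult:
    """Paths, standard errors, and bootstrap percentile intervals."""

    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    ci_a: tuple[float, float] | None
    ci_b: tuple[float, float] | None
    ci_c: tuple[float, float] | None
    ci_c_prime: tuple[float, float] | None
    ci_ab: tuple[float, float] | None
    n: int
    n_boot: int
    level: float
    seed: int | None
    covariate_names: list[str] = field(default_factory=list)
    n_redraws: int = 0

    def to_dict(self) -> dict:
        d = {
            "a": self.a, "b": self.b, "c": self.c,
            "c_prime": self.c_prime, "ab": self.ab,
            "se_a": self.se_a, "se_b": self.se_b,
            "se_c": self.se_c, "se_c_prime": self.se_c_prime,
            "ci_a": self.ci_a, "ci_b": self.ci_b, "ci_c": self.ci_c,
            "ci_c_prime": self.ci_c_prime, "ci_ab": self.ci_ab,
            "n": self.n, "n_boot": self.n_boot, "level": self.level,
            "seed": self.seed, "covariate_names": list(self.covariate_names),
            "n_redraws": self.n_redraws,
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _batched_coef(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Solve B stacked least-squares problems via normal equations.

    ``Xb`` is ``(B, n, p)``, ``yb`` is ``(B, n)``; returns ``(B, p)``.
    Falls back to a pseudoinverse if any replicate is singular.
    """
    Xt = Xb.transpose(0, 2, 1)
    G = Xt @ Xb
    h = Xt @ yb[..., None]  # (B, p, 1)
    try:
        return np.linalg.solve(G, h)[..., 0]
    except np.linalg.LinAlgError:
        return (np.linalg.pinv(G) @ h)[..., 0]


def fit_model4(
    x,
    m,
    y,
    covariates=None,
    covariate_names: list[str] | None = None,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """Fit the single-mediator model and bootstrap all paths.

    Parameters
    ----------
    x, m, y
        Exposure codes, mediator values, outcome values; equal length,
        listwise complete.  ``x`` must take at least two distinct values.
    covariates
        Optional ``(n, k)`` array entered in all three regressions.
    n_boot
        Bootstrap replicates; ``0`` fits point estimates only (no CIs),
        useful for large calibration studies.
    seed
        Seeds the case-resampling; identical inputs and seed give a
        bit-identical result.

    Notes
    -----
    Bootstrap replicates in which the resampled exposure is constant
    cannot identify the paths; they are redrawn and counted
    (``n_redraws``), with a warning if redraws exceed 10% of ``n_boot``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise DesignError("x, m, y must have equal length")
    if np.unique(x).size < 2:
        raise DesignError("exposure x must take at least 2 distinct values")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if not np.all(np.isfinite(v)):
            raise DesignError(f"{name} contains non-finite values; listwise-complete input required")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise DesignError("covariate rows must match x length")
        if not np.all(np.isfinite(Z)):
            raise DesignError("covariates contain non-finite values")
    if covariate_names is None:
        covariate_names = [f"cov{i}" for i in range(Z.shape[1])]
    if len(covariate_names) != Z.shape[1]:
        raise DesignError("covariate_names length must match covariate columns")

    ones = np.ones((n, 1))
    X_a = np.hstack([ones, x[:, None], Z])          # m ~ x (+Z);      a at col 1
    X_y = np.hstack([ones, m[:, None], x[:, None], Z])  # y ~ m + x (+Z); b at 1, c' at 2
    X_c = np.hstack([ones, x[:, None], Z])          # y ~ x (+Z);      c at col 1

    fit_a = ols(X_a, m)
    fit_y = ols(X_y, y)
    fit_c = ols(X_c, y)
    a, se_a = float(fit_a.coef[1]), float(fit_a.se[1])
    b, se_b = float(fit_y.coef[1]), float(fit_y.se[1])
    c_prime, se_cp = float(fit_y.coef[2]), float(fit_y.se[2])
    c, se_c = float(fit_c.coef[1]), float(fit_c.se[1])
    ab = a * b

    ci_a = ci_b = ci_c = ci_cp = ci_ab = None
    n_redraws = 0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        # redraw replicates whose resampled exposure is constant
        for _ in range(1000):
            xb = x[idx]
            bad = np.all(xb == xb[:, :1], axis=1)
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            n_redraws += n_bad
            idx[bad] = rng.integers(0, n, size=(n_bad, n))
        else:
            raise DegenerateInputError(
                "could not draw bootstrap replicates with non-constant exposure"
            )
        if n_redraws > 0.10 * n_boot:
            warnings.warn(
                f"{n_redraws} bootstrap redraws (> 10% of {n_boot}): "
                "exposure groups are very unbalanced",
                stacklevel=2,
            )
        # batched refits, chunked to bound memory
        a_s = np.empty(n_boot)
        b_s = np.empty(n_boot)
        cp_s = np.empty(n_boot)
        c_s = np.empty(n_boot)
        chunk = max(1, int(2e7) // max(1, n * X_y.shape[1]))
        for start in range(0, n_boot, chunk):
            sl = slice(start, min(start + chunk, n_boot))
            ii = idx[sl]
            coef_a = _batched_coef(X_a[ii], m[ii])
            coef_y = _batched_coef(X_y[ii], y[ii])
            coef_c = _batched_coef(X_c[ii], y[ii])
            a_s[sl] = coef_a[:, 1]
            b_s[sl] = coef_y[:, 1]
            cp_s[sl] = coef_y[:, 2]
            c_s[sl] = coef_c[:, 1]
        ci_a = percentile_ci(a_s, level)
        ci_b = percentile_ci(b_s, level)
        ci_cp = percentile_ci(cp_s, level)
        ci_c = percentile_ci(c_s, level)
        ci_ab = percentile_ci(a_s * b_s, level)

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, ab=ab,
        se_a=se_a, se_b=se_b, se_c=se_c, se_c_prime=se_cp,
        ci_a=ci_a, ci_b=ci_b, ci_c=ci_c, ci_c_prime=ci_cp, ci_ab=ci_ab,
        n=n, n_boot=n_boot, level=level, seed=seed,
        covariate_names=list(covariate_names), n_redraws=n_redraws,
    )
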
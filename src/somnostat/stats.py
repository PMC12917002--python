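"""The statistical layer: change scores, correlations, regression, paired
tests, FDR, and percentile-bootstrap mediation.

Sign convention (stated once, used everywhere): overnight anxiety change
is ``post − mean(pre1, pre2)`` — positive values mean anxiety *rose*
overnight.  A beneficial night (e.g. rich slow-wave activity) therefore
shows up as a *negative* association with the change score.

The mediation model is the product-of-coefficients form for linear
models: fit ``M ~ X + covariates`` (path a) and ``Y ~ X + M + covariates``
(paths c′ and b) by least squares; the indirect effect is a·b, with a
nonparametric subject-level bootstrap (resampling rows with replacement)
supplying the 2.5th/97.5th-percentile confidence interval.  For linear
models the exact identity ``total effect = c′ + a·b`` holds on the fitted
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "overnight_change",
    "CorrelationResult",
    "correlate",
    "ols_regression",
    "paired_t",
    "bh_fdr",
    "MediationResult",
    "mediation_bootstrap",
    "log_transform",
]


def overnight_change(pre1, pre2, post) -> np.ndarray:
    """Overnight anxiety change: post − mean of the two pre-sleep scores.

    Vectorized; any missing (NaN) input yields NaN so the record can be
    flagged and excluded from analysis.
    """
    pre1 = np.asarray(pre1, dtype=float)
    pre2 = np.asarray(pre2, dtype=float)
    post = np.asarray(post, dtype=float)
    return post - (pre1 + pre2) / 2.0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a Fisher-z 95% CI.

    NaN pairs are dropped (complete cases); zero variance raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(r)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = 1.959963984540054 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi),
                             p=float(p), n=n, method=method)


DEFAULT_COVARIATES = ("age", "gender", "trait_anxiety")


def ols_regression(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Covariate-adjusted least-squares regression of ``outcome``.

    Returns a tidy coefficient table (coef, 95% CI, t-based p) with the
    model R² attached as ``.attrs["r2"]``.  Complete cases only; a
    rank-deficient design raises, listing the collinear columns.
    """
    cols = [outcome, predictor, *covariates]
    frame = data.loc[:, cols].dropna()
    y = frame[outcome].to_numpy(dtype=float)
    X = frame.loc[:, [predictor, *covariates]].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, ["const", predictor, *covariates])
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    if len(frame) <= design.shape[1]:
        raise ValueError("need more observations than coefficients")
    fit = sm.OLS(y, design).fit()
    names = ["const", predictor, *covariates]
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": fit.pvalues,
        }
    )
    table.attrs["r2"] = float(fit.rsquared)
    table.attrs["n"] = int(len(frame))
    return table


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (simple diagnosis)."""
    full = np.linalg.matrix_rank(design)
    out = []
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[j])
    return out


def paired_t(x1, x2) -> tuple[float, int, tuple[float, float], float]:
    """Classical paired t-test: (t, df, 95% CI of mean difference, p)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if len(x1) < 2:
        raise ValueError("need at least 2 pairs")
    d = x1 - x2
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    n = len(d)
    df = n - 1
    t, p = sps.ttest_rel(x1, x2)
    se = d.std(ddof=1) / np.sqrt(n)
    half = sps.t.ppf(0.975, df) * se
    mean = d.mean()
    return float(t), df, (float(mean - half), float(mean + half)), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_transform(data: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """log10-transform skewed columns, explicitly and loggably.

    Returns a copy with each named column replaced by its log10; the
    transformed names are recorded in ``.attrs["log_transformed"]``.
    Non-positive values raise.
    """
    out = data.copy()
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"column {col!r} has non-positive values; cannot log")
        out[col] = np.log10(vals)
    out.attrs["log_transformed"] = list(columns)
    return out


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients mediation with a percentile-bootstrap CI.

    ``total`` is the coefficient of X in ``Y ~ X + covariates``; for
    linear models ``total == c_prime + indirect`` exactly on the fitted
    sample.  The effect is significant when the CI is entirely above or
    below zero.
    """

    a: float
    b: float
    c_prime: float
    total: float
    indirect: float
    ci_low: float
    ci_high: float
    p_boot: float
    n_boot: int
    seed: int
    n: int

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _fit_paths(X1: np.ndarray, m: np.ndarray, X2: np.ndarray, y: np.ndarray):
    beta1, *_ = np.linalg.lstsq(X1, m, rcond=None)
    beta2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    return beta1, beta2


def mediation_bootstrap(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: tuple[str, ...] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Bootstrap the indirect effect a·b of ``x`` on ``y`` through ``m``.

    Complete cases only (n ≥ 10).  Subjects are resampled with
    replacement ``n_boot`` times; both path models are refit per resample
    and the 95% CI is the 2.5th/97.5th percentile of the a·b draws.  The
    bootstrap p-value is ``2·min(frac ≤ 0, frac ≥ 0)``.
    """
    cols = [x, m, y, *covariates]
    frame = data.loc[:, cols].dropna()
    n = len(frame)
    if n < 10:
        raise ValueError("need at least 10 complete cases for mediation")
    xv = frame[x].to_numpy(dtype=float)
    mv = frame[m].to_numpy(dtype=float)
    yv = frame[y].to_numpy(dtype=float)
    C = frame.loc[:, list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))
    ones = np.ones((n, 1))
    X1 = np.hstack([ones, xv[:, None], C])              # M ~ X + covars
    X2 = np.hstack([ones, xv[:, None], mv[:, None], C])  # Y ~ X + M + covars
    for name, Xd in (("mediator", X1), ("outcome", X2)):
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise ValueError(f"rank-deficient design in the {name} model")

    beta1, beta2 = _fit_paths(X1, mv, X2, yv)
    a_hat, b_hat, c_hat = float(beta1[1]), float(beta2[2]), float(beta2[1])
    Xt = np.hstack([ones, xv[:, None], C])
    beta_t, *_ = np.linalg.lstsq(Xt, yv, rcond=None)
    total = float(beta_t[1])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Z1 = X1[idx]          # (B, n, p1)
    Z2 = X2[idx]          # (B, n, p2)
    mB = mv[idx]
    yB = yv[idx]
    G1 = np.einsum("bni,bnj->bij", Z1, Z1)
    r1 = np.einsum("bni,bn->bi", Z1, mB)
    G2 = np.einsum("bni,bnj->bij", Z2, Z2)
    r2 = np.einsum("bni,bn->bi", Z2, yB)
    try:
        a_b = np.linalg.solve(G1, r1[..., None])[:, 1, 0]
        b_b = np.linalg.solve(G2, r2[..., None])[:, 2, 0]
    except np.linalg.LinAlgError:
        a_b = np.einsum("bij,bj->bi", np.linalg.pinv(G1), r1)[:, 1]
        b_b = np.einsum("bij,bj->bi", np.linalg.pinv(G2), r2)[:, 2]
    dist = a_b * b_b
    ci_low, ci_high = np.percentile(dist, [2.5, 97.5])
    p_boot = 2.0 * min(float(np.mean(dist <= 0)), float(np.mean(dist >= 0)))
    return MediationResult(
        a=a_hat,
        b=b_hat,
        c_prime=c_hat,
        total=total,
        indirect=a_hat * b_hat,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_boot=min(p_boot, 1.0),
        n_boot=n_boot,
        seed=seed,
        n=n,
    )
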
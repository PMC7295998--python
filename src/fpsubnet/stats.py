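"""Inferential machinery: random-intercept multilevel model, repeated
measures correlation, paired-swap permutation test, Bonferroni.

The multilevel model is

    outcome_it = gamma_00 + X_it gamma + u_0i + e_it,
    u_0i ~ N(0, sigma_u^2),  e_it ~ N(0, sigma_e^2),

fit by maximum likelihood: for a fixed variance ratio
lambda = sigma_u^2 / sigma_e^2 the GLS coefficients and the residual
variance have closed forms (the marginal covariance per subject is
compound symmetric), so the profiled likelihood is maximized over a
single scalar.  Wald tests use df = n_obs - n_fixed - n_subjects + 1.

The robust option iteratively reweights observations with Huber weights
(tuning constant 1.345) computed from standardized marginal residuals;
this is a simplified analog of dedicated robust mixed-model estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "MultilevelFit",
    "RmcorrResult",
    "fit_random_intercept_model",
    "rmcorr",
    "paired_swap_permutation",
    "bonferroni",
]

HUBER_C = 1.345


@dataclass
class MultilevelFit:
    params: np.ndarray  # intercept first, then slopes
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma2_subject: float
    sigma2_residual: float
    df: int
    n_obs: int
    n_subjects: int
    loglik: float


def _profiled_fit(x, y, subject_index, n_subjects, log_lambda):
    """GLS fit and -2 loglik at a fixed variance ratio lambda."""
    lam = np.exp(log_lambda) if np.isfinite(log_lambda) else 0.0
    n_obs, p = x.shape
    counts = np.bincount(subject_index, minlength=n_subjects).astype(float)
    shrink = lam / (1.0 + lam * counts)  # per-subject factor of W = I - s*J
    sx = np.zeros((n_subjects, p))
    np.add.at(sx, subject_index, x)
    sy = np.bincount(subject_index, weights=y, minlength=n_subjects)
    xtwx = x.T @ x - (sx * shrink[:, None]).T @ sx
    xtwy = x.T @ y - sx.T @ (shrink * sy)
    ytwy = y @ y - shrink @ sy**2
    beta = np.linalg.solve(xtwx, xtwy)
    rss = float(ytwy - 2 * beta @ xtwy + beta @ xtwx @ beta)
    rss = max(rss, 1e-300)
    sigma2_e = rss / n_obs
    neg2ll = (
        n_obs * np.log(2 * np.pi * sigma2_e)
        + np.log1p(lam * counts).sum()
        + n_obs
    )
    return beta, sigma2_e, lam, neg2ll, xtwx


def fit_random_intercept_model(
    outcome: np.ndarray,
    predictors: np.ndarray,
    subject_ids: np.ndarray,
    robust: bool = False,
    alpha: float = 0.05,
) -> MultilevelFit:
    """ML fit of a random-intercept model with Wald tests per coefficient.

    ``predictors`` is (n_obs, n_slopes); an intercept column is added
    automatically.
    """
    y = np.asarray(outcome, dtype=float)
    xs = np.atleast_2d(np.asarray(predictors, dtype=float))
    if xs.shape[0] != y.shape[0]:
        xs = xs.T
    if xs.shape[0] != y.shape[0]:
        raise ValueError("outcome/predictor length mismatch")
    x = np.column_stack([np.ones_like(y), xs])
    subjects, subject_index = np.unique(subject_ids, return_inverse=True)
    n_subjects = len(subjects)
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    counts = np.bincount(subject_index)
    if (counts == 1).any():
        warnings.warn("subject(s) with a single observation")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix")
    n_obs, n_fixed = x.shape

    weights = np.ones(n_obs)
    for _iteration in range(20 if robust else 1):
        sw = np.sqrt(weights)
        xw = x * sw[:, None]
        yw = y * sw

        def objective(log_lambda, xw=xw, yw=yw):
            return _profiled_fit(xw, yw, subject_index, n_subjects, log_lambda)[3]

        res = optimize.minimize_scalar(
            objective, bounds=(-25.0, 12.0), method="bounded"
        )
        candidates = [res.x, -np.inf]  # also test the lambda -> 0 boundary
        best = min(candidates, key=objective)
        beta, sigma2_e, lam, neg2ll, xtwx = _profiled_fit(
            xw, yw, subject_index, n_subjects, best
        )
        if not robust:
            break
        resid = y - x @ beta
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            break
        r = np.abs(resid) / scale
        new_weights = np.where(r > HUBER_C, HUBER_C / np.maximum(r, 1e-12), 1.0)
        if np.max(np.abs(new_weights - weights)) < 1e-8:
            weights = new_weights
            break
        weights = new_weights

    sigma2_u = lam * sigma2_e
    cov = sigma2_e * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    df = n_obs - n_fixed - n_subjects + 1
    if df < 1:
        raise ValueError("not enough observations for the df convention")
    tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), df)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return MultilevelFit(
        params=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        ci_lower=beta - tcrit * se,
        ci_upper=beta + tcrit * se,
        sigma2_subject=float(sigma2_u),
        sigma2_residual=float(sigma2_e),
        df=int(df),
        n_obs=int(n_obs),
        n_subjects=int(n_subjects),
        loglik=float(-0.5 * neg2ll),
    )


# ---------------------------------------------------------------------------
# Repeated measures correlation
# ---------------------------------------------------------------------------


@dataclass
class RmcorrResult:
    rrm: float
    slope: float
    df: int
    p_value: float


def rmcorr(
    m1: np.ndarray, m2: np.ndarray, subject_ids: np.ndarray
) -> RmcorrResult:
    """Repeated-measures correlation via ANCOVA with subject intercepts.

    Removes subject means of both measures, fits the common slope, and
    returns the signed square root of the partial variance explained by
    the within-subject covariate.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("measure length mismatch")
    subjects, idx = np.unique(subject_ids, return_inverse=True)
    n_subjects = len(subjects)
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    counts = np.bincount(idx).astype(float)
    mean1 = np.bincount(idx, weights=m1) / counts
    mean2 = np.bincount(idx, weights=m2) / counts
    c1 = m1 - mean1[idx]
    c2 = m2 - mean2[idx]
    ss2 = float(c2 @ c2)
    if ss2 == 0:
        raise ValueError("zero within-subject variance in the second measure")
    slope = float(c1 @ c2) / ss2
    sse_reduced = float(c1 @ c1)
    sse_full = sse_reduced - slope**2 * ss2
    if sse_reduced == 0:
        raise ValueError("zero within-subject variance in the first measure")
    rrm = np.sign(slope) * np.sqrt(max(1.0 - sse_full / sse_reduced, 0.0))
    df = len(m1) - n_subjects - 1
    if df < 1:
        raise ValueError("not enough within-subject observations")
    if abs(rrm) >= 1.0:
        p = 0.0
    else:
        t = rrm * np.sqrt(df / (1.0 - rrm**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return RmcorrResult(rrm=float(rrm), slope=slope, df=int(df), p_value=p)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def paired_swap_permutation(
    y1: np.ndarray,
    y2: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Paired swap test of mean(Y1) - mean(Y2).

    Each permutation independently swaps or keeps every paired element
    (a sign flip of the paired difference).  ``alternative='greater'``
    (the default) reports the proportion of null differences >= the
    observed difference; ``'two-sided'`` compares absolute values.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("length mismatch between Y1 and Y2")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = y1 - y2
    observed = float(d.mean())
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null = (signs * d).mean(axis=1)
    if alternative == "greater":
        p = (1 + (null >= observed).sum()) / (n_perm + 1)
    else:
        p = (1 + (np.abs(null) >= abs(observed)).sum()) / (n_perm + 1)
    return observed, float(p)


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m smaller than the number of tests supplied")
    return np.minimum(1.0, m * p)
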
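"""Reliability and response-bias statistics.

Cronbach's alpha and composite reliability are the two reliability
indicators carried through the simulations; the leniency-bias statistic
(mean minus median of rescaled scores) and a chi-square test for the
equality of two independent alpha coefficients support the empirical-style
comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "cronbach_alpha",
    "composite_reliability",
    "leniency_bias",
    "alpha_difference_test",
]


def cronbach_alpha(values: np.ndarray) -> float:
    """Cronbach's alpha of an n x k item-score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample variances (denominator n-1).
    """
    X = np.asarray(values, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need at least three respondents")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero")
    k = X.shape[1]
    return k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var)


def composite_reliability(loadings, residual_vars) -> float:
    """Composite reliability of a unit-weighted composite,
    rho_c = (sum lambda)^2 / ((sum lambda)^2 + sum var(eps)).

    Fed with fitted factor loadings and residual variances this is the
    model-based counterpart of alpha; it is invariant under the common
    rescaling (lambda -> c lambda, var eps -> c^2 var eps).
    """
    lam = np.asarray(loadings, float)
    var = np.asarray(residual_vars, float)
    if lam.shape != var.shape:
        raise ValueError("loadings and residual variances must align")
    if np.any(var < 0):
        raise ValueError("residual variances must be nonnegative")
    s2 = lam.sum() ** 2
    denom = s2 + var.sum()
    if denom == 0:
        raise ValueError("degenerate: all loadings and variances zero")
    return s2 / denom


def leniency_bias(scores) -> float:
    """Mean minus median of per-respondent subscale scores on a common
    [0, 1] range.  Values below zero indicate responses concentrated toward
    the high (preference) end of the scale."""
    s = np.asarray(scores, float).ravel()
    if s.size == 0:
        raise ValueError("empty score vector")
    return float(s.mean() - np.median(s))


def alpha_difference_test(
    alpha_a: float, n_a: int, k_a: int,
    alpha_b: float, n_b: int, k_b: int,
) -> tuple[float, float]:
    """Test equality of two independent Cronbach's alpha coefficients.

    Uses the Hakstian-Whalen cube-root transform t = (1 - alpha)^(1/3),
    which is approximately normal with variance
    18 k (n-1) (1-alpha)^(2/3) / ((k-1)(9n-11)^2); the squared standardized
    contrast against the precision-weighted mean is chi-square with 1 df
    under equality.  Returns (statistic, p value).
    """
    alphas = np.array([alpha_a, alpha_b], float)
    ns = np.array([n_a, n_b], float)
    ks = np.array([k_a, k_b], float)
    if np.any(alphas >= 1):
        raise ValueError("alpha must be < 1")
    if np.any(ns <= ks):
        raise ValueError("need n > k in each sample")
    t = (1.0 - alphas) ** (1.0 / 3.0)
    var = 18.0 * ks * (ns - 1) * (1.0 - alphas) ** (2.0 / 3.0) / (
        (ks - 1) * (9.0 * ns - 11.0) ** 2
    )
    w = 1.0 / var
    t_bar = np.sum(w * t) / np.sum(w)
    chi2 = float(np.sum((t - t_bar) ** 2 * w))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
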
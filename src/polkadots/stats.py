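"""Statistical primitives shared across the analyses.

Conventions: Pearson product-moment correlations,
t-based 95% confidence intervals of the mean, two-tailed tests with the 0.05
significance threshold, and no multiple-testing correction.  Undefined
statistics propagate as NaN sentinels, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["FitResult", "pearson", "mean_ci95", "two_sample_tests", "fit_mle"]

UNDEFINED = np.nan
ALPHA = 0.05


@dataclass
class FitResult:
    family: str                  # "gamma" or "normal"
    params: tuple[float, float]  # (alpha, beta) for gamma, (mu, sigma) for normal
    log_likelihood: float


def pearson(x, y) -> float:
    """Pearson product-moment correlation; NaN sentinel on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(sps.pearsonr(x, y).statistic)


def mean_ci95(sample) -> tuple[float, float, float]:
    """Mean with t-based 95% CI: mean +/- t(0.975, n-1) * s / sqrt(n)."""
    a = np.asarray(sample, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    m = float(a.mean())
    h = float(sps.t.ppf(0.975, a.size - 1) * a.std(ddof=1) / np.sqrt(a.size))
    return m, m - h, m + h


def two_sample_tests(a, b, kind: str = "t") -> tuple[float, float]:
    """Two-tailed two-sample test: 't', 'paired_t', or 'ks'."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t test needs n >= 2 per sample")
        r = sps.ttest_ind(a, b)
    elif kind == "paired_t":
        if a.shape != b.shape:
            raise ValueError("paired test needs equal lengths")
        if a.size < 2:
            raise ValueError("paired t test needs n >= 2")
        d = a - b
        if np.ptp(d) == 0:
            # constant differences: zero statistic for equal samples,
            # infinite for a constant offset (scipy returns NaN here)
            if d[0] == 0:
                return 0.0, 1.0
            return float(np.sign(d[0]) * np.inf), 0.0
        r = sps.ttest_rel(a, b)
    elif kind == "ks":
        if a.size < 1 or b.size < 1:
            raise ValueError("ks test needs non-empty samples")
        r = sps.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return float(r.statistic), float(r.pvalue)


def fit_mle(sample, family: str) -> FitResult:
    """Maximum-likelihood fit of a gamma or normal distribution.

    Gamma uses shape-scale parameterization (alpha, beta) with location fixed
    at zero, matching how cell-level count distributions are modeled; normal
    MLE is closed form.
    """
    a = np.asarray(sample, dtype=float)
    if a.size < 10:
        raise ValueError("need at least 10 observations for a stable fit")
    if family == "normal":
        mu, sigma = float(a.mean()), float(a.std(ddof=0))
        ll = float(sps.norm.logpdf(a, mu, sigma).sum())
        return FitResult("normal", (mu, sigma), ll)
    if family == "gamma":
        if np.any(a <= 0):
            raise ValueError("gamma fit requires strictly positive values")
        shape, _loc, scale = sps.gamma.fit(a, floc=0)
        ll = float(sps.gamma.logpdf(a, shape, scale=scale).sum())
        return FitResult("gamma", (float(shape), float(scale)), ll)
    raise ValueError(f"unknown family {family!r}")
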
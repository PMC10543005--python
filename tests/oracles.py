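"""Independent reference computations used by the test suite.

Each oracle is deliberately naive (explicit loops, textbook formulas,
one-dimensional quadrature) and shares no code with the implementation it
checks.
"""

import numpy as np
from scipy import integrate


def loop_signature_score(values, weights, mask):
    """Triple-loop masked dot product."""
    total = 0.0
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k]:
                    total += float(values[i, j, k]) * float(weights[i, j, k])
    return total


def loop_roi_mean(values, mask):
    total, count = 0.0, 0
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k]:
                    total += float(values[i, j, k])
                    count += 1
    return total / count


def oneway_anova_components(y, groups):
    """Closed-form REML variance components for balanced one-way data.

    For m groups of equal size n: between variance (MSB - MSW)/n, within
    variance MSW.
    """
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    m = len(labels)
    n_per = len(y) // m
    means = np.array([y[groups == g].mean() for g in labels])
    grand = y.mean()
    msb = n_per * np.sum((means - grand) ** 2) / (m - 1)
    msw = sum(np.sum((y[groups == g] - y[groups == g].mean()) ** 2) for g in labels) / (
        m * (n_per - 1)
    )
    return (msb - msw) / n_per, msw


def welch_df(y_a, y_b):
    va, vb = np.var(y_a, ddof=1), np.var(y_b, ddof=1)
    na, nb = len(y_a), len(y_b)
    return (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )


def jzs_one_sample_bf(t, n, rscale=1.0):
    """One-dimensional quadrature for the JZS one-sample t Bayes factor."""
    df = n - 1

    def integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * df)) ** (-n / 2)
            * (rscale / np.sqrt(2 * np.pi)) * g ** -1.5
            * np.exp(-rscale * rscale / (2 * g))
        )

    numerator, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    return numerator / (1 + t * t / df) ** (-n / 2)


def gaussian_intercept_log_ml(y):
    """Closed-form log marginal likelihood of the flat-intercept model.

    y = alpha + eps with flat prior on alpha and Jeffreys prior on sigma^2:
    log p(y) = log Gamma((n-1)/2) - ((n-1)/2) log(pi * RSS) - 0.5 log n.
    """
    from scipy.special import gammaln

    y = np.asarray(y, float)
    n = len(y)
    rss = float(np.sum((y - y.mean()) ** 2))
    return float(gammaln((n - 1) / 2.0) - ((n - 1) / 2.0) * np.log(np.pi * rss) - 0.5 * np.log(n))
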
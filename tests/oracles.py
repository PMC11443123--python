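"""Independent brute-force oracles used by the test suite.

Everything here is written with plain loops and elementary formulas so it
shares no code path with the package implementation.
"""

import math

import numpy as np
from scipy import integrate, optimize


def pearson_oracle(x, y):
    """Textbook product-moment formula with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)))
    dy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)))
    return num / (dx * dy)


def average_ranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(average_ranks(list(x)), average_ranks(list(y)))


def ols_t_oracle(x, y):
    """Simple-regression slope t statistic from the closed-form formulas."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    slope = sxy / sxx
    intercept = my - slope * mx
    rss = sum((y[i] - intercept - slope * x[i]) ** 2 for i in range(n))
    df = n - 2
    se = math.sqrt(rss / df / sxx)
    if se == 0.0:
        return 0.0 if slope == 0.0 else math.copysign(float("inf"), slope)
    return slope / se


def paired_t_oracle(a, b):
    n = len(a)
    d = [a[i] - b[i] for i in range(n)]
    md = sum(d) / n
    sd = math.sqrt(sum((di - md) ** 2 for di in d) / (n - 1))
    return md / (sd / math.sqrt(n))


def variogram_oracle(values, D, edges):
    """Double loop over parcel pairs; NaN for empty bins."""
    nb = len(edges) - 1
    sums = [0.0] * nb
    counts = [0] * nb
    P = len(values)
    for i in range(P):
        for j in range(i + 1, P):
            d = D[i][j]
            b = nb - 1 if d >= edges[-1] else max(
                0, next(k for k in range(nb) if edges[k] <= d < edges[k + 1]))
            sums[b] += (values[i] - values[j]) ** 2
            counts[b] += 1
    return [sums[b] / (2 * counts[b]) if counts[b] else float("nan")
            for b in range(nb)]


def _t_pdf(u, df):
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))
    return c * (1.0 + u * u / df) ** (-(df + 1) / 2.0)


def _phi(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def t_to_z_quadrature(t, df):
    """Numerically integrate the t density, invert the normal CDF by root
    finding — independent of any scipy distribution object."""
    if t >= 0:
        tail, _ = integrate.quad(_t_pdf, t, np.inf, args=(df,))
        p = 1.0 - tail
    else:
        p, _ = integrate.quad(_t_pdf, -np.inf, t, args=(df,))
    return optimize.brentq(lambda z: _phi(z) - p, -40, 40, xtol=1e-12)
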
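"""Low-level statistical kernels shared by several modules.

Everything here is plain numpy in / numpy out; the public modules wrap these
in domain types.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .errors import ZeroVarianceError

#: z-values are clamped to this magnitude; it is roughly where the normal
#: survival function underflows double precision through the probit.
Z_CAP = 8.2


def t_cap(df: float) -> float:
    """The t magnitude that maps onto the z-score cap for a given df.

    Perfect (zero-residual) fits would otherwise yield an infinite t; they are
    reported at this finite value so the subsequent t->z conversion lands
    exactly on ``Z_CAP``.
    """
    return float(stats.t.isf(stats.norm.sf(Z_CAP), df))


def t_to_z(t, df):
    """Convert Student-t statistics to standard-normal (z) equivalents.

    The conversion is probit(T_cdf(t; df)), evaluated through the survival
    function on the positive side so both tails keep full precision, and
    clamped to ``|z| <= Z_CAP``.  Sign-symmetric: t -> -t gives z -> -z.

    Parameters
    ----------
    t : float or array
        t statistics (``+-inf`` allowed; they map to the cap).
    df : float
        Degrees of freedom, >= 1.
    """
    if df < 1:
        raise ValueError(f"t->z conversion requires df >= 1, got {df}")
    arr = np.asarray(t, dtype=float)
    z = np.empty_like(arr)
    pos = arr > 0
    with np.errstate(divide="ignore"):
        z[~pos] = special.ndtri(stats.t.cdf(arr[~pos], df))
        z[pos] = -special.ndtri(stats.t.sf(arr[pos], df))
    z = np.clip(z, -Z_CAP, Z_CAP)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(z)
    return z


def ols_slope_t(x, Y):
    """Per-column simple linear regression of ``Y`` on ``[1, x]``.

    Parameters
    ----------
    x : (n,) array
        Common regressor.
    Y : (n, p) array
        One response per column.

    Returns
    -------
    intercept, slope, t : (p,) arrays
    df : int
        Residual degrees of freedom, ``n - 2``.

    Notes
    -----
    Columns that are exactly constant get slope 0 and t defined as 0.
    Exact zero-residual fits get ``|t|`` capped at :func:`t_cap` (which the
    t->z conversion maps onto the z cap).  A constant ``x`` is an error:
    the slope is unidentified.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != x.shape[0]:
        Y = Y.T
    n = x.shape[0]
    df = n - 2
    if df < 1:
        raise ValueError(f"need at least 3 observations, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise ZeroVarianceError("regressor has zero variance; slope unidentified")
    ymean = Y.mean(axis=0)
    Yc = Y - ymean
    slope = (xc @ Yc) / sxx
    intercept = ymean - slope * x.mean()
    resid = Yc - np.outer(xc, slope)
    rss = np.einsum("ij,ij->j", resid, resid)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    cap = t_cap(df)
    exact = se == 0.0
    t = np.where(exact, np.where(slope == 0.0, 0.0, np.sign(slope) * cap), t)
    t = np.clip(t, -cap, cap)
    return intercept, slope, t, df


def pearson(x, y):
    """Pearson correlation with an explicit zero-variance error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: an input is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y):
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: an input is constant")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
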
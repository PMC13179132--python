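"""Shared statistical primitives.

These are the handful of statistics used across every stage: the
Benjamini-Hochberg step-up adjustment, the t transform of a Pearson
correlation into a two-sided p-value, the one-sided hypergeometric tail
(which also serves as the one-sided Fisher exact p for a 2x2 table with
fixed margins), and a vectorised Pearson correlation for paired profiles.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested hypotheses, e.g. undefined correlations) are left
    NaN and excluded from the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson r via the t transform with n-2 df.

    ``|r| = 1`` maps to p = 0; undefined r (NaN) stays NaN.
    """
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    r = np.asarray(r, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r * r
        t = np.abs(r) * np.sqrt(df / np.where(denom <= 0, np.nan, denom))
    p = 2.0 * sps.t.sf(t, df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return np.minimum(p, 1.0)


def hypergeom_tail(k: np.ndarray, universe: np.ndarray, n_set: np.ndarray,
                   n_draw: np.ndarray) -> np.ndarray:
    """One-sided over-representation tail P(X >= k).

    X ~ Hypergeometric(universe, n_set, n_draw): drawing ``n_draw`` items
    from a universe in which ``n_set`` are marked, the probability of seeing
    ``k`` or more marked items.
    """
    k = np.asarray(k, dtype=int)
    return sps.hypergeom.sf(k - 1, np.asarray(universe, dtype=int),
                            np.asarray(n_set, dtype=int),
                            np.asarray(n_draw, dtype=int))


def fisher_one_sided(a, b, c, d) -> np.ndarray:
    """One-sided (enrichment) Fisher exact p for 2x2 tables [[a, b], [c, d]].

    With all margins fixed this is the hypergeometric tail P(A >= a) where
    A ~ Hypergeometric(a+b+c+d, a+b, a+c).  Vectorised over table arrays.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    c = np.asarray(c, dtype=int)
    d = np.asarray(d, dtype=int)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("2x2 table cells must be non-negative")
    return hypergeom_tail(a, a + b + c + d, a + b, a + c)


def paired_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between paired 2-D arrays (rows = features).

    Rows with zero variance on either side yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc ** 2).sum(axis=-1) * (yc ** 2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where(den == 0, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Per-row z-score; constant rows become all-zero rows."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    return np.where(sd == 0, 0.0, (x - mu) / np.where(sd == 0, 1.0, sd))
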
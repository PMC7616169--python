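"""Independent oracles used by the test suite.

These deliberately avoid the package's own linear-algebra path: the CCA
oracle maximizes the sample Pearson correlation over projection directions by
direct numerical optimization (with deflation for higher-order pairs), and
the warp oracle re-derives the piecewise-linear interpolation from first
principles.
"""

import numpy as np
from scipy import optimize


def _pearson(u, v):
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    return (u @ v) / denom if denom > 0 else 0.0


def _residualize(x, scores):
    """Remove the span of ``scores`` (n-vector) from every column of x."""
    s = scores - scores.mean()
    xc = x - x.mean(axis=0)
    coef = (s @ xc) / (s @ s)
    return xc - np.outer(s, coef)


def brute_force_cca(x1, x2, k=1, restarts=6, seed=0):
    """Top-k canonical correlations by direct search with deflation."""
    x1 = np.asarray(x1, float).copy()
    x2 = np.asarray(x2, float).copy()
    corrs = []
    for level in range(k):
        rng = np.random.default_rng(seed + level)
        d1, d2 = x1.shape[1], x2.shape[1]

        def neg(ab):
            a, b = ab[:d1], ab[d1:]
            if np.allclose(a, 0) or np.allclose(b, 0):
                return 0.0
            return -abs(_pearson(x1 @ a, x2 @ b))

        best_val, best_ab = 0.0, None
        for _ in range(restarts):
            res = optimize.minimize(neg, rng.normal(size=d1 + d2), method="BFGS",
                                    options={"gtol": 1e-12, "maxiter": 2000})
            if -res.fun > best_val:
                best_val, best_ab = -res.fun, res.x
        corrs.append(best_val)
        if level + 1 < k:
            a, b = best_ab[:d1], best_ab[d1:]
            x1 = _residualize(x1, x1 @ a)
            x2 = _residualize(x2, x2 @ b)
    return np.array(corrs)


def piecewise_warp_columns(values_per_frame, es_index, T, es_canonical):
    """Independent re-derivation of the two-segment warp for a scalar sequence."""
    n = len(values_per_frame)
    out = np.empty(T)
    for j in range(T):
        if j <= es_canonical:
            t = j * es_index / es_canonical
        else:
            t = es_index + (j - es_canonical) * (n - 1 - es_index) / (T - 1 - es_canonical)
        lo = int(np.floor(t))
        hi = min(lo + 1, n - 1)
        frac = t - lo
        out[j] = (1 - frac) * values_per_frame[lo] + frac * values_per_frame[hi]
    return out
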
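"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they check: monotone cubic
interpolation is written out from the Fritsch-Carlson derivative
formulas (with the Matlab-style one-sided ends), and rigid registration
from the SVD construction.
"""

from __future__ import annotations

import numpy as np


def fritsch_carlson_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Shape-preserving Hermite slopes: weighted-harmonic interior rule,
    one-sided three-point ends with monotonicity clamps."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    h = np.diff(x)
    d = np.diff(y) / h
    m = np.zeros(n)
    if n == 2:
        return np.array([d[0], d[0]])
    for k in range(1, n - 1):
        if d[k - 1] == 0.0 or d[k] == 0.0 or np.sign(d[k - 1]) != np.sign(d[k]):
            m[k] = 0.0
        else:
            w1 = 2.0 * h[k] + h[k - 1]
            w2 = h[k] + 2.0 * h[k - 1]
            m[k] = (w1 + w2) / (w1 / d[k - 1] + w2 / d[k])

    def one_sided(h0, h1, d0, d1):
        s = ((2.0 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if np.sign(s) != np.sign(d0):
            return 0.0
        if np.sign(d0) != np.sign(d1) and abs(s) > 3.0 * abs(d0):
            return 3.0 * d0
        return s

    m[0] = one_sided(h[0], h[1], d[0], d[1])
    m[-1] = one_sided(h[-1], h[-2], d[-1], d[-2])
    return m


def fritsch_carlson_eval(x, y, xq) -> np.ndarray:
    """Evaluate the monotone cubic Hermite defined by the slopes above."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xq = np.atleast_1d(np.asarray(xq, float))
    m = fritsch_carlson_slopes(x, y)
    out = np.empty_like(xq)
    for j, q in enumerate(xq):
        k = int(np.clip(np.searchsorted(x, q, side="right") - 1, 0, x.size - 2))
        h = x[k + 1] - x[k]
        t = (q - x[k]) / h
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[j] = h00 * y[k] + h10 * h * m[k] + h01 * y[k + 1] + h11 * h * m[k + 1]
    return out


def kabsch_svd(template: np.ndarray, observed: np.ndarray):
    """Least-squares rigid fit observed ~ R @ template + t via SVD."""
    template = np.asarray(template, float)
    observed = np.asarray(observed, float)
    tc = template - template.mean(axis=0)
    oc = observed - observed.mean(axis=0)
    H = tc.T @ oc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = observed.mean(axis=0) - R @ template.mean(axis=0)
    return R, t
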
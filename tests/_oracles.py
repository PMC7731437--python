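"""Independent scalar-loop and closed-form reference implementations.

Deliberately written as naive per-pixel Python loops / textbook formulas so
they share no code path with the vectorized package implementation.
"""

import math

import numpy as np
from scipy import stats as _scipy_stats


def oracle_preprocess_band(band):
    """Standardize + min-max rescale one band, one pixel at a time."""
    h = len(band)
    w = len(band[0])
    n = h * w
    total = 0.0
    for row in band:
        for v in row:
            total += float(v)
    mean = total / n
    ss = 0.0
    for row in band:
        for v in row:
            ss += (float(v) - mean) ** 2
    std = math.sqrt(ss / n)
    z = [[(float(v) - mean) / std for v in row] for row in band]
    lo = min(min(row) for row in z)
    hi = max(max(row) for row in z)
    return np.array(
        [[1023.0 * (v - lo) / (hi - lo) for v in row] for row in z]
    )


def oracle_preprocess_image(pixels):
    """Per-band scalar-loop preprocessing of an H x W x 3 array."""
    return tuple(
        oracle_preprocess_band([[px[b] for px in row] for row in pixels])
        for b in range(3)
    )


def oracle_classify(red, green, blue, g1, g2, d):
    """Per-pixel application of the GV and SDM rules.

    Returns (gv_mask, sdm_mask) boolean arrays.
    """
    h, w = len(red), len(red[0])
    n = h * w
    mean_r = sum(float(v) for row in red for v in row) / n
    mean_g = sum(float(v) for row in green for v in row) / n
    mean_b = sum(float(v) for row in blue for v in row) / n
    gv = [[False] * w for _ in range(h)]
    sdm = [[False] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            r, g, b = float(red[i][j]), float(green[i][j]), float(blue[i][j])
            if (g - r) > g1 and (g - b) > g2:
                gv[i][j] = True
            elif r > d * mean_r and g > d * mean_g and b > d * mean_b:
                sdm[i][j] = True
    return np.array(gv), np.array(sdm)


def oracle_linregress(x, y):
    """OLS via the normal equations plus the slope t-test.

    Returns (slope, intercept, r_squared, p_value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    intercept, slope = beta
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    sigma2 = ss_res / (n - 2)
    se_slope = math.sqrt(sigma2 / float(((x - x.mean()) ** 2).sum()))
    if se_slope == 0:
        p = 0.0
    else:
        t = slope / se_slope
        p = 2.0 * _scipy_stats.t.sf(abs(t), df=n - 2)
    return slope, intercept, r_squared, p
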
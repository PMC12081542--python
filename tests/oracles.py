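"""Independent reference implementations used only as test oracles.

Deliberately written with different tools than the package (scipy Hermite
splines, per-pair lstsq loops, dense grid scans, closed forms) so agreement
is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from tblmkit.constants import R_GAS

SSE_TIE_RTOL = 1e-10  # same documented tie rule as the package


def conductive_model(v, v1, v2, g_low, g_high):
    """Reference three-region conductive current via scipy's Hermite spline."""
    v = np.asarray(v, dtype=float)
    y1 = g_low * v1
    if v2 > v1:
        y2 = y1 + 0.5 * (g_low + g_high) * (v2 - v1)
        spline = CubicHermiteSpline([v1, v2], [y1, y2], [g_low, g_high])
        mid = spline(np.clip(v, v1, v2))
    else:
        y2 = y1
        mid = np.full_like(v, y1)
    return np.where(v <= v1, g_low * v,
                    np.where(v >= v2, y2 + g_high * (v - v2), mid))


def segment_oracle(v, y, min_pts=3):
    """Brute-force exhaustive two-breakpoint least squares.

    For every ordered pair on the voltage grid, fit the full three-region
    model (intercept + two conductance basis columns built numerically from
    :func:`conductive_model`) by numpy lstsq over all samples; pick the
    minimal SSE with the documented tie rule (tolerance, then widest
    coverage, then smallest v1, then smallest v2).
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(v)
    syy_total = float(np.sum((y - y.mean()) ** 2))
    tol = SSE_TIE_RTOL * syy_total
    results = []
    for i1 in range(min_pts - 1, n - min_pts + 1):
        for j2 in range(i1, n - min_pts + 1):
            f1 = conductive_model(v, v[i1], v[j2], 1.0, 0.0)
            f2 = conductive_model(v, v[i1], v[j2], 0.0, 1.0)
            x = np.column_stack([np.ones(n), f1, f2])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            sse = float(resid @ resid)
            coverage = (i1 + 1) + (n - j2)
            results.append((sse, coverage, i1, j2, beta))
    best_sse = min(r[0] for r in results)
    tied = [r for r in results if r[0] <= best_sse + tol]
    tied.sort(key=lambda r: (-r[1], r[2], r[3]))
    sse, _cov, i1, j2, beta = tied[0]
    return {
        "v1": v[i1], "v2": v[j2],
        "g_low": beta[1], "g_high": beta[2], "intercept": beta[0],
        "sse": sse,
    }


def two_point_activation_energy(g1, t1, g2, t2):
    """Closed-form Ea from two (T, G) points."""
    return R_GAS * np.log(g1 / g2) / (1.0 / t2 - 1.0 / t1)


def grid_invert_radius(target, spec, model, r_min=1e-12, r_max=1e-8,
                       n=1_000_000):
    """Dense log-grid argmin of |W(r) - target|; returns (radius, step)."""
    grid = np.geomspace(r_min, r_max, n)
    w = model(grid, spec)
    k = int(np.argmin(np.abs(w - target)))
    step = grid[min(k + 1, n - 1)] - grid[max(k - 1, 0)]
    return float(grid[k]), float(step)
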
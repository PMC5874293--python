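"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the cosinor oracle is a
dense grid search over the acrophase with the mesor and amplitude profiled
out per grid point, followed by a local refinement of the 1-d nonlinear
least-squares problem.
"""

import numpy as np
from scipy.optimize import minimize_scalar

PHI_GRID_STEP = 1e-4


def grid_search_cosinor(t, y, period=12.0):
    """Direct nonlinear least squares for y ~ M + A cos(2 pi t/period + phi).

    Dense phi grid (step 1e-4 rad) with (M, A) profiled per phi by simple
    regression, then a bounded local refinement around the best grid point.
    Returns (M, A, phi) with A >= 0 and phi wrapped to (-pi, pi].
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    om = 2 * np.pi / period
    n = len(t)
    phis = np.arange(-np.pi, np.pi, PHI_GRID_STEP)
    ym = y.mean()
    syy = float(np.sum((y - ym) ** 2)) / n
    # profile RSS(phi) in manageable chunks
    best_phi, best_rss = None, np.inf
    for lo in range(0, len(phis), 8192):
        chunk = phis[lo : lo + 8192]
        C = np.cos(om * t[None, :] + chunk[:, None])
        cm = C.mean(axis=1)
        sxy = C @ y / n - cm * ym
        sxx = (C * C).mean(axis=1) - cm**2
        rss = syy - sxy**2 / np.maximum(sxx, 1e-300)
        i = int(np.argmin(rss))
        if rss[i] < best_rss:
            best_rss, best_phi = float(rss[i]), float(chunk[i])

    def rss_at(phi):
        c = np.cos(om * t + phi)
        X = np.column_stack([np.ones(n), c])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), coef

    res = minimize_scalar(
        lambda p: rss_at(p)[0],
        bounds=(best_phi - 2 * PHI_GRID_STEP, best_phi + 2 * PHI_GRID_STEP),
        method="bounded",
        options={"xatol": 1e-12},
    )
    phi = float(res.x)
    _, coef = rss_at(phi)
    M, A = float(coef[0]), float(coef[1])
    if A < 0:
        A, phi = -A, phi + np.pi
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    return M, A, phi
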
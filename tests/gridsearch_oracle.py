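"""Independent brute-force oracle fits: exhaustive grid + simplex polish.

For each model the nonlinear parameters are scanned on a dense grid with
the linear (amplitude) parameters solved in closed form, then the best
grid point is polished with Nelder-Mead.  Entirely independent of the
analytic-Jacobian trust-region path used by the package.
"""

import numpy as np
from scipy.optimize import minimize


def _polish(fun, x0):
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14,
                            "maxiter": 20000, "maxfev": 20000})
    return res.x


def logistic_oracle(conc, y):
    """Grid over pEC50 with (bottom, top) solved linearly, then polish."""
    x = np.log10(np.asarray(conc, float))
    y = np.asarray(y, float)
    best = None
    for p in np.arange(3.0, 13.0, 0.02):
        f = 1.0 / (1.0 + 10.0 ** (-p - x))
        design = np.column_stack([1.0 - f, f])
        coef, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
        cost = float(np.sum((design @ coef - y) ** 2))
        if best is None or cost < best[0]:
            best = (cost, coef[0], coef[1], p)

    def fun(params):
        b, t, p = params
        f = 1.0 / (1.0 + 10.0 ** (-p - x))
        return np.sum((b + (t - b) * f - y) ** 2)

    b, t, p = _polish(fun, np.array(best[1:]))
    return {"bottom": b, "top": t, "pec50": p}


def onephase_oracle(times, y):
    t = np.asarray(times, float)
    y = np.asarray(y, float)
    best = None
    for k in np.geomspace(1e-3, 30.0, 600):
        g = 1.0 - np.exp(-k * t)
        denom = float(g @ g)
        if denom == 0:
            continue
        ss = float(g @ y) / denom
        cost = float(np.sum((ss * g - y) ** 2))
        if best is None or cost < best[0]:
            best = (cost, ss, k)

    def fun(params):
        ss, k = params
        return np.sum((ss * (1 - np.exp(-k * t)) - y) ** 2)

    ss, k = _polish(fun, np.array(best[1:]))
    return {"ss": ss, "k": k, "ktau": ss * k}


def riseandfall_oracle(times, y):
    t = np.asarray(times, float)
    y = np.asarray(y, float)
    best = None
    k1_grid = np.concatenate([[0.0], np.geomspace(1e-3, 3.0, 80)])
    for k1 in k1_grid:
        for k2 in np.geomspace(1e-2, 30.0, 120):
            if k2 <= k1:
                continue
            g = np.exp(-k1 * t) - np.exp(-k2 * t)
            denom = float(g @ g)
            if denom == 0:
                continue
            d = float(g @ y) / denom
            cost = float(np.sum((d * g - y) ** 2))
            if best is None or cost < best[0]:
                best = (cost, d, k1, k2)

    def fun(params):
        d, k1, k2 = params
        if k1 < 0 or k2 <= k1:
            return np.inf
        return np.sum((d * (np.exp(-k1 * t) - np.exp(-k2 * t)) - y) ** 2)

    d, k1, k2 = _polish(fun, np.array(best[1:]))
    return {"d": d, "k1": k1, "k2": k2, "ktau": d * (k2 - k1)}
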
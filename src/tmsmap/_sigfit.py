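"""Sigmoid least-squares fitting engines.

Two routes fit the three-parameter sigmoid y = ymax / (1 + e^{-k(x - x0)}):

* ``fit_sigmoid_scalar`` — scipy ``least_squares(method='lm')``
  (Levenberg-Marquardt) on a single compartment; the canonical path.
* ``batch_fit_sigmoid`` — a vectorised Levenberg-Marquardt that solves all
  K compartment fits simultaneously.  Map construction performs thousands
  of small identical-structure fits, which per-compartment scipy calls
  cannot do within the experiment budgets; the batch engine is verified
  against the scalar path in the test suite.

Shared conventions: initialisation ymax0 = max(y), x00 = y-weighted median
of x, slope0 = 4 ymax0 / range(x); validity requires finite parameters,
0 < ymax <= 2 max(y) and slope > 0 (checked after the unconstrained LM
solve); R² = 1 - SS_res/SS_tot floored at 0, with degenerate data
(SS_tot = 0) or invalid fits reported as failed with R² = 0.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

# parameter vector layout: (x0, ymax, slope)


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cum = np.cumsum(w)
    if cum[-1] <= 0:
        return float(np.median(x))
    return float(x[np.searchsorted(cum, 0.5 * cum[-1])])


def initial_guess(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ymax0 = float(y.max())
    x00 = _weighted_median(x, y)
    rng_x = float(x.max() - x.min())
    if rng_x <= 0:
        rng_x = max(abs(float(x.max())), 1.0)
    slope0 = 4.0 * max(ymax0, 1e-12) / rng_x
    return np.array([x00, max(ymax0, 1e-12), slope0])


def _sigmoid(x, p):
    return p[1] * expit(p[2] * (x - p[0]))


def _valid(p: np.ndarray, ymax_cap: float) -> bool:
    return bool(
        np.all(np.isfinite(p)) and 0.0 < p[1] <= ymax_cap and p[2] > 0.0
    )


def r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    ss_res = float(np.sum((y - fitted) ** 2))
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_sigmoid_scalar(
    x: np.ndarray, y: np.ndarray, p0: np.ndarray | None = None
) -> tuple[np.ndarray, float, bool]:
    """Levenberg-Marquardt sigmoid fit of one compartment.

    Returns ``(params, r2, failed)``.  Degenerate responses (constant y) and
    fits that leave the validity region are flagged failed with r2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise ValueError("sigmoid fit needs at least 4 data points")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    if np.any(y < 0):
        raise ValueError("MEP amplitudes must be >= 0")

    nan3 = np.full(3, np.nan)
    if np.ptp(y) == 0.0:  # SS_tot = 0: R² undefined -> degenerate
        return nan3, 0.0, True
    if p0 is None:
        p0 = initial_guess(x, y)

    def resid(p):
        return _sigmoid(x, p) - y

    try:
        sol = least_squares(
            resid, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=400,
        )
    except Exception:
        return nan3, 0.0, True
    p = sol.x
    if not sol.success or not _valid(p, 2.0 * y.max()):
        return p, 0.0, True
    return p, r_squared(y, _sigmoid(x, p)), False


def batch_initial_guess(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised initial guesses for K fits sharing the response y.

    X is (n, K): column k is the predictor of compartment k.
    """
    n, K = X.shape
    ymax0 = max(float(y.max()), 1e-12)
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    ws = y[order]
    cum = np.cumsum(ws, axis=0)
    total = cum[-1]
    half = 0.5 * total
    pos = (cum < half[None, :]).sum(axis=0)
    x00 = xs[np.minimum(pos, n - 1), np.arange(K)]
    rng_x = np.clip(xs[-1] - xs[0], 1e-12, None)
    slope0 = 4.0 * ymax0 / rng_x
    p0 = np.empty((K, 3))
    p0[:, 0] = x00
    p0[:, 1] = ymax0
    p0[:, 2] = slope0
    return p0


def batch_fit_sigmoid(
    X: np.ndarray,
    y: np.ndarray,
    p0: np.ndarray | None = None,
    max_iter: int = 60,
    gtol: float = 1e-10,
    ftol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Levenberg-Marquardt over K sigmoid fits simultaneously.

    Parameters
    ----------
    X : (n, K) predictors (|E| at compartment k for the n stimulations).
    y : (n,) shared MEP amplitudes.
    p0 : optional (K, 3) warm-start parameters; rows that are non-finite
        fall back to the default initial guess.

    Returns ``(params (K,3), r2 (K,), failed (K,))``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, K = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match rows of X")
    if n < 4:
        raise ValueError("sigmoid fit needs at least 4 data points")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return (np.full((K, 3), np.nan), np.zeros(K), np.ones(K, dtype=bool))

    Xt = np.ascontiguousarray(X.T)  # (K, n)

    def cost_of(p):
        s = expit(p[:, 2:3] * (Xt - p[:, 0:1]))
        r = p[:, 1:2] * s - y[None, :]
        return np.einsum("kn,kn->k", r, r), s, r

    params = batch_initial_guess(X, y)
    cost, s, r = cost_of(params)
    if p0 is not None:
        # warm starts can sit in poor local minima for the enlarged data;
        # keep them only where they beat the default initialisation
        p0 = np.asarray(p0, dtype=float)
        ok = np.all(np.isfinite(p0), axis=1) & (p0[:, 1] > 0) & (p0[:, 2] > 0)
        if ok.any():
            cand = np.where(ok[:, None], p0, params)
            cost_w, s_w, r_w = cost_of(cand)
            use = ok & (cost_w < cost)
            params[use], cost[use] = cand[use], cost_w[use]
            s[use], r[use] = s_w[use], r_w[use]
    lam = np.full(K, 1e-3)
    active = np.ones(K, dtype=bool)
    eye = np.eye(3)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        p = params[idx]
        sa, ra = s[idx], r[idx]
        xa = Xt[idx]
        w = sa * (1.0 - sa)
        J = np.empty((len(idx), xa.shape[1], 3))
        J[:, :, 0] = -p[:, 1:2] * p[:, 2:3] * w        # d/dx0
        J[:, :, 1] = sa                                 # d/dymax
        J[:, :, 2] = p[:, 1:2] * (xa - p[:, 0:1]) * w   # d/dslope
        JTJ = np.einsum("knp,knq->kpq", J, J)
        g = np.einsum("knp,kn->kp", J, ra)

        gmax = np.abs(g).max(axis=1)
        scale = np.maximum(cost[idx], 1e-30)
        conv = gmax < gtol * np.maximum(1.0, scale)
        if conv.any():
            active[idx[conv]] = False
            keep = ~conv
            idx, JTJ, g = idx[keep], JTJ[keep], g[keep]
            if idx.size == 0:
                continue

        diag = np.einsum("kpp->kp", JTJ)
        diag = np.maximum(diag, 1e-12)
        A = JTJ + lam[idx, None, None] * (diag[:, :, None] * eye[None])
        try:
            delta = np.linalg.solve(A, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            A = A + 1e-8 * eye[None]
            delta = np.linalg.solve(A, -g[:, :, None])[:, :, 0]

        trial = params[idx] + delta
        s_t = expit(trial[:, 2:3] * (Xt[idx] - trial[:, 0:1]))
        r_t = trial[:, 1:2] * s_t - y[None, :]
        cost_t = np.einsum("kn,kn->k", r_t, r_t)
        better = cost_t < cost[idx]

        imp = idx[better]
        rel_impr = (cost[imp] - cost_t[better]) / np.maximum(cost[imp], 1e-30)
        params[imp] = trial[better]
        s[imp], r[imp] = s_t[better], r_t[better]
        cost[imp] = cost_t[better]
        lam[imp] = np.maximum(lam[imp] / 3.0, 1e-12)
        active[imp[rel_impr < ftol]] = False
        worse = idx[~better]
        lam[worse] *= 4.0
        active[worse[lam[worse] > 1e10]] = False

    ymax_cap = 2.0 * float(y.max())
    failed = ~(
        np.all(np.isfinite(params), axis=1)
        & (params[:, 1] > 0)
        & (params[:, 1] <= ymax_cap)
        & (params[:, 2] > 0)
    )
    r2 = np.clip(1.0 - cost / ss_tot, 0.0, 1.0)
    r2[failed] = 0.0
    return params, r2, failed
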
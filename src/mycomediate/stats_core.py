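"""Bespoke statistical estimators used throughout the analysis chain.

Three estimators are implemented from first principles because their exact
behaviour is part of the analysis contract:

* tie-corrected Kendall tau-b with a tie-adjusted normal approximation for
  the two-sided p value (exact permutation enumeration for n <= 8),
* one-breakpoint segmented (piecewise-linear, continuous) least squares
  with a dense-grid search, golden-section refinement and a case-bootstrap
  percentile interval for the breakpoint,
* generalized least squares under an exponential spatial correlation
  structure with a nugget, cor(d) = (1 - nugget) * exp(-d / range) off the
  diagonal, fitted by (restricted) maximum likelihood over transformed
  parameters (log range, logit nugget) with multi-start bounded
  optimization.

AIC is computed as 2k - 2 loglik throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve, cholesky
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

__all__ = [
    "AssociationTest",
    "SegmentedFit",
    "SpatialGLSFit",
    "kendall_tau",
    "fit_segmented",
    "fit_spatial_gls",
    "aic",
]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 loglik."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


# ---------------------------------------------------------------------------
# Kendall tau-b


@dataclass
class AssociationTest:
    statistic_name: str
    estimate: float
    p_value: float
    n: int


def _tau_counts(x: np.ndarray, y: np.ndarray):
    """Concordant-minus-discordant count S and tie-corrected denominator.

    O(n^2) sign-matrix formulation; n stays in the hundreds here, where
    this is both fast and transparently equal to the pair-counting
    definition.
    """
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    s = int(np.sum(np.triu(dx * dy, k=1)))
    n = x.size
    n0 = n * (n - 1) // 2
    # tied pairs within each vector
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    n1 = int(np.sum(cx * (cx - 1) // 2))
    n2 = int(np.sum(cy * (cy - 1) // 2))
    return s, n0, n1, n2, cx, cy


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    s, n0, n1, n2, _, _ = _tau_counts(x, y)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    return s / denom


def kendall_tau(x, y, exact_max_n: int = 8) -> AssociationTest:
    """Tie-corrected Kendall tau-b with a two-sided significance test.

    For n <= ``exact_max_n`` the p value is an exact permutation
    enumeration of the S statistic; otherwise the normal approximation
    with the tie-adjusted variance is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values not allowed")
    s, n0, n1, n2, cx, cy = _tau_counts(x, y)
    if n1 == n0 or n2 == n0:
        raise ValueError("tau undefined: one vector is completely tied")
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom

    if n <= exact_max_n:
        obs = abs(tau)
        hits = total = 0
        for perm in itertools.permutations(y):
            t = _tau_b(x, np.asarray(perm))
            total += 1
            if abs(t) >= obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        # tie-adjusted variance of S (standard tau-b significance formula)
        vt = int(np.sum(cx * (cx - 1) * (2 * cx + 5)))
        vu = int(np.sum(cy * (cy - 1) * (2 * cy + 5)))
        v1t = int(np.sum(cx * (cx - 1)))
        v1u = int(np.sum(cy * (cy - 1)))
        v2t = int(np.sum(cx * (cx - 1) * (cx - 2)))
        v2u = int(np.sum(cy * (cy - 1) * (cy - 2)))
        v0 = n * (n - 1) * (2 * n + 5)
        var_s = (
            (v0 - vt - vu) / 18.0
            + v1t * v1u / (2.0 * n * (n - 1))
            + v2t * v2u / (9.0 * n * (n - 1) * (n - 2))
        )
        z = s / math.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))
    return AssociationTest("kendall_tau", float(tau), float(min(p, 1.0)), n)


# ---------------------------------------------------------------------------
# Segmented regression


@dataclass
class SegmentedFit:
    """Continuous one-breakpoint piecewise-linear least-squares fit.

    Mean function a + b1*x + b2*(x - psi)_+ ; ``slope_left`` = b1,
    ``slope_right`` = b1 + b2.  ``material`` is False when the segmented
    model does not beat the single line by more than ``material_delta_aic``
    AIC units (grid selection of psi makes a plain likelihood-ratio test
    anticonservative, hence the strong-evidence threshold).
    """

    psi: float
    intercept: float
    slope_left: float
    slope_right: float
    sse: float
    sse_line: float
    n_left: int
    n_right: int
    n: int
    delta_aic: float
    material: bool
    psi_ci: tuple[float, float] | None = None
    material_delta_aic: float = 6.0


def _segmented_sse_batch(xs, ys, suffix, psis):
    """SSE of the 3-parameter piecewise fit for many candidate psi.

    ``xs``/``ys`` sorted by x; ``suffix`` holds suffix sums so each
    candidate costs O(1) after an O(log n) bisect.  Returns (sse, coefs).
    """
    n = xs.size
    sx_r, sx2_r, sy_r, sxy_r = suffix
    sx, sx2, sy, sxy, syy = sx_r[0], sx2_r[0], sy_r[0], sxy_r[0], float(ys @ ys)
    idx = np.searchsorted(xs, psis, side="right")
    m = n - idx
    sxr, sx2r, syr, sxyr = sx_r[idx], sx2_r[idx], sy_r[idx], sxy_r[idx]
    s_h = sxr - m * psis
    s_h2 = sx2r - 2.0 * psis * sxr + m * psis**2
    s_xh = sx2r - psis * sxr
    s_yh = sxyr - psis * syr

    k = psis.size
    g = np.empty((k, 3, 3))
    g[:, 0, 0] = n
    g[:, 0, 1] = g[:, 1, 0] = sx
    g[:, 0, 2] = g[:, 2, 0] = s_h
    g[:, 1, 1] = sx2
    g[:, 1, 2] = g[:, 2, 1] = s_xh
    g[:, 2, 2] = s_h2
    b = np.stack([np.full(k, sy), np.full(k, sxy), s_yh], axis=1)

    sse = np.full(k, np.inf)
    dets = np.linalg.det(g)
    ok = np.abs(dets) > 1e-10 * max(1.0, n * sx2 if sx2 else 1.0)
    coefs = np.full((k, 3), np.nan)
    if ok.any():
        sol = np.linalg.solve(g[ok], b[ok][..., None])[..., 0]
        coefs[ok] = sol
        sse[ok] = np.maximum(syy - np.einsum("ij,ij->i", sol, b[ok]), 0.0)
    return sse, coefs


def fit_segmented(
    x,
    y,
    n_grid: int = 200,
    grid=None,
    quantile_span: tuple[float, float] = (0.05, 0.95),
    min_per_side: int = 2,
    n_boot: int = 500,
    seed: int | None = None,
    material_delta_aic: float = 6.0,
) -> SegmentedFit:
    """Fit y = a + b1*x + b2*(x - psi)_+ by least squares over psi.

    The breakpoint is searched on a dense grid (default 200 points between
    the 5th and 95th percentile of x, leaving at least ``min_per_side``
    observations on each side), then refined by golden-section
    minimization of SSE(psi) between the best grid point's neighbours.
    A case-bootstrap percentile CI for psi is attached when
    ``n_boot`` > 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 6:
        raise ValueError(f"need n >= 6, got {n}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if xs[min_per_side - 1] >= xs[-min_per_side]:
        raise ValueError("degenerate predictor: no variation to place a breakpoint")

    def _suffix(xs_, ys_):
        z = np.zeros(1)
        return (
            np.concatenate([np.cumsum(xs_[::-1])[::-1], z]),
            np.concatenate([np.cumsum((xs_**2)[::-1])[::-1], z]),
            np.concatenate([np.cumsum(ys_[::-1])[::-1], z]),
            np.concatenate([np.cumsum((xs_ * ys_)[::-1])[::-1], z]),
        )

    def _grid_for(xs_):
        lo = max(np.quantile(xs_, quantile_span[0]), xs_[min_per_side - 1])
        hi = min(np.quantile(xs_, quantile_span[1]), xs_[-min_per_side])
        if not lo < hi:
            lo, hi = xs_[min_per_side - 1], xs_[-min_per_side]
        eps = 1e-9 * (xs_[-1] - xs_[0] + 1.0)
        return np.linspace(lo + eps, hi - eps, n_grid)

    def _best_psi(xs_, ys_):
        suffix = _suffix(xs_, ys_)
        g = np.asarray(grid, float) if grid is not None else _grid_for(xs_)
        sse, _ = _segmented_sse_batch(xs_, ys_, suffix, g)
        j = int(np.argmin(sse))
        lo = g[max(j - 1, 0)]
        hi = g[min(j + 1, g.size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda p: _segmented_sse_batch(xs_, ys_, suffix, np.array([p]))[0][0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun <= sse[j]:
                return float(res.x), float(res.fun), suffix
        return float(g[j]), float(sse[j]), suffix

    psi, sse, suffix = _best_psi(xs, ys)
    _, coefs = _segmented_sse_batch(xs, ys, suffix, np.array([psi]))
    a, b1, b2 = coefs[0]

    # single-line baseline
    X1 = np.column_stack([np.ones(n), xs])
    beta1, res1, *_ = np.linalg.lstsq(X1, ys, rcond=None)
    sse_line = float(res1[0]) if res1.size else float(np.sum((ys - X1 @ beta1) ** 2))
    sse = min(sse, sse_line)  # never worse than the nested single line

    def _gauss_aic(sse_, k_):
        sse_ = max(sse_, 1e-300)
        return n * math.log(sse_ / n) + 2 * k_

    delta = _gauss_aic(sse_line, 3) - _gauss_aic(sse, 5)
    material = delta > material_delta_aic

    psi_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            ob = np.argsort(xb, kind="stable")
            xb, yb = xb[ob], yb[ob]
            if xb[min_per_side - 1] >= xb[-min_per_side]:
                continue
            try:
                pb, _, _ = _best_psi(xb, yb)
            except ValueError:
                continue
            boots.append(pb)
        if len(boots) >= max(20, n_boot // 2):
            psi_ci = tuple(np.quantile(boots, [0.025, 0.975]).tolist())

    return SegmentedFit(
        psi=float(psi),
        intercept=float(a),
        slope_left=float(b1),
        slope_right=float(b1 + b2),
        sse=float(sse),
        sse_line=float(sse_line),
        n_left=int(np.sum(xs <= psi)),
        n_right=int(np.sum(xs > psi)),
        n=n,
        delta_aic=float(delta),
        material=bool(material),
        psi_ci=psi_ci,
        material_delta_aic=material_delta_aic,
    )


# ---------------------------------------------------------------------------
# Spatial GLS


@dataclass
class SpatialGLSFit:
    """GLS fit under cor(d) = (1 - nugget) exp(-d / range), 1 on the diagonal."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    range_param: float
    nugget: float
    sigma2: float
    loglik: float
    aic: float
    k: int
    n: int
    method: str = "ML"
    correlation: str = "exp_nugget"
    converged: bool = True
    names: list = field(default_factory=list)


def _gls_profile(dist, X, y, rng_, nug, method):
    """Profile loglik and GLS estimates for fixed (range, nugget).

    Returns (loglik, beta, se, sigma2) or None when the implied
    correlation matrix is not positive definite.
    """
    n, p = X.shape
    R = (1.0 - nug) * np.exp(-dist / rng_)
    np.fill_diagonal(R, 1.0)
    try:
        c, low = cho_factor(R, lower=True)
    except (LinAlgError, ValueError):
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Xw = cho_solve((c, low), X)
    yw = cho_solve((c, low), y)
    xtx = X.T @ Xw
    xty = X.T @ yw
    try:
        beta = np.linalg.solve(xtx, xty)
    except LinAlgError:
        return None
    r = y - X @ beta
    rw = cho_solve((c, low), r)
    rss = float(r @ rw)
    if rss <= 0:
        rss = 1e-300
    if method == "REML":
        sigma2 = rss / (n - p)
        sign, logdet_x = np.linalg.slogdet(xtx)
        if sign <= 0:
            return None
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sigma2)
            + logdet
            + logdet_x
            - p * math.log(sigma2)
            + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    try:
        cov = sigma2 * np.linalg.inv(xtx)
    except LinAlgError:
        return None
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return ll, beta, se, sigma2


def fit_spatial_gls(
    X,
    y,
    coords,
    correlation: str = "exp_nugget",
    method: str = "ML",
    n_starts: int = 5,
    seed: int | None = 0,
    fix_range: float | None = None,
    fix_nugget: float | None = None,
    names=None,
    tol: float = 1e-8,
) -> SpatialGLSFit:
    """Fit y = X beta + e with spatially correlated errors.

    ``correlation="none"`` reduces to ordinary least squares.  Otherwise
    the exponential-plus-nugget correlation parameters are profiled out by
    bounded multi-start L-BFGS-B over (log range, logit nugget); fixing
    either parameter restricts the search accordingly.  Coefficient tests
    use the normal approximation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of design columns ({n} <= {p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")
    names = list(names) if names is not None else [f"b{i}" for i in range(p)]

    if correlation == "none":
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        sigma2 = rss / n
        ll = -0.5 * n * (math.log(2 * math.pi * max(sigma2, 1e-300)) + 1.0)
        cov = (rss / (n - p)) * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        k = p + 1
        t = beta / se
        pv = 2.0 * stats.t.sf(np.abs(t), df=n - p)
        return SpatialGLSFit(
            beta=beta, se=se, t=t, p=pv, range_param=np.nan, nugget=np.nan,
            sigma2=sigma2, loglik=ll, aic=aic(ll, k), k=k, n=n,
            method=method, correlation="none", names=names,
        )
    if correlation != "exp_nugget":
        raise ValueError(f"unknown correlation structure {correlation!r}")

    coords = np.asarray(coords, float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    dist = squareform(pdist(coords))
    d_pos = dist[np.triu_indices(n, 1)]
    d_pos = d_pos[d_pos > 0]
    d_lo = max(float(np.min(d_pos)) * 0.1, 1e-6) if d_pos.size else 1e-6
    d_hi = float(np.max(dist)) * 10.0 if d_pos.size else 1.0

    def unpack(theta):
        i = 0
        if fix_range is None:
            rng_ = math.exp(theta[i]); i += 1
        else:
            rng_ = float(fix_range)
        if fix_nugget is None:
            nug = float(expit(theta[i]))
        else:
            nug = float(fix_nugget)
        return rng_, min(max(nug, 1e-10), 1.0)

    def nll(theta):
        rng_, nug = unpack(theta)
        out = _gls_profile(dist, X, y, rng_, nug, method)
        return 1e10 if out is None else -out[0]

    free = (fix_range is None) + (fix_nugget is None)
    if free == 0:
        best_theta = np.empty(0)
        converged = True
    else:
        rng = np.random.default_rng(seed)
        qs = np.quantile(d_pos, [0.1, 0.25, 0.5, 0.75, 0.9]) if d_pos.size else [1.0]
        base_r = np.log(np.clip(qs, d_lo, d_hi))
        base_n = stats.norm.ppf([0.1, 0.2, 0.3, 0.4, 0.5])  # logit-scale starts
        starts = []
        for i in range(max(1, n_starts)):
            th = []
            if fix_range is None:
                th.append(base_r[i % len(base_r)] + 0.3 * rng.standard_normal())
            if fix_nugget is None:
                th.append(base_n[i % len(base_n)] + 0.3 * rng.standard_normal())
            starts.append(np.array(th))
        bounds = []
        if fix_range is None:
            bounds.append((math.log(d_lo), math.log(d_hi)))
        if fix_nugget is None:
            bounds.append((-12.0, 12.0))
        best, best_theta, converged = np.inf, starts[0], False
        for th0 in starts:
            res = optimize.minimize(
                nll, th0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-8},
            )
            if res.fun < best:
                best, best_theta, converged = res.fun, res.x, bool(res.success)

    rng_opt, nug_opt = unpack(best_theta)
    out = _gls_profile(dist, X, y, rng_opt, nug_opt, method)
    if out is None:
        raise RuntimeError("correlation matrix not positive definite at optimum")
    ll, beta, se, sigma2 = out
    k = p + 1 + free  # sigma2 plus free correlation parameters
    t = beta / se
    pv = 2.0 * stats.norm.sf(np.abs(t))
    return SpatialGLSFit(
        beta=beta, se=se, t=t, p=pv, range_param=float(rng_opt), nugget=float(nug_opt),
        sigma2=float(sigma2), loglik=float(ll), aic=aic(ll, k), k=k, n=n,
        method=method, correlation="exp_nugget", converged=converged, names=names,
    )
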
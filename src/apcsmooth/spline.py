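"""Penalised regression-spline APC smoother.

Each curvature function is expanded in a cubic spline basis, f = Z @ gamma,
and fitting maximises the penalised log-likelihood

    l(beta, gamma, theta) - sum_T lambda_T * gamma_T' S_T gamma_T,

where S is the integrated squared second-derivative penalty matrix
S_st = int g_s''(x) g_t''(x) dx.  The penalty leaves straight lines free
(null space of dimension two) and shrinks curvature as lambda grows.  The
two Holford identifiability constraints (zero sum, zero linear trend over
the observed index set) are absorbed into the basis by a null-space
reparameterisation, after which fitting proceeds by penalised iteratively
reweighted least squares (PIRLS) with a log-exposure offset for count
families.  Smoothing parameters are selected by GCV (gaussian) or a
Laplace-approximate REML criterion (count families).  Uncertainty intervals
use the Bayesian posterior covariance of the coefficients; forecasts
evaluate the basis beyond the fitted range (natural linear extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import BSpline, CubicSpline
from scipy.linalg import cho_factor, cho_solve, null_space

from .grid import APCDataset, APCGrid, HolfordDesign, ModelFamily
from .scoring import PredictionSet

__all__ = [
    "CurvatureBasis",
    "SplineFit",
    "make_knots",
    "build_basis",
    "penalty_matrix",
    "make_default_bases",
    "fit_pirls",
    "select_smoothing",
    "predict_spline",
]

BasisKind = Literal["crs", "bs", "identity"]

PIRLS_TOL = 1e-8
PIRLS_MAXIT = 200
LAMBDA_GRID = (1e-4, 1e8, 31)  # lo, hi, points of the log-lambda search grid


# ---------------------------------------------------------------------------
# Bases
# ---------------------------------------------------------------------------

def make_knots(values, n_knots: int) -> np.ndarray:
    """Equally spaced knots covering [min(values), max(values)]."""
    vals = np.unique(np.asarray(values, dtype=float))
    if n_knots < 4:
        raise ValueError("cubic bases need at least 4 knots")
    if len(vals) < 2 or vals[-1] == vals[0]:
        raise ValueError("values span a degenerate range")
    if n_knots > len(vals):
        raise ValueError(
            f"{n_knots} knots exceed the {len(vals)} distinct values "
            "(unpenalised rank deficiency)"
        )
    return np.linspace(vals[0], vals[-1], n_knots)


class _SplineEval:
    """Evaluates a family of cubic basis functions with linear extension
    outside the knot range (value + slope continuation at the boundary)."""

    def __init__(self, kind: str, knots: np.ndarray):
        self.kind = kind
        self.knots = np.asarray(knots, dtype=float)
        if kind == "crs":
            # cardinal natural-cubic basis: column j interpolates e_j
            self._f = CubicSpline(self.knots, np.eye(len(self.knots)),
                                  axis=0, bc_type="natural")
            self.T = len(self.knots)
        elif kind == "bs":
            t = np.r_[[self.knots[0]] * 3, self.knots, [self.knots[-1]] * 3]
            self.T = len(t) - 4
            self._f = BSpline(t, np.eye(self.T), 3)
        else:
            raise ValueError(f"unknown basis kind {kind!r}")
        self._d1 = self._f.derivative(1)
        self._d2 = self._f.derivative(2)

    def evaluate(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.knots[0], self.knots[-1]
        xi = np.clip(x, lo, hi)
        Z = self._f(xi)
        left, right = x < lo, x > hi
        if np.any(left):
            Z[left] += np.outer(x[left] - lo, self._d1(lo))
        if np.any(right):
            Z[right] += np.outer(x[right] - hi, self._d1(hi))
        return Z

    def second_deriv(self, x) -> np.ndarray:
        return self._d2(np.atleast_1d(np.asarray(x, dtype=float)))


class _IdentityEval:
    """Saturated representation: one coefficient per anchor point."""

    def __init__(self, anchors: np.ndarray):
        self.anchors = np.asarray(anchors, dtype=float)
        self.T = len(self.anchors)
        self.knots = self.anchors

    def evaluate(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        Z = np.zeros((len(x), self.T))
        for i, xv in enumerate(x):
            j = np.argmin(np.abs(self.anchors - xv))
            if abs(self.anchors[j] - xv) > 1e-9:
                raise ValueError(
                    "identity (saturated) basis is only defined at its anchors"
                )
            Z[i, j] = 1.0
        return Z


def _difference_penalty(T: int) -> np.ndarray:
    D = np.diff(np.eye(T), n=2, axis=0)
    return D.T @ D


def _integral_penalty(ev: _SplineEval) -> np.ndarray:
    """Exact S = int g'' g''^T dx by per-interval Simpson quadrature (the
    integrand is piecewise quadratic, so Simpson is exact)."""
    S = np.zeros((ev.T, ev.T))
    kn = ev.knots
    for a, b in zip(kn[:-1], kn[1:]):
        B0 = ev.second_deriv(a)[0]
        Bm = ev.second_deriv(0.5 * (a + b))[0]
        B1 = ev.second_deriv(b)[0]
        S += (b - a) / 6.0 * (
            np.outer(B0, B0) + 4.0 * np.outer(Bm, Bm) + np.outer(B1, B1)
        )
    return 0.5 * (S + S.T)


@dataclass
class CurvatureBasis:
    """Spline basis with its second-derivative penalty and the Holford
    constraints absorbed.

    ``Z``/``S`` are the full basis evaluation at the anchor (constraint)
    points and penalty; ``Zt``/``St`` the constraint-reduced forms after
    projecting the coefficients onto {gamma : sum f = 0, sum x*f = 0 over
    the anchors}, with ``Nc`` the T x (T-2) null-space map.
    """

    basis_kind: str
    knots: np.ndarray
    T: int
    Z: np.ndarray
    S: np.ndarray
    Zt: np.ndarray
    St: np.ndarray
    Nc: np.ndarray
    anchor_x: np.ndarray
    _eval: object = field(repr=False, default=None)

    def rows(self, x) -> tuple[np.ndarray, np.ndarray]:
        """(full, constraint-reduced) basis rows at points x."""
        Z = self._eval.evaluate(x)
        return Z, Z @ self.Nc

    def extrapolation_distance(self, x) -> float:
        x = np.asarray(x, dtype=float)
        return float(max(np.max(x) - self.knots[-1],
                         self.knots[0] - np.min(x), 0.0))


def build_basis(
    kind: BasisKind,
    x,
    knots=None,
    penalty: Literal["integral", "difference"] = "integral",
) -> CurvatureBasis:
    """Construct a cubic spline basis at anchor points ``x``.

    ``x`` doubles as the constraint set: the two Holford constraints are
    imposed over these points.  ``penalty='difference'`` replaces the exact
    integral penalty with the second-order coefficient-difference penalty
    D'D (the P-spline flavour, tri-diagonal like an RW2 structure matrix).
    """
    x = np.asarray(x, dtype=float)
    if kind == "identity":
        ev = _IdentityEval(x)
        S = _difference_penalty(ev.T)
    else:
        if knots is None:
            raise ValueError("spline bases require knots")
        knots = np.asarray(knots, dtype=float)
        if len(knots) < 4:
            raise ValueError("cubic bases need at least 4 knots")
        ev = _SplineEval(kind, knots)
        S = _difference_penalty(ev.T) if penalty == "difference" \
            else _integral_penalty(ev)
    Z = ev.evaluate(x)
    A = np.vstack([np.ones(len(x)), x]) @ Z
    Nc = null_space(A)
    if Nc.shape[1] != ev.T - 2:
        raise ValueError("constraint matrix is rank deficient for this basis")
    return CurvatureBasis(
        basis_kind=kind, knots=np.asarray(ev.knots), T=ev.T, Z=Z, S=S,
        Zt=Z @ Nc, St=Nc.T @ S @ Nc, Nc=Nc, anchor_x=x, _eval=ev,
    )


def penalty_matrix(basis: CurvatureBasis) -> np.ndarray:
    """The T x T second-derivative penalty matrix S of a basis."""
    return basis.S


def _scale_anchor_values(design: HolfordDesign, scale: str) -> np.ndarray:
    """Label values of a time scale over the *fitted* window (the constraint
    and knot-placement set)."""
    g = design.grid
    if scale == "age":
        return g.age_values
    if scale == "period":
        return g.period_values[: g.n_fitted_periods]
    k_fit = g.M * (g.I - 1) + g.n_fitted_periods
    return g.cohort_values[:k_fit]


def make_default_bases(
    design: HolfordDesign,
    kind: BasisKind = "crs",
    n_knots: tuple[int, int, int] = (10, 10, 12),
    penalty: str = "integral",
) -> dict[str, CurvatureBasis]:
    """Bases for the three curvatures with the default knot counts
    (10 age, 10 period, 12 cohort)."""
    out = {}
    for scale, nk in zip(("age", "period", "cohort"), n_knots):
        vals = _scale_anchor_values(design, scale)
        nk_eff = min(nk, len(vals))
        out[scale] = build_basis(kind, vals, make_knots(vals, nk_eff),
                                 penalty=penalty)
    return out


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _cell_label_values(design: HolfordDesign, grid: APCGrid):
    a, p, c = grid.cell_indices()
    xa = grid.age_values[a - 1]
    xp = grid.period_values[p - 1]
    xc = grid.cohort_values[c - 1]
    return (a, p, c), (xa, xp, xc)


def _assemble(design: HolfordDesign, bases: dict, grid: APCGrid):
    """Full design matrix over all cells of ``grid`` plus column slices."""
    (a, p, c), (xa, xp, xc) = _cell_label_values(design, grid)
    blocks = [design.fixed_columns(a, p, c)]
    sizes = [blocks[0].shape[1]]
    for scale, xv in (("age", xa), ("period", xp), ("cohort", xc)):
        _, Zt = bases[scale].rows(xv)
        blocks.append(Zt)
        sizes.append(Zt.shape[1])
    X = np.concatenate(blocks, axis=1)
    slices = design.block_slices(sizes)
    return X, slices


def _penalty_blocks(bases: dict, slices, q: int, lam: dict) -> np.ndarray:
    P = np.zeros((q, q))
    for scale, sl in zip(("age", "period", "cohort"), slices[1:]):
        P[sl, sl] = lam[scale] * bases[scale].St
    return P


def _as_lambda_dict(lam) -> dict:
    if np.isscalar(lam):
        return {s: float(lam) for s in ("age", "period", "cohort")}
    return {s: float(lam[s]) for s in ("age", "period", "cohort")}


# ---------------------------------------------------------------------------
# PIRLS
# ---------------------------------------------------------------------------

@dataclass
class SplineFit:
    """Result of a penalised spline APC fit."""

    design: HolfordDesign
    bases: dict
    family: ModelFamily
    lam: dict
    coef: np.ndarray
    cov: np.ndarray              # Bayesian posterior covariance
    slices: list
    edf: dict
    edf_total: float
    scale: float                 # dispersion phi (1 for counts)
    penalized_deviance: float
    loglik: float
    iterations: int
    converged: bool
    separation_flag: bool
    criterion: str | None = None
    criterion_value: float | None = None
    criterion_profile: dict = field(default_factory=dict)
    _cached: dict = field(default_factory=dict, repr=False)

    def component(self, scale: str) -> np.ndarray:
        """Fitted curvature values at the scale's anchor points."""
        idx = {"age": 1, "period": 2, "cohort": 3}[scale]
        return self.bases[scale].Zt @ self.coef[self.slices[idx]]


def fit_pirls(
    dataset: APCDataset,
    design: HolfordDesign,
    bases: dict,
    family: ModelFamily,
    lam,
    fixed_ridge: float = 0.0,
) -> SplineFit:
    """Maximise the penalised log-likelihood by penalised IRLS at fixed
    smoothing parameters ``lam`` (scalar or {age, period, cohort} dict).

    ``fixed_ridge`` adds a gaussian prior precision on the intercept/slope
    block (default none, i.e. flat); matching it to a Bayesian model's vague
    prior makes the two fits agree exactly in the gaussian case.
    """
    lam = _as_lambda_dict(lam)
    if min(lam.values()) < 0:
        raise ValueError("smoothing parameters must be non-negative")
    g = dataset.grid
    X_all, slices = _assemble(design, bases, g)
    obs = dataset.observed_mask.ravel()
    X = X_all[obs]
    y = dataset.counts.ravel()[obs]
    off = (np.zeros_like(y) if family.link == "identity"
           else np.log(dataset.exposure.ravel()[obs]))
    n, q = X.shape
    if n < 3 + 0:  # need at least the unpenalised dimension
        raise ValueError("too few observed cells")
    P = _penalty_blocks(bases, slices, q, lam)
    if fixed_ridge > 0:
        # H = X'WX + 2P, so half the precision here yields +fixed_ridge*I
        P[slices[0], slices[0]] += 0.5 * fixed_ridge * np.eye(3)

    if family.link == "identity":
        eta = y.astype(float).copy()
    else:
        eta = np.log((y + 0.5) / np.exp(off))

    coef = np.zeros(q)
    pdev = np.inf
    converged = False
    it = 0
    for it in range(1, PIRLS_MAXIT + 1):
        w = family.weight(y, eta, off)
        s = family.score(y, eta, off)
        z = eta + s / w
        XtW = X.T * w
        # maximising l - sum lam*gamma'S gamma gives Hessian X'WX + 2*P
        H = XtW @ X + 2.0 * P
        coef_new = np.linalg.solve(H, XtW @ z)
        eta_new = X @ coef_new
        pen = sum(lam[sc] * coef_new[sl] @ bases[sc].St @ coef_new[sl]
                  for sc, sl in zip(("age", "period", "cohort"), slices[1:]))
        pdev_new = family.deviance(y, eta_new, off) + 2.0 * pen
        # step halving if the penalised deviance worsens
        step = 1.0
        while pdev_new > pdev + 1e-10 and step > 1e-4 and np.isfinite(pdev):
            step *= 0.5
            coef_new = coef + step * (coef_new - coef)
            eta_new = X @ coef_new
            pen = sum(lam[sc] * coef_new[sl] @ bases[sc].St @ coef_new[sl]
                      for sc, sl in zip(("age", "period", "cohort"),
                                        slices[1:]))
            pdev_new = family.deviance(y, eta_new, off) + 2.0 * pen
        rel = abs(pdev - pdev_new) / (abs(pdev_new) + 0.1)
        coef, eta = coef_new, eta_new
        if rel < PIRLS_TOL:
            converged = True
            pdev = pdev_new
            break
        pdev = pdev_new

    separation = bool(np.max(np.abs(eta)) > 30) and family.link == "log"

    w = family.weight(y, eta, off)
    XtWX = (X.T * w) @ X
    H = XtWX + 2.0 * P
    c, low = cho_factor(H)
    F = cho_solve((c, low), XtWX)
    edf = {"fixed": float(np.trace(F[slices[0], slices[0]]))}
    for sc, sl in zip(("age", "period", "cohort"), slices[1:]):
        edf[sc] = float(np.trace(F[sl, sl]))
    edf_total = float(np.trace(F))

    if family.family_name == "gaussian":
        rss = float(np.sum((y - eta) ** 2))
        scale = rss / max(n - edf_total, 1.0)
    else:
        scale = 1.0
    cov = cho_solve((c, low), np.eye(q)) * scale

    pen = sum(lam[sc] * coef[sl] @ bases[sc].St @ coef[sl]
              for sc, sl in zip(("age", "period", "cohort"), slices[1:]))
    fit = SplineFit(
        design=design, bases=bases, family=family, lam=lam, coef=coef,
        cov=cov, slices=slices, edf=edf, edf_total=edf_total, scale=scale,
        penalized_deviance=pdev, loglik=family.loglik(y, eta, off),
        iterations=it, converged=converged, separation_flag=separation,
    )
    fit._cached = {"X": X, "y": y, "off": off, "w": w, "H": H, "P": P,
                   "pen": pen, "n": n}
    return fit


# ---------------------------------------------------------------------------
# Smoothing-parameter selection
# ---------------------------------------------------------------------------

def _criterion_value(fit: SplineFit, criterion: str) -> float:
    cache = fit._cached
    n = cache["n"]
    if criterion == "gcv":
        dev = fit.family.deviance(cache["y"], cache["X"] @ fit.coef,
                                  cache["off"])
        denom = max(n - fit.edf_total, 1e-6)
        return n * dev / denom ** 2
    if criterion == "laplace_reml":
        sign, logdet_H = np.linalg.slogdet(cache["H"])
        if sign <= 0:
            return np.inf
        logdet_pen = 0.0
        for sc, sl in zip(("age", "period", "cohort"), fit.slices[1:]):
            St = fit.bases[sc].St
            dim = St.shape[0]
            if dim == 0 or fit.lam[sc] <= 0:
                continue
            s2, ld = np.linalg.slogdet(St)
            # implied prior precision of the penalty exp(-lam*g'Sg) is 2*lam*S
            logdet_pen += dim * np.log(2.0 * fit.lam[sc]) + ld
        lp = fit.loglik - cache["pen"]
        return float(-lp + 0.5 * logdet_H - 0.5 * logdet_pen)
    raise ValueError(f"unknown criterion {criterion!r}")


def _golden(fun, lo, hi, tol=1e-3, maxit=40):
    """Golden-section minimisation of fun over [lo, hi] (log-lambda)."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(maxit):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (c, fc) if fc < fd else (d, fd)


def select_smoothing(
    dataset: APCDataset,
    design: HolfordDesign,
    bases: dict,
    family: ModelFamily,
    criterion: str | None = None,
    n_sweeps: int = 2,
) -> SplineFit:
    """Choose smoothing parameters by coordinate-wise search of the
    criterion over a log-lambda grid with golden-section refinement.

    ``criterion`` defaults to GCV for gaussian data and the
    Laplace-approximate REML criterion for count families.  Grid ties break
    toward larger lambda (the smoother fit).
    """
    if criterion is None:
        criterion = "gcv" if family.family_name == "gaussian" else "laplace_reml"
    lo, hi, npts = LAMBDA_GRID
    grid_log = np.linspace(np.log(lo), np.log(hi), npts)
    scales = [s for s in ("age", "period", "cohort")
              if bases[s].St.shape[0] > 0]
    lam = {s: 1.0 for s in ("age", "period", "cohort")}
    profile: dict = {}

    def crit_at(lam_dict):
        f = fit_pirls(dataset, design, bases, family, lam_dict)
        return _criterion_value(f, criterion), f

    for sweep in range(n_sweeps):
        for sc in scales:
            vals = []
            for lg in grid_log:
                trial = dict(lam)
                trial[sc] = float(np.exp(lg))
                v, _ = crit_at(trial)
                vals.append(v)
            vals = np.asarray(vals)
            if not np.any(np.isfinite(vals)):
                raise RuntimeError(
                    f"criterion non-finite over the whole grid for {sc}: "
                    f"{vals}"
                )
            # ties toward larger lambda: last index attaining the minimum
            best = len(vals) - 1 - int(np.argmin(vals[::-1]))
            profile[(sweep, sc)] = {"log_lambda": grid_log.copy(),
                                    "criterion": vals.copy()}
            a = grid_log[max(best - 1, 0)]
            b = grid_log[min(best + 1, len(grid_log) - 1)]

            def f1(lg, _sc=sc):
                trial = dict(lam)
                trial[_sc] = float(np.exp(lg))
                return crit_at(trial)[0]

            lg_best, v_best = _golden(f1, a, b)
            if v_best <= vals[best]:
                lam[sc] = float(np.exp(lg_best))
            else:
                lam[sc] = float(np.exp(grid_log[best]))

    crit_val, fit = crit_at(lam)
    fit.criterion = criterion
    fit.criterion_value = crit_val
    fit.criterion_profile = profile
    return fit


def estimate_dispersion(
    dataset: APCDataset,
    design: HolfordDesign,
    bases: dict,
    lam,
    theta_bounds=(1e-2, 1e4),
) -> tuple[float, SplineFit]:
    """Outer maximisation of the penalised likelihood over the
    negative-binomial dispersion theta (on the log scale)."""
    from scipy.optimize import minimize_scalar

    def neg_pll(log_th):
        fam = ModelFamily("negative_binomial", theta=float(np.exp(log_th)))
        f = fit_pirls(dataset, design, bases, fam, lam)
        return -(f.loglik - f._cached["pen"])

    res = minimize_scalar(neg_pll, bounds=np.log(theta_bounds),
                          method="bounded")
    theta = float(np.exp(res.x))
    fam = ModelFamily("negative_binomial", theta=theta)
    return theta, fit_pirls(dataset, design, bases, fam, lam)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_spline(
    fit: SplineFit,
    target_grid: APCGrid,
    level: float = 0.95,
) -> PredictionSet:
    """Predict the linear predictor on every cell of ``target_grid``
    (which may extend the fitted grid) with +/- z * SE intervals from the
    Bayesian posterior covariance."""
    from scipy.stats import norm

    X, _ = _assemble(fit.design, fit.bases, target_grid)
    eta = X @ fit.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov, X), 0.0))
    z = 1.96 if abs(level - 0.95) < 1e-12 else float(norm.ppf(0.5 + level / 2))
    a, p, _ = target_grid.cell_indices()
    is_forecast = p > target_grid.n_fitted_periods
    extrap = {
        sc: fit.bases[sc].extrapolation_distance(xv)
        for sc, xv in zip(
            ("age", "period", "cohort"),
            _cell_label_values(fit.design, target_grid)[1],
        )
    }
    return PredictionSet(
        age_idx=a, period_idx=p, eta=eta,
        lower=eta - z * se, upper=eta + z * se,
        is_forecast=is_forecast, alpha_level=1.0 - level,
        meta={"extrapolation_distance": extrap, "se": se,
              "lam": dict(fit.lam), "edf": dict(fit.edf)},
    )


def export_fit(fit: SplineFit, preds: PredictionSet, path) -> None:
    """Serialise per-cell predictions and per-component smoothing summaries
    to delimited text."""
    import pandas as pd

    df = pd.DataFrame({
        "age_idx": preds.age_idx,
        "period_idx": preds.period_idx,
        "eta": preds.eta,
        "lower": preds.lower,
        "upper": preds.upper,
        "forecast": preds.is_forecast.astype(int),
    })
    with open(path, "w") as fh:
        for sc in ("age", "period", "cohort"):
            fh.write(f"# {sc}: lambda={fit.lam[sc]:.6g} edf={fit.edf[sc]:.4f}\n")
        df.to_csv(fh, index=False)
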
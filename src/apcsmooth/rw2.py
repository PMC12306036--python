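"""Bayesian APC model with second-order random-walk (RW2) priors.

Each curvature field f (age, period or cohort, evaluated on its full index
set) gets an intrinsic Gaussian Markov random field prior penalising second
differences:

    pi(f | tau) propto tau^((n-2)/2) * exp(-tau/2 * sum_a (f_a - 2 f_{a+1}
                                                           + f_{a+2})^2)
               = tau^((n-2)/2) * exp(-1/2 * f' (tau R) f),

where R = D'D (D the second-difference operator) is the structure matrix of
rank n - 2; its null space holds constants and linear trends, which are
removed by the two Holford constraints (zero sum, zero linear trend), fixing
the rank deficiency of two.  The precision tau is the smoothing parameter
and carries a penalised-complexity (PC) prior: an exponential prior on the
standard deviation sigma = tau^(-1/2) with rate kappa = -ln(alpha)/U,
calibrated by P(sigma > U) = alpha.

Inference is by MCMC: the latent Gaussian block (intercept, slopes and the
three constrained fields jointly) is proposed from a Gaussian approximation
at the conditional mode with a Metropolis-Hastings correction (exact Gibbs
for gaussian observations), and each log-precision takes a random-walk
Metropolis step.  The hard constraints are handled by working in the
orthonormal null-space coordinates of the constraint matrix, which samples
the constrained Gaussian exactly (the same conditional law that
conditioning-by-kriging projection produces).  Forecasting extends the
period and cohort fields; unobserved cells contribute no likelihood and
their linear-predictor posterior is the forecast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky

from .grid import (
    APCDataset,
    HolfordDesign,
    ModelFamily,
    build_design,
    constraint_nullspace,
    extend_dataset,
)
from .scoring import PredictionSet

__all__ = [
    "PCPrior",
    "RW2Component",
    "SamplerConfig",
    "RW2Fit",
    "second_difference_matrix",
    "rw2_structure",
    "pc_prior_rate",
    "log_pc_prior_tau",
    "log_prior_rw2",
    "default_priors",
    "conditional_posterior",
    "fit_bayes",
    "forecast_rw2",
    "rw2_conditional_forecast",
    "summarize_posterior",
]

BETA_PREC = 1e-6  # vague gaussian prior precision on intercept and slopes


# ---------------------------------------------------------------------------
# Structure matrices and priors
# ---------------------------------------------------------------------------

def second_difference_matrix(n: int) -> sp.csr_matrix:
    """Sparse (n-2) x n second-difference operator with stencil (1, -2, 1)."""
    if n < 3:
        raise ValueError("second differences need a field of length >= 3")
    data = np.tile([1.0, -2.0, 1.0], n - 2)
    rows = np.repeat(np.arange(n - 2), 3)
    cols = np.concatenate([np.arange(i, i + 3) for i in range(n - 2)])
    return sp.csr_matrix((data, (rows, cols)), shape=(n - 2, n))


def rw2_structure(n: int, order: int = 2) -> sp.csr_matrix:
    """RW structure matrix R = D'D in sparse banded form.

    For order 2 the interior stencil is (1, -4, 6, -4, 1) with corner rows
    (1, -2, 1, ...) and (-2, 5, -4, 1, ...); rank is n - 2 (null space:
    constants and linear trends).  Order 1 (first differences) is accepted
    for completeness.
    """
    if order == 2:
        D = second_difference_matrix(n)
    elif order == 1:
        if n < 2:
            raise ValueError("first differences need length >= 2")
        data = np.tile([-1.0, 1.0], n - 1)
        rows = np.repeat(np.arange(n - 1), 2)
        cols = np.concatenate([np.arange(i, i + 2) for i in range(n - 1)])
        D = sp.csr_matrix((data, (rows, cols)), shape=(n - 1, n))
    else:
        raise ValueError("order must be 1 or 2")
    return (D.T @ D).tocsr()


def pc_prior_rate(U: float, alpha: float) -> float:
    """Rate kappa = -ln(alpha)/U of the exponential PC prior on sigma."""
    if U <= 0:
        raise ValueError("U must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return -np.log(alpha) / U


def log_pc_prior_tau(tau: float, kappa: float) -> float:
    """Log density of the PC (type-2 Gumbel) prior on the precision tau,
    i.e. sigma = tau^(-1/2) ~ Exp(kappa)."""
    if tau <= 0:
        return -np.inf
    return float(np.log(kappa / 2.0) - 1.5 * np.log(tau) - kappa / np.sqrt(tau))


def log_prior_rw2(f: np.ndarray, tau: float) -> float:
    """Log RW2 prior density of a field up to an additive constant:
    ((n-2)/2) ln(tau) - (tau/2) * sum of squared second differences."""
    f = np.asarray(f, dtype=float)
    n = len(f)
    if n < 3:
        raise ValueError("field must have length >= 3")
    if tau <= 0:
        raise ValueError("precision tau must be positive")
    d2 = f[:-2] - 2.0 * f[1:-1] + f[2:]
    return float(0.5 * (n - 2) * np.log(tau) - 0.5 * tau * np.sum(d2 ** 2))


@dataclass(frozen=True)
class PCPrior:
    """P(sigma > U) = alpha calibration of the exponential prior on sigma."""

    U: float = 1.0
    alpha: float = 0.01

    @property
    def kappa(self) -> float:
        return pc_prior_rate(self.U, self.alpha)


@dataclass
class RW2Component:
    """RW2 field specification: length, structure matrix, constraints, and
    either a fixed precision ``tau`` or a PC prior on it."""

    n: int
    R: sp.csr_matrix = None
    A: np.ndarray = None
    tau: float | None = None
    prior: PCPrior | None = None

    def __post_init__(self) -> None:
        if self.R is None:
            self.R = rw2_structure(self.n)
        if self.A is None:
            t = np.arange(1, self.n + 1, dtype=float)
            self.A = np.vstack([np.ones(self.n), t])
        if self.tau is None and self.prior is None:
            self.prior = PCPrior()
        if self.tau is not None and self.tau <= 0:
            raise ValueError("fixed tau must be positive")


def default_priors(design: HolfordDesign, U: float = 1.0,
                   alpha: float = 0.01) -> dict[str, RW2Component]:
    """One RW2 component per time scale with a shared PC prior spec."""
    sizes = design.scale_sizes
    return {s: RW2Component(n=sizes[s], prior=PCPrior(U=U, alpha=alpha))
            for s in ("age", "period", "cohort")}


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    adapt: bool = True
    tau_step: float = 0.8        # initial RW step on ln(tau)
    newton_maxit: int = 50
    newton_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.iterations < self.burn_in:
            raise ValueError("iterations must be >= burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class _Model:
    """Precomputed constrained-coordinate representation of the model."""

    Xz_obs: np.ndarray            # observed-cell design in z coordinates
    Xz_all: np.ndarray            # all-cell design in z coordinates
    y: np.ndarray
    off: np.ndarray
    slices: list                  # z-blocks: fixed, age, period, cohort
    Rz: dict                      # reduced structure matrices per scale
    null_bases: dict              # N_T per scale
    field_sizes: dict
    components: dict


def _build_model(dataset: APCDataset, design: HolfordDesign,
                 priors: dict, family: ModelFamily) -> _Model:
    g = dataset.grid
    obs = dataset.observed_mask.ravel()
    if not np.any(obs):
        raise ValueError("dataset has no observed cells")
    Xz_all = design.full_design_matrix(g)
    y = dataset.counts.ravel()[obs]
    off_all = (np.zeros(g.I * g.J) if family.link == "identity"
               else np.log(dataset.exposure.ravel()))
    sizes = design.scale_sizes
    Rz, nulls = {}, {}
    for s in ("age", "period", "cohort"):
        comp = priors[s]
        if comp.n != sizes[s]:
            raise ValueError(
                f"{s} component length {comp.n} != grid size {sizes[s]}"
            )
        N = design.null_basis(s)
        nulls[s] = N
        Rz[s] = N.T @ (comp.R @ N)
    slices = design.block_slices(
        [3] + [sizes[s] - 2 for s in ("age", "period", "cohort")]
    )
    return _Model(Xz_obs=Xz_all[obs], Xz_all=Xz_all, y=y,
                  off=off_all[obs], slices=slices, Rz=Rz,
                  null_bases=nulls, field_sizes=sizes, components=priors)


def _qz(model: _Model, taus: dict) -> np.ndarray:
    q = model.Xz_obs.shape[1]
    Q = np.zeros((q, q))
    Q[model.slices[0], model.slices[0]] = BETA_PREC * np.eye(3)
    for s, sl in zip(("age", "period", "cohort"), model.slices[1:]):
        Q[sl, sl] = taus[s] * model.Rz[s]
    return Q


def _log_joint_z(model: _Model, family: ModelFamily, z: np.ndarray,
                 Qz: np.ndarray) -> float:
    eta = model.Xz_obs @ z
    return family.loglik(model.y, eta, model.off) - 0.5 * z @ Qz @ z


def _newton_mode(model: _Model, family: ModelFamily, Qz: np.ndarray,
                 z0: np.ndarray, cfg: SamplerConfig):
    """Conditional mode of z given tau, via damped Newton; returns
    (mode, H_at_mode, chol_lower)."""
    X = model.Xz_obs
    z = z0.copy()
    obj = _log_joint_z(model, family, z, Qz)
    for _ in range(cfg.newton_maxit):
        eta = X @ z
        w = family.weight(model.y, eta, model.off)
        s = family.score(model.y, eta, model.off)
        grad = X.T @ s - Qz @ z
        H = (X.T * w) @ X + Qz
        c, low = cho_factor(H, lower=True)
        step = cho_solve((c, low), grad)
        t = 1.0
        while t > 1e-6:
            z_new = z + t * step
            obj_new = _log_joint_z(model, family, z_new, Qz)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        if not np.isfinite(obj_new):
            raise RuntimeError("Newton mode search diverged")
        converged = np.max(np.abs(t * step)) < cfg.newton_tol * (
            1.0 + np.max(np.abs(z)))
        z, obj = z_new, obj_new
        if converged:
            break
    eta = X @ z
    w = family.weight(model.y, eta, model.off)
    H = (X.T * w) @ X + Qz
    L = cholesky(H, lower=True)
    return z, H, L


@dataclass
class RW2Fit:
    """Posterior samples of the constrained APC model.

    ``z_samples`` holds the latent block in constrained coordinates
    (intercept, two slopes, then the three curvature fields each re-expressed
    in the null space of its constraints); every reconstructed field sample
    satisfies the zero-sum and zero-trend constraints by construction.
    """

    dataset: APCDataset
    design: HolfordDesign
    family: ModelFamily
    config: SamplerConfig
    z_samples: np.ndarray          # (n_ret, dim_z)
    tau_samples: np.ndarray        # (n_ret, 3) ordered age, period, cohort
    diagnostics: dict
    _model: _Model = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.z_samples.shape[0]

    def eta_samples(self) -> np.ndarray:
        """(n_ret, n_cells) posterior samples of the linear predictor over
        every grid cell (log-rate scale for count families)."""
        return self.z_samples @ self._model.Xz_all.T

    def f_samples(self, scale: str) -> np.ndarray:
        """(n_ret, n_scale) samples of a curvature field."""
        i = ("age", "period", "cohort").index(scale)
        sl = self._model.slices[1 + i]
        return self.z_samples[:, sl] @ self._model.null_bases[scale].T

    def beta_samples(self) -> np.ndarray:
        return self.z_samples[:, self._model.slices[0]]

    def diagnostics_report(self) -> str:
        d = self.diagnostics
        lines = [
            f"retained samples: {self.n_samples}",
            f"latent acceptance rate: {d['latent_acceptance']:.3f}",
        ]
        for s in ("age", "period", "cohort"):
            lines.append(
                f"tau[{s}] acceptance: {d['tau_acceptance'][s]:.3f}, "
                f"ess: {d['tau_ess'][s]:.0f}"
            )
        lines.extend(d.get("warnings", []))
        return "\n".join(lines)


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size estimate."""
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - np.mean(x)
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.var(x) * n)
    s = 0.0
    for k in range(1, min(n // 2, 200)):
        if acf[k] < 0.01:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def _init_taus(priors: dict) -> dict:
    taus = {}
    for s, comp in priors.items():
        if comp.tau is not None:
            taus[s] = float(comp.tau)
        else:
            sigma_med = np.log(2.0) / comp.prior.kappa  # prior median of sigma
            taus[s] = float(1.0 / max(sigma_med, 1e-3) ** 2)
    return taus


def fit_bayes(
    dataset: APCDataset,
    design: HolfordDesign,
    priors: dict[str, RW2Component] | None = None,
    family: ModelFamily | None = None,
    config: SamplerConfig | None = None,
) -> RW2Fit:
    """Posterior sampling for the RW2 APC model.

    Cells with missing counts (NaN) contribute no likelihood; their linear
    predictor is still part of the latent field, so its posterior is the
    forecast.  Components with a fixed ``tau`` skip the precision update.
    Reproducible for a given ``config.seed``.
    """
    family = family or ModelFamily("poisson")
    config = config or SamplerConfig()
    if priors is None:
        priors = default_priors(design)
    model = _build_model(dataset, design, priors, family)
    rng = np.random.default_rng(config.seed)
    dim = model.Xz_obs.shape[1]

    taus = _init_taus(priors)
    steps = {s: config.tau_step for s in ("age", "period", "cohort")}
    z = np.zeros(dim)
    gaussian = family.family_name == "gaussian"

    n_ret = (config.iterations - config.burn_in) // config.thin
    z_out = np.empty((n_ret, dim))
    tau_out = np.empty((n_ret, 3))
    acc_latent = np.zeros(2)   # accepted, proposed (post burn-in)
    acc_tau = {s: np.zeros(2) for s in ("age", "period", "cohort")}
    tau_acc_window = {s: np.zeros(2) for s in ("age", "period", "cohort")}

    mode_cache = {"taus": None, "mode": z.copy(), "H": None, "L": None}
    k_out = 0

    for it in range(config.iterations):
        in_burn = it < config.burn_in
        Qz = _qz(model, taus)

        # --- latent block: Gaussian approximation at the conditional mode
        key = tuple(taus[s] for s in ("age", "period", "cohort"))
        if mode_cache["taus"] != key:
            m, H, L = _newton_mode(model, family, Qz, mode_cache["mode"],
                                   config)
            mode_cache.update(taus=key, mode=m, H=H, L=L)
        m, H, L = mode_cache["mode"], mode_cache["H"], mode_cache["L"]
        xi = rng.standard_normal(dim)
        z_prop = m + np.linalg.solve(L.T, xi)
        if gaussian:
            z = z_prop
            accepted = True
        else:
            def logq(v):
                d = v - m
                return -0.5 * d @ H @ d
            log_r = (_log_joint_z(model, family, z_prop, Qz) - logq(z_prop)) \
                - (_log_joint_z(model, family, z, Qz) - logq(z))
            accepted = np.log(rng.uniform()) < log_r
            if accepted:
                z = z_prop
        if not in_burn:
            acc_latent += [float(accepted), 1.0]

        # --- precision updates on ln(tau) with the PC prior
        for s, sl in zip(("age", "period", "cohort"), model.slices[1:]):
            comp = model.components[s]
            if comp.tau is not None:
                continue
            u = z[sl]
            quad = float(u @ model.Rz[s] @ u)
            n_f = model.field_sizes[s]
            kappa = comp.prior.kappa

            def logp(ltau):
                tau = np.exp(ltau)
                return (0.5 * (n_f - 2) * ltau - 0.5 * tau * quad
                        + log_pc_prior_tau(tau, kappa) + ltau)

            lt = np.log(taus[s])
            lt_prop = lt + steps[s] * rng.standard_normal()
            ok = np.log(rng.uniform()) < logp(lt_prop) - logp(lt)
            if ok:
                taus[s] = float(np.exp(lt_prop))
            tau_acc_window[s] += [float(ok), 1.0]
            if not in_burn:
                acc_tau[s] += [float(ok), 1.0]
            # step-size adaptation during burn-in only
            if config.adapt and in_burn and tau_acc_window[s][1] >= 50:
                rate = tau_acc_window[s][0] / tau_acc_window[s][1]
                steps[s] = float(np.clip(
                    steps[s] * np.exp(rate - 0.44), 1e-3, 10.0))
                tau_acc_window[s][:] = 0.0

        if not in_burn and (it - config.burn_in) % config.thin == 0 \
                and k_out < n_ret:
            z_out[k_out] = z
            tau_out[k_out] = [taus["age"], taus["period"], taus["cohort"]]
            k_out += 1

    z_out = z_out[:k_out]
    tau_out = tau_out[:k_out]

    warnings = []
    lat_rate = acc_latent[0] / max(acc_latent[1], 1.0)
    if not gaussian and not 0.1 <= lat_rate <= 1.0:
        warnings.append(f"latent acceptance rate {lat_rate:.2f} below 0.1")
    tau_rates = {}
    for s in ("age", "period", "cohort"):
        r = acc_tau[s][0] / max(acc_tau[s][1], 1.0)
        tau_rates[s] = r
        if acc_tau[s][1] > 0 and not 0.1 <= r <= 0.9:
            warnings.append(f"tau[{s}] acceptance rate {r:.2f} outside [0.1, 0.9]")
    diagnostics = {
        "latent_acceptance": lat_rate if not gaussian else 1.0,
        "tau_acceptance": tau_rates,
        "tau_ess": {s: _ess(np.log(tau_out[:, i])) if len(tau_out) else 0.0
                    for i, s in enumerate(("age", "period", "cohort"))},
        "tau_steps": dict(steps),
        "warnings": warnings,
        "seed": config.seed,
    }
    return RW2Fit(dataset=dataset, design=design, family=family,
                  config=config, z_samples=z_out, tau_samples=tau_out,
                  diagnostics=diagnostics, _model=model)


def conditional_posterior(
    dataset: APCDataset,
    design: HolfordDesign,
    taus: dict[str, float],
    family: ModelFamily | None = None,
):
    """Deterministic conditional posterior of the latent block at fixed
    precisions: the exact Gaussian posterior for gaussian observations, the
    Laplace (mode + curvature) approximation otherwise.

    Returns ``(eta_mean, eta_sd, fields, z_mode, H)`` where ``fields`` maps
    each time scale to its posterior-mode curvature values.
    """
    family = family or ModelFamily("gaussian")
    priors = {s: RW2Component(n=design.scale_sizes[s], tau=taus[s])
              for s in ("age", "period", "cohort")}
    model = _build_model(dataset, design, priors, family)
    cfg = SamplerConfig(iterations=1, burn_in=0, thin=1)
    Qz = _qz(model, taus)
    z0 = np.zeros(model.Xz_obs.shape[1])
    z_mode, H, _ = _newton_mode(model, family, Qz, z0, cfg)
    cov = np.linalg.inv(H)
    eta_mean = model.Xz_all @ z_mode
    eta_var = np.einsum("ij,jk,ik->i", model.Xz_all, cov, model.Xz_all)
    fields = {s: model.null_bases[s] @ z_mode[sl]
              for s, sl in zip(("age", "period", "cohort"), model.slices[1:])}
    return eta_mean, np.sqrt(np.maximum(eta_var, 0.0)), fields, z_mode, H


def forecast_rw2(
    dataset: APCDataset,
    t: int,
    dropped_slope: str = "cohort",
    priors_spec: PCPrior | None = None,
    family: ModelFamily | None = None,
    config: SamplerConfig | None = None,
    future_exposure: np.ndarray | None = None,
) -> RW2Fit:
    """Fit with the grid extended by ``t`` forecast periods (t = 0 fits
    without extension); the period field gains t nodes and the cohort field
    t new cohorts, all carrying no likelihood contribution."""
    if t < 0:
        raise ValueError("forecast horizon must be >= 0")
    ds = dataset if t == 0 else extend_dataset(dataset, t, future_exposure)
    design = build_design(ds, dropped_slope=dropped_slope)
    spec = priors_spec or PCPrior()
    priors = default_priors(design, U=spec.U, alpha=spec.alpha)
    return fit_bayes(ds, design, priors, family, config)


def rw2_conditional_forecast(f_obs: np.ndarray, tau: float, t: int):
    """Distribution of t future RW2 nodes given the observed field, by
    direct conditioning on the joint (n + t)-node precision matrix.

    Returns (mean, cov); the conditional mean continues the line through the
    last two nodes and the variance grows cubically in the horizon.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    n = len(f_obs)
    if n < 2:
        raise ValueError("need at least two observed nodes")
    if t == 0:
        return np.empty(0), np.empty((0, 0))
    Q = tau * rw2_structure(n + t).toarray()
    QBB = Q[n:, n:]
    QBA = Q[n:, :n]
    c, low = cho_factor(QBB)
    mean = -cho_solve((c, low), QBA @ f_obs)
    cov = cho_solve((c, low), np.eye(t))
    return mean, cov


def summarize_posterior(fit: RW2Fit, level: float = 0.95) -> PredictionSet:
    """Per-cell posterior (2.5%, 50%, 97.5%) quantiles of the linear
    predictor; point prediction is the posterior median."""
    if fit.n_samples < 100:
        raise ValueError(
            f"need at least 100 retained samples, have {fit.n_samples}"
        )
    alpha = 1.0 - level
    eta = fit.eta_samples()
    qs = np.quantile(eta, [alpha / 2, 0.5, 1 - alpha / 2], axis=0)
    g = fit.dataset.grid
    a, p, _ = g.cell_indices()
    return PredictionSet(
        age_idx=a, period_idx=p, eta=qs[1], lower=qs[0], upper=qs[2],
        is_forecast=p > g.n_fitted_periods, alpha_level=alpha,
        meta={"taus_median": np.median(fit.tau_samples, axis=0),
              "diagnostics": fit.diagnostics},
    )


def export_posterior(fit: RW2Fit, preds: PredictionSet, path) -> None:
    """Serialise per-cell posterior summaries and diagnostics to text."""
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
        for line in fit.diagnostics_report().splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
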
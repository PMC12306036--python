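"""Synthetic APC count data emulating a rare-event mortality surface.

The generator works on a single-year grid (ages 10-84, periods 2000-2020 by
default) with a fixed population at risk of 750,000 per single-year cell.
The true linear predictor combines an intercept, age and period slopes, and
three smooth curvature functions (low-order polynomial/trigonometric shapes
with a scale and shift, in the spirit of the Luo-Hodges simulation
functions), each projected onto the identifiable curvature space (zero sum,
zero linear trend over its single-year index set).  Counts are Poisson (or
negative binomial) draws with rate population * exp(eta), and the
single-year table is then aggregated into five-year age bands modelled at
their midpoints (12.5, 17.5, ..., 82.5; M = 5) -- mimicking how mortality
data are disseminated.

The intercept default (-11.3 on the log-rate scale) makes aggregated cells
average some tens of events, matching the order of magnitude of the
alcohol-related death counts that motivate the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grid import APCDataset, APCGrid, build_grid, constraint_nullspace

__all__ = [
    "SimulationConfig",
    "true_linear_predictor",
    "true_curvatures_on",
    "simulate_counts",
    "aggregate_ages",
    "true_aggregated_log_rate",
    "fixture_dataset",
]


def _default_age_shape(u: np.ndarray) -> np.ndarray:
    # concave-in-the-middle mortality-style age curvature
    return (u - 0.35) ** 2 + 0.15 * np.sin(2.0 * np.pi * u)


def _default_period_shape(u: np.ndarray) -> np.ndarray:
    # oscillation whose slope keeps changing through the forecast window,
    # so period trends do not flatten out conveniently at the range end
    return np.sin(2.5 * np.pi * u)


def _default_cohort_shape(u: np.ndarray) -> np.ndarray:
    return np.sin(2.0 * np.pi * u) + 0.5 * (u - 0.5) ** 2


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic APC data.

    Ages and periods are single years; ``population`` is the fixed exposure
    of every single-year cell.  The fit window ends at ``fit_end`` and the
    remaining periods form the forecast window.  Curvature shapes are
    callables on [0, 1]; ``scale_*`` multiply them and ``intercept`` shifts
    the whole log-rate surface.
    """

    age_start: int = 10
    age_end: int = 84
    period_start: int = 2000
    period_end: int = 2020
    population: float = 750_000.0
    agg_width: int = 5
    fit_end: int = 2017
    n_replicates: int = 100
    family: str = "poisson"
    dispersion: float | None = None
    intercept: float = -11.3
    slope_age: float = 0.02       # per single-year age index
    slope_period: float = 0.005   # per period index
    scale_age: float = 1.2
    scale_period: float = 0.2
    scale_cohort: float = 0.35
    age_shape: Callable = field(default=None)
    period_shape: Callable = field(default=None)
    cohort_shape: Callable = field(default=None)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_shape is None:
            self.age_shape = _default_age_shape
        if self.period_shape is None:
            self.period_shape = _default_period_shape
        if self.cohort_shape is None:
            self.cohort_shape = _default_cohort_shape
        if not self.period_start <= self.fit_end <= self.period_end:
            raise ValueError("fit_end must lie within the period range")
        if (self.age_end - self.age_start + 1) % self.agg_width != 0:
            raise ValueError("age range must divide evenly into bands")

    @property
    def n_ages(self) -> int:
        return self.age_end - self.age_start + 1

    @property
    def n_periods(self) -> int:
        return self.period_end - self.period_start + 1

    @property
    def forecast_horizon(self) -> int:
        return self.period_end - self.fit_end

    def single_year_grid(self) -> APCGrid:
        return build_grid(self.age_start - 0.5, 1.0, self.n_ages,
                          self.period_start, 1.0, self.n_periods)


def _project_curvature(raw: np.ndarray) -> np.ndarray:
    """Project onto {f : sum f = 0, sum t*f = 0} on the function's grid."""
    n = len(raw)
    N = constraint_nullspace(n)
    return N @ (N.T @ raw)


def true_curvatures_on(config: SimulationConfig, grid: APCGrid) -> dict:
    """True curvature functions evaluated on an arbitrary APC grid's index
    sets and projected onto that grid's identifiable curvature space.

    Shapes are parameterised on [0, 1] over the single-year label ranges, so
    the same underlying functions can be compared across aggregation levels.
    """
    a_lo, a_hi = config.age_start, config.age_end
    p_lo, p_hi = config.period_start, config.period_end
    c_lo = p_lo - a_hi
    c_hi = p_hi - a_lo
    u_age = (grid.age_values - a_lo) / (a_hi - a_lo)
    u_per = (grid.period_values - p_lo) / (p_hi - p_lo)
    u_coh = (grid.cohort_values - c_lo) / (c_hi - c_lo)
    return {
        "age": _project_curvature(config.scale_age * config.age_shape(u_age)),
        "period": _project_curvature(
            config.scale_period * config.period_shape(u_per)),
        "cohort": _project_curvature(
            config.scale_cohort * config.cohort_shape(u_coh)),
    }


def true_linear_predictor(config: SimulationConfig) -> np.ndarray:
    """Noiseless log-rate surface eta (I_single x J) on the single-year grid:
    intercept + centred slopes + the three projected curvatures."""
    g = config.single_year_grid()
    curv = true_curvatures_on(config, g)
    for s, f in curv.items():
        n = len(f)
        t = np.arange(1, n + 1)
        if abs(np.sum(f)) > 1e-8 or abs(np.sum(t * f)) > 1e-8:
            raise ValueError(f"{s} curvature violates constraints")
    a, p, c = g.cell_indices()
    eta = (config.intercept
           + config.slope_age * (a - (g.I + 1) / 2.0)
           + config.slope_period * (p - (g.J + 1) / 2.0)
           + curv["age"][a - 1]
           + curv["period"][p - 1]
           + curv["cohort"][c - 1])
    return eta.reshape(g.I, g.J)


def simulate_counts(config: SimulationConfig, replicate_seed: int) -> APCDataset:
    """One replicate of single-year counts: y ~ Poisson(population * exp(eta))
    (or negative binomial with the configured dispersion)."""
    g = config.single_year_grid()
    eta = true_linear_predictor(config)
    rate = config.population * np.exp(eta)
    if np.any(rate > 1e12):
        bad = np.unravel_index(int(np.argmax(rate)), rate.shape)
        raise ValueError(f"rate overflow at cell {bad}: {rate[bad]:.3g}")
    rng = np.random.default_rng(replicate_seed)
    if config.family == "poisson":
        counts = rng.poisson(rate).astype(float)
    elif config.family == "negative_binomial":
        th = config.dispersion
        if th is None or th <= 0:
            raise ValueError("negative_binomial needs dispersion > 0")
        # gamma-poisson mixture: var = mu + mu^2/theta
        counts = rng.poisson(rng.gamma(th, rate / th)).astype(float)
    else:
        raise ValueError(f"unknown family {config.family!r}")
    exposure = np.full((g.I, g.J), config.population)
    return APCDataset(grid=g, counts=counts, exposure=exposure)


def aggregate_ages(dataset: APCDataset, width: int = 5) -> APCDataset:
    """Sum counts and exposure into ``width``-year age bands, modelled at
    their midpoints; total counts and exposure are conserved exactly."""
    g = dataset.grid
    if g.I % width != 0:
        raise ValueError(
            f"ragged final band: {g.I} single-year ages not divisible by {width}"
        )
    I_new = g.I // width
    counts = dataset.counts.reshape(I_new, width, g.J).sum(axis=1)
    exposure = dataset.exposure.reshape(I_new, width, g.J).sum(axis=1)
    w_p = float(np.mean(np.diff(g.period_values))) if g.J > 1 else 1.0
    # single-year label a denotes the year interval [a, a+1), so the first
    # band's left edge is the first label and band 10-14 gets midpoint 12.5
    new_grid = build_grid(float(g.age_values[0]), width * w_p * g.M, I_new,
                          float(g.period_values[0]), w_p, g.J)
    return APCDataset(grid=new_grid, counts=counts, exposure=exposure)


def true_aggregated_log_rate(config: SimulationConfig) -> np.ndarray:
    """Noiseless log-rate truth on the aggregated grid: the log of the
    exposure-weighted mean rate within each age band (the linear predictor
    a correctly specified model targets)."""
    eta = true_linear_predictor(config)
    I_new = config.n_ages // config.agg_width
    rate = np.exp(eta).reshape(I_new, config.agg_width, config.n_periods)
    return np.log(rate.mean(axis=1))


def fixture_dataset(seed: int = 1234) -> APCDataset:
    """Small deterministic aggregated dataset (I=5, J=8) for unit tests."""
    cfg = SimulationConfig(age_start=10, age_end=34, period_start=2000,
                           period_end=2007, fit_end=2005, seed=seed)
    return aggregate_ages(simulate_counts(cfg, seed), cfg.agg_width)
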
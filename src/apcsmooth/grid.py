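"""Age-period-cohort grids, count datasets, and the identifiable Holford design.

An APC table indexes events by age group ``a = 1..I`` and period ``p = 1..J``.
When age groups span ``M`` periods each (e.g. five-year age bands with annual
periods, ``M = 5``), the cohort index is ``c = M*(I - a) + p``, running from 1
(oldest age, first period) to ``K = M*(I - 1) + J`` (youngest age, last
period).

Because cohort = period - age, the three linear trends are confounded: only an
intercept, two slopes and three curvature functions (each orthogonal to its own
level and linear trend) are estimable.  :func:`build_design` constructs that
identifiable parameterisation: the curvature of each time scale is represented
on its full index set subject to the two Holford constraints
``sum_t f(t) = 0`` and ``sum_t t*f(t) = 0``, imposed by a null-space
reparameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "APCGrid",
    "APCDataset",
    "ModelFamily",
    "HolfordDesign",
    "build_grid",
    "extend_grid",
    "extend_dataset",
    "build_design",
    "constraint_nullspace",
    "read_apc_table",
    "write_apc_table",
]

TimeScale = Literal["age", "period", "cohort"]


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APCGrid:
    """Rectangular age x period grid with derived cohort indexing.

    Parameters
    ----------
    I, J : int
        Number of age groups and periods.
    M : int
        Ratio of age-interval width to period-interval width (>= 1).
    age_values, period_values : ndarray
        Ordered numeric labels; age labels are interval midpoints when
        intervals are aggregated.
    n_fitted_periods : int
        Number of periods present when the grid was built; periods beyond
        this index are forecast extensions (see :func:`extend_grid`).
    """

    I: int
    J: int
    M: int
    age_values: np.ndarray
    period_values: np.ndarray
    n_fitted_periods: int | None = None

    def __post_init__(self) -> None:
        if self.M < 1 or int(self.M) != self.M:
            raise ValueError(f"M must be a positive integer, got {self.M}")
        av = np.asarray(self.age_values, dtype=float)
        pv = np.asarray(self.period_values, dtype=float)
        if av.shape != (self.I,) or pv.shape != (self.J,):
            raise ValueError("age/period label lengths must match I and J")
        if np.any(np.diff(av) <= 0) or np.any(np.diff(pv) <= 0):
            raise ValueError("age and period values must be strictly increasing")
        object.__setattr__(self, "age_values", av)
        object.__setattr__(self, "period_values", pv)
        if self.n_fitted_periods is None:
            object.__setattr__(self, "n_fitted_periods", self.J)

    @property
    def K(self) -> int:
        """Number of cohorts, ``M*(I-1) + J``."""
        return self.M * (self.I - 1) + self.J

    def cohort_index(self, a: int, p: int) -> int:
        """Cohort index ``c = M*(I-a) + p`` (1-based; p may exceed J)."""
        if not 1 <= a <= self.I:
            raise ValueError(f"age index {a} outside 1..{self.I}")
        if p < 1:
            raise ValueError(f"period index {p} must be >= 1")
        return self.M * (self.I - a) + p

    @property
    def cohort_values(self) -> np.ndarray:
        """Birth-time labels for cohorts c = 1..K (period label - age label)."""
        w_p = float(np.mean(np.diff(self.period_values))) if self.J > 1 else 1.0
        base = self.period_values[0] - self.age_values[0]
        return base + w_p * (np.arange(self.K) - self.M * (self.I - 1))

    def cell_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-based (a, p, c) index arrays for all I*J cells, age-major order."""
        a = np.repeat(np.arange(1, self.I + 1), self.J)
        p = np.tile(np.arange(1, self.J + 1), self.I)
        c = self.M * (self.I - a) + p
        return a, p, c

    def metadata(self) -> dict:
        return {
            "I": self.I,
            "J": self.J,
            "M": self.M,
            "K": self.K,
            "age_start": float(self.age_values[0]),
            "period_start": float(self.period_values[0]),
            "n_fitted_periods": self.n_fitted_periods,
        }


def build_grid(
    age_start: float,
    age_width: float,
    n_age: int,
    period_start: float,
    period_width: float,
    n_period: int,
) -> APCGrid:
    """Build an :class:`APCGrid` with age labels at interval midpoints.

    ``age_width`` must be an integer multiple of ``period_width``; the ratio
    becomes ``M`` in the cohort index.
    """
    if n_age < 2 or n_period < 2:
        raise ValueError("need at least 2 age groups and 2 periods")
    ratio = age_width / period_width
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"age width {age_width} is not an integer multiple of period "
            f"width {period_width}"
        )
    M = int(round(ratio))
    age_values = age_start + age_width / 2.0 + age_width * np.arange(n_age)
    period_values = period_start + period_width * np.arange(n_period)
    return APCGrid(I=n_age, J=n_period, M=M, age_values=age_values,
                   period_values=period_values)


def extend_grid(grid: APCGrid, t: int) -> APCGrid:
    """Extend a grid by ``t`` forecast periods.

    The new grid has ``J' = J + t`` and ``K' = M*(I-1) + J + t``; every
    original cell keeps its (a, p, c) triple.  Cohort indices above the old
    ``K`` are new (they require forecasting); cohorts at or below ``K`` repeat
    over several period columns and need no new cohort effect.
    """
    if t < 1:
        raise ValueError("forecast horizon t must be >= 1")
    w_p = float(np.mean(np.diff(grid.period_values)))
    new_periods = grid.period_values[-1] + w_p * np.arange(1, t + 1)
    return APCGrid(
        I=grid.I,
        J=grid.J + t,
        M=grid.M,
        age_values=grid.age_values,
        period_values=np.concatenate([grid.period_values, new_periods]),
        n_fitted_periods=grid.n_fitted_periods,
    )


def new_cohorts(original: APCGrid, extended: APCGrid) -> np.ndarray:
    """Cohort indices present in the extended grid but not the original."""
    return np.arange(original.K + 1, extended.K + 1)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class APCDataset:
    """Counts and exposure on an APC grid.

    ``counts`` may contain NaN for missing cells (e.g. forecast targets);
    those cells contribute nothing to any likelihood but their linear
    predictor is still predicted.  ``exposure`` (population at risk) must be
    positive wherever a count is observed.
    """

    grid: APCGrid
    counts: np.ndarray
    exposure: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        shape = (self.grid.I, self.grid.J)
        if self.counts.shape != shape or self.exposure.shape != shape:
            raise ValueError(
                f"counts/exposure shape must be {shape}, got "
                f"{self.counts.shape} and {self.exposure.shape}"
            )
        obs = ~np.isnan(self.counts)
        # counts are non-negative for the count families; gaussian responses
        # (e.g. observed log-rates) may be any finite real
        if np.any(~np.isfinite(self.counts[obs])):
            raise ValueError("observed responses must be finite")
        if np.any(self.exposure[obs] <= 0):
            raise ValueError("exposure must be positive where counts observed")

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.counts)

    def empirical_log_rates(self, continuity: bool = True) -> np.ndarray:
        """Observed log-rates for display/scoring; adds 1/2 event when
        ``continuity`` to avoid log(0).  Never used in model fitting."""
        y = self.counts + (0.5 if continuity else 0.0)
        with np.errstate(divide="ignore"):
            return np.log(y / self.exposure)


def extend_dataset(
    dataset: APCDataset,
    t: int,
    future_exposure: np.ndarray | None = None,
) -> APCDataset:
    """Append ``t`` forecast periods with NaN counts.

    ``future_exposure`` is an (I, t) array; defaults to repeating the last
    observed period's exposure.
    """
    grid = extend_grid(dataset.grid, t)
    if future_exposure is None:
        future_exposure = np.tile(dataset.exposure[:, -1:], (1, t))
    counts = np.concatenate(
        [dataset.counts, np.full((dataset.grid.I, t), np.nan)], axis=1
    )
    exposure = np.concatenate([dataset.exposure, future_exposure], axis=1)
    return APCDataset(grid=grid, counts=counts, exposure=exposure)


def mask_periods(dataset: APCDataset, last_fit_period: float) -> APCDataset:
    """Return a copy with counts after ``last_fit_period`` (by label) set NaN."""
    hold = dataset.grid.period_values > last_fit_period
    counts = dataset.counts.copy()
    counts[:, hold] = np.nan
    g = replace(dataset.grid, n_fitted_periods=int(np.sum(~hold)))
    return APCDataset(grid=g, counts=counts, exposure=dataset.exposure.copy())


# ---------------------------------------------------------------------------
# Model family
# ---------------------------------------------------------------------------

@dataclass
class ModelFamily:
    """Observation family with its canonical link for APC rate modelling.

    poisson and negative_binomial use a log link with a log-exposure offset,
    so the linear predictor is a log rate; gaussian uses the identity link
    and ignores exposure.  ``theta`` is the negative-binomial dispersion
    (var = mu + mu^2/theta) or the gaussian variance.
    """

    family_name: Literal["poisson", "negative_binomial", "gaussian"] = "poisson"
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.family_name not in ("poisson", "negative_binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family_name!r}")
        if self.family_name == "negative_binomial":
            if self.theta is None or self.theta <= 0:
                raise ValueError("negative_binomial requires dispersion theta > 0")
        if self.family_name == "gaussian" and self.theta is None:
            self.theta = 1.0
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def link(self) -> str:
        return "identity" if self.family_name == "gaussian" else "log"

    # log-likelihood and its first two derivatives in eta (the linear
    # predictor on the log-rate scale for count families); `off` is the log
    # exposure offset (ignored for gaussian).

    def loglik(self, y: np.ndarray, eta: np.ndarray, off: np.ndarray) -> float:
        from scipy.special import gammaln

        if self.family_name == "gaussian":
            s2 = self.theta
            return float(np.sum(-0.5 * (y - eta) ** 2 / s2
                                - 0.5 * np.log(2 * np.pi * s2)))
        mu = np.exp(eta + off)
        if self.family_name == "poisson":
            return float(np.sum(y * (eta + off) - mu - gammaln(y + 1)))
        th = self.theta
        return float(np.sum(
            gammaln(y + th) - gammaln(th) - gammaln(y + 1)
            + th * np.log(th / (th + mu)) + y * np.log(mu / (th + mu))
        ))

    def score(self, y: np.ndarray, eta: np.ndarray, off: np.ndarray) -> np.ndarray:
        if self.family_name == "gaussian":
            return (y - eta) / self.theta
        mu = np.exp(eta + off)
        if self.family_name == "poisson":
            return y - mu
        th = self.theta
        return y - (y + th) * mu / (th + mu)

    def weight(self, y: np.ndarray, eta: np.ndarray, off: np.ndarray) -> np.ndarray:
        """Expected negative second derivative of loglik wrt eta (IRLS weight)."""
        if self.family_name == "gaussian":
            return np.full_like(eta, 1.0 / self.theta)
        mu = np.exp(eta + off)
        if self.family_name == "poisson":
            return mu
        th = self.theta
        return th * mu / (th + mu)

    def deviance(self, y: np.ndarray, eta: np.ndarray, off: np.ndarray) -> float:
        if self.family_name == "gaussian":
            return float(np.sum((y - eta) ** 2))
        mu = np.exp(eta + off)
        if self.family_name == "poisson":
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            return float(2.0 * np.sum(term - (y - mu)))
        th = self.theta
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + th) * np.log((y + th) / (mu + th))
        return float(2.0 * np.sum(t1 - t2))


# ---------------------------------------------------------------------------
# Holford design
# ---------------------------------------------------------------------------

def constraint_nullspace(n: int) -> np.ndarray:
    """Orthonormal basis (n x (n-2)) of {f : sum f = 0, sum t*f = 0}.

    The two constraints remove the level and linear trend of an index-valued
    function, leaving its identifiable curvature.
    """
    from scipy.linalg import null_space

    t = np.arange(1, n + 1, dtype=float)
    A = np.vstack([np.ones(n), t])
    return null_space(A)


@dataclass
class HolfordDesign:
    """Identifiable APC parameterisation: intercept, two slopes, three
    constrained curvature components.

    ``dropped_slope`` names the time scale whose slope is omitted (default
    cohort).  Slope covariates are centred, unit-spaced integer indices;
    curvatures are functions on the full index set of each scale, subject to
    zero-sum and zero-linear-trend constraints.  The assembled full-index
    design has rank ``I + J + K - 3``.
    """

    grid: APCGrid
    dropped_slope: TimeScale = "cohort"
    # orthonormal constraint null-space bases per scale, built lazily
    _null_bases: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dropped_slope not in ("age", "period", "cohort"):
            raise ValueError(f"unknown slope {self.dropped_slope!r}")

    @property
    def scale_sizes(self) -> dict[str, int]:
        return {"age": self.grid.I, "period": self.grid.J, "cohort": self.grid.K}

    @property
    def slope_scales(self) -> tuple[str, str]:
        return tuple(s for s in ("age", "period", "cohort")
                     if s != self.dropped_slope)  # type: ignore[return-value]

    def null_basis(self, scale: TimeScale) -> np.ndarray:
        n = self.scale_sizes[scale]
        key = (scale, n)
        if key not in self._null_bases:
            self._null_bases[key] = constraint_nullspace(n)
        return self._null_bases[key]

    def centred_index(self, scale: TimeScale, idx: np.ndarray) -> np.ndarray:
        """Centred covariate for a 1-based index array; centring uses the
        fitted grid so forecast rows extend the same line."""
        if scale == "age":
            n = self.grid.I
        elif scale == "period":
            n = self.grid.n_fitted_periods
        else:
            n = self.grid.M * (self.grid.I - 1) + self.grid.n_fitted_periods
        return np.asarray(idx, dtype=float) - (n + 1) / 2.0

    def fixed_columns(
        self, a: np.ndarray, p: np.ndarray, c: np.ndarray
    ) -> np.ndarray:
        """Intercept + two slope columns for cells with 1-based indices."""
        idx = {"age": a, "period": p, "cohort": c}
        cols = [np.ones(len(a))]
        for s in self.slope_scales:
            cols.append(self.centred_index(s, idx[s]))
        return np.column_stack(cols)

    def full_design_matrix(self, grid: APCGrid | None = None) -> np.ndarray:
        """Design matrix with each curvature at full (constrained) index
        dimension: one constrained-indicator block per time scale."""
        g = grid if grid is not None else self.grid
        a, p, c = g.cell_indices()
        blocks = [self.fixed_columns(a, p, c)]
        for scale, idx in (("age", a), ("period", p), ("cohort", c)):
            N = self.null_basis(scale)
            blocks.append(N[idx - 1, :])
        return np.concatenate(blocks, axis=1)

    def block_slices(self, sizes: list[int]) -> list[slice]:
        """Column slices [fixed, age, period, cohort] for given block sizes."""
        out, start = [], 0
        for s in sizes:
            out.append(slice(start, start + s))
            start += s
        return out


def build_design(dataset: APCDataset, dropped_slope: TimeScale = "cohort") -> HolfordDesign:
    """Construct the identifiable Holford design for a dataset's grid."""
    return HolfordDesign(grid=dataset.grid, dropped_slope=dropped_slope)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _parse_age_label(label) -> float:
    """Midpoint of an age label: numeric as-is, 'lo-hi' bands to lo + w/2."""
    s = str(label).strip()
    if "-" in s and not s.lstrip().startswith("-"):
        lo, hi = s.split("-")
        lo_f, hi_f = float(lo), float(hi)
        return (lo_f + hi_f + 1.0) / 2.0  # band "25-29" spans [25, 30)
    return float(s)


def read_apc_table(path) -> APCDataset:
    """Read a delimited APC count table.

    Expected columns (case-insensitive): age (midpoint or "lo-hi" band
    label), year, deaths, population.  Rows with unparseable fields are
    reported with their line numbers.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"age", "year", "deaths", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    errors = []
    ages = []
    for i, v in enumerate(df["age"]):
        try:
            ages.append(_parse_age_label(v))
        except (ValueError, TypeError):
            errors.append(f"line {i + 2}: bad age label {v!r}")
    if errors:
        raise ValueError("; ".join(errors))
    df["age_mid"] = ages
    age_vals = np.sort(df["age_mid"].unique())
    per_vals = np.sort(df["year"].unique())
    if len(age_vals) < 2 or len(per_vals) < 2:
        raise ValueError("need at least 2 distinct ages and periods")
    w_a = float(np.min(np.diff(age_vals)))
    w_p = float(np.min(np.diff(per_vals)))
    ratio = w_a / w_p
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"age spacing {w_a} is not an integer multiple of period spacing {w_p}"
        )
    grid = APCGrid(I=len(age_vals), J=len(per_vals), M=int(round(ratio)),
                   age_values=age_vals, period_values=per_vals)
    counts = np.full((grid.I, grid.J), np.nan)
    exposure = np.full((grid.I, grid.J), np.nan)
    a_pos = {v: i for i, v in enumerate(age_vals)}
    p_pos = {v: j for j, v in enumerate(per_vals)}
    for _, row in df.iterrows():
        i, j = a_pos[row["age_mid"]], p_pos[row["year"]]
        counts[i, j] = row["deaths"]
        exposure[i, j] = row["population"]
    if np.any(np.isnan(exposure)):
        raise ValueError("table does not cover the full age x year grid")
    return APCDataset(grid=grid, counts=counts, exposure=exposure)


def write_apc_table(dataset: APCDataset, path) -> None:
    """Write a dataset in the delimited format read_apc_table accepts."""
    g = dataset.grid
    rows = []
    for i, av in enumerate(g.age_values):
        for j, pv in enumerate(g.period_values):
            rows.append({
                "age": av,
                "year": pv,
                "deaths": dataset.counts[i, j],
                "population": dataset.exposure[i, j],
            })
    pd.DataFrame(rows).to_csv(path, index=False)
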
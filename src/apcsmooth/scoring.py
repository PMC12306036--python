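"""Predictive scoring: MAE, MSE, 95% interval score, width, coverage.

Point accuracy is measured on the linear-predictor (log-rate) scale.  The
interval score for a central (1 - alpha) interval [l, u] and outcome eta is

    IS_alpha = (u - l) + (2/alpha) * (l - eta) * 1[eta < l]
             + (2/alpha) * (eta - u) * 1[eta > u],

a proper scoring rule balancing interval width against coverage; scores are
aggregated by averaging over cells (and replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictionSet",
    "WindowScores",
    "ScoreReport",
    "interval_score",
    "point_scores",
    "distributional_scores",
    "score_report",
]


@dataclass
class PredictionSet:
    """Per-cell point predictions with uncertainty intervals.

    ``eta`` is the predicted linear predictor (log rate for count models),
    ``lower``/``upper`` the central-interval bounds at level 1 - alpha_level,
    ``is_forecast`` flags out-of-sample cells.
    """

    age_idx: np.ndarray
    period_idx: np.ndarray
    eta: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    is_forecast: np.ndarray
    alpha_level: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("age_idx", "period_idx", "eta", "lower", "upper",
                     "is_forecast"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = len(self.eta)
        for name in ("age_idx", "period_idx", "lower", "upper", "is_forecast"):
            if len(getattr(self, name)) != n:
                raise ValueError("prediction arrays must have equal length")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")

    def subset(self, mask: np.ndarray) -> "PredictionSet":
        return PredictionSet(
            self.age_idx[mask], self.period_idx[mask], self.eta[mask],
            self.lower[mask], self.upper[mask], self.is_forecast[mask],
            self.alpha_level, dict(self.meta),
        )


@dataclass
class WindowScores:
    mae: float
    mse: float
    interval_score: float
    width: float
    coverage: float
    n_cells: int


@dataclass
class ScoreReport:
    """Scores split into estimation (in-sample) and forecasting windows.

    ``truth_convention`` records what served as the ground truth: the
    noiseless generator linear predictor for simulated data, or observed
    empirical log-rates (with or without the +1/2 continuity correction) for
    real data.
    """

    estimation: WindowScores
    forecasting: WindowScores | None
    N: int = 1
    truth_convention: str = "generator"


def interval_score(l, u, eta, alpha: float = 0.05) -> np.ndarray:
    """Interval score of [l, u] at level 1 - alpha for outcome eta."""
    l = np.asarray(l, dtype=float)
    u = np.asarray(u, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.any(l > u):
        raise ValueError("interval lower bound exceeds upper bound")
    below = np.maximum(l - eta, 0.0)
    above = np.maximum(eta - u, 0.0)
    return (u - l) + (2.0 / alpha) * (below + above)


def _stack(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def point_scores(eta_hat, truth) -> dict:
    """MAE and MSE per cell (averaged over replicates) and grand means.

    ``eta_hat`` and ``truth`` are arrays of shape (N, n_cells) or (n_cells,);
    truth may be a single row shared by all replicates.
    """
    eh, tr = _stack(eta_hat), _stack(truth)
    if tr.shape[0] == 1 and eh.shape[0] > 1:
        tr = np.broadcast_to(tr, eh.shape)
    if eh.shape != tr.shape:
        raise ValueError(f"shape mismatch: {eh.shape} vs {tr.shape}")
    err = eh - tr
    mae_cell = np.mean(np.abs(err), axis=0)
    mse_cell = np.mean(err ** 2, axis=0)
    return {
        "mae_cell": mae_cell,
        "mse_cell": mse_cell,
        "mae": float(np.mean(mae_cell)),
        "mse": float(np.mean(mse_cell)),
    }


def distributional_scores(lower, upper, truth, alpha: float = 0.05) -> dict:
    """Mean interval score, mean width and empirical coverage over cells
    (and replicates)."""
    lo, up, tr = _stack(lower), _stack(upper), _stack(truth)
    if tr.shape[0] == 1 and lo.shape[0] > 1:
        tr = np.broadcast_to(tr, lo.shape)
    if not lo.shape == up.shape == tr.shape:
        raise ValueError("shape mismatch between bounds and truth")
    is_vals = interval_score(lo, up, tr, alpha)
    inside = (lo <= tr) & (tr <= up)
    return {
        "interval_score": float(np.mean(is_vals)),
        "width": float(np.mean(up - lo)),
        "coverage": float(np.mean(inside)),
    }


def _window(preds: list[PredictionSet], truths: list[np.ndarray],
            forecast: bool) -> WindowScores | None:
    mask = preds[0].is_forecast.astype(bool)
    sel = mask if forecast else ~mask
    if not np.any(sel):
        return None
    eh = np.stack([p.eta[sel] for p in preds])
    lo = np.stack([p.lower[sel] for p in preds])
    up = np.stack([p.upper[sel] for p in preds])
    tr = np.stack([np.asarray(t)[sel] for t in truths])
    pt = point_scores(eh, tr)
    ds = distributional_scores(lo, up, tr, preds[0].alpha_level)
    return WindowScores(mae=pt["mae"], mse=pt["mse"],
                        interval_score=ds["interval_score"],
                        width=ds["width"], coverage=ds["coverage"],
                        n_cells=int(np.sum(sel)))


def score_report(preds, truths, truth_convention: str = "generator") -> ScoreReport:
    """Score one or more replicates' predictions against their truths.

    ``preds`` is a PredictionSet or list of them (one per replicate, same
    cell layout); ``truths`` the matching truth array(s) on the same cells.
    """
    if isinstance(preds, PredictionSet):
        preds = [preds]
        truths = [truths]
    if len(preds) != len(truths):
        raise ValueError("need one truth array per prediction set")
    est = _window(preds, truths, forecast=False)
    fc = _window(preds, truths, forecast=True)
    if est is None:
        raise ValueError("no estimation cells to score")
    return ScoreReport(estimation=est, forecasting=fc, N=len(preds),
                       truth_convention=truth_convention)


def report_table(reports: dict[str, ScoreReport], scale: float = 1.0):
    """Tabulate reports as rows (model x window), optionally scaled
    (e.g. scale=100 mirrors tables printed as x10^-2)."""
    import pandas as pd

    rows = []
    for name, rep in reports.items():
        for window, ws in (("estimation", rep.estimation),
                           ("forecasting", rep.forecasting)):
            if ws is None:
                continue
            rows.append({
                "model": name,
                "window": window,
                "interval_score": ws.interval_score * scale,
                "width": ws.width * scale,
                "coverage": ws.coverage * 100.0,
                "mae": ws.mae * scale,
                "mse": ws.mse * scale,
                "n_cells": ws.n_cells,
                "N": rep.N,
            })
    return pd.DataFrame(rows)
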
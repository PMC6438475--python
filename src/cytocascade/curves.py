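"""Pass-through spline fitting of sparse series and minute-grid resampling.

The analysis relies on a cubic piecewise-polynomial interpolant: with the
default smoothing parameter p = 1 the fitted curve reproduces every
observed sample exactly, so no information in the sparse measurements is
discarded — the spline only supplies a smooth estimate *between* draws.
Negative undershoot (possible near sharp pulses) is clipped to zero on the
resampled grid, since concentrations are physical quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .data import AnalysisConfig, CytokineSeries

__all__ = ["FittedCurve", "FitError", "fit_curve", "curve_at"]


class FitError(ValueError):
    """A series cannot be fitted (too few points, duplicate times, ...)."""


@dataclass
class FittedCurve:
    """A minute-resolution curve covering [first sample, last sample].

    ``grid`` is uniform at the configured resample step except possibly for
    a shortened final step so that the last sample time is always included;
    no extrapolation beyond the observed span ever occurs.
    """

    grid: np.ndarray  # minutes
    values: np.ndarray  # pg/mL, clipped at 0
    source: CytokineSeries
    step: float
    clipped_negative: bool = False  # did the raw interpolant undershoot 0?

    @property
    def t_first(self) -> float:
        return float(self.grid[0])

    @property
    def t_last(self) -> float:
        return float(self.grid[-1])

    def __len__(self) -> int:
        return len(self.grid)


def _resample_grid(t_first: float, t_last: float, step: float) -> np.ndarray:
    n = int(np.floor((t_last - t_first) / step + 1e-9))
    grid = t_first + step * np.arange(n + 1)
    if grid[-1] < t_last - 1e-9:  # shortened final step
        grid = np.append(grid, t_last)
    else:
        grid[-1] = t_last
    return grid


def fit_curve(series: CytokineSeries, config: AnalysisConfig | None = None) -> FittedCurve:
    """Fit a natural cubic spline through a sparse series and resample it.

    With ``config.smoothing_parameter == 1`` (the default) the spline passes
    through every observation exactly; values below 1 blend toward a
    penalised smoothing spline and are intended for sensitivity analysis
    only.

    Raises
    ------
    FitError
        If the series has fewer than 4 points or duplicate sample times.
    """
    config = config or AnalysisConfig()
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.conc, dtype=float)
    if len(t) < 4:
        raise FitError(
            f"series {series.animal_id}/{series.cytokine}: need at least 4 points, got {len(t)}"
        )
    if np.any(np.diff(t) <= 0):
        raise FitError(
            f"series {series.animal_id}/{series.cytokine}: duplicate or unordered times"
        )

    p = config.smoothing_parameter
    if p >= 1.0:
        spline = CubicSpline(t, y, bc_type="natural")
    else:
        # Penalised cubic smoothing spline; lam -> 0 recovers the interpolant.
        lam = (1.0 - p) / max(p, 1e-12)
        spline = make_smoothing_spline(t, y, lam=lam)

    grid = _resample_grid(t[0], t[-1], config.resample_step)
    raw = spline(grid)
    clipped = bool(np.any(raw < 0))
    values = np.clip(raw, 0.0, None)
    return FittedCurve(grid=grid, values=values, source=series,
                       step=config.resample_step, clipped_negative=clipped)


def curve_at(curve: FittedCurve, t: float) -> float:
    """Value at time ``t`` by nearest grid point (grid resolution is the
    configured resample step, so this is within half a step of the spline).

    Raises
    ------
    ValueError
        If ``t`` lies outside the fitted domain — the curve never
        extrapolates.
    """
    if t < curve.t_first - 1e-9 or t > curve.t_last + 1e-9:
        raise ValueError(
            f"t={t} outside fitted domain [{curve.t_first}, {curve.t_last}]"
        )
    i = int(np.argmin(np.abs(curve.grid - t)))
    return float(curve.values[i])
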
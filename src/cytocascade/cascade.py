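"""Peak and onset detection, starting-point alignment, and effective AUC.

This is the core statistic chain. Each fitted curve is baseline-corrected
(mean of pre-injection samples, by default), its first prominent peak is
located, and the elevation *starting point* is the earliest time at which
the corrected curve reaches ``onset_fraction`` (default 5 %) of the peak
amplitude and stays there until the peak. Curves of a group are then
re-indexed so that each starting point becomes time zero, truncated to the
longest duration covered by every member, and quantified by the trapezoidal
"effective" area under the curve over that common window.

Late-rising cytokines that have not peaked by the last sample use the last
recorded concentration as an *effective peak*; series with no elevation
above baseline raise :class:`NoElevationError` and are excluded (and
counted), which is how reduced per-cytokine n arises in practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .curves import FittedCurve, FitError, fit_curve
from .data import AnalysisConfig, Cohort

__all__ = [
    "NoElevationError",
    "PeakInfo",
    "OnsetResult",
    "AlignedCurve",
    "AlignedSet",
    "corrected_values",
    "detect_peak",
    "detect_onset",
    "analyze_series",
    "align_set",
    "compute_auc",
    "onset_table",
]


class NoElevationError(ValueError):
    """The corrected curve never rises meaningfully above baseline."""


@dataclass(frozen=True)
class PeakInfo:
    t_peak: float  # minutes
    peak_amp: float  # pg/mL above baseline
    effective_peak_is_last: bool
    baseline: float  # pg/mL subtracted before peak logic
    peak_index: int  # index of the peak on the curve grid


@dataclass(frozen=True)
class OnsetResult:
    baseline: float
    t_peak: float
    peak_amp: float
    effective_peak_is_last: bool
    t_onset: float  # minutes; the elevation starting point
    threshold_value: float  # onset_fraction * peak_amp, pg/mL
    left_censored: bool = False  # curve already above threshold at first grid point
    onset_index: int = 0
    peak_index: int = 0


@dataclass
class AlignedCurve:
    """A baseline-corrected, zero-clipped curve re-indexed to its onset."""

    times: np.ndarray  # minutes since onset, starting at 0
    values: np.ndarray  # pg/mL above baseline, clipped at 0
    source: FittedCurve
    onset: OnsetResult


@dataclass
class AlignedSet:
    """Onset-zeroed curves truncated to the common duration, with AUCs."""

    curves: list[AlignedCurve]
    common_duration: float  # minutes
    aucs: np.ndarray  # pg·min/mL, one per curve
    has_saturation: np.ndarray  # AUC is a lower bound where True

    def __len__(self) -> int:
        return len(self.curves)


def corrected_values(curve: FittedCurve, config: AnalysisConfig) -> tuple[np.ndarray, float]:
    """Baseline-corrected curve values and the baseline used.

    In ``subtract_baseline`` mode the baseline is the mean of fitted values
    at pre-injection grid times; in ``raw`` mode it is zero.
    """
    if config.baseline_mode == "subtract_baseline":
        pre = curve.grid < 0
        baseline = float(curve.values[pre].mean()) if np.any(pre) else 0.0
    else:
        baseline = 0.0
    return curve.values - baseline, baseline


def detect_peak(curve: FittedCurve, config: AnalysisConfig | None = None) -> PeakInfo:
    """Locate the first prominent peak of the baseline-corrected curve.

    Candidate peaks are local maxima with prominence at least
    ``prominence_fraction`` of the corrected curve's global range, so assay
    jitter does not register; the earliest candidate wins. A curve still
    rising at its last sample (no interior candidate, last value is the
    running maximum) uses the last value as the effective peak.

    Raises
    ------
    NoElevationError
        If the corrected peak amplitude is non-positive or does not exceed
        ``elevation_min_ratio`` times the baseline level.
    """
    config = config or AnalysisConfig()
    y, baseline = corrected_values(curve, config)
    rng = float(y.max() - y.min())
    effective_last = False
    idx: int
    if rng > 0:
        cand, _ = find_peaks(y, prominence=config.prominence_fraction * rng)
    else:
        cand = np.array([], dtype=int)
    if cand.size:
        idx = int(cand[0])  # first peak, if there are multiple
    elif y[-1] >= y.max() - 1e-12:
        idx = len(y) - 1
        effective_last = True
    else:
        idx = int(np.argmax(y))
        effective_last = idx == len(y) - 1
    amp = float(y[idx])
    if amp <= 0 or amp < config.elevation_min_ratio * baseline:
        raise NoElevationError(
            f"series {curve.source.animal_id}/{curve.source.cytokine}: "
            f"no calculable elevation (peak {amp:.3g} pg/mL over baseline "
            f"{baseline:.3g} pg/mL)"
        )
    return PeakInfo(
        t_peak=float(curve.grid[idx]),
        peak_amp=amp,
        effective_peak_is_last=effective_last,
        baseline=baseline,
        peak_index=idx,
    )


def detect_onset(curve: FittedCurve, peak: PeakInfo,
                 config: AnalysisConfig | None = None) -> OnsetResult:
    """Find the elevation starting point: the earliest grid time at which
    the corrected curve reaches ``onset_fraction`` of the peak amplitude
    and remains at or above it up to the peak (sustained-crossing rule;
    identical to first-touch on noise-free curves).

    If the curve already exceeds the threshold at its first grid point the
    onset is left-censored: it is reported at the first grid point with a
    warning, never extrapolated before the observations.
    """
    config = config or AnalysisConfig()
    y, _ = corrected_values(curve, config)
    threshold = config.onset_fraction * peak.peak_amp
    # tolerance so exact analytic crossings are not missed to rounding
    thr = threshold - 1e-9 * max(1.0, abs(peak.peak_amp))
    i = peak.peak_index
    while i > 0 and y[i - 1] >= thr:
        i -= 1
    left_censored = i == 0 and y[0] >= thr
    if left_censored:
        warnings.warn(
            f"series {curve.source.animal_id}/{curve.source.cytokine}: onset "
            "left-censored (already above threshold at first sample)",
            stacklevel=2,
        )
    return OnsetResult(
        baseline=peak.baseline,
        t_peak=peak.t_peak,
        peak_amp=peak.peak_amp,
        effective_peak_is_last=peak.effective_peak_is_last,
        t_onset=float(curve.grid[i]),
        threshold_value=threshold,
        left_censored=left_censored,
        onset_index=i,
        peak_index=peak.peak_index,
    )


def analyze_series(series, config: AnalysisConfig | None = None) -> tuple[FittedCurve, OnsetResult]:
    """Convenience: fit, then peak + onset, in one call."""
    config = config or AnalysisConfig()
    curve = fit_curve(series, config)
    peak = detect_peak(curve, config)
    return curve, detect_onset(curve, peak, config)


def align_set(onsets: list[tuple[FittedCurve, OnsetResult]],
              config: AnalysisConfig | None = None) -> AlignedSet:
    """Re-index each curve to its onset (t' = t - t_onset), truncate all to
    the shortest post-onset span, and compute effective AUCs.

    The common duration D is ``min(t_last - t_onset)`` over members; every
    stored curve covers exactly [0, D].
    """
    config = config or AnalysisConfig()
    if not onsets:
        raise ValueError("align_set needs at least one (curve, onset) member")
    spans = [c.t_last - o.t_onset for c, o in onsets]
    D = float(min(spans))
    curves: list[AlignedCurve] = []
    aucs = np.empty(len(onsets))
    sat = np.zeros(len(onsets), dtype=bool)
    for j, (curve, onset) in enumerate(onsets):
        y, _ = corrected_values(curve, config)
        y = np.clip(y, 0.0, None)
        t = curve.grid - onset.t_onset
        keep = (t >= -1e-9) & (t <= D + 1e-9)
        tt, yy = t[keep], y[keep]
        if tt[-1] < D - 1e-9:  # member grids can differ; close the window at D
            yv = float(np.interp(D, t, y))
            tt = np.append(tt, D)
            yy = np.append(yy, yv)
        tt[0], tt[-1] = 0.0, D
        aligned = AlignedCurve(times=tt, values=yy, source=curve, onset=onset)
        curves.append(aligned)
        aucs[j] = compute_auc(aligned, D)
        sat[j] = curve.source.has_saturation
    return AlignedSet(curves=curves, common_duration=D, aucs=aucs, has_saturation=sat)


def compute_auc(curve: AlignedCurve, D: float) -> float:
    """Trapezoidal effective area under an aligned curve on [0, D],
    pg·min/mL; the integrand is baseline-corrected and zero-clipped."""
    if D <= 0:
        raise ValueError("common duration D must be positive")
    t, y = curve.times, np.clip(curve.values, 0.0, None)
    inside = t <= D + 1e-9
    return float(np.trapezoid(y[inside], t[inside]))


def onset_table(cohort: Cohort, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-cytokine onset summary over all animals with calculable
    elevations: mean, SD, s.e.m. = SD/sqrt(n), n, and the number of
    excluded (no-elevation or unfittable) series; ordered by mean onset."""
    config = config or AnalysisConfig()
    rows = []
    for cyto in cohort.cytokines:
        onsets = []
        n_excluded = 0
        for s in cohort.subset(cytokine=cyto):
            try:
                _, res = analyze_series(s, config)
            except (NoElevationError, FitError):
                n_excluded += 1
                continue
            onsets.append(res.t_onset)
        if not onsets:
            rows.append((cyto, math.nan, math.nan, math.nan, 0, n_excluded))
            continue
        arr = np.asarray(onsets)
        n = len(arr)
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        rows.append((cyto, float(arr.mean()), sd, sd / math.sqrt(n), n, n_excluded))
    df = pd.DataFrame(
        rows,
        columns=["cytokine", "mean_onset_min", "sd_onset_min", "sem_onset_min",
                 "n", "n_excluded"],
    )
    return df.sort_values("mean_onset_min", na_position="last").reset_index(drop=True)
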
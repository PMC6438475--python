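"""Domain types, tidy-table cohort IO, and input validation.

The unit conventions used throughout the package:

* time is in minutes relative to the endotoxin (LPS) injection, with the
  injection at t = 0 and baseline samples at negative times;
* concentrations are in pg/mL;
* areas under curves are in pg·min/mL.

A cohort is stored on disk as a tidy, one-row-per-measurement CSV with
columns ``animal_id, subgroup, cytokine, time_min, conc_pg_ml, flag``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_CYTOKINES",
    "VALID_FLAGS",
    "COHORT_COLUMNS",
    "SampleSchedule",
    "CytokineSeries",
    "Cohort",
    "AnalysisConfig",
    "CohortFormatError",
    "default_schedule",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "load_config",
    "save_config",
]

#: The 13-plex rat Th cytokine panel the assay quantifies.
CANONICAL_CYTOKINES = (
    "IL-2", "IL-4", "IL-5", "IL-6", "IL-9", "IL-10", "IL-13",
    "IL-17A", "IL-17F", "IL-22", "GM-CSF", "IFN-g", "TNF-a",
)

#: Per-point censoring states carried from the assay.
VALID_FLAGS = ("ok", "below_floor", "saturated")

COHORT_COLUMNS = ("animal_id", "subgroup", "cytokine", "time_min", "conc_pg_ml", "flag")


class CohortFormatError(ValueError):
    """A cohort file or in-memory cohort violates the data contract."""


def default_schedule() -> "SampleSchedule":
    """The standard acute collection grid: 12 samples, 30 min apart,
    one baseline draw 30 min before injection ({-30, 0, 30, ..., 300})."""
    return SampleSchedule(times=tuple(range(-30, 301, 30)))


@dataclass(frozen=True)
class SampleSchedule:
    """Blood-collection times in minutes relative to the LPS injection."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 4:
            raise CohortFormatError("schedule needs at least 4 sample times")
        if not np.all(np.diff(t) > 0):
            raise CohortFormatError("schedule times must be strictly increasing")
        if not np.any(t < 0):
            raise CohortFormatError("schedule needs at least one pre-injection (t < 0) sample")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    @property
    def span(self) -> float:
        return self.times[-1] - self.times[0]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CytokineSeries:
    """One animal x one cytokine sparse concentration time series."""

    animal_id: str
    subgroup: str
    cytokine: str
    times: np.ndarray  # minutes, strictly increasing
    conc: np.ndarray  # pg/mL, non-negative
    flags: np.ndarray | None = None  # entries from VALID_FLAGS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.times.shape, "ok", dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if not (len(self.times) == len(self.conc) == len(self.flags)):
            raise CohortFormatError(
                f"series {self.animal_id}/{self.cytokine}: times, conc and flags "
                "must have equal length"
            )
        if not np.all(np.diff(self.times) > 0):
            raise CohortFormatError(
                f"series {self.animal_id}/{self.cytokine}: times must be strictly increasing"
            )
        if np.any(self.conc < 0):
            raise CohortFormatError(
                f"series {self.animal_id}/{self.cytokine}: negative concentration"
            )
        if self.cytokine not in CANONICAL_CYTOKINES:
            warnings.warn(
                f"cytokine name {self.cytokine!r} is not in the canonical 13-plex panel",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def key(self) -> tuple[str, str]:
        return (self.animal_id, self.cytokine)

    @property
    def has_saturation(self) -> bool:
        return bool(np.any(self.flags == "saturated"))


@dataclass
class Cohort:
    """A collection of per-animal, per-cytokine series plus study metadata."""

    series: list[CytokineSeries]
    dose_mg_kg: float | None = None
    route: str | None = None  # "IP" or "IV"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def animals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.series:
            seen.setdefault(s.animal_id, None)
        return list(seen)

    @property
    def cytokines(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.series:
            seen.setdefault(s.cytokine, None)
        return list(seen)

    def subset(self, *, subgroup: str | None = None, cytokine: str | None = None) -> "Cohort":
        kept = [
            s
            for s in self.series
            if (subgroup is None or s.subgroup == subgroup)
            and (cytokine is None or s.cytokine == cytokine)
        ]
        return Cohort(kept, self.dose_mg_kg, self.route, self.provenance)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the curve-fitting / onset / statistics chain.

    onset_fraction
        Fraction of the (baseline-corrected) peak amplitude that defines the
        elevation starting point; 0.05 reproduces the 5 %-of-peak rule.
    smoothing_parameter
        Spline smoothing parameter p in [0, 1]; p = 1 is a pure interpolant
        that preserves every sample value (the default analysis mode).
    resample_step
        Resolution, in minutes, of the resampled fitted curve.
    prominence_fraction
        A local maximum counts as a peak only if its prominence exceeds this
        fraction of the corrected curve's global range; guards the
        "first peak" rule against assay jitter.
    baseline_mode
        "subtract_baseline" corrects by the mean of pre-injection samples
        before peak/threshold logic; "raw" uses concentrations as measured.
    elevation_min_ratio
        Minimum corrected peak amplitude, as a multiple of the baseline
        level, for a series to count as a calculable elevation. Separates
        responders from baseline-only noise; dimensionless and therefore
        scale-invariant.
    iqr_multiplier
        Tukey fence half-width k: values outside [Q1 - k*IQR, Q3 + k*IQR]
        are outliers.
    no_change_band
        Percent-change magnitude below which a group effect is called
        "no_change" regardless of its p-value.
    alpha_levels
        Significance benchmarks, most to least stringent.
    """

    onset_fraction: float = 0.05
    smoothing_parameter: float = 1.0
    resample_step: float = 1.0
    prominence_fraction: float = 0.2
    baseline_mode: str = "subtract_baseline"
    elevation_min_ratio: float = 0.5
    iqr_multiplier: float = 1.5
    no_change_band: float = 15.0
    alpha_levels: tuple[float, ...] = (0.01, 0.05, 0.1)
    equal_var_ttest: bool = True
    multitest: str | None = None  # None or "bh"

    def __post_init__(self) -> None:
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset_fraction must lie in (0, 1)")
        if not 0 <= self.smoothing_parameter <= 1:
            raise ValueError("smoothing_parameter must lie in [0, 1]")
        if self.resample_step <= 0:
            raise ValueError("resample_step must be positive")
        if self.iqr_multiplier < 0:
            raise ValueError("iqr_multiplier must be non-negative")
        if self.baseline_mode not in ("subtract_baseline", "raw"):
            raise ValueError("baseline_mode must be 'subtract_baseline' or 'raw'")
        object.__setattr__(self, "alpha_levels", tuple(sorted(self.alpha_levels)))


# ---------------------------------------------------------------------------
# IO


def _series_sort_key(s: CytokineSeries) -> tuple[str, str]:
    return (s.animal_id, s.cytokine)


def read_cohort(path: str | Path, *, dose_mg_kg: float | None = None,
                route: str | None = None) -> Cohort:
    """Read a tidy cohort CSV into a validated :class:`Cohort`.

    Rows are grouped into one series per (animal_id, cytokine) and sorted by
    time within each series. Structural problems (missing columns,
    non-numeric or negative concentrations, duplicated sample times) are
    rejected with the offending row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "subgroup": str,
                                  "cytokine": str, "flag": str},
                     float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {', '.join(missing)}")

    for col in ("time_min", "conc_pg_ml"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise CohortFormatError(
                f"{path}: non-numeric {col} at row {bad[0] + 2} "
                f"(value {df.loc[bad[0], col]!r})"
            )
        if coerced.isna().any():
            raise CohortFormatError(f"{path}: empty {col} at row {coerced.index[coerced.isna()][0] + 2}")
        df[col] = coerced

    neg = df.index[df["conc_pg_ml"] < 0]
    if len(neg):
        raise CohortFormatError(
            f"{path}: negative concentration at row {neg[0] + 2} "
            f"(animal {df.loc[neg[0], 'animal_id']}, t={df.loc[neg[0], 'time_min']})"
        )
    dup = df.duplicated(subset=["animal_id", "cytokine", "time_min"])
    if dup.any():
        i = df.index[dup][0]
        raise CohortFormatError(
            f"{path}: duplicate sample at row {i + 2} "
            f"(animal {df.loc[i, 'animal_id']}, cytokine {df.loc[i, 'cytokine']}, "
            f"t={df.loc[i, 'time_min']})"
        )
    badflag = ~df["flag"].isin(VALID_FLAGS)
    if badflag.any():
        i = df.index[badflag][0]
        raise CohortFormatError(
            f"{path}: unknown flag {df.loc[i, 'flag']!r} at row {i + 2}"
        )

    series: list[CytokineSeries] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-canonical names warn once below
        noncanonical: set[str] = set()
        for (animal, cyto), g in df.groupby(["animal_id", "cytokine"], sort=True):
            g = g.sort_values("time_min")
            subgroups = g["subgroup"].unique()
            if len(subgroups) > 1:
                raise CohortFormatError(
                    f"{path}: animal {animal} appears under multiple subgroups "
                    f"{sorted(subgroups)}"
                )
            if cyto not in CANONICAL_CYTOKINES:
                noncanonical.add(str(cyto))
            series.append(
                CytokineSeries(
                    animal_id=str(animal),
                    subgroup=str(subgroups[0]),
                    cytokine=str(cyto),
                    times=g["time_min"].to_numpy(),
                    conc=g["conc_pg_ml"].to_numpy(),
                    flags=g["flag"].to_numpy(dtype=object),
                )
            )
    for name in sorted(noncanonical):
        warnings.warn(f"cytokine name {name!r} is not in the canonical 13-plex panel",
                      stacklevel=2)
    series.sort(key=_series_sort_key)
    return Cohort(series, dose_mg_kg=dose_mg_kg, route=route, provenance=str(path))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the tidy one-row-per-measurement table."""
    rows = []
    for s in sorted(cohort.series, key=_series_sort_key):
        for t, c, f in zip(s.times, s.conc, s.flags):
            rows.append((s.animal_id, s.subgroup, s.cytokine, t, c, f))
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a tidy CSV with deterministic (animal, cytokine,
    time) row order; an empty cohort yields a header-only file."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Report every invariant violation; an empty report means valid.

    Total: never raises, including on badly malformed input.
    """
    report: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    animal_schedules: dict[str, tuple[float, ...]] = {}
    for i, s in enumerate(cohort.series):
        label = f"series[{i}] ({s.animal_id}/{s.cytokine})"
        if s.key in seen:
            report.append(f"{label}: duplicate (animal_id, cytokine) pair")
        else:
            seen[s.key] = i
        try:
            times = np.asarray(s.times, dtype=float)
            conc = np.asarray(s.conc, dtype=float)
        except (TypeError, ValueError):
            report.append(f"{label}: non-numeric times or concentrations")
            continue
        if not (len(times) == len(conc) == len(s.flags)):
            report.append(f"{label}: unequal lengths of times/conc/flags")
            continue
        if len(times) < 4:
            report.append(f"{label}: fewer than 4 samples")
        if len(times) and not np.all(np.diff(times) > 0):
            report.append(f"{label}: times not strictly increasing")
        if np.any(conc < 0):
            report.append(f"{label}: negative concentration")
        if not np.any(times < 0):
            report.append(f"{label}: no pre-injection (t < 0) baseline sample")
        if not set(map(str, s.flags)) <= set(VALID_FLAGS):
            report.append(f"{label}: unknown censor flag")
        sched = tuple(times)
        prev = animal_schedules.setdefault(s.animal_id, sched)
        if prev != sched:
            report.append(f"{label}: schedule differs from other series of animal {s.animal_id}")
    return report


# ---------------------------------------------------------------------------
# Config IO


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CohortFormatError(f"{path}: config must be a YAML mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise CohortFormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "alpha_levels" in raw:
        raw["alpha_levels"] = tuple(raw["alpha_levels"])
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    data = {k: getattr(config, k) for k in AnalysisConfig.__dataclass_fields__}
    data["alpha_levels"] = list(data["alpha_levels"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
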
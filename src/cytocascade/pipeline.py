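"""End-to-end orchestration: fit -> peak/onset -> align -> AUC -> stats.

`analyze_cohort` runs the whole chain on a cohort and returns the tables a
study report needs. Curves of one cytokine are aligned *jointly across all
subgroups*, so every animal's effective AUC is integrated over the same
common post-onset duration and between-group AUC comparisons are
like-for-like. Series that fail a stage (no calculable elevation, too few
points) are reported and skipped, never fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import NoElevationError, align_set, analyze_series, onset_table
from .curves import FitError
from .data import AnalysisConfig, Cohort
from .groupstats import effect_matrix, group_summaries

__all__ = ["AnalysisResult", "analyze_cohort"]


@dataclass
class AnalysisResult:
    """All pipeline outputs for one cohort.

    per_series
        One row per analysed (animal, cytokine): onset, peak, AUC, flags.
    onsets
        Per-cytokine onset summary (mean, SD, s.e.m., n), ordered by mean.
    groups
        Per-(subgroup, cytokine) AUC and onset summaries.
    effects
        Effect-call matrix vs the reference subgroup (None if the cohort
        has a single subgroup or no reference was given).
    events
        Structured log of per-series skips and warnings.
    """

    per_series: pd.DataFrame
    onsets: pd.DataFrame
    groups: pd.DataFrame
    effects: pd.DataFrame | None
    events: list[dict] = field(default_factory=list)

    @property
    def n_no_elevation(self) -> int:
        return sum(1 for e in self.events if e["event"] == "no_elevation")


def analyze_cohort(cohort: Cohort, config: AnalysisConfig | None = None,
                   reference: str | None = None) -> AnalysisResult:
    """Run the full statistic chain on a cohort.

    ``reference`` names the subgroup against which effect calls are made
    (e.g. the sham-stimulated controls); if None and the cohort has more
    than one subgroup, the lexicographically first subgroup is used.
    """
    config = config or AnalysisConfig()
    events: list[dict] = []
    rows: list[dict] = []

    for cyto in cohort.cytokines:
        members = []
        for s in cohort.subset(cytokine=cyto):
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    curve, onset = analyze_series(s, config)
                for w in caught:
                    if "left-censored" in str(w.message):
                        events.append({"stage": "onset", "animal_id": s.animal_id,
                                       "cytokine": cyto, "event": "left_censored"})
            except NoElevationError:
                events.append({"stage": "peak", "animal_id": s.animal_id,
                               "cytokine": cyto, "event": "no_elevation"})
                continue
            except FitError as exc:
                events.append({"stage": "fit", "animal_id": s.animal_id,
                               "cytokine": cyto, "event": "fit_error",
                               "detail": str(exc)})
                continue
            members.append((s, curve, onset))
        if not members:
            continue
        aligned = align_set([(c, o) for _, c, o in members], config)
        for (s, curve, onset), auc, sat in zip(members, aligned.aucs,
                                               aligned.has_saturation):
            rows.append({
                "animal_id": s.animal_id,
                "subgroup": s.subgroup,
                "cytokine": cyto,
                "t_onset": onset.t_onset,
                "t_peak": onset.t_peak,
                "peak_amp": onset.peak_amp,
                "baseline": onset.baseline,
                "effective_peak_is_last": onset.effective_peak_is_last,
                "left_censored": onset.left_censored,
                "auc": float(auc),
                "auc_is_lower_bound": bool(sat),  # saturation clipped the curve
                "common_duration_min": aligned.common_duration,
            })
            if sat:
                events.append({"stage": "auc", "animal_id": s.animal_id,
                               "cytokine": cyto, "event": "saturated_lower_bound"})

    per_series = pd.DataFrame(rows)
    if per_series.empty:
        raise ValueError("no analysable series in cohort")
    onsets = onset_table(cohort, config)
    groups = group_summaries(per_series)

    effects = None
    subgroups = sorted(per_series["subgroup"].unique())
    if len(subgroups) > 1:
        ref = reference or subgroups[0]
        if ref not in subgroups:
            raise ValueError(f"reference subgroup {ref!r} not present in cohort")
        effects = effect_matrix(per_series, ref, config)
    return AnalysisResult(per_series=per_series, onsets=onsets, groups=groups,
                          effects=effects, events=events)
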
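"""Outlier handling, group statistics, percent-change effects, and the
direction matrix comparing stimulated subgroups with the sham reference.

Statistics match the study design these tools serve: Tukey IQR fences for
outlier removal, classical one-way fixed-effects ANOVA across subgroups,
and a two-sided pooled-variance Student's t-test for post-hoc pairwise
comparisons (Welch available as an option). No multiple-testing correction
is applied by default; Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import AnalysisConfig

__all__ = [
    "GroupSummary",
    "EffectCall",
    "remove_outliers_iqr",
    "anova_oneway",
    "ttest_two_sample",
    "pct_change",
    "group_summaries",
    "effect_matrix",
    "render_effect_matrix",
]


@dataclass(frozen=True)
class GroupSummary:
    subgroup: str
    cytokine: str
    n: int
    mean_auc: float
    sem_auc: float
    mean_onset: float
    sem_onset: float


@dataclass(frozen=True)
class EffectCall:
    subgroup: str
    cytokine: str
    pct_change: float  # % vs the reference subgroup's mean AUC
    p_value: float
    direction: str  # "up" | "down" | "no_change"
    significance: str  # "none" | "p<0.1" | "p<0.05" | "p<0.01"


def remove_outliers_iqr(values, config: AnalysisConfig | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by Tukey fences
    [Q1 - k*IQR, Q3 + k*IQR] with k = ``iqr_multiplier``.

    Quartiles use the linear-interpolation convention
    (``numpy.percentile`` default). The fence is re-applied until no
    further value falls outside it, so the operation is idempotent: the
    kept set is a fixed point of the fence rule. Fewer than 4 values
    cannot support a quartile estimate: everything is kept, with a warning.
    """
    config = config or AnalysisConfig()
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values: IQR outlier removal skipped", stacklevel=2)
        return x, np.empty(0)
    k = config.iqr_multiplier
    if np.isinf(k):
        return x, np.empty(0)
    kept = x
    removed: list[np.ndarray] = []
    while kept.size >= 4:
        q1, q3 = np.percentile(kept, [25, 75])
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        keep = (kept >= lo) & (kept <= hi)
        if keep.all():
            break
        removed.append(kept[~keep])
        kept = kept[keep]
    out = np.concatenate(removed) if removed else np.empty(0)
    return kept, out


def anova_oneway(*groups) -> tuple[float, float, tuple[int, int]]:
    """Classical one-way fixed-effects ANOVA.

    Returns ``(F, p, (df_between, df_within))``. Groups of fewer than two
    observations are rejected. Identical groups with zero between-group
    variance give F = 0, p = 1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            len(groups[0]) and hasattr(groups[0][0], "__len__"):
        groups = tuple(groups[0])
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each ANOVA group needs at least 2 observations")
    dfb = len(arrays) - 1
    dfw = sum(g.size for g in arrays) - len(arrays)
    F, p = sps.f_oneway(*arrays)
    if np.isnan(F):  # zero within- and between-group variance
        F, p = 0.0, 1.0
    return float(F), float(p), (dfb, dfw)


def ttest_two_sample(a, b, *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance by default; set
    ``equal_var=False`` for Welch). Degenerate zero-variance inputs with
    equal means give (0, 1); with unequal means, (inf, 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pct_change(group_mean: float, ref_mean: float) -> float:
    """Percent change of a group mean relative to the reference mean:
    100 * (group - ref) / ref. The reference must be positive."""
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive for a percent change")
    return 100.0 * (group_mean - ref_mean) / ref_mean


def group_summaries(results: pd.DataFrame) -> pd.DataFrame:
    """Per (subgroup, cytokine) summary of AUCs and onsets.

    ``results`` is a per-animal table with columns subgroup, cytokine,
    animal_id, auc, t_onset (as produced by the pipeline).
    """
    def _sem(x):
        x = np.asarray(x, dtype=float)
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    out = (
        results.groupby(["subgroup", "cytokine"], sort=True)
        .agg(
            n=("auc", "size"),
            mean_auc=("auc", "mean"),
            sem_auc=("auc", _sem),
            mean_onset=("t_onset", "mean"),
            sem_onset=("t_onset", _sem),
        )
        .reset_index()
    )
    return out


_SIG_LABELS = {0.1: "p<0.1", 0.05: "p<0.05", 0.01: "p<0.01"}


def _significance(p: float, alpha_levels) -> str:
    for alpha in sorted(alpha_levels):  # most stringent first
        if p < alpha:
            return _SIG_LABELS.get(alpha, f"p<{alpha:g}")
    return "none"


def effect_matrix(auc_table: pd.DataFrame, reference: str,
                  config: AnalysisConfig | None = None) -> pd.DataFrame:
    """One effect call per (subgroup, cytokine) versus the reference
    subgroup: percent change of mean AUC, p-value from the post-hoc
    two-sample t-test on per-animal AUCs (after IQR outlier removal),
    direction via the no-change band, and a significance bracket.

    ``auc_table`` needs columns subgroup, cytokine, auc (one row per
    animal). The reference subgroup must be present for every cytokine.
    """
    config = config or AnalysisConfig()
    calls: list[EffectCall] = []
    cytokines = sorted(auc_table["cytokine"].unique())
    subgroups = [g for g in sorted(auc_table["subgroup"].unique()) if g != reference]
    raw_ps = []
    for cyto in cytokines:
        sub = auc_table[auc_table["cytokine"] == cyto]
        ref_vals = sub.loc[sub["subgroup"] == reference, "auc"].to_numpy(dtype=float)
        if ref_vals.size == 0:
            raise ValueError(f"reference subgroup {reference!r} missing for {cyto}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref_kept, _ = remove_outliers_iqr(ref_vals, config)
        for grp in subgroups:
            vals = sub.loc[sub["subgroup"] == grp, "auc"].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, _ = remove_outliers_iqr(vals, config)
            pct = pct_change(float(kept.mean()), float(ref_kept.mean()))
            if kept.size >= 2 and ref_kept.size >= 2:
                _, p = ttest_two_sample(kept, ref_kept, equal_var=config.equal_var_ttest)
            else:
                p = float("nan")
            raw_ps.append(p)
            calls.append(EffectCall(grp, cyto, pct, p, "", ""))

    ps = np.array([c.p_value for c in calls])
    if config.multitest == "bh" and np.isfinite(ps).any():
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(ps)
        adj = ps.copy()
        adj[finite] = multipletests(ps[finite], method="fdr_bh")[1]
        ps = adj

    rows = []
    for call, p in zip(calls, ps):
        if abs(call.pct_change) < config.no_change_band:
            direction = "no_change"
        else:
            direction = "up" if call.pct_change > 0 else "down"
        sig = _significance(p, config.alpha_levels) if np.isfinite(p) else "none"
        rows.append((call.subgroup, call.cytokine, call.pct_change, p, direction, sig))
    return pd.DataFrame(
        rows, columns=["subgroup", "cytokine", "pct_change", "p_value",
                       "direction", "significance"],
    )


_ARROWS = {"up": "↑", "down": "↓", "no_change": "♦"}
_STARS = {"none": "", "p<0.1": "#", "p<0.05": "*", "p<0.01": "**"}


def render_effect_matrix(matrix: pd.DataFrame) -> str:
    """Render the effect matrix as a text table with direction arrows and
    significance markers (# p<0.1, * p<0.05, ** p<0.01)."""
    cytokines = list(dict.fromkeys(matrix["cytokine"]))
    lines = ["subgroup\t" + "\t".join(cytokines)]
    for grp, g in matrix.groupby("subgroup", sort=True):
        cells = []
        by_cyto = g.set_index("cytokine")
        for cyto in cytokines:
            if cyto in by_cyto.index:
                row = by_cyto.loc[cyto]
                cells.append(_ARROWS[row["direction"]] + _STARS.get(row["significance"], ""))
            else:
                cells.append("")
        lines.append(grp + "\t" + "\t".join(cells))
    return "\n".join(lines)
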
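# cytocascade

Onset-aligned analysis of sparse plasma cytokine time courses after an
acute endotoxin (LPS) challenge.

## The problem

After a systemic LPS injection, plasma cytokines rise and fall in an
ordered cascade (IL-10 first, then TNF-α, GM-CSF, IL-17F, IL-6, IL-22 and
finally IFN-γ for intraperitoneal dosing). Blood can only be drawn sparsely
— typically a dozen samples 30 minutes apart — and the *timing* of each
animal's cascade varies by tens of minutes, so naive time-locked averaging
smears the group response and hides treatment effects (e.g. of vagus nerve
stimulation) on response magnitude. `cytocascade` implements the analysis
chain that solves this:

1. **Curve fitting** — a pass-through (interpolating, smoothing parameter
   p = 1) natural cubic spline through each animal × cytokine series,
   resampled at 1-minute resolution. No extrapolation; negative undershoot
   is clipped at zero.
2. **Onset detection** — the elevation *starting point* t₀ is the earliest
   time the baseline-corrected curve reaches 5 % of its peak amplitude
   (first peak if there are several; the last recorded concentration serves
   as the *effective peak* for curves still rising at the final sample) and
   stays above it until the peak.
3. **Alignment and effective AUC** — curves of a group are re-indexed so
   each starting point becomes time zero, truncated to the common duration
   D = min(t_last − t₀), and quantified by the trapezoidal area under the
   curve on [0, D] (pg·min/mL).
4. **Group statistics** — IQR outlier removal (Tukey fences), one-way
   ANOVA, post-hoc two-sided pooled t-tests, percent change versus a sham
   reference subgroup, and a direction matrix (↑ / ↓ / ♦ with p < 0.1,
   0.05, 0.01 markers).

Two companion components make the chain testable end to end:

* a **synthetic cohort generator** producing LPS-challenge cohorts with
  known ground truth — gamma-like pulses, a dominant animal-level shared
  timing shift, per-cytokine onset means/SDs from the published IP
  characterization, measurement noise, assay saturation and non-responders;
* an **offset-subsampling validation harness** that splits densely sampled
  (10-min) series into staggered 30-min subsets and measures how stable the
  estimated onsets and AUCs are against sampling-schedule choice.

## Worked example

Simulate a small two-subgroup cohort in which hepatic-branch stimulation
(`HBes`) multiplies the IL-10 response amplitude by 1.73, then analyse it:

```bash
cat > spec.yaml <<EOF
n_animals: 8
seed: 42
effects:
  HBes:
    IL-10: 1.73
EOF
cytocascade simulate --spec spec.yaml --out sim
cytocascade analyze --cohort sim/cohort.csv --reference SubD-Sham --out results
```

`analyze` prints `analysed 96 series (16 without calculable elevation)` —
the 16 exclusions are simulated non-responders (IL-17F and IL-22 elevate in
only a subset of animals, which is why their n is reduced below). The
onset table (`results/onset_table.csv`) orders the cascade by mean
starting time in minutes post-injection:

```
cytokine  mean_onset_min  sd_onset_min  sem_onset_min   n  n_excluded
   IL-10            50.9          19.7            4.9  16           0
   TNF-a            79.6          21.3            5.3  16           0
  IL-17F           109.7          27.9            9.3   9           7
  GM-CSF           121.8          29.0            7.2  16           0
    IL-6           130.8          19.9            5.0  16           0
   IL-22           164.1          51.4           19.4   7           9
   IFN-g           186.5          26.0            6.5  16           0
```

and the effect matrix (`results/effect_matrix.csv`) recovers the planted
IL-10 effect against the sham reference:

```
subgroup cytokine  pct_change  p_value direction significance
    HBes    IL-10        68.2    0.048        up       p<0.05
```

i.e. a +68 % mean effective-AUC elevation (true value +73 %), significant
at the 0.05 level. `cytocascade validate` runs the offset-subsampling
harness on a dense cohort, and `cytocascade report` re-prints a run's
manifest (config snapshot, file digests, seed, warnings).

The same operations are available as a library
(`cytocascade.simulate_cohort`, `analyze_cohort`, `offset_invariance`, …);
see `docs/methods.md` for the model and every tunable parameter.

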
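# fiberphot

Analysis of two-channel fiber-photometry recordings of dopamine sensor
signals (dLight/GRAB class), built for studies that ask whether
dopamine release is time-locked to behavioral events — social
investigation bouts, elevated-plus-maze arm entries — and whether it
habituates across sessions. The package also covers the accompanying
histology quantification: Mander's colocalization of presynaptic
markers with labeled axon terminals, and ROI-based fiber density
comparisons.

## What it computes

Starting from a 465 nm signal channel and a 405 nm isosbestic control
channel (volts):

1. **Motion/bleach correction** — 3 Hz zero-phase low-pass on both
   channels, least-squares scaling of the control onto the signal
   channel, then ΔF/F0 = (F₄₆₅ − fitted F₄₀₅) / fitted F₄₀₅.
2. **Peri-event z-scores** — ΔF/F0 epochs from −1 to +3 s around each
   event onset (t = 0), standardized by the mean and SD of the 1 s
   pre-onset baseline; per-second bin means; per-animal averages.
3. **Random-sampling null** — the same analysis on 10 + 10 timestamps
   drawn uniformly from the first and second halves of the 5 min
   recording, not locked to behavior.
4. **Repeated-measures statistics** — one-way RM ANOVA over time bins
   with Dunnett contrasts against the pre-onset baseline, the two-way
   RM time × (signal vs random) interaction with Bonferroni post hocs,
   and unpaired two-tailed t tests for group comparisons.
5. **Imaging** — Otsu auto-thresholding, Mander's M1/M2, and
   supra-threshold pixel counts in randomly allocated 0.3 × 0.4 mm
   ROIs.

Because no recordings are publicly available for this paradigm, the
package ships a ground-truth simulator (`fiberphot.synthetic`) that
emulates the recordings' statistical structure — shared motion
artifacts, double-exponential photobleaching, second-scale dopamine
transients, spontaneous activity, habituation — and every claim the
package makes about itself is validated against that ground truth.
See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from fiberphot import SimParams, BehaviorSpec, simulate_cohort, preprocess_session
from fiberphot.pipeline import PipelineConfig, cohort_bin_design, analyze_oneway

params = SimParams()                     # 300 s @ 240 Hz reference conditions
behavior = BehaviorSpec(paradigm="social_novel", n_events=10)
sessions = simulate_cohort(10, params, behavior, day="novel", seed=1)

trace, events, truth = sessions[0]
proc = preprocess_session(trace)         # 3 Hz filter -> OLS -> dF/F0
print(f"isosbestic fit: slope={proc.fit.slope:.3f}, "
      f"intercept={proc.fit.intercept:.3f} V")

summary = cohort_bin_design(sessions, PipelineConfig(), label="social_novel")
res = analyze_oneway(summary, alpha=0.05, seed=1)
a = res["anova"]
print(f"one-way RM ANOVA: F({a.df1:.0f},{a.df2:.0f}) = {a.F:.2f}, p = {a.p:.2e}")
for c in res["contrasts"]:
    print(f"  {c.level} vs baseline: dz = {c.estimate:+.2f}, "
          f"p_adj = {c.p_adjusted:.4f}, CI [{c.ci_low:.2f}, {c.ci_high:.2f}]")
```

Output:

```
isosbestic fit: slope=0.995, intercept=0.205 V
one-way RM ANOVA: F(3,27) = 94.76, p = 1.89e-14
  [0,1) vs baseline: dz = +1.30, p_adj = 0.0000, CI [1.08, 1.51]
  [1,2) vs baseline: dz = +0.68, p_adj = 0.0000, CI [0.50, 0.86]
  [2,3) vs baseline: dz = +0.35, p_adj = 0.0079, CI [0.10, 0.60]
```

The fitted slope ≈ 1 recovers the simulator's equal motion coupling of
the two channels. The cohort shows a strong dopamine response in the
first second after sniffing onset (mean z ≈ 1.3 above baseline),
decaying over the next two seconds — every post-onset bin is
Dunnett-significant against the pre-onset baseline. Re-running with
`day="familiar"` (habituated amplitude 0) gives a non-significant
ANOVA, and the same cohorts analyzed at random timestamps hover at
z ≈ 0.

## Command line

```bash
fiberphot simulate --paradigm social --n-animals 10 --seed 1 --out data/
fiberphot preprocess data/animal00_trace.csv --out out/animal00_dff.csv
fiberphot align out/animal00_dff.csv data/animal00_events.csv --out out/animal00
fiberphot stats out/per_animal_bins.csv --out out/stats.json
fiberphot run --demo --seed 1 --out demo_out/   # end-to-end with report
```

`run` writes every intermediate (traces, ΔF/F0 + fit JSON, z-matrices,
bin tables, contrasts, a statistics JSON) plus `run_report.json` with
SHA-256 checksums; identical config and seed reproduce identical
checksums.

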
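# luciclock

Circadian analysis of bioluminescence plate-luminometer recordings.

Population-level luciferase reporters are the workhorse readout for the
*C. elegans* circadian clock: ~50 adult worms per well of a 96-well plate,
luminescence integrated every 30 minutes for a week, typically three days
under dual light/temperature cycles (12:12 LD/CW) followed by four days of
constant darkness and temperature (DD/WW), or seven days of constant
conditions only. `luciclock` turns those raw count traces into the standard
clock phenotypes:

- **Signal conditioning** — background subtraction, removal of the first
  24 h (luciferase accumulation), centered moving-average detrending (24-h
  window) and smoothing (2.5-h window), normalization to the initial maximum.
- **Period estimation** — a Lomb–Scargle periodogram over the circadian band
  (periods 18–35 h, oversampling factor 30), valid for unevenly sampled or
  gappy series. Power is variance-normalized: at each frequency it equals
  the variance fraction explained by the best single sinusoid.
- **Rhythmicity classification** — cosinor regression
  `y(t) = M + A·cos(2π(t−φ)/τ)`, solved exactly by linear least squares at
  fixed τ. A well is **Synchronized** when the 24-h fit on the entrained
  epoch reaches R² ≥ 0.5, and **Circadian** when the free-run fit at the
  Lomb–Scargle period reaches R² ≥ 0.5 with 18 ≤ τ ≤ 35 h.
- **Phase clustering** — per-well peak phases (last entrained cycle, and the
  first peak after release), circular mean and resultant length R, and the
  Rayleigh uniformity test (Zar's approximation), i.e. everything on a
  Rayleigh plot including the p = 0.05 circle.
- **Synthetic data** — a seeded generator producing whole plates with the
  statistical structure of real recordings (accumulation/decay baseline,
  multiplicative oscillation, entrainment with masking transients, partial
  rhythmicity, counting noise) plus a per-well truth table, so every stage
  is testable against known ground truth.

## Worked example

```sh
luciclock simulate --out demo --seed 1
luciclock analyze --input demo/plate.csv --schedule demo/schedule.json --out demo/results
luciclock report --in demo/results
```

or, in Python:

```python
from luciclock import (simulate_plate, default_study_config,
                       analyze_recording, summarize_groups)

rec, truth = simulate_plate(default_study_config(seed=1))
results = analyze_recording(rec)
for s in summarize_groups(results):
    print(f"{s.group}: {s.n_rhythmic}/{s.n_total} rhythmic "
          f"({s.percent_rhythmic:.0f}%), period "
          f"{s.period_mean_h:.2f} ± {s.period_sem_h:.2f} h, "
          f"entrained-phase R = {s.phase_summary_ldcw.resultant_R:.2f}")
```

prints

```
control: 19/30 rhythmic (63%), period 24.62 ± 0.20 h, entrained-phase R = 0.95
mutant: 21/30 rhythmic (70%), period 26.29 ± 0.25 h, entrained-phase R = 0.95
```

Reading: of 30 control wells, 19 expressed a free-running rhythm (cosinor
R² ≥ 0.5 at the Lomb–Scargle period); their mean endogenous period is
24.62 h (SEM over wells). The simulated long-period mutant comes out ~1.7 h
longer, and both groups are tightly phase-clustered under entrainment
(R ≈ 0.95, Rayleigh p ≪ 0.05). The generating values behind this run were
24.4 h and 26.4 h with 60% rhythmic wells.

`analyze` writes `wells.csv` (per-well calls, periods, fits, phases),
`groups.csv` (summaries as above), `periodograms/*.csv`, `phases.csv`,
`processed.csv` (conditioned traces), and a `manifest.json` with all
parameters; `report` renders trace plots and Rayleigh plots from them.

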
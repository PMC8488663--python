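# chronodelay

Analysis toolkit for mouse studies of **dim light in the evening (DLE)** —
a 20-lux, 4-hour light segment appended to a standard 12:12 light/dark cycle
(ZT12–16) — and its effects on circadian behaviour, peripheral clocks, sleep
and short-term memory.  It implements the complete analysis chain such a
study needs, together with a synthetic-data generator whose ground truth
makes every stage testable by parameter recovery:

- **Locomotor phase markers** from passive-infrared (PIR) counts at 10-s
  resolution: daily activity *onset* and *offset* as the crossings of a
  short (3-h) and a long (24-h) centred moving average of the 1-h-smoothed
  series, and the *midpoint* as the time where activity in the preceding 8 h
  equals that in the subsequent 8 h.  Condition phase delays and the
  free-running period τ under constant darkness follow from the per-day
  marker tables.
- **Immobility-defined sleep**: a 10-s bin is asleep iff it lies in a run of
  ≥ 4 consecutive zero-count bins (≥ 40 s immobility); sleep proportion,
  bout durations in 4-h ZT bins, and the sleep history preceding arbitrary
  events.
- **qPCR rhythm phases**: 2^−ΔCt against the geometric mean of two
  housekeeping genes, peak normalisation to 2^−ΔΔCt within each lighting
  condition, single-harmonic (cosinor) acrophase φ with a centre-of-gravity
  cross-check, and pooled phase shifts Δφ = φ_DLE − φ_LD with one-sample
  t tests.
- **In vivo bioluminescence**: background correction of shutter-gated
  photon counts (1 closed minute per 15), stationary-wavelet isolation of
  the 16–32 h band, per-cycle acrophases, period and signal-to-noise ratio;
  continuous-wavelet power spectra of activity for ~24-h vs ~8-h components.
- **Sleep → memory**: recognition ratios (novel / total exploration), the
  sliding-window scan relating prior-sleep proportion (widths 10–180 min)
  to performance via group-level R²(t), and a random-intercept linear
  mixed model with a maximum-likelihood likelihood-ratio test and a
  parametric-bootstrap CI for the sleep effect.

## Worked example

Simulate a 12-mouse cohort (7 days LD baseline, 13 days DLE), extract
markers, and recover the programmed effect sizes:

```python
from chronodelay.pipeline import RunConfig, run_experiment

summary = run_experiment(RunConfig(preset="wt_dle", n_animals=12, seed=1,
                                   out_dir="run"))
print(summary["phase_markers"])
```

prints (values in hours; `*_truth_h` is the generator's programmed value):

```
{'preset': 'wt_dle',
 'onset_delay_h': 3.50,  'onset_delay_sem_h': 0.08,  'onset_delay_truth_h': 3.59,
 'midpoint_delay_h': 2.52, 'midpoint_delay_sem_h': 0.07, 'midpoint_delay_truth_h': 2.57,
 'offset_delay_h': 2.26,  'offset_delay_sem_h': 0.10,  'offset_delay_truth_h': 2.52}
```

i.e. under DLE the activity onset is delayed by ~3.5 h relative to the LD
baseline, the midpoint by ~2.5 h and the offset by ~2.3 h — the pipeline
recovers the programmed delays to within the cohort's re-entrainment
dynamics.  The same run reports the hepatic reporter acrophase delay
(`dbp_acrophase_delay_h: 2.39`, programmed 2.34 h) and the qPCR phase-shift
recovery (`reverba_pooled_shift_h: 1.97`, programmed 2.07 h, one-sample
t(3) = 14.6).

The same stages are exposed on the command line:

```sh
chronodelay simulate --protocol dle --days 13 --ld-days 7 --animals 12 --seed 1 --out sim/
chronodelay phases --activity sim/activity_a00.csv --out markers.csv
chronodelay sleep --activity sim/activity_a00.csv --out sleep.csv
```

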
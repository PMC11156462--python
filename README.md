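# fesfatigue

Muscle-fatigue analysis of surface electromyography (sEMG) under functional
electrical stimulation (FES), for rehabilitation-engineering researchers who
need to choose stimulation parameters that stop short of damaging fatigue.

FES drives a paralysed or weakened muscle with a pulse train defined by a
current amplitude *I* (mA), a frequency *f* (Hz) and a pulse width *w* (µs).
Stimulating too long drives the muscle into excessive fatigue; the safe
duration shrinks as the current grows.  `fesfatigue` implements the complete
analysis chain that turns raw sEMG recordings into that dose–duration law:

1. **Preprocessing** — 4th-order Butterworth band-pass, 20–450 Hz,
   zero-phase (forward–backward); for voluntary trials the final 60 s
   before exhaustion are analysed.
2. **Evoked-signal separation** — a mixed FES recording superimposes the
   stimulator artifact on the muscle's evoked response.  The single-scale
   continuous wavelet transform

   WT(a, τ) = a^(−1/2) ∫ f(t) ψ((t − τ)/a) dt,   a = 128,

   evaluated at every translation τ on the sample grid, yields the evoked
   sEMG as the scale-128 coefficient series.  The default analyzing wavelet
   ψ is a zero-mean Gabor atom whose scale-128 passband sits mid-band
   (≈156 Hz at 1 kHz sampling); Mexican-hat and Morlet are selectable.
3. **Fatigue features** — windowed RMS = √(Σxᵢ²/n) over non-overlapping
   n = 1000-sample windows (1 s at 1 kHz), min–max standardized to [0, 1],
   then fitted: a power law iRMS = a·t^b for voluntary contractions, a
   degree-6 polynomial for FES-evoked responses.
4. **Four-stage "M"-wave decomposition** — the fitted evoked curve splits
   at its critical points into activation, recovery, fatigue, and excessive
   fatigue stages; the time of the global (stage-3) maximum is the
   **maximum stimulation time** t_max, the safe stimulation duration at
   that current.
5. **Dose–duration law** — across currents, t_max follows the inverse
   proportion t_max = k/(I − i0) with an optional rheobase-like offset
   i0 ≥ 0, fitted by bounded nonlinear least squares, plus one-factor
   trend reports for frequency (shortens t_max) and pulse width
   (prolongs it).

Human recordings of this kind are not openly deposited, so the package
ships a first-class synthetic-cohort generator
(`fesfatigue.synthetic`) that plants every quantity the pipeline is meant
to recover — power-law fatigue envelopes, biphasic artifact trains,
four-stage evoked envelopes, and a cohort-level k/(I − i0) law with
per-subject log-normal jitter — making every stage verifiable by parameter
recovery.

## Worked example

```python
import numpy as np
from fesfatigue import (FesTrialSpec, PlantedGroundTruth, analyze_fes_trial,
                        fit_current_time_relationship, generate_cohort,
                        simulate_fes_trial)

# one canonical FES trial: 12 mA, 24 Hz, 200 us, four-stage envelope peaking at 40 s
sim = simulate_fes_trial(FesTrialSpec(seed=7))
res = analyze_fes_trial(sim.mixed)      # separate -> RMS -> normalize -> fit -> segment
print("stage boundaries (s):", np.round(res.segmentation.boundaries, 2))
print("maximum stimulation time (s):", round(res.t_max, 2))

# a 10-subject cohort with planted t = 120/I and 5% subject jitter
truth = PlantedGroundTruth(k=120.0, i0=0.0)
cohort = generate_cohort(10, range(2, 16), truth, seed=11, jitter=0.05)
points = [(t.spec.protocol.current_amplitude, analyze_fes_trial(t.record).t_max)
          for t in cohort.trials]
print(fit_current_time_relationship(points).summary())
```

prints

```
stage boundaries (s): [ 5.77 16.49 42.02]
maximum stimulation time (s): 42.02
Inverse-proportional current -> max stimulation time fit
--------------------------------------------------------
model        t_max = k / (I - i0)
k            126.052 mA*s
i0           2.99429e-27 mA
n points     140
R^2          0.9905
P (F-test)   4.23e-139
```

The three boundaries split the session into the four stages; the planted
peak was at 40 s, recovered at 42.0 s (the 1-s RMS windows and the smooth
polynomial fit bound the resolution).  Across the cohort the planted
k = 120 mA·s is recovered within 5% and the offset i0 collapses to zero —
the stricter the current, the shorter the safe stimulation window.

A command-line interface wires the same chain into reproducible runs:

```sh
fesfatigue simulate --seed 42 --out run/sim      # signals + trial table + ground truth
fesfatigue analyze run/sim/trial_table.csv --out run/ana
fesfatigue report run/ana                        # four summary figures
```

Every run writes a `manifest.json` with the resolved parameters and seed.

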
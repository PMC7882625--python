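# neurodyn

Neurodynamic information (NI) analysis of team EEG.

Teams working through difficult moments — a flight nurse drilling an
intraosseous line, a navigation team fixing a submarine's position — show
stretches where the EEG power of a member, at a particular sensor and
frequency, stays persistently high or persistently low. `neurodyn`
quantifies that persistence as *information*: it turns multi-channel EEG
power into per-second ternary symbol streams, measures the organization of
those streams with sliding-window Shannon entropy, and characterizes the
frequency, magnitude, and duration of the resulting NI peaks at team,
member, sensor, and 1-Hz frequency resolution.

## The measure

Each second, the band power of every (member, channel, 1-Hz bin) stream is
labelled **3** (high), **1** (average), or **−1** (low) relative to the
whole performance, with the empirical tertiles as cuts so that each symbol
labels exactly one third of the epochs (*equal occupancy*). Member symbols
combine into a composite team symbol over the 3^k team state space (9
labels for a dyad, 27 for a triad). For a window of *N* seconds (default
60, stepped 1 s) with symbol proportions *p₁ … p_S*,

    H = −Σᵢ pᵢ log₂ pᵢ          (plug-in Shannon entropy, bits)
    NI = log₂(S) − H            (neurodynamic information, bits)

so NI ranges from 0 (disordered) to log₂ S: 1.59 bits for one member, 3.17
for a dyad, 4.75 for a triad. Because the plug-in estimator is biased at
finite *N* (≈ (S−1)/(2N ln 2) bits of spurious NI), every trace is paired
with a **randomized baseline** — the same computation on temporal
permutations of the stream (default 6) — whose per-index mean is
subtracted.

On top of the corrected traces the package computes:

- **EEG-PV**: the numeric moving average of the −1/1/3 values, which keeps
  the activation/deactivation meaning of power (values above 1 = net
  activation); its Pearson correlation with NI, whole-performance or
  windowed, at scalp / region / region×frequency granularity;
- **shared information**: per-window mutual information between dyad
  members, satisfying `NI_team = NI_X + NI_Y + MI` exactly;
- **NI peaks**: local maxima with prominence ≥ 0.1 bits, their
  half-prominence durations, and the fraction of all analyzed
  stream-epochs falling inside peaks (incidence).

A synthetic-data module generates symbol streams and raw EEG with planted
persistent epochs so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
from neurodyn import (PlantedEpoch, SimConfig, WindowSpec, compose_team,
                      detect_peaks, ni_trace, randomized_baseline,
                      simulate_symbols, subtract_baseline)

# a dyad at sensor C3, 18 Hz; the follower holds "low power" for 120 s
cfg = SimConfig(
    seed=42, members=("giver", "follower"), channels=("C3",), bins=(18.0,),
    duration_s=600,
    epochs=(PlantedEpoch(start=300, duration=120, member="follower",
                         channel="C3", bin_hz=18.0, held_symbol=-1,
                         hold_prob=0.9),))
streams, truth = simulate_symbols(cfg)

window = WindowSpec(length=60, step=1)
follower = streams[("follower", "C3", 18.0)]
raw = ni_trace(follower, window)
base = randomized_baseline(follower, window, n_shuffles=6, seed=42)
ni = subtract_baseline(raw, base)

print(f"mean raw NI:       {np.nanmean(raw.values):.3f} bits")
print(f"mean baseline NI:  {np.nanmean(base.values):.3f} bits")
print(f"mean corrected NI: {np.nanmean(ni.values):.3f} bits")
for p in detect_peaks(ni, min_prominence=0.1):
    print(f"peak at {p.anchor_time:.0f} s: {p.magnitude:.2f} bits, "
          f"duration {p.duration:.0f} s")

team = compose_team([streams[("giver", "C3", 18.0)], follower])
print(f"team alphabet: {team.n_states} symbols, "
      f"max NI {ni_trace(team, window).hmax:.2f} bits")
```

prints

```
mean raw NI:       0.240 bits
mean baseline NI:  0.055 bits
mean corrected NI: 0.205 bits
peak at 366 s: 1.33 bits, duration 86 s
peak at 391 s: 1.21 bits, duration 5 s
team alphabet: 9 symbols, max NI 3.17 bits
```

The baseline (0.055 bits) is pure estimator bias — the same stream,
shuffled, carries it too — and subtracting it leaves the planted episode
as the dominant peak: 1.33 bits (84% of the 1.59-bit single-member
maximum), 86 s at half prominence, bracketing the 120-s planted epoch as
seen through a trailing 60-s window. The 5-s secondary peak is a noise dip
inside the same episode, the kind of fragment a higher prominence
threshold removes.

## Command line

```
neurodyn simulate --config sim.yaml --out run/      # symbols + ground truth
neurodyn psd --input rec.edf --out psd.csv          # per-second Welch PSD
neurodyn symbolize --psd psd.csv --out symbols.csv  # equal-occupancy symbols
neurodyn ni --symbols symbols.csv --out ni.csv      # baseline-corrected NI
neurodyn peaks --ni ni.csv --out peaks/             # peak + incidence tables
neurodyn report --config run.yaml                   # full pipeline bundle
```

All stages exchange plain delimited tables; `report` writes a manifest
(seed, config hash, version) sufficient to reproduce a run exactly.

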
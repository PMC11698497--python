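# chirplab

Synthesis and analysis of electric-organ-discharge (EOD) **chirps** in
wave-type weakly electric fish (*Apteronotus leptorhynchus*, the brown
ghost knifefish). Brown ghosts emit quasi-sinusoidal electric fields
(females ~600–800 Hz, males ~800–1000 Hz); when two fish meet, the
superposition of their EODs is amplitude-modulated at the frequency
difference DF — the *beat* — and brief Gaussian frequency excursions
(*chirps*, classified into types 1–3 and rises by FM and duration)
transiently disrupt it. This package is for neuroethologists and
electrophysiologists who want to simulate such signals, detect and
classify chirps in multichannel voltage recordings, quantify how much
a chirp interferes with the beat, analyze chirp time series, and model
the dipole field geometry of chirping encounters.

The package core:

- **`synth`** — EOD and chirp synthesis. A chirp is a Gaussian bump of
  the instantaneous frequency, `f(t) = f₀ + FM·exp(−(t−t₀)²/2σ²)`,
  with a co-timed fractional amplitude loss; waveform phase is
  `φ(t) = 2π∫f dt`. Also: playback protocols (15 DF levels × 4 chirp
  modes), frequency ramps, Q10 EODf normalization, sex-dependent fish
  sampling, bursty chirp trains, and simulated two-fish recordings
  with planted chirps.
- **`beat`** — the beat-interference statistic: within a 700 ms window
  centered on the chirp, the fraction of beat-cycle time occupied by
  quartile-outlier inter-peak intervals, averaged over four beat
  phases; computed per chirp, on (duration × FM × DF) grids, and
  cumulated per type over recorded events.
- **`detect`** — FFT band-power chirp detection in
  `[EODf−5, 2·EODf−100]` Hz (nfft 4096, 90% overlap), instantaneous-
  frequency measurement of FM and duration, classification by the
  105 Hz / 50 ms cut-offs, sender assignment by channel intensity, and
  k-means/silhouette chirp clustering.
- **`timeseries`** — 8×8 sender/type transition maps with quadrant
  structure, cross-correlation index of binned chirp trains (±2 s lags,
  50 ms bins, ±3 SD band), inter-chirp intervals, peri-stimulus time
  histograms against behavior annotations.
- **`field`** — reduced two-pole electric-field model (cube-law far
  field, calibrated to 1 mV/cm at 5 cm), chirp distance/angle
  geometry from tracking data, and electric-image beat AUC with vs
  without chirps.

`analysis/` holds numbered driver scripts that run each stage and
write tables under `results/`; `chirplab` is also a CLI
(`chirplab demo`, `chirplab detect`, `chirplab interfere`, ...).

## Worked example

Simulate a fish pair, detect the planted chirps, and measure the
interference of the canonical chirp types:

```sh
python analysis/01_simulate_recordings.py 0
python analysis/02_detect_and_classify.py 0
python analysis/03_beat_interference.py 0
```

prints

```
simulated pair: male 927.4 Hz, female 654.0 Hz (DF = +273.4 Hz)
planted 50 chirps ({'rise': 14, 'type1': 14, 'type3': 12, 'type2': 10}); ...
detected 52 events; 50/50 planted chirps recovered (0 missed, 2 unmatched detections)
type agreement: 94%; median |FM error| = 2.5 Hz
interference at DF = +100 Hz: {'type1': 0.0626, 'type2': 0.0386, 'type3': 0.158, 'rise': 0.1689}
ordering type3 > type1 > type2: True
```

Reading this: every planted chirp was recovered within ±100 ms (the
two extra detections are the same chirps crossing both fishes'
detection bands); measured FM is accurate to a few Hz, and 94% of
recovered chirps land in the correct type region of the
(FM, duration) plane. The interference row says a canonical type 3
chirp (300 Hz / 100 ms) disrupts 15.8% of the beat-cycle time in its
700 ms neighborhood at DF = +100 Hz, a type 1 chirp 6.3%, and a small
fast type 2 chirp 3.9% — large, long chirps perturb the beat most,
and the ordering matches what the interference model predicts for
positive frequency differences.

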
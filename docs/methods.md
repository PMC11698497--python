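# Methods

`chirplab` models the electrocommunication signals of the brown ghost
knifefish (*Apteronotus leptorhynchus*) and re-implements the analysis
chain used to study chirping as a possibly self-directed (probing)
behavior: signal synthesis, beat-interference estimation, chirp
detection and classification, chirp time-series analytics, and a
reduced electric-field model. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not show.

## Signal model

A fish's electric organ discharge (EOD) is a pure sinusoid of frequency
`EODf` (harmonics are deliberately excluded). At 27 °C female EODfs lie
in 600–800 Hz, males in 800–1000 Hz; EODf measured at other water
temperatures is normalized with a Q10 of 2 to 25 °C, and fish with a
normalized EODf above 750 Hz are treated as males.

A chirp is a Gaussian excursion of the instantaneous frequency: height
`peak_fm` (Hz) at time `t_peak`, width set by `sigma`. The waveform
phase is the cumulative integral of the frequency trace
(left-endpoint rule, so a chirp-free trace reproduces the plain
sinusoid sample for sample), and the amplitude is multiplied by
`1 − amp_loss · exp(−(t−t_peak)²/2σ²)` — the amplitude loss shares the
FM bump's time course, since only its magnitude is known per type
(type 1: 47%, type 2: 7%, type 3: 45%, rises: 3%).

**Chirp duration** is operationalized as the width of the frequency
excursion above baseline + 10 Hz. This definition has a closed-form
inverse, `sigma = duration / (2·sqrt(2·ln(peak_fm/10)))`, which we use
instead of a numerical solve. For small chirps (`peak_fm ≤ 20 Hz`) the
10 Hz threshold degenerates, so the half-height width
(`threshold = peak_fm/2`) is used; the measurement side applies the
same rule, keeping synthesis→measurement round trips consistent.
Overlapping chirps (±3σ supports intersecting) are rejected rather
than summed.

Canonical type parameters used for forward modelling: type 1 =
200 Hz / 40 ms, type 2 = 100 Hz / 20 ms, type 3 = 300 Hz / 100 ms,
rise = 50 Hz / 100 ms.

## Beat interference

Two superposed EODs produce a beat whose frequency is the absolute
carrier difference |DF|. The interference statistic asks how much a
chirp disrupts beat periodicity in its temporal neighborhood:

1. Synthesize 700 ms of a chirping 862 Hz carrier (chirp peak at
   350 ms) plus an equal-amplitude sinusoid at `862 + DF` Hz. The
   700 ms window is the empirical median inter-chirp interval (0.6987 s)
   of the pair-interaction dataset.
2. Extract the *first-order envelope* — linear interpolation through
   the successive local maxima of |signal| — and find beat peaks as
   envelope maxima with prominence ≥ 5% of the envelope maximum.
   Prominence is referenced to the maximum, not the range: an
   unmodulated carrier's envelope "range" is pure sampling ripple
   (≈3.7% of the amplitude at 862 Hz / 20 kHz), and a range-relative
   threshold would accept every ripple peak. Peak times are refined by
   parabolic interpolation.
3. Beat cycles are the intervals between successive peaks. Outliers
   are intervals outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, with a fence
   half-width floor of one carrier half-period (1/(2·862) s ≈ 0.58 ms):
   cycle intervals are only measured to the envelope's temporal
   resolution, and on noise-free synthetic beats a bare IQR fence
   would flag arbitrarily small perturbations, collapsing the statistic
   onto the chirp's temporal footprint.
4. The index is the cumulative duration of outlier cycles divided by
   the cumulative duration of all cycles, averaged over four phase
   offsets of the partner signal (0°, 90°, 180°, 270°).

`DF = 0` (no beat) and beat periods longer than the window return NaN
with a warning. Grids over (duration 10–400 ms, FM 0–400 Hz,
DF ±300 Hz) default to 10 ms × 10 Hz × 5 Hz steps with
nearest-neighbor lookup (no interpolation) for matching recorded
chirps, and are stored in HDF5 with carrier/window/phase/fence
attributes. The normalized cumulative per-type profile divides by each
type's own maximum (a flag switches to the global maximum).

Known behavior of the statistic: it keys on the long "stalled" beat
cycles that arise when the chirp's instantaneous frequency crosses the
partner's (possible only when `peak_fm ≥ DF > 0` on the appropriate
side), and it saturates on the chirp's temporal footprint. At
DF = +100 Hz the canonical types order type 3 > type 1 > type 2
(0.154 / 0.063 / 0.039), but adjacent-type contrasts are ≈1.6–2.5×,
not order-of-magnitude; per-chirp contrasts at a single DF are much
smaller than contrasts accumulated over each type's empirical
(FM, duration, DF) distribution. At strongly negative DF (beat
accelerating under the chirp) more than 25% of the window's cycles can
be perturbed, which is beyond the quartile fence's breakdown point —
the statistic is then conservative (near zero). With ~81 lag bins, the
±3·SD confidence band of the cross-correlation index (below) is
crossed by chance in roughly a fifth of independent pairs; that
multiple-comparison floor is intrinsic to a per-lag band.

## Chirp detection and classification

Detection integrates spectrogram power (Hann window, nfft = 4096,
90% overlap, 20 kHz) between each fish's fundamental and first
harmonic, `[EODf − 5, 2·EODf − 100]` Hz. Within that band a ±20 Hz
neighborhood of the fish's own carrier is excluded from the sum: the
carrier's constant power otherwise dominates and the transient energy
a chirp spreads above it stays invisible. The band-power series is
baseline-corrected by a 2 s rolling median and peaks above
4 robust SDs (1.4826·MAD) are candidates; the threshold is exposed and
logged, since the original workflow validated detections manually.

Each candidate is measured on the instantaneous frequency of the
band-passed analytic signal around the event, smoothed over one beat
period to suppress the partner-induced ripple (capped at 30 ms so the
smoother never swallows the chirp; measurements at |DF| below ~30 Hz
are accordingly less accurate). FM is the peak excursion over the
segment-edge baseline; duration uses the synthesis-side width rule.
Classification applies the standard cut-offs — 105 Hz FM and 50 ms
duration — with boundaries closed on the type-2 side so the four
half-open regions partition the plane: short/small = type 2,
short/large = type 1, long/large = type 3, long/small = rise. Gradual
frequency rises are outside scope. Senders are assigned by compartment
channel power (ratio ≥ 1.2), with baseline-EODf proximity of the
modulated ridge as tie-breaker; irresolvable events are flagged for
review rather than guessed.

The standard benchmark plants 50 chirps (types drawn uniformly from
the four parameter sets, FM ≥ 30 Hz) in 20 simulated 60 s
male–female recordings — each compartment channel carries its own fish
at unit amplitude, the partner at 0.3, plus 2% Gaussian noise — and
scores a chirp as detected if an event lands within ±100 ms. At
default settings the false-negative rate is 0% and precision ≈ 0.95
(duplicate band crossings account for the unmatched detections).

K-means clustering of standardized (FM, duration) with silhouette
validation over k = 2..8 reproduces the 2–3 cluster optimum on
synthetic populations drawn at the published type proportions
(76% type 2) when the hard literature ranges are smeared with 15%
relative log-normal jitter — the dispersion scale of real chirp
clouds; unjittered boxes are unrealistically separable and favor
k = 4.

## Chirp time series

Transition maps count successive (fish, type) symbol pairs of the
chronologically merged series on an 8×8 matrix whose 4×4 quadrants
group transitions by sender identity (a per-fish 4×4 reduction and
general n-gram counting are provided). Rows-sum-to-one normalization
is the default; global-sum normalization is available. Simultaneous
events are tie-broken by fish identity and logged. The
cross-correlation index bins two event trains at 50 ms, mean-subtracts,
and evaluates the Pearson-normalized correlation over ±2 s lags; the
confidence band is ±3 SDs of the cci values across lags. Inter-chirp
intervals and peri-stimulus time histograms (occupancy of labeled
behavior intervals in a 4 s window around each chirp, using the
standard ethogram vocabulary) complete the module.

Bursty chirp trains (Poisson bout onsets, geometric bout sizes,
log-normal within-bout intervals with the 0.6987 s median) are the
reference train generator; burstiness, not rate asymmetry, is what
concentrates transition mass in the within-fish quadrants for
independent fish.

## Electric field and electric images

The full boundary-element model (Poisson solve over an 835-node fish
mesh with realistic conductivities) is replaced by a **two-pole
line-fish approximation**: opposite point poles at head and tail
(3-D monopole potentials evaluated in the tank-floor plane), with the
pole moment calibrated so the on-axis field 5 cm beyond the head is
1 mV/cm. This preserves far-field cube-law decay, exact superposition,
and the relative electric-image quantities, but **not absolute
transcutaneous voltages** — deltas are comparable within a simulation,
not across models. Body nodes (default 64; the original model used
835) sample a laterally offset head–tail segment placed asymmetrically
toward the tail, mimicking the roughly tenfold head–tail EOD intensity
asymmetry. Geometry is planar, appropriate to the shallow tanks.

An electric image renders, at each node, the summed potential of a
778 Hz sender (optionally chirping at the window center) and a
receiver at a relative frequency offset (the ±20% grid in 5% steps),
integrates the first-order envelope over a 500 ms window (beat AUC),
and reports the summed per-node AUC difference between chirp and
no-chirp conditions, averaged over 8 phase offsets (45° steps). With
no chirp the delta is exactly zero by construction; every canonical
chirp shape produces a nonzero delta, stable to <1% under phase-count
doubling. Beat periods exceeding the window are flagged unreliable.

Decay curves sample the field at 5 cm steps out to 60 cm and fit a
log-log slope; a compact dipole (1 cm pole separation, the playback-
electrode mimic) gives −3.00, while a 15 cm fish measured from 5 cm is
still in its near field (slope ≈ −2.4 over that range). The distance
at which the field falls to 1% of its 5 cm value is ≈ 5·100^(1/3) ≈
23 cm in the ideal-dipole limit, matching the ~30 cm chirping radius
scale. Chirp geometry (distances, angles in 30° polar bins) reads
40 FPS tracking tables with nearest-frame lookup.

## What the synthetic data show — and what they do not

The generator reproduces the study conditions structurally: sex-
dependent EODfs, the four chirp types with their amplitude losses,
bursty trains, playback protocols (15 DF levels ±240..0 Hz × 4 chirp
modes, 50 s stimuli with 5 s fades and 180 s inter-trial intervals,
seeded shuffling), and two-compartment recordings. It does not emulate
harmonic-rich natural EODs, fish motion during recordings, tank
reflections and conductivity drift, or electrode artifacts; detector
scores on the benchmark are therefore upper bounds on real-data
performance, and the manual-validation step of the original workflow
has no synthetic counterpart. Headline counts of the original dataset
(67,522 chirps across seven experiments) enter only as bookkeeping
inputs and population proportions, never as simulation targets.

## Numerical choices and limitations

- Sampling rate 20 kHz throughout; all randomness flows through
  numpy Generators seeded explicitly (per-recording seeds spawned via
  `SeedSequence`).
- Detection assumes reasonably stable baseline EODfs over a recording;
  slow drift is absorbed by the rolling median, fast drift is not.
- Interference values at |DF| ≤ 1/window (no complete beat cycle) are
  undefined (NaN), not zero.
- The quartile fence constant (1.5), beat-peak prominence (5%),
  detector threshold (4 robust SDs), carrier margin (20 Hz) and sender
  power ratio (1.2) are exposed parameters; defaults were chosen on
  synthetic data.
- WAV I/O is float32 via `scipy.io.wavfile`; raw binary recordings
  carry a JSON sidecar (fs, channel map, metadata). Event tables are
  comma-separated UTF-8 with unit-suffixed columns and `#` provenance
  headers.
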
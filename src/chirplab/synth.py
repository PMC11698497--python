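"""Synthetic EOD and chirp generation for wave-type weakly electric fish.

The electric organ discharge (EOD) of *Apteronotus leptorhynchus* is
modelled as a pure sinusoid (harmonics excluded); chirps are transient
Gaussian excursions of the instantaneous frequency, optionally with a
co-timed Gaussian amplitude loss. The module also builds playback
protocols (chirping EOD mimics at fixed frequency differences from a
fish's own EODf), frequency ramps, and simulated two-fish recordings
with planted chirps of known times and types.

Conventions: times in s, frequencies in Hz, chirp durations in ms.
Chirp *duration* is operationalized as the width of the instantaneous-
frequency excursion above baseline + 10 Hz (for small chirps whose peak
FM is below twice that threshold, the half-height width is used instead
so the definition stays well posed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets

#: Excursion threshold (Hz above baseline) defining chirp duration.
DURATION_THRESHOLD_HZ = 10.0

FEMALE_EODF_RANGE = (600.0, 800.0)
MALE_EODF_RANGE = (800.0, 1000.0)
#: Normalized-EODf boundary above which a fish is considered male.
SEX_THRESHOLD_HZ = 750.0


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class EODModel:
    """One fish's carrier signal.

    Parameters
    ----------
    frequency : float
        EOD fundamental frequency (Hz), > 0.
    amplitude : float
        Field strength at the calibration distance (mV/cm), > 0.
    phase0 : float
        Initial phase (rad).
    fs : float
        Sampling rate (Hz); must be at least 4x the carrier frequency.
    """

    frequency: float
    amplitude: float = 1.0
    phase0: float = 0.0
    fs: float = 20_000.0

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.fs < 4 * self.frequency:
            raise ValueError(
                f"fs = {self.fs} Hz violates the Nyquist margin "
                f"(need fs >= 4 x {self.frequency} Hz)")


@dataclass(frozen=True)
class ChirpShape:
    """One Gaussian frequency-modulation event.

    ``peak_fm`` is the peak frequency excursion above the carrier (Hz),
    ``duration_ms`` the excursion width per the module-level duration
    definition, ``amp_loss`` the fractional EOD amplitude reduction at
    the chirp peak, and ``t_peak`` the peak time (s) within the trace.
    """

    type_label: str
    peak_fm: float
    duration_ms: float
    amp_loss: float = 0.0
    t_peak: float = 0.0

    def __post_init__(self):
        if self.peak_fm < 0:
            raise ValueError("peak_fm must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if not 0.0 <= self.amp_loss <= 1.0:
            raise ValueError("amp_loss must lie in [0, 1]")

    @property
    def sigma_s(self) -> float:
        """Gaussian sigma (s) realizing the nominal duration."""
        return gaussian_sigma(self.peak_fm, self.duration_ms)

    def at(self, t_peak: float) -> "ChirpShape":
        """Copy of this shape re-timed to ``t_peak`` (s)."""
        return replace(self, t_peak=t_peak)


def canonical_shape(type_label: str, t_peak: float = 0.0) -> ChirpShape:
    """Canonical parameter set for one of the four chirp types."""
    p = datasets.CANONICAL_SHAPES[type_label]
    return ChirpShape(type_label, p["peak_fm"], p["duration_ms"],
                      p["amp_loss"], t_peak)


@dataclass(frozen=True)
class FishState:
    """Identity, sex, EOD frequency and planar pose of one fish."""

    id: str
    sex: str
    eodf: float
    position: tuple[float, float] = (0.0, 0.0)
    heading: float = 0.0

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        lo, hi = MALE_EODF_RANGE if self.sex == "male" else FEMALE_EODF_RANGE
        if not lo <= self.eodf <= hi:
            raise ValueError(
                f"eodf {self.eodf} Hz inconsistent with sex {self.sex!r} "
                f"(expected {lo}-{hi} Hz)")
        if not 0.0 <= self.heading < 2 * math.pi:
            raise ValueError("heading must lie in [0, 2*pi)")


@dataclass(frozen=True)
class PlaybackTrial:
    index: int
    mode: int
    df: float
    stim_duration: float
    fade: float
    iti: float
    chirp_times: tuple[float, ...]


@dataclass(frozen=True)
class PlaybackProtocol:
    """Seeded, shuffled sequence of playback trials.

    Each trial is one (mode, DF) combination; chirp content is fully
    determined by the mode.
    """

    trials: tuple[PlaybackTrial, ...]
    fish_eodf: float
    seed: int

    def __len__(self):
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        return sum(t.stim_duration + t.iti for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        onset = 0.0
        rows = []
        for t in self.trials:
            rows.append((t.index, t.mode, t.df, onset, t.stim_duration,
                         t.fade, t.iti, len(t.chirp_times)))
            onset += t.stim_duration + t.iti
        return pd.DataFrame(rows, columns=[
            "trial", "mode", "df_hz", "onset_s", "stim_s", "fade_s",
            "iti_s", "n_chirps"])


# ---------------------------------------------------------------------------
# waveform primitives

def gaussian_sigma(peak_fm: float, duration_ms: float,
                   threshold: float = DURATION_THRESHOLD_HZ) -> float:
    """Gaussian sigma (s) whose excursion above ``threshold`` Hz has the
    given width.

    Solves peak_fm * exp(-(w/2)^2 / (2 sigma^2)) = thr for sigma, with
    thr = min(threshold, peak_fm / 2) so small chirps fall back to the
    half-height width.
    """
    if peak_fm <= 0:
        # degenerate chirp: no excursion; sigma only shapes amp_loss
        return duration_ms / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    thr = min(threshold, peak_fm / 2.0)
    return duration_ms / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(peak_fm / thr)))


def make_eod(model: EODModel, duration: float) -> np.ndarray:
    """Sampled pure-sinusoid EOD of the given duration (s)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = round(duration * model.fs)
    t = np.arange(n) / model.fs
    return model.amplitude * np.sin(
        2 * np.pi * model.frequency * t + model.phase0)


def gaussian_chirp_trace(carrier_f: float, shape: ChirpShape,
                         duration: float, fs: float) -> np.ndarray:
    """Instantaneous-frequency series: carrier plus one Gaussian bump."""
    if not 0.0 <= shape.t_peak <= duration:
        raise ValueError("shape.t_peak must lie inside [0, duration]")
    sigma = shape.sigma_s
    if 6 * sigma > duration:
        raise ValueError(
            f"chirp support (~{6 * sigma:.3f} s) wider than the "
            f"{duration} s trace")
    t = np.arange(round(duration * fs)) / fs
    trace = np.full(t.shape, float(carrier_f))
    if shape.peak_fm > 0:
        trace += shape.peak_fm * np.exp(
            -0.5 * ((t - shape.t_peak) / sigma) ** 2)
    return trace


def _check_non_overlapping(chirps: list[ChirpShape]) -> None:
    peaks = [c.t_peak for c in chirps]
    if any(b < a for a, b in zip(peaks, peaks[1:])):
        raise ValueError("chirp peaks must be sorted by t_peak")
    for a, b in zip(chirps, chirps[1:]):
        if b.t_peak - a.t_peak < 3 * a.sigma_s + 3 * b.sigma_s:
            raise ValueError(
                f"overlapping chirps at t = {a.t_peak:.3f} s and "
                f"{b.t_peak:.3f} s: Gaussian supports (+-3 sigma) intersect")


def frequency_trace(model: EODModel, chirps: list[ChirpShape],
                    duration: float) -> np.ndarray:
    """Instantaneous frequency of a chirping EOD (carrier + all bumps)."""
    _check_non_overlapping(chirps)
    t = np.arange(round(duration * model.fs)) / model.fs
    trace = np.full(t.shape, model.frequency)
    for c in chirps:
        if c.peak_fm > 0:
            trace += c.peak_fm * np.exp(-0.5 * ((t - c.t_peak) / c.sigma_s) ** 2)
    return trace


def waveform_from_trace(trace: np.ndarray, fs: float, amplitude: float = 1.0,
                        phase0: float = 0.0) -> np.ndarray:
    """Waveform whose phase is the cumulative integral of ``trace``.

    Left-endpoint integration so sample 0 carries exactly ``phase0``; a
    constant trace reproduces a plain sinusoid sample for sample.
    """
    phase = phase0 + 2 * np.pi * np.r_[0.0, np.cumsum(trace[:-1])] / fs
    return amplitude * np.sin(phase)


def synth_chirping_eod(model: EODModel, chirps: list[ChirpShape],
                       duration: float) -> np.ndarray:
    """EOD waveform carrying the given chirps.

    Phase is the integral of the instantaneous-frequency trace; the
    amplitude is multiplied by (1 - amp_loss * gaussian) co-timed with
    each chirp's FM bump.
    """
    trace = frequency_trace(model, chirps, duration)
    wave = waveform_from_trace(trace, model.fs, model.amplitude, model.phase0)
    if chirps:
        t = np.arange(len(wave)) / model.fs
        env = np.ones_like(wave)
        for c in chirps:
            if c.amp_loss > 0:
                env *= 1.0 - c.amp_loss * np.exp(
                    -0.5 * ((t - c.t_peak) / c.sigma_s) ** 2)
        wave = wave * env
    return wave


def make_frequency_ramp(center_f: float, duration: float, span: float = 300.0,
                        direction: str = "up", fs: float = 20_000.0
                        ) -> np.ndarray:
    """Linear instantaneous-frequency sweep center_f +- span over ``duration`` s."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    n = round(duration * fs)
    ramp = np.linspace(center_f - span, center_f + span, n)
    return ramp if direction == "up" else ramp[::-1].copy()


# ---------------------------------------------------------------------------
# fish sampling and EODf normalization

def q10_normalize(f: float, temp: float, t_ref: float = 25.0,
                  q10: float = 2.0, temp_range=(15.0, 35.0)) -> float:
    """EODf normalized to the reference water temperature with a Q10 law."""
    if not temp_range[0] <= temp <= temp_range[1]:
        raise ValueError(f"temperature {temp} C outside plausible range "
                         f"{temp_range}")
    return f * q10 ** ((t_ref - temp) / 10.0)


def sex_from_eodf(f_norm: float, threshold: float = SEX_THRESHOLD_HZ) -> str:
    """Sex assignment from the temperature-normalized EODf."""
    return "male" if f_norm > threshold else "female"


def sample_fish(sex: str, rng, id: str | None = None,
                position=(0.0, 0.0), heading: float = 0.0) -> FishState:
    """Draw a fish with a sex-consistent EODf (uniform in the sex range)."""
    rng = np.random.default_rng(rng)
    lo, hi = MALE_EODF_RANGE if sex == "male" else FEMALE_EODF_RANGE
    eodf = float(rng.uniform(lo, hi))
    if id is None:
        id = f"{sex[0]}{eodf:.0f}"
    return FishState(id=id, sex=sex, eodf=eodf, position=tuple(position),
                     heading=heading)


# ---------------------------------------------------------------------------
# playback protocols

def _mode_chirp_times(mode: int, stim: float) -> tuple[float, ...]:
    # chirping spans the first 50 s of the stimulus regardless of its
    # length ("0.1 Hz for 50 s" / "2 Hz for 5 s ... every 10 s")
    p = datasets.PLAYBACK_MODES[mode]
    if p["chirps_per_trial"] == 0:
        return ()
    span = min(stim, 50.0)
    if p["train_s"] is None:
        # one chirp every 1/rate seconds, centered in its slot
        step = 1.0 / p["rate_hz"]
        return tuple(np.arange(step / 2, span, step))
    times = []
    t0 = 0.0
    while t0 + p["train_s"] <= span:
        step = 1.0 / p["rate_hz"]
        times.extend(t0 + step / 2 + step * np.arange(
            round(p["train_s"] * p["rate_hz"])))
        t0 += p["train_every_s"]
    return tuple(times)


def mode_shape(mode: int) -> ChirpShape | None:
    """Chirp shape embedded by a playback mode (None for mode 0)."""
    p = datasets.PLAYBACK_MODES[mode]
    if p["peak_fm"] is None:
        return None
    label = {1: "type1-like", 2: "type2", 3: "rise"}[mode]
    return ChirpShape(label, p["peak_fm"], p["duration_ms"])


def build_playback_protocol(fish_eodf: float,
                            df_levels=datasets.DF_LEVELS,
                            modes=(0, 1, 2, 3),
                            stim: float = 50.0, fade: float = 5.0,
                            iti: float = 180.0, seed: int = 0
                            ) -> PlaybackProtocol:
    """One trial per (DF, mode) combination, in seeded shuffled order.

    Mode 0 carries no chirps; modes 1 and 3 embed one large chirp or
    rise every 10 s (5 per 50 s trial); mode 2 embeds 2 Hz trains of
    type 2 chirps for 5 s every 10 s (50 per trial).
    """
    if len(df_levels) == 0:
        raise ValueError("df_levels must be non-empty")
    for m in modes:
        if m not in datasets.PLAYBACK_MODES:
            raise ValueError(f"unknown playback mode {m!r}")
    combos = [(df, m) for df in df_levels for m in modes]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    trials = tuple(
        PlaybackTrial(index=i, mode=combos[j][1], df=float(combos[j][0]),
                      stim_duration=stim, fade=fade, iti=iti,
                      chirp_times=_mode_chirp_times(combos[j][1], stim))
        for i, j in enumerate(order))
    return PlaybackProtocol(trials=trials, fish_eodf=fish_eodf, seed=seed)


def render_playback_trial(protocol: PlaybackProtocol, trial: PlaybackTrial,
                          fs: float = 20_000.0) -> np.ndarray:
    """Playback waveform of one trial: EOD mimic at fish_eodf + DF with
    the mode's chirps embedded and linear fade-in/out ramps."""
    f = protocol.fish_eodf + trial.df
    model = EODModel(frequency=f, fs=fs)
    shape = mode_shape(trial.mode)
    chirps = [shape.at(t) for t in trial.chirp_times] if shape else []
    wave = synth_chirping_eod(model, chirps, trial.stim_duration)
    n_fade = round(trial.fade * fs)
    if n_fade > 0:
        ramp = np.linspace(0.0, 1.0, n_fade)
        wave[:n_fade] *= ramp
        wave[-n_fade:] *= ramp[::-1]
    return wave


def sample_chirp_population(n: int, rng, proportions=None,
                            jitter: float = 0.15):
    """(FM, duration, type) population emulating a recorded chirp dataset.

    Types are drawn at ``proportions`` (default: the published
    pair-interaction counts), parameters uniformly from the literature
    ranges, then smeared with ``jitter`` relative log-normal dispersion:
    real chirp clouds are continuous (within-type variability plus
    measurement error), not hard-edged boxes.

    Returns (fm array, duration array, type-label list).
    """
    rng = np.random.default_rng(rng)
    labels_all = list(datasets.TYPE_PARAM_RANGES)
    if proportions is None:
        row = datasets.CHIRP_DATASET_COUNTS.set_index("experiment").loc[
            "fish pair interactions", labels_all]
        proportions = row.values.astype(float)
    p = np.asarray(proportions, float)
    p = p / p.sum()
    fm = np.empty(n)
    dur = np.empty(n)
    labels = []
    for i in range(n):
        label = labels_all[rng.choice(len(labels_all), p=p)]
        s = sample_chirp_shape(label, rng)
        fm[i] = s.peak_fm * np.exp(jitter * rng.standard_normal())
        dur[i] = s.duration_ms * np.exp(jitter * rng.standard_normal())
        labels.append(label)
    return fm, dur, labels


def sample_chirp_train(duration: float, rng, bout_rate: float = 0.02,
                       chirps_per_bout: float = 8.0,
                       ici_median: float = datasets.MEDIAN_ICI_S,
                       ici_sigma: float = 0.6) -> np.ndarray:
    """Bursty chirp times over ``duration`` s.

    Chirping happens in bouts (Poisson onsets at ``bout_rate`` per s);
    within a bout the chirp count is geometric with the given mean and
    inter-chirp intervals are log-normal with the empirical median
    (~0.7 s). This reproduces the strongly clustered trains of real
    recordings, where most chirps are emitted in repeats.
    """
    rng = np.random.default_rng(rng)
    n_bouts = rng.poisson(bout_rate * duration)
    times = []
    for onset in rng.uniform(0, duration, n_bouts):
        n = 1 + rng.geometric(1.0 / chirps_per_bout)
        icis = np.exp(np.log(ici_median) + ici_sigma * rng.standard_normal(n - 1))
        t = onset + np.r_[0.0, np.cumsum(icis)]
        times.extend(t[t < duration])
    times = np.unique(times)
    return times


# ---------------------------------------------------------------------------
# two-fish recordings with planted chirps

def sample_chirp_shape(type_label: str, rng,
                       min_fm: float | None = None) -> ChirpShape:
    """Draw a chirp from the literature parameter range of its type.

    ``min_fm`` optionally truncates the FM range from below (used by the
    detector benchmark, which plants chirps with FM >= 30 Hz only).
    """
    r = datasets.TYPE_PARAM_RANGES[type_label]
    fm_lo, fm_hi = r["fm"]
    if min_fm is not None:
        fm_lo = max(fm_lo, min_fm)
        fm_hi = max(fm_hi, fm_lo + 1.0)
    fm = float(rng.uniform(fm_lo, fm_hi))
    dur = float(rng.uniform(*r["duration_ms"]))
    amp_loss = datasets.CANONICAL_SHAPES[type_label]["amp_loss"]
    return ChirpShape(type_label, fm, dur, amp_loss)


def simulate_pair_recording(fish1: FishState, fish2: FishState,
                            duration: float = 60.0, n_chirps: int = 50,
                            rng=None,
                            type_labels=("type1", "type2", "type3", "rise"),
                            min_fm: float = 30.0,
                            rel_amp_other: float = 0.3,
                            noise_std: float = 0.02,
                            fs: float = 20_000.0):
    """Two-channel recording of a fish pair with planted chirps.

    Each compartment channel carries its own fish at unit amplitude plus
    the partner attenuated by ``rel_amp_other`` and additive Gaussian
    noise. Chirps are planted at jittered regular times, assigned to a
    random sender, with types drawn uniformly from ``type_labels`` and
    parameters from the literature ranges (FM truncated at ``min_fm``).

    Returns
    -------
    recording : ndarray, shape (2, n_samples)
    events : DataFrame with columns t_s, fish, type, fm_hz, duration_ms
    """
    rng = np.random.default_rng(rng)
    # jittered regular grid keeps same-fish chirps comfortably apart
    slots = np.linspace(1.0, duration - 1.0, n_chirps + 1)[:-1]
    slot = slots[1] - slots[0] if n_chirps > 1 else duration - 2.0
    times = np.sort(slots + rng.uniform(0.1, max(0.11, 0.6 * slot), n_chirps))
    rows = []
    per_fish: dict[int, list[ChirpShape]] = {1: [], 2: []}
    for t in times:
        label = type_labels[rng.integers(len(type_labels))]
        sender = int(rng.integers(1, 3))
        shape = sample_chirp_shape(label, rng, min_fm=min_fm).at(float(t))
        per_fish[sender].append(shape)
        rows.append((float(t), sender, label, shape.peak_fm, shape.duration_ms))
    waves = {}
    for k, fish in ((1, fish1), (2, fish2)):
        model = EODModel(frequency=fish.eodf, fs=fs,
                         phase0=float(rng.uniform(0, 2 * np.pi)))
        waves[k] = synth_chirping_eod(model, per_fish[k], duration)
    n = len(waves[1])
    rec = np.vstack([
        waves[1] + rel_amp_other * waves[2] + noise_std * rng.standard_normal(n),
        waves[2] + rel_amp_other * waves[1] + noise_std * rng.standard_normal(n),
    ])
    events = pd.DataFrame(rows, columns=["t_s", "fish", "type", "fm_hz",
                                         "duration_ms"])
    return rec, events
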
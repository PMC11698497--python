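"""Beat-envelope analysis and the chirp beat-interference statistic.

When two wave-type EODs superpose, the summed signal is amplitude
modulated at the carrier frequency difference (the *beat*). A chirp
transiently shifts one carrier's frequency, compressing and stretching
the beat cycles around it. The interference statistic quantifies this
perturbation: within a fixed window centered on the chirp, the beat
inter-peak intervals are extracted from the first-order envelope, the
intervals lying outside the quartile fences are flagged as outliers, and
the statistic is the cumulative duration of outlier cycles divided by
the cumulative duration of all cycles, averaged over the chirp's phase
relative to the beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import ChirpShape, EODModel, synth_chirping_eod

#: Default carrier frequency (Hz) for the interference computation.
DEFAULT_CARRIER = 862.0
#: Default analysis window (s); the chirp peak sits at its center.
DEFAULT_WINDOW = 0.7
#: Beat-peak prominence threshold as a fraction of the envelope range.
PROMINENCE_FRAC = 0.05
#: Conventional quartile fence constant.
FENCE = 1.5


@dataclass
class BeatTrace:
    """Envelope peak times and beat-cycle intervals of a superposition."""

    peak_times: np.ndarray
    cycle_intervals: np.ndarray
    envelope: np.ndarray | None = None
    envelope_times: np.ndarray | None = None

    def __post_init__(self):
        assert len(self.cycle_intervals) == max(0, len(self.peak_times) - 1)


def superpose(w1: np.ndarray, w2: np.ndarray, rel_amp: float = 1.0
              ) -> np.ndarray:
    """Elementwise sum of two equally sampled waveforms, w1 + rel_amp*w2."""
    if w1.shape != w2.shape:
        raise ValueError("waveforms must have equal length")
    return w1 + rel_amp * w2


def beat_frequency(f1: float, f2: float) -> float:
    """Beat frequency of two sinusoid carriers: |f1 - f2|."""
    return abs(f1 - f2)


def first_order_envelope(x: np.ndarray, fs: float):
    """First-order envelope: linear interpolation through the successive
    local maxima of |x| (one per carrier half-cycle).

    Returns (times, envelope) sampled at the carrier-extremum instants.
    """
    idx, _ = sps.find_peaks(np.abs(x))
    if len(idx) < 2:
        return np.array([]), np.array([])
    return idx / fs, np.abs(x)[idx]


def envelope_peaks(x: np.ndarray, fs: float,
                   prominence_frac: float = PROMINENCE_FRAC) -> BeatTrace:
    """Beat peaks of a two-signal superposition.

    Local maxima of the first-order envelope are accepted if their
    prominence exceeds ``prominence_frac`` of the envelope maximum (the
    carrier-sampling ripple of an unmodulated signal stays below that,
    so a pure sinusoid yields no beat peaks); peak times are refined by
    parabolic interpolation.
    """
    t_env, env = first_order_envelope(x, fs)
    if len(env) < 3:
        return BeatTrace(np.array([]), np.array([]))
    idx, _ = sps.find_peaks(env, prominence=prominence_frac * env.max())
    # parabolic refinement on the (irregularly sampled) envelope
    times = []
    for i in idx:
        if 0 < i < len(env) - 1:
            y0, y1, y2 = env[i - 1], env[i], env[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
            delta = np.clip(delta, -1.0, 1.0)
            # local sample spacing
            dt = 0.5 * (t_env[i + 1] - t_env[i - 1])
            times.append(t_env[i] + delta * dt)
        else:
            times.append(t_env[i])
    times = np.asarray(times)
    return BeatTrace(times, np.diff(times), env, t_env)


def quartile_outliers(intervals, fence: float = FENCE,
                      min_fence: float = 0.0) -> np.ndarray:
    """Boolean mask of intervals outside [Q1 - h, Q3 + h].

    The fence half-width h is ``fence`` times the inter-quartile range,
    but never below ``min_fence``: deviations smaller than the timing
    resolution of the measurement are not counted as outliers (the
    interference computation passes one carrier half-period here; the
    plain statistic uses 0, i.e. the conventional quartile fence).
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.size == 0:
        return np.zeros(0, dtype=bool)
    q1, q3 = np.percentile(iv, [25, 75])
    h = max(fence * (q3 - q1), min_fence)
    return (iv < q1 - h) | (iv > q3 + h)


def interference_index(shape: ChirpShape, df: float,
                       carrier: float = DEFAULT_CARRIER,
                       window: float = DEFAULT_WINDOW,
                       n_phases: int = 4, fs: float = 20_000.0,
                       fence: float = FENCE,
                       carrier_phase0: float = 0.0) -> float:
    """Beat-interference of one chirp at one frequency difference.

    A chirping EOD (carrier + Gaussian chirp peaking at window/2) is
    superposed with an equal-amplitude sinusoid at carrier + df; beat
    cycles are extracted within the window and the fraction of cycle
    time flagged as quartile outliers is returned, averaged over
    ``n_phases`` equally spaced phase offsets of the partner signal.

    Returns NaN (with a warning) when df = 0 or the beat period does not
    fit the window, since no beat cycles exist to perturb.
    """
    if df == 0 or 1.0 / abs(df) >= window:
        warnings.warn(
            f"df = {df} Hz yields no measurable beat within the "
            f"{window} s window; interference undefined", stacklevel=2)
        return float("nan")
    shape = shape.at(window / 2.0)
    model = EODModel(frequency=carrier, fs=fs, phase0=carrier_phase0)
    w1 = synth_chirping_eod(model, [shape], window)
    n = len(w1)
    t = np.arange(n) / fs
    # beat timing is only resolved to one carrier half-period; interval
    # deviations below that are measurement noise, not outliers
    min_fence = 1.0 / (2.0 * carrier)
    vals = []
    for k in range(n_phases):
        phi = 2 * np.pi * k / n_phases
        w2 = np.sin(2 * np.pi * (carrier + df) * t + phi)
        trace = envelope_peaks(superpose(w1, w2), fs)
        iv = trace.cycle_intervals
        if iv.size < 3:
            continue
        mask = quartile_outliers(iv, fence=fence, min_fence=min_fence)
        vals.append(iv[mask].sum() / iv.sum())
    if not vals:
        warnings.warn("too few beat cycles to estimate interference",
                      stacklevel=2)
        return float("nan")
    return float(np.mean(vals))


@dataclass
class InterferenceGrid:
    """Interference values over a (duration, FM, DF) lattice.

    ``values[i, j, k]`` is the phase-averaged interference of a chirp of
    duration ``duration_axis[i]`` (ms) and peak FM ``fm_axis[j]`` (Hz)
    at frequency difference ``df_axis[k]`` (Hz). Undefined combinations
    (no beat within the window) are NaN.
    """

    duration_axis: np.ndarray
    fm_axis: np.ndarray
    df_axis: np.ndarray
    values: np.ndarray
    carrier: float = DEFAULT_CARRIER
    window: float = DEFAULT_WINDOW
    n_phases: int = 4
    fence: float = FENCE

    def __post_init__(self):
        for ax in (self.duration_axis, self.fm_axis, self.df_axis):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing")
        assert self.values.shape == (len(self.duration_axis),
                                     len(self.fm_axis), len(self.df_axis))

    def lookup(self, duration_ms: float, fm: float, df: float) -> float:
        """Nearest-grid-point interference for a recorded chirp."""
        i = int(np.argmin(np.abs(self.duration_axis - duration_ms)))
        j = int(np.argmin(np.abs(self.fm_axis - fm)))
        k = int(np.argmin(np.abs(self.df_axis - df)))
        return float(self.values[i, j, k])

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("duration_axis_ms", data=self.duration_axis)
            f.create_dataset("fm_axis_hz", data=self.fm_axis)
            f.create_dataset("df_axis_hz", data=self.df_axis)
            f.create_dataset("values", data=self.values)
            f.attrs["carrier_hz"] = self.carrier
            f.attrs["window_s"] = self.window
            f.attrs["n_phases"] = self.n_phases
            f.attrs["fence"] = self.fence

    @classmethod
    def load(cls, path) -> "InterferenceGrid":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(duration_axis=f["duration_axis_ms"][:],
                       fm_axis=f["fm_axis_hz"][:],
                       df_axis=f["df_axis_hz"][:],
                       values=f["values"][:],
                       carrier=float(f.attrs["carrier_hz"]),
                       window=float(f.attrs["window_s"]),
                       n_phases=int(f.attrs["n_phases"]),
                       fence=float(f.attrs["fence"]))


def default_axes():
    """Published lattice: duration 10-400 ms x FM 0-400 Hz x DF +-300 Hz
    at 10 ms x 10 Hz x 5 Hz resolution."""
    return (np.arange(10.0, 401.0, 10.0),
            np.arange(0.0, 401.0, 10.0),
            np.arange(-300.0, 301.0, 5.0))


def interference_grid(duration_axis=None, fm_axis=None, df_axis=None,
                      carrier: float = DEFAULT_CARRIER,
                      window: float = DEFAULT_WINDOW, n_phases: int = 4,
                      fs: float = 20_000.0, fence: float = FENCE,
                      amp_loss: float = 0.0) -> InterferenceGrid:
    """Interference values over the full (duration, FM, DF) lattice."""
    d_ax, f_ax, df_ax = default_axes()
    duration_axis = d_ax if duration_axis is None else np.asarray(duration_axis, float)
    fm_axis = f_ax if fm_axis is None else np.asarray(fm_axis, float)
    df_axis = df_ax if df_axis is None else np.asarray(df_axis, float)
    values = np.full((len(duration_axis), len(fm_axis), len(df_axis)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, dur in enumerate(duration_axis):
            for j, fm in enumerate(fm_axis):
                shape = ChirpShape("grid", fm, dur, amp_loss)
                for k, df in enumerate(df_axis):
                    values[i, j, k] = interference_index(
                        shape, df, carrier=carrier, window=window,
                        n_phases=n_phases, fs=fs, fence=fence)
    return InterferenceGrid(duration_axis, fm_axis, df_axis, values,
                            carrier, window, n_phases, fence)


def cumulative_interference_by_type(events, grid: InterferenceGrid,
                                    per_type_max: bool = True):
    """Normalized cumulative interference profile per chirp type over DF.

    Looks up every event's interference at its (duration, FM, DF) grid
    point, sums per (type, DF bin), and divides each type's profile by
    its maximum (or by the global maximum if ``per_type_max`` is False).

    ``events`` is a DataFrame with columns type, fm_hz, duration_ms,
    df_hz. Returns a DataFrame indexed by DF bin with one column per type.
    """
    import pandas as pd

    events = pd.DataFrame(events)
    out = {}
    for label, grp in events.groupby("type"):
        prof = np.zeros(len(grid.df_axis))
        for _, ev in grp.iterrows():
            k = int(np.argmin(np.abs(grid.df_axis - ev.df_hz)))
            v = grid.lookup(ev.duration_ms, ev.fm_hz, ev.df_hz)
            if np.isfinite(v):
                prof[k] += v
        out[label] = prof
    profiles = pd.DataFrame(out, index=pd.Index(grid.df_axis, name="df_hz"))
    if per_type_max:
        denom = profiles.max(axis=0).replace(0.0, np.nan)
        profiles = profiles / denom
    else:
        m = profiles.to_numpy().max()
        if m > 0:
            profiles = profiles / m
    return profiles.fillna(0.0)
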
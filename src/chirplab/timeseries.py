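"""Chirp time-series analytics for interacting fish pairs.

Covers chirp-type transition matrices with sender/receiver quadrants,
cross-correlation of binned event trains, inter-chirp-interval
statistics, and peri-stimulus time histograms of annotated behaviors
around chirps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CHIRP_TYPES = ("type1", "type2", "type3", "rise")


@dataclass(frozen=True)
class EventSeries:
    """Chirp times (s, strictly increasing) and type labels of one fish."""

    times: np.ndarray
    labels: tuple[str, ...]
    fish_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        if len(t) != len(self.labels):
            raise ValueError("times and labels must have equal length")

    def __len__(self):
        return len(self.times)


def _symbols(pair_index: int, labels) -> list[int]:
    return [pair_index * 4 + CHIRP_TYPES.index(lb) for lb in labels]


@dataclass
class TransitionMap:
    """8x8 chirp-type transition counts for one fish pair.

    Rows/columns are ordered (fish1-type1 .. fish1-rise, fish2-type1 ..
    fish2-rise); the four 4x4 quadrants therefore group transitions by
    sender identity: within-fish-1 (1-1), fish-1-to-fish-2 (1-2),
    fish-2-to-fish-1 (2-1) and within-fish-2 (2-2).
    """

    counts: np.ndarray
    pair_id: str = ""

    SYMBOLS = tuple(f"f{i}{t}" for i in (1, 2) for t in CHIRP_TYPES)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        assert self.counts.shape == (8, 8)
        assert (self.counts >= 0).all()

    def normalized(self, mode: str = "row") -> np.ndarray:
        """Transition probabilities: 'row' (conditional on the previous
        symbol) or 'global' (joint frequencies summing to 1)."""
        c = self.counts.astype(float)
        if mode == "row":
            s = c.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(s > 0, c / s, 0.0)
            return out
        if mode == "global":
            tot = c.sum()
            return c / tot if tot > 0 else c
        raise ValueError("mode must be 'row' or 'global'")

    def quadrant(self, i: int, j: int) -> np.ndarray:
        """4x4 block of transitions from fish i to fish j (i, j in 1, 2)."""
        return self.counts[(i - 1) * 4:(i - 1) * 4 + 4,
                           (j - 1) * 4:(j - 1) * 4 + 4]

    def per_fish(self) -> np.ndarray:
        """Reduction to a single 4x4 type-transition matrix, summing the
        four sender/receiver quadrants."""
        return (self.quadrant(1, 1) + self.quadrant(1, 2)
                + self.quadrant(2, 1) + self.quadrant(2, 2))


def merge_series(series1: EventSeries, series2: EventSeries):
    """Chronologically merged symbol sequence of a pair.

    Simultaneous events are tie-broken by fish identity (fish 1 first)
    with a warning.
    """
    t = np.concatenate([series1.times, series2.times])
    sym = np.array(_symbols(0, series1.labels) + _symbols(1, series2.labels))
    if len(np.unique(t)) < len(t):
        warnings.warn("simultaneous events tie-broken by fish id",
                      stacklevel=2)
    order = np.lexsort((np.r_[np.zeros(len(series1)), np.ones(len(series2))],
                        t))
    return t[order], sym[order]


def transition_counts(series1: EventSeries, series2: EventSeries,
                      pair_id: str = "") -> TransitionMap:
    """8x8 counts of successive symbol pairs in the merged series."""
    _, sym = merge_series(series1, series2)
    counts = np.zeros((8, 8), dtype=int)
    for a, b in zip(sym, sym[1:]):
        counts[a, b] += 1
    return TransitionMap(counts, pair_id=pair_id)


def ngram_counts(series1: EventSeries, series2: EventSeries, n: int = 2):
    """Counts of length-n symbol sequences in the merged series, keyed by
    tuples of TransitionMap.SYMBOLS names (n=2 reproduces the pairwise
    transition map)."""
    _, sym = merge_series(series1, series2)
    names = TransitionMap.SYMBOLS
    out: dict[tuple, int] = {}
    for i in range(len(sym) - n + 1):
        key = tuple(names[s] for s in sym[i:i + n])
        out[key] = out.get(key, 0) + 1
    return out


def median_transition_map(maps, normalize: str = "row") -> np.ndarray:
    """Elementwise median of normalized transition maps across pairs."""
    stack = np.stack([m.normalized(normalize) for m in maps])
    return np.median(stack, axis=0)


def chirp_xcorr(series1, series2, bin_s: float = 0.05, max_lag: float = 2.0,
                span: tuple[float, float] | None = None):
    """Cross-correlation index of two binned chirp trains.

    Event times are binned at ``bin_s``, mean-subtracted, and the
    Pearson-normalized cross-correlation is evaluated at every lag in
    [-max_lag, +max_lag]. The confidence band is +-3 standard deviations
    of the cci values across lags.

    Returns (lags_s, cci, band).
    """
    t1 = np.asarray(getattr(series1, "times", series1), float)
    t2 = np.asarray(getattr(series2, "times", series2), float)
    if span is None:
        lo = min(t1.min(), t2.min())
        hi = max(t1.max(), t2.max())
    else:
        lo, hi = span
    if hi - lo < 2 * max_lag:
        raise ValueError("recording span must cover at least 2 x max_lag")
    edges = np.arange(lo, hi + bin_s, bin_s)
    x = np.histogram(t1, edges)[0].astype(float)
    y = np.histogram(t2, edges)[0].astype(float)
    x -= x.mean()
    y -= y.mean()
    denom = len(x) * x.std() * y.std()
    nlag = int(round(max_lag / bin_s))
    lags = np.arange(-nlag, nlag + 1)
    cci = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            cci[i] = np.dot(x[:len(x) - k], y[k:])
        else:
            cci[i] = np.dot(x[-k:], y[:len(y) + k])
    cci = cci / denom if denom > 0 else np.zeros_like(cci)
    band = 3.0 * cci.std()
    return lags * bin_s, cci, band


def ici_stats(times, bins=None):
    """Inter-chirp intervals of one fish: successive differences, median,
    and a histogram. A single event yields an empty interval list."""
    t = np.sort(np.asarray(getattr(times, "times", times), float))
    intervals = np.diff(t)
    hist_bins = bins if bins is not None else np.arange(0.0, 10.5, 0.25)
    hist, edges = np.histogram(intervals, hist_bins)
    return {
        "intervals": intervals,
        "median": float(np.median(intervals)) if intervals.size else float("nan"),
        "mean": float(np.mean(intervals)) if intervals.size else float("nan"),
        "n": int(intervals.size),
        "hist": hist,
        "bin_edges": edges,
    }


def psth(chirp_times, behavior_intervals, window: float = 4.0,
         bin_s: float = 0.1) -> pd.DataFrame:
    """Peri-stimulus time histograms of behaviors around chirps.

    For every behavior label, the fraction of each time bin in
    [-window/2, +window/2] around each chirp covered by an interval of
    that behavior, averaged over chirps.

    ``behavior_intervals`` is a DataFrame with columns start_s, end_s,
    label. Returns a DataFrame indexed by bin center with one column per
    label.
    """
    chirps = np.asarray(chirp_times, float)
    iv = pd.DataFrame(behavior_intervals)
    half = window / 2.0
    edges = np.arange(-half, half + bin_s / 2, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for label, grp in iv.groupby("label"):
        starts = grp.start_s.values
        ends = grp.end_s.values
        acc = np.zeros(len(centers))
        for t0 in chirps:
            lo = t0 + edges[:-1]
            hi = t0 + edges[1:]
            # overlap of every bin with every interval of this label
            ov = np.maximum(
                0.0,
                np.minimum(hi[:, None], ends[None, :])
                - np.maximum(lo[:, None], starts[None, :]))
            acc += np.minimum(ov.sum(axis=1), bin_s) / bin_s
        out[label] = acc / max(len(chirps), 1)
    return pd.DataFrame(out, index=pd.Index(centers, name="lag_s"))
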
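"""Reference tables for the *Apteronotus leptorhynchus* chirp dataset.

These are the published bookkeeping numbers of the chirp study this
pipeline models: per-experiment chirp counts, the canonical chirp-type
parameter sets, the classification cut-offs, and the playback protocol
parameters. They are inputs to the analysis (e.g. synthetic populations
are drawn at these proportions), not values the pipeline computes.
"""

from __future__ import annotations

import pandas as pd

#: Chirp counts per experiment (grand total 67,522 chirps).
#: Columns: experiment, n_fish, total and per-type counts.
CHIRP_DATASET_COUNTS = pd.DataFrame(
    [
        ("fish pair interactions", 130, 30486, 4842, 23169, 2395, 80),
        ("playback chirps", 16, 15720, 2428, 12880, 331, 81),
        ("playback freq ramps", 14, 3966, 779, 3012, 89, 86),
        ("freely swimming pairs", 24, 4672, 252, 4164, 77, 179),
        ("novel environment", 30, 7893, 1059, 5172, 239, 1423),
        ("cluttered environment", 12, 1864, 529, 1225, 80, 32),
        ("cluttered playback", 8, 2921, 405, 2258, 241, 17),
    ],
    columns=["experiment", "n_fish", "total", "type1", "type2", "type3", "rise"],
)

#: Grand total printed with the dataset table.
CHIRP_DATASET_GRAND_TOTAL = 67522

#: Classification cut-offs separating the four chirp types on the
#: (FM, duration) plane: short/long at 50 ms, small/large FM at 105 Hz.
DURATION_CUTOFF_MS = 50.0
FM_CUTOFF_HZ = 105.0

#: Canonical single-chirp parameter sets (peak FM in Hz, duration in ms,
#: amplitude loss as a fraction) used for forward modelling.
CANONICAL_SHAPES = {
    "type1": {"peak_fm": 200.0, "duration_ms": 40.0, "amp_loss": 0.47},
    "type2": {"peak_fm": 100.0, "duration_ms": 20.0, "amp_loss": 0.07},
    "type3": {"peak_fm": 300.0, "duration_ms": 100.0, "amp_loss": 0.45},
    "rise": {"peak_fm": 50.0, "duration_ms": 100.0, "amp_loss": 0.03},
}

#: Literature parameter ranges per chirp type: (fm_lo, fm_hi) Hz and
#: (dur_lo, dur_hi) ms. Point values are degenerate ranges.
TYPE_PARAM_RANGES = {
    "type1": {"fm": (200.0, 400.0), "duration_ms": (25.0, 25.0)},
    "type2": {"fm": (50.0, 100.0), "duration_ms": (15.0, 20.0)},
    "type3": {"fm": (200.0, 300.0), "duration_ms": (75.0, 200.0)},
    "rise": {"fm": (10.0, 20.0), "duration_ms": (50.0, 100.0)},
}

#: Frequency-difference levels (Hz, relative to the fish's own EODf)
#: used in the static playback sessions.
DF_LEVELS = (-240.0, -160.0, -80.0, -40.0, -20.0, -10.0, -5.0, 0.0,
             5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 240.0)

#: Playback chirp content per stimulation mode. ``rate_hz`` is the chirp
#: emission rate inside a train, ``train_s``/``train_every_s`` describe
#: the 2 Hz train motif of mode 2 (5 s of chirps every 10 s); modes 1 and
#: 3 emit one chirp every 10 s for the whole 50 s stimulus.
PLAYBACK_MODES = {
    0: {"label": "no chirps", "duration_ms": None, "peak_fm": None,
        "rate_hz": 0.0, "train_s": None, "train_every_s": None,
        "chirps_per_trial": 0},
    1: {"label": "large chirps", "duration_ms": 120.0, "peak_fm": 500.0,
        "rate_hz": 0.1, "train_s": None, "train_every_s": None,
        "chirps_per_trial": 5},
    2: {"label": "type 2 chirp trains", "duration_ms": 20.0, "peak_fm": 120.0,
        "rate_hz": 2.0, "train_s": 5.0, "train_every_s": 10.0,
        "chirps_per_trial": 50},
    3: {"label": "rises", "duration_ms": 60.0, "peak_fm": 30.0,
        "rate_hz": 0.1, "train_s": None, "train_every_s": None,
        "chirps_per_trial": 5},
}

#: Ethogram vocabulary used for behavior annotations of freely swimming
#: pairs (attacks, chasing, escapes, head butts, jaw quivering, backward
#: swimming, locomotion, rest, tail approaches/waving, wrestling).
ETHOGRAM = ("atk", "ch", "esc", "head", "jaw", "knife", "loc", "rest",
            "tail1", "tail2", "wrestle")

#: Median inter-chirp interval (s) of the pair-interaction dataset; the
#: default analysis window of the beat-interference statistic (0.7 s)
#: derives from it.
MEDIAN_ICI_S = 0.6987
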
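"""Simulate the study conditions: two-fish recordings with planted chirps
and a full playback protocol.

Writes results/simulated_pair_events.csv (planted ground truth of one
60 s male-female pair recording), results/pair_recording.wav, and
results/playback_protocol.csv (the 15 DF x 4 mode session).
"""

import sys
from pathlib import Path

import numpy as np

from chirplab import io as cio
from chirplab import synth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(SEED)
male = synth.sample_fish("male", rng, id="1")
female = synth.sample_fish("female", rng, id="2")
print(f"simulated pair: male {male.eodf:.1f} Hz, female {female.eodf:.1f} Hz "
      f"(DF = {male.eodf - female.eodf:+.1f} Hz)")

rec, events = synth.simulate_pair_recording(male, female, duration=60.0,
                                            n_chirps=50, rng=rng)
cio.write_wav(OUT / "pair_recording.wav", rec, 20_000.0)
cio.write_events(
    events.rename(columns={"fish": "sender"}),
    OUT / "simulated_pair_events.csv", seed=SEED,
    eodf_1=male.eodf, eodf_2=female.eodf)
print(f"planted {len(events)} chirps "
      f"({events['type'].value_counts().to_dict()}); "
      f"wrote {OUT / 'pair_recording.wav'}")

proto = synth.build_playback_protocol(male.eodf, seed=SEED)
cio.write_protocol(proto, OUT / "playback_protocol.csv")
per_mode = {m: len(synth._mode_chirp_times(m, 50.0)) for m in (0, 1, 2, 3)}
print(f"playback protocol: {len(proto)} trials, "
      f"{proto.total_duration_s / 3600:.2f} h; chirps per trial by mode: "
      f"{per_mode}")
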
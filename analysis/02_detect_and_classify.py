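"""Detect, measure and classify the chirps planted by 01_simulate_recordings.

Reads results/pair_recording.wav and the planted ground truth, runs the
band-power detector at default settings, matches detections to planted
chirps (+-100 ms) and reports recovery, measurement error, and k-means
clustering of the detected (FM, duration) cloud.

Writes results/detected_events.csv and results/detection_recovery.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from chirplab import benchmark, detect
from chirplab import io as cio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results"

truth = cio.read_events(OUT / "simulated_pair_events.csv")
header = dict(
    line.strip("# \n").split(" = ")
    for line in open(OUT / "simulated_pair_events.csv")
    if line.startswith("#"))
eodfs = {"1": float(header["eodf_1"]), "2": float(header["eodf_2"])}

bundle = cio.read_recording(OUT / "pair_recording.wav",
                            {"channel_map": {0: "1", 1: "2"}})
events = detect.detect_chirps(bundle.waveform, eodfs,
                              channel_map={"1": 0, "2": 1})
cio.write_events(events, OUT / "detected_events.csv", seed=SEED, **eodfs)

matched, missed, fp = benchmark.match_events(truth.t_s.values,
                                             [e.t for e in events])
print(f"detected {len(events)} events; {matched}/{len(truth)} planted "
      f"chirps recovered ({missed} missed, {fp} unmatched detections)")

det_t = np.array([e.t for e in events])
rows = []
for _, row in truth.iterrows():
    j = int(np.argmin(np.abs(det_t - row.t_s)))
    ok = abs(det_t[j] - row.t_s) <= benchmark.MATCH_TOL_S
    rows.append((row.t_s, row["type"], row.fm_hz, row.duration_ms, ok,
                 events[j].fm if ok else np.nan,
                 events[j].duration_ms if ok else np.nan,
                 events[j].type_label if ok else "",
                 events[j].sender if ok else ""))
rec = pd.DataFrame(rows, columns=[
    "t_s", "type_true", "fm_true_hz", "dur_true_ms", "recovered",
    "fm_est_hz", "dur_est_ms", "type_est", "sender_est"])
rec.to_csv(OUT / "detection_recovery.csv", index=False)
got = rec[rec.recovered]
print("type agreement: "
      f"{(got.type_true == got.type_est).mean():.0%}; median |FM error| = "
      f"{np.nanmedian(np.abs(got.fm_est_hz - got.fm_true_hz)):.1f} Hz")

labels, sil, k_opt = detect.cluster_chirps(
    [e.fm for e in events], [e.duration_ms for e in events], seed=SEED)
print(f"k-means on detected (FM, duration): optimal k = {k_opt} "
      f"(silhouettes: { {k: round(v, 3) for k, v in sil.items()} }); "
      f"note: planted types are equally represented here, so more "
      f"clusters resolve than in naturally proportioned populations")
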
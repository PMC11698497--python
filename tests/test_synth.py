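"""EOD/chirp synthesis: waveform invariants, duration round-trips,
playback protocols, ramps and fish sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chirplab import datasets, synth
from chirplab.detect import measure_chirp_trace

FS = 20_000.0


class TestMakeEOD:
    def test_cycle_count(self):
        model = synth.EODModel(frequency=100.0, fs=FS)
        w = synth.make_eod(model, 1.0)
        up = np.sum((w[:-1] <= 0) & (w[1:] > 0))
        assert up == 100

    def test_unit_amplitude(self):
        w = synth.make_eod(synth.EODModel(frequency=862.0, fs=FS), 1.0)
        assert abs(np.abs(w).max() - 1.0) < 1e-3

    def test_sample_count(self):
        w = synth.make_eod(synth.EODModel(frequency=778.0, fs=FS), 0.5)
        assert len(w) == 10_000

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            synth.make_eod(synth.EODModel(frequency=500.0, fs=FS), -1.0)
        with pytest.raises(ValueError):
            synth.EODModel(frequency=-5.0, fs=FS)
        with pytest.raises(ValueError):
            synth.EODModel(frequency=6000.0, fs=FS)  # Nyquist margin


class TestGaussianChirpTrace:
    def test_degenerate_chirp_is_constant(self):
        shape = synth.ChirpShape("x", 0.0, 40.0, t_peak=0.35)
        tr = synth.gaussian_chirp_trace(862.0, shape, 0.7, FS)
        assert np.allclose(tr, 862.0)

    def test_peak_additivity(self):
        shape = synth.ChirpShape("x", 200.0, 40.0, t_peak=0.35)
        tr = synth.gaussian_chirp_trace(862.0, shape, 0.7, FS)
        assert abs(tr.max() - 1062.0) < 1.0

    @pytest.mark.parametrize("label", ["type1", "type2", "type3", "rise"])
    def test_measure_round_trip(self, label):
        # synthesize-then-measure oracle: FM within 5%, duration within 20%
        shape = synth.canonical_shape(label, t_peak=0.35)
        tr = synth.gaussian_chirp_trace(862.0, shape, 0.7, FS)
        fm, dur = measure_chirp_trace(tr, FS)
        assert abs(fm - shape.peak_fm) / shape.peak_fm < 0.05
        assert abs(dur - shape.duration_ms) / shape.duration_ms < 0.20

    def test_too_wide_bump_rejected(self):
        shape = synth.ChirpShape("x", 200.0, 400.0, t_peak=0.1)
        with pytest.raises(ValueError):
            synth.gaussian_chirp_trace(862.0, shape, 0.2, FS)


class TestChirpingEOD:
    def test_empty_chirp_list_is_plain_eod(self):
        model = synth.EODModel(frequency=862.0, fs=FS)
        assert np.allclose(synth.synth_chirping_eod(model, [], 0.5),
                           synth.make_eod(model, 0.5), atol=1e-9)

    def test_type2_amplitude_loss(self):
        # 7% amplitude loss at the chirp peak
        model = synth.EODModel(frequency=862.0, fs=FS)
        w = synth.synth_chirping_eod(
            model, [synth.canonical_shape("type2", 0.5)], 1.0)
        t = np.arange(len(w)) / FS
        near_peak = np.abs(t - 0.5) < 0.002
        assert abs(np.abs(w[near_peak]).max() - 0.93) < 0.01

    def test_instantaneous_frequency_peak(self):
        # analytic-signal oracle, independent of the synthesis path
        from scipy.signal import hilbert

        model = synth.EODModel(frequency=862.0, fs=FS)
        w = synth.synth_chirping_eod(
            model, [synth.canonical_shape("type1", 0.35).at(0.35)], 0.7)
        inst = np.diff(np.unwrap(np.angle(hilbert(w)))) * FS / (2 * np.pi)
        sm = np.convolve(inst, np.ones(40) / 40, mode="same")
        assert abs(sm[2000:-2000].max() - 1062.0) < 10.0

    def test_energy_preserved_without_amp_loss(self):
        model = synth.EODModel(frequency=862.0, fs=FS)
        chirp = synth.ChirpShape("x", 200.0, 40.0, amp_loss=0.0, t_peak=0.5)
        w = synth.synth_chirping_eod(model, [chirp], 1.0)
        plain = synth.make_eod(model, 1.0)
        assert np.abs(w).max() <= model.amplitude + 1e-9
        rms = lambda x: np.sqrt(np.mean(x ** 2))
        assert abs(rms(w) - rms(plain)) / rms(plain) < 0.01

    def test_overlapping_chirps_rejected(self):
        model = synth.EODModel(frequency=862.0, fs=FS)
        chirps = [synth.canonical_shape("type3", 0.30),
                  synth.canonical_shape("type3", 0.33)]
        with pytest.raises(ValueError, match="overlap"):
            synth.synth_chirping_eod(model, chirps, 1.0)

    @pytest.mark.parametrize("fm", [30.0, 80.0, 200.0, 400.0])
    def test_round_trip_fm_and_timing(self, fm):
        # synthesize -> measure recovers FM within 5% and peak within 10 ms
        from chirplab.detect import measure_chirp

        model = synth.EODModel(frequency=862.0, fs=FS)
        chirp = synth.ChirpShape("x", fm, 40.0, t_peak=0.9)
        w = synth.synth_chirping_eod(model, [chirp], 2.0)
        got_fm, _, t_ref = measure_chirp(w, FS, 0.9, 862.0)
        assert abs(got_fm - fm) / fm < 0.05
        assert abs(t_ref - 0.9) < 0.010


class TestFrequencyRamp:
    def test_midpoint_and_symmetry(self):
        up = synth.make_frequency_ramp(800.0, 60.0, direction="up", fs=FS)
        down = synth.make_frequency_ramp(800.0, 60.0, direction="down", fs=FS)
        assert abs(up[len(up) // 2] - 800.0) < 0.1
        assert np.allclose(down, up[::-1])

    def test_slope(self):
        r = synth.make_frequency_ramp(800.0, 180.0, fs=FS)
        slope = np.polyfit(np.arange(len(r)) / FS, r, 1)[0]
        assert abs(slope - 600.0 / 180.0) < 1e-6


class TestQ10AndSex:
    def test_identity_at_reference(self):
        assert synth.q10_normalize(800.0, 25.0) == pytest.approx(800.0)

    def test_full_decade(self):
        assert synth.q10_normalize(800.0, 35.0) == pytest.approx(400.0)

    def test_sex_threshold(self):
        assert synth.sex_from_eodf(760.0) == "male"
        assert synth.sex_from_eodf(740.0) == "female"

    def test_implausible_temperature_rejected(self):
        with pytest.raises(ValueError):
            synth.q10_normalize(800.0, 40.0)


class TestSampleFish:
    @pytest.mark.parametrize("sex,lo,hi", [("female", 600, 800),
                                           ("male", 800, 1000)])
    def test_eodf_in_sex_range(self, sex, lo, hi):
        for seed in range(20):
            fish = synth.sample_fish(sex, seed)
            assert lo <= fish.eodf <= hi

    def test_seed_determinism(self):
        a = synth.sample_fish("male", 123)
        b = synth.sample_fish("male", 123)
        assert a == b

    def test_sex_consistency_enforced(self):
        with pytest.raises(ValueError):
            synth.FishState(id="x", sex="female", eodf=950.0)


class TestPlaybackProtocol:
    def test_trial_count_and_mode_content(self):
        proto = synth.build_playback_protocol(750.0, seed=1)
        assert len(proto) == 60  # 15 DF levels x 4 modes
        by_mode = {m: [t for t in proto.trials if t.mode == m]
                   for m in (0, 1, 2, 3)}
        assert all(len(v) == 15 for v in by_mode.values())
        assert all(len(t.chirp_times) == 0 for t in by_mode[0])
        assert all(len(t.chirp_times) == 5 for t in by_mode[1])
        assert all(len(t.chirp_times) == 50 for t in by_mode[2])
        assert all(len(t.chirp_times) == 5 for t in by_mode[3])

    @given(st.integers(0, 10_000))
    def test_shuffle_is_permutation(self, seed):
        proto = synth.build_playback_protocol(
            750.0, df_levels=(-20.0, 0.0, 20.0), seed=seed)
        combos = sorted((t.df, t.mode) for t in proto.trials)
        assert combos == sorted((df, m) for df in (-20.0, 0.0, 20.0)
                                for m in (0, 1, 2, 3))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            synth.build_playback_protocol(750.0, modes=(0, 9))

    def test_rendered_trial_has_fades(self):
        proto = synth.build_playback_protocol(750.0, seed=0)
        trial = next(t for t in proto.trials if t.mode == 0)
        w = synth.render_playback_trial(proto, trial, fs=FS)
        assert len(w) == round(trial.stim_duration * FS)
        assert np.abs(w[:100]).max() < 0.05       # fade-in from zero
        assert np.abs(w[-100:]).max() < 0.05


class TestPopulationAndTrains:
    def test_population_proportions(self):
        fm, dur, labels = synth.sample_chirp_population(3000, 11)
        share = labels.count("type2") / len(labels)
        assert 0.70 < share < 0.82  # pair-interaction row: 76% type 2
        assert (fm > 0).all() and (dur > 0).all()

    def test_bursty_train_is_sorted_unique(self):
        t = synth.sample_chirp_train(900.0, 3)
        assert np.all(np.diff(t) > 0)
        assert t.min() >= 0 and t.max() < 900.0
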
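import dataclasses

import numpy as np
import pytest

import finchloop as fl
from finchloop.feedback_controller import ContingencyConfig
from finchloop.pitch_contingency import decide_outcome, initialize_threshold, update_threshold
from finchloop.synthetic_bird import (
    AliasingError,
    expected_daily_pitch_change,
    simulate_perch_day,
    place_choice_probs,
)


def _power_spectrum(buf):
    spec = np.abs(np.fft.rfft(buf.samples, n=buf.n_samples * 8)) ** 2
    freqs = np.fft.rfftfreq(buf.n_samples * 8, d=1.0 / buf.sample_rate)
    return freqs, spec


class TestSyllableSynthesis:
    def test_fundamental_peak_in_zero_padded_dft(self):
        """Largest spectral peak below 1 kHz lies within one native DFT bin of 600 Hz."""
        spec = fl.SyllableSpec(fundamental_hz=600, n_harmonics=8, duration_ms=120)
        buf = fl.synthesize_syllable(spec, 600.0)
        freqs, power = _power_spectrum(buf)
        below = freqs < 1000
        peak_hz = freqs[below][np.argmax(power[below])]
        native_bin = buf.sample_rate / buf.n_samples
        assert abs(peak_hz - 600.0) <= native_bin

    def test_pure_tone_band_power(self):
        spec = fl.SyllableSpec(fundamental_hz=700, n_harmonics=1, duration_ms=120)
        buf = fl.synthesize_syllable(spec, 700.0)
        freqs, power = _power_spectrum(buf)
        in_band = power[(freqs >= 650) & (freqs <= 750)].sum()
        assert in_band / power.sum() >= 0.99

    def test_aliasing_rejected(self):
        spec = fl.SyllableSpec(fundamental_hz=600, n_harmonics=8, duration_ms=120)
        with pytest.raises(AliasingError):
            fl.synthesize_syllable(spec, 3000.0)  # 8 x 3000 > 20 kHz Nyquist

    def test_harmonic_band_limit_validated(self):
        with pytest.raises(ValueError):
            fl.SyllableSpec(fundamental_hz=1500, n_harmonics=8, duration_ms=50)


class TestSongDay:
    def test_determinism_and_count(self, motif):
        vocal = fl.VocalAgentState()
        d1 = fl.generate_song_day(motif, vocal, 10, seed=42)
        d2 = fl.generate_song_day(motif, vocal, 10, seed=42)
        assert len(d1.renditions) == 10
        assert np.array_equal(d1.audio.samples, d2.audio.samples)
        assert d1.renditions.equals(d2.renditions)

    def test_degenerate_variance(self, motif):
        vocal = dataclasses.replace(fl.VocalAgentState(), pitch_sd_hz=1e-12)
        day = fl.generate_song_day(motif, vocal, 5, seed=0)
        assert np.allclose(day.renditions["pitch_hz"], vocal.pitch_mean_hz, atol=1e-6)

    def test_pitch_sd_recovered(self, motif):
        vocal = fl.VocalAgentState(pitch_sd_hz=25.0)
        day = fl.generate_song_day(motif, vocal, 400, seed=7)
        sd = day.renditions["pitch_hz"].std()
        assert abs(sd - 25.0) / 25.0 < 0.15  # chi-square interval at n=400

    def test_inter_bout_silences(self, motif):
        """Bout-final motifs are followed by >= 2 s of silence."""
        day = fl.generate_song_day(motif, fl.VocalAgentState(), 12, seed=1)
        r = day.renditions
        for bout, sub in r.groupby("bout"):
            last_off = sub["target_offset_s"].max()
            later_onsets = day.syllables[day.syllables.onset_s > last_off]["onset_s"]
            if len(later_onsets):
                assert later_onsets.min() - last_off >= 2.0

    def test_ground_truth_matches_audio_energy(self, motif):
        """Logged syllable onsets line up with acoustic energy onsets."""
        day = fl.generate_song_day(motif, fl.VocalAgentState(), 6, seed=3)
        x = day.audio.samples
        sr = day.audio.sample_rate
        for onset in day.syllables["onset_s"]:
            i = int(round(onset * sr))
            before = np.abs(x[max(0, i - 200) : max(0, i - 40)])
            after = np.abs(x[i : i + 200])
            assert before.max() < 1e-9 if before.size else True
            assert after.max() > 1e-3


class TestVocalAgent:
    def test_strobe_identity_with_zero_visual_coupling(self):
        v = fl.VocalAgentState(visual_learning_rate=0.0)
        assert fl.vocal_update(v, 580.0, "hit", "strobe") == v

    def test_zero_auditory_rate_identity(self):
        v = fl.VocalAgentState(auditory_learning_rate=0.0)
        assert fl.vocal_update(v, 580.0, "hit", "noise") == v

    def test_escape_identity(self):
        v = fl.VocalAgentState()
        assert fl.vocal_update(v, 640.0, "escape", "noise") == v

    def test_hit_moves_mean_away_from_penalized_side(self):
        v = fl.VocalAgentState(auditory_learning_rate=0.01)
        up = fl.vocal_update(v, 580.0, "hit", "noise", direction="below")
        down = fl.vocal_update(v, 620.0, "hit", "noise", direction="above")
        assert up.pitch_mean_hz > v.pitch_mean_hz
        assert down.pitch_mean_hz < v.pitch_mean_hz

    def test_closed_loop_daily_means_increase(self):
        """Noise hits below a ratcheting median threshold drive the mean up day by day."""
        vocal = fl.calibrated_vocal_agent(8.8, renditions_per_day=400)
        rng = np.random.default_rng(0)
        baseline = rng.normal(vocal.pitch_mean_hz, vocal.pitch_sd_hz, 400)
        thr = initialize_threshold(baseline)
        day_means = []
        block = []
        for _day in range(4):
            pitches = []
            for _ in range(400):
                p = float(rng.normal(vocal.pitch_mean_hz, vocal.pitch_sd_hz))
                outcome = decide_outcome(p, thr)
                if outcome == "hit":
                    vocal = fl.vocal_update(vocal, p, outcome, "noise")
                pitches.append(p)
                block.append(p)
                if len(block) == 400:
                    thr = update_threshold(thr, block)
                    block = []
            day_means.append(np.mean(pitches))
        assert all(b > a for a, b in zip(day_means, day_means[1:]))

    def test_calibration_reproduces_target_shift(self):
        v = fl.calibrated_vocal_agent(8.8)
        predicted = expected_daily_pitch_change(v.auditory_learning_rate * v.pitch_sd_hz)
        assert abs(predicted - 8.8) < 0.01


class TestPlaceAgent:
    def test_high_temperature_symmetry(self, short_schedule):
        place = dataclasses.replace(fl.PlaceAgentState(), softmax_temperature=1e9)
        events, _, _ = simulate_perch_day(place, short_schedule, None, 0, seed=0)
        counts = np.array([sum(e.perch_id == p for e in events) for p in (1, 2)])
        frac = counts[0] / counts.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / counts.sum())

    def test_choice_probabilities_sum_to_one(self):
        probs = place_choice_probs(fl.PlaceAgentState(perch_values=(1.2, -0.7)))
        assert probs.shape == (3,)
        assert np.isclose(probs.sum(), 1.0)

    def test_null_valences_no_occupancy_trend(self, short_schedule):
        """With zero valences occupancy shows no day-over-day trend (slope ~ 0)."""
        place = dataclasses.replace(
            fl.PlaceAgentState(), noise_valence=0.0, strobe_valence=0.0
        )
        cont = ContingencyConfig(mode="perch_noise", target_perch=1)
        slopes = []
        for seed in range(12):
            p = place
            occ = []
            for day in range(4):
                events, _, p = simulate_perch_day(
                    p, short_schedule, cont, day, seed=fl.make_rng(seed, day),
                    collect_stimuli=False,
                )
                t = {1: 0.0, 2: 0.0}
                for e in events:
                    t[e.perch_id] += e.duration_s
                occ.append(t[1] / (t[1] + t[2]))
            slopes.append(np.polyfit(range(4), occ, 1)[0])
        mean_slope = np.mean(slopes)
        sem = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean_slope) < 3 * sem + 1e-3

    def test_aversive_strobe_reduces_target_occupancy(self, short_schedule):
        """Strobed-perch occupancy declines from first to final day while the
        value accumulator is still converging (slow learner exposes the trend)."""
        cont = ContingencyConfig(mode="perch_strobe", target_perch=1)
        place = dataclasses.replace(
            fl.calibrated_place_agent("strobe", 1, 0.813, 0.737),
            stimulus_learning_rate=2e-4,
            value_decay_per_day=0.0,
        )
        diffs = []
        for seed in range(20):
            p = place
            occ = []
            for day in range(3):
                events, _, p = simulate_perch_day(
                    p, short_schedule, cont, day, seed=fl.make_rng(seed, 100 + day),
                    collect_stimuli=False,
                )
                t = {1: 0.0, 2: 0.0}
                for e in events:
                    t[e.perch_id] += e.duration_s
                occ.append(t[1] / (t[1] + t[2]))
            diffs.append(occ[-1] - occ[0])
        # paired comparison across seeds: final-day target occupancy drops
        assert np.mean(diffs) < 0
        assert sum(d < 0 for d in diffs) >= 15

    def test_valence_sign_flip_reverses_preference(self, short_schedule):
        """Appetitive and aversive wiring are antisymmetric in preference direction."""
        cont = ContingencyConfig(mode="perch_noise", target_perch=1)
        results = {}
        for sign in (+1.0, -1.0):
            place = dataclasses.replace(fl.PlaceAgentState(), noise_valence=sign * 1.5)
            p = place
            t = {1: 0.0, 2: 0.0}
            for day in range(2):
                events, _, p = simulate_perch_day(
                    p, short_schedule, cont, day, seed=fl.make_rng(9, day),
                    collect_stimuli=False,
                )
                for e in events:
                    t[e.perch_id] += e.duration_s
            results[sign] = t[1] / (t[1] + t[2])
        assert results[+1.0] > 0.5 > results[-1.0]

    def test_no_events_during_lights_off(self, short_schedule):
        place = fl.PlaceAgentState()
        cont = ContingencyConfig(mode="perch_noise", target_perch=1)
        for day in range(2):
            events, stims, _ = simulate_perch_day(place, short_schedule, cont, day, seed=day)
            t0, t1 = short_schedule.lights_window(day)
            for e in events:
                assert t0 <= e.t_land_s and e.t_leave_s <= t1
            for s in stims:
                assert t0 <= s.time_s <= t1

    def test_determinism(self, short_schedule):
        place = fl.PlaceAgentState()
        cont = ContingencyConfig(mode="perch_noise", target_perch=1)
        a = simulate_perch_day(place, short_schedule, cont, 0, seed=5)
        b = simulate_perch_day(place, short_schedule, cont, 0, seed=5)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]
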
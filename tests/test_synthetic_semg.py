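"""Generator contracts: determinism, protocol timing, spectral structure."""

import numpy as np
import pytest
from scipy import signal

from armband_bench.synthetic_semg import (
    BASELINE_RMS, DEFAULT_ELECTRODE_RING, ProtocolConfig, VariabilityConfig,
    generate_participant_sessions, make_gesture_bank, make_participant,
    synthesize_gesture_segment,
)


def _bank_min_pairwise_distance(bank):
    """Min pairwise L2 distance between gestures' (low, high) profile pair,
    by numeric integration over the ring."""
    grid = np.linspace(0, 360, 720, endpoint=False)
    dmin = np.inf
    for i in range(1, len(bank)):
        for j in range(i + 1, len(bank)):
            d2 = np.trapezoid(
                (bank[i].spatial_profile(grid) - bank[j].spatial_profile(grid)) ** 2
                + (bank[i].high_profile(grid) - bank[j].high_profile(grid)) ** 2,
                grid)
            dmin = min(dmin, float(np.sqrt(d2)))
    return dmin


class TestGestureBank:
    def test_bank_shape_and_neutral_definition(self):
        bank = make_gesture_bank(seed=0)
        assert len(bank) == 11
        assert [m.gesture_id for m in bank] == list(range(11))
        assert bank[0].mean_amplitude == BASELINE_RMS

    def test_same_seed_same_bank(self):
        a = make_gesture_bank(3)
        b = make_gesture_bank(3)
        for ma, mb in zip(a, b):
            assert ma.band_weights == mb.band_weights
            assert ma.mean_amplitude == mb.mean_amplitude
            grid = np.linspace(0, 360, 100)
            assert np.array_equal(ma.spatial_profile(grid), mb.spatial_profile(grid))

    def test_easy_bank_more_separated_than_hard(self):
        easy = _bank_min_pairwise_distance(make_gesture_bank(0, "easy"))
        hard = _bank_min_pairwise_distance(make_gesture_bank(0, "hard"))
        assert easy > hard

    def test_high_band_differentiated_pairs(self):
        # at default difficulty, several pairs differ mainly in the high band
        bank = make_gesture_bank(0, "default")
        n_high = sum(
            abs(bank[i].band_weights[1] - bank[i + 1].band_weights[1]) > 0.1
            or bank[i + 1].high_tilt is not None
            for i in range(1, 10, 2))
        assert n_high >= 4

    def test_unknown_difficulty_rejected(self):
        with pytest.raises(ValueError, match="difficulty"):
            make_gesture_bank(0, "impossible")


class TestSegmentSynthesis:
    def test_linear_ramp_envelope(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        kw = dict(duration_s=2.0, master_rate=4000)
        a = synthesize_gesture_segment(bank[3], part, rng=np.random.default_rng(5),
                                       ramp_duration_s=0.5, **kw)
        b = synthesize_gesture_segment(bank[3], part, rng=np.random.default_rng(5),
                                       ramp_duration_s=0.0, **kw)
        env = a[0, :2001] / b[0, :2001]
        n_ramp = 2000
        assert env[0] == 0.0
        assert env[n_ramp] == pytest.approx(1.0)
        assert np.allclose(env[:n_ramp], np.arange(n_ramp) / n_ramp)

    def test_neutral_rms_near_baseline(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        part.gain_harmonics = np.zeros((3, 2))
        rms = []
        for k in range(20):
            seg = synthesize_gesture_segment(bank[0], part, 2.0,
                                             rng=np.random.default_rng(k))
            rms.append(np.sqrt(np.mean(seg[:, 4000:] ** 2)))
        assert abs(np.mean(rms) - BASELINE_RMS) / BASELINE_RMS < 0.20

    def test_pure_low_band_power(self, rng):
        from dataclasses import replace
        bank = make_gesture_bank(0)
        model = replace(bank[1], band_weights=(1.0, 0.0), high_tilt=None)
        part = make_participant(0, rng)
        seg = synthesize_gesture_segment(model, part, 6.0, rng=rng)
        f, psd = signal.periodogram(seg[0, 4000:], fs=4000)
        frac_low = np.trapezoid(psd[f <= 100], f[f <= 100]) / np.trapezoid(psd, f)
        assert frac_low >= 0.90

    def test_per_channel_rms_matches_target(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(1, rng)
        angles = np.asarray(DEFAULT_ELECTRODE_RING)
        m = bank[5]
        seg = synthesize_gesture_segment(m, part, 6.0, electrode_angles=angles, rng=rng)
        measured = np.sqrt(np.mean(seg[:, 4000:] ** 2, axis=1))
        look = angles + part.rotation_offset_deg
        g = part.channel_gains(angles)
        w_low, w_high = m.band_weights
        target = m.mean_amplitude * g * np.sqrt(
            w_low * m.spatial_profile(look) ** 2 + w_high * m.high_profile(look) ** 2)
        assert np.all(np.abs(measured - target) / target < 0.10)

    def test_spectral_contract(self, rng):
        # fraction of power above 100 Hz within 10% of w_high on a 5 s segment
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        for gid in (2, 4, 7):
            m = bank[gid]
            seg = synthesize_gesture_segment(m, part, 6.0, rng=rng)
            f, psd = signal.periodogram(seg, fs=4000, axis=-1)
            psd = psd.mean(axis=0)
            inband = (f >= 20) & (f <= 450)
            hi = (f > 100) & (f <= 450)
            frac = np.trapezoid(psd[hi], f[hi]) / np.trapezoid(psd[inband], f[inband])
            assert frac == pytest.approx(m.band_weights[1], rel=0.10)

    def test_rotation_by_electrode_spacing_permutes_rms(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        part.gain_harmonics = np.zeros((3, 2))  # isolate the rotation effect
        ring = np.arange(0.0, 360.0, 45.0)
        seg_a = synthesize_gesture_segment(bank[3], part, 8.0, electrode_angles=ring,
                                           rng=np.random.default_rng(0))
        seg_b = synthesize_gesture_segment(bank[3], part, 8.0, electrode_angles=ring,
                                           rng=np.random.default_rng(1),
                                           rotation_extra_deg=45.0)
        rms_a = np.sqrt(np.mean(seg_a[:, 4000:] ** 2, axis=1))
        rms_b = np.sqrt(np.mean(seg_b[:, 4000:] ** 2, axis=1))
        assert np.allclose(np.roll(rms_a, -1), rms_b, rtol=0.08)

    def test_invalid_inputs_rejected(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        with pytest.raises(ValueError):
            synthesize_gesture_segment(bank[1], part, 0.0, rng=rng)
        with pytest.raises(ValueError):
            synthesize_gesture_segment(bank[1], part, 2.0, master_rate=500, rng=rng)


class TestSessions:
    def test_protocol_durations(self, rng):
        proto = ProtocolConfig()
        assert proto.cycle_duration_s == 55.0
        assert proto.session_duration_s == 220.0
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        train, test = generate_participant_sessions(part, bank, proto)
        assert train.duration_s == pytest.approx(220.0)
        assert test.duration_s == pytest.approx(220.0)
        # samples per cycle at 4000 sps
        assert train.samples.shape[1] // proto.cycles_per_session == 220_000

    def test_sessions_deterministic(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(0, rng)
        t1, _ = generate_participant_sessions(part, bank)
        t2, _ = generate_participant_sessions(part, bank)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(t1.labels, t2.labels)

    def test_labels_cover_session_and_start_neutral(self, rng):
        bank = make_gesture_bank(0)
        part = make_participant(2, rng)
        train, _ = generate_participant_sessions(part, bank)
        total = sum(e - s for _, s, e in train.boundaries)
        assert total == pytest.approx(train.duration_s)
        assert train.labels[0] == 0            # cycles start with neutral
        assert train.boundaries[0][0] == 0
        # each cycle presents all 11 gestures once
        gids = [g for g, _, _ in train.boundaries]
        assert gids == list(range(11)) * 4

    def test_bad_bank_size_rejected(self, rng):
        bank = make_gesture_bank(0)[:-1]
        with pytest.raises(ValueError, match="11"):
            generate_participant_sessions(make_participant(0, rng), bank)
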
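import numpy as np
import pandas as pd
import pytest

import isoload as il
from isoload.neuromech import (
    emg_rep_features,
    fatigue_slopes,
    rep_metrics,
    session_rep_table,
    torque_onset,
)
from isoload.signals import RepetitionSegment, UniformSignal
from isoload.synth import (
    EMGChannels,
    MechChannels,
    NoiseConfig,
    ProtocolSpec,
    generate_session,
)

FS = 148.0


def mech_from_torque(torque, velocity=None, fs=FS):
    torque = np.asarray(torque, dtype=float)
    v = np.zeros_like(torque) if velocity is None else np.asarray(velocity)
    return MechChannels(fs=fs, torque=torque, velocity=v,
                        position=np.cumsum(v) / fs)


class TestTorqueOnset:
    def test_ramp_after_quiet_period(self):
        fs = FS
        t = np.arange(0, 3.0, 1 / fs)
        torque = np.clip((t - 1.0) * 1000.0, 0.0, 300.0)
        seg = RepetitionSegment(1, 1, 0, t.size)
        onset = torque_onset(UniformSignal(fs, torque), seg)
        # the 2.5%-of-peak crossing of a steep ramp sits within a sample
        assert abs(onset / fs - 1.0) <= 1.5 / fs

    def test_flat_torque_missing(self):
        seg = RepetitionSegment(1, 1, 0, 100)
        assert torque_onset(UniformSignal(FS, np.zeros(100)), seg) is None

    def test_fast_generator_ramp_within_10ms(self):
        # high RFD -> short raised-cosine ramp -> threshold crossing close
        # to the mechanical start of the repetition
        p = il.generate_participant(
            1, {"mvc": (150.0, 150.0), "rfd_base": (3000.0, 3000.0)})
        proto = ProtocolSpec("x", 58.0, 1, 4, 0.0, 1.0,
                             baseline_s=5.0, recovery_s=5.0)
        rec = generate_session(p, proto, 2, noise=NoiseConfig.noiseless(),
                               channels=("mech",))
        segs = il.segment_recording(rec)
        for seg, t_start in zip(segs, rec.truth.rep_start_s):
            onset = torque_onset(UniformSignal(FS, rec.mech.torque), seg)
            assert abs(onset / FS - t_start) <= 0.010 + 1.0 / FS

    def test_slow_ramp_crossing_matches_closed_form(self, li_noiseless):
        # 2.5% crossing of a raised cosine sits at (t_ramp/pi)*acos(0.95)
        segs = il.segment_recording(li_noiseless)
        tr = li_noiseless.truth
        torque = UniformSignal(FS, li_noiseless.mech.torque)
        for seg, t_start, ramp in zip(segs[:5], tr.rep_start_s, tr.ramp_s):
            expected = t_start + ramp / np.pi * np.arccos(1 - 0.05)
            onset = torque_onset(torque, seg)
            assert abs(onset / FS - expected) <= 2.0 / FS


class TestRepMetricsClosedForms:
    def test_constant_torque_impulse_and_work(self):
        # T = 100 N.m for 2 s, constant velocity sweeping 1.5 rad
        n = int(2.0 * FS) + 1
        v = np.full(n, 1.5 / 2.0)
        mech = mech_from_torque(np.full(n, 100.0), v)
        seg = RepetitionSegment(1, 1, 0, n)
        m = rep_metrics(mech, seg, mvc=250.0)
        assert m.impulse == pytest.approx(200.0, rel=1e-3)
        assert m.work == pytest.approx(150.0, rel=1e-3)
        assert m.mean_torque == pytest.approx(100.0)
        assert m.norm_torque == pytest.approx(40.0)
        assert m.tut == pytest.approx(2.0, abs=1.5 / FS)

    def test_linear_ramp_rfd(self):
        # 0 -> 300 N.m in 0.3 s: both RFD measures equal the 1000 N.m/s slope
        fs = FS
        t = np.arange(0, 1.6, 1 / fs)
        torque = np.clip((t - 0.2) * 1000.0, 0.0, 300.0)
        mech = mech_from_torque(torque, fs=fs)
        seg = RepetitionSegment(1, 1, 0, t.size)
        m = rep_metrics(mech, seg, mvc=350.0)
        assert m.rfd_0_100 == pytest.approx(1000.0, rel=1e-9)
        # zero-phase pre-filtering rings slightly at the ramp corners, so
        # the smoothed-derivative peak can overshoot the true slope by a
        # few percent
        assert m.rfd_peak == pytest.approx(1000.0, rel=0.05)

    def test_generator_rep_against_truth(self, li_noiseless, participant):
        table = session_rep_table(li_noiseless.mech,
                                  il.segment_recording(li_noiseless),
                                  participant.mvc)
        tr = li_noiseless.truth
        assert np.allclose(table["impulse"], tr.impulse, rtol=0.01)
        assert np.allclose(table["work"], tr.work, rtol=0.01)
        assert np.allclose(table["peak_torque"], tr.peak_torque, rtol=0.01)
        assert np.allclose(table["rfd_peak"], tr.rfd_peak, rtol=0.01)
        assert np.allclose(table["rfd_0_100"], tr.rfd_0_100, rtol=0.02)

    def test_impulse_and_work_additive_over_split(self, li_noiseless):
        segs = il.segment_recording(li_noiseless)
        s = segs[0]
        mid = (s.i0 + s.i1) // 2
        full = rep_metrics(li_noiseless.mech, s, mvc=250.0)
        left = rep_metrics(li_noiseless.mech,
                           RepetitionSegment(1, 1, s.i0, mid + 1), mvc=250.0)
        right = rep_metrics(li_noiseless.mech,
                            RepetitionSegment(2, 1, mid, s.i1), mvc=250.0)
        assert left.impulse + right.impulse == pytest.approx(full.impulse,
                                                             rel=1e-9)
        assert left.work + right.work == pytest.approx(full.work, rel=1e-9)

    def test_peak_dominates_windowed_mean_slope(self, short_session, participant):
        segs = il.segment_recording(short_session)
        for seg in segs:
            inst = rep_metrics(short_session.mech, seg, participant.mvc,
                               rfd_peak_mode="instantaneous")
            wind = rep_metrics(short_session.mech, seg, participant.mvc,
                               rfd_peak_mode="windowed")
            assert inst.rfd_peak >= wind.rfd_peak - 1e-6 * abs(wind.rfd_peak)


class TestFatigueSlopes:
    def test_exact_line(self):
        table = pd.DataFrame({"idx": [1, 2, 3, 4],
                              "rfd_peak": [1200.0, 1150.0, 1100.0, 1050.0]})
        out = fatigue_slopes(table, metrics=("rfd_peak",))
        assert out[0].slope == pytest.approx(-50.0)
        assert out[0].n_reps == 4

    def test_constant_metric_zero_slope(self):
        table = pd.DataFrame({"idx": [1, 2, 3], "rfd_peak": [900.0] * 3})
        out = fatigue_slopes(table, metrics=("rfd_peak",))
        assert out[0].slope == pytest.approx(0.0)

    def test_too_few_reps_skipped(self):
        table = pd.DataFrame({"idx": [1, 2], "rfd_peak": [1.0, 2.0]})
        assert fatigue_slopes(table, metrics=("rfd_peak",)) == []

    def test_generator_slope_recovered_within_3se(self, participant):
        proto = ProtocolSpec("LI", 58.0, 1, 24, 0.0, 1.68)
        rec = generate_session(participant, proto, 77, channels=("mech",))
        table, slopes = il.analyze_mech(rec, participant.mvc)
        rfd = {s.metric: s for s in slopes}["rfd_peak"]
        fit = il.linear_slope(table["idx"].to_numpy(float),
                              table["rfd_peak"].to_numpy(float))
        assert abs(rfd.slope - rec.truth.rfd_slope) < max(3 * fit.stderr,
                                                          0.05 * abs(rec.truth.rfd_slope))


class TestEMGFeatures:
    def test_first_rep_normalized_to_one(self, short_session):
        segs = il.segment_recording(short_session)
        feats = emg_rep_features(short_session.emg, segs, short_session.mech.fs)
        for m in ("vlat", "vmed", "rfem"):
            assert feats[f"rms_{m}"].iloc[0] == pytest.approx(1.0)

    def test_identical_reps_flat_features(self):
        # tile the same burst so every repetition sees identical EMG
        fs_emg, fs_mech = 2048.0, FS
        hop = 256
        rng = np.random.default_rng(0)
        burst = rng.normal(0, 0.3, 4 * hop)
        block = np.concatenate([burst, np.zeros(4 * hop)])
        # leading and trailing silence keep filter edge effects away
        x = np.concatenate([np.zeros(block.size), np.tile(block, 6),
                            np.zeros(block.size)])
        emg = EMGChannels(fs=fs_emg, vlat=x, vmed=x.copy(), rfem=x.copy())
        segs = []
        block_s = block.size / fs_emg
        burst_s = burst.size / fs_emg
        for k in range(1, 7):
            i0 = int(k * block_s * fs_mech)
            i1 = int((k * block_s + burst_s) * fs_mech)
            segs.append(RepetitionSegment(k, 1, i0, i1))
        feats = emg_rep_features(emg, segs, fs_mech)
        assert np.allclose(feats["rms_vlat"], 1.0, atol=1e-9)
        assert np.allclose(np.diff(feats["mdf_mean"]), 0.0, atol=1e-9)

    def test_envelope_time_normalized(self, short_session):
        segs = il.segment_recording(short_session)
        feats = emg_rep_features(short_session.emg, segs,
                                 short_session.mech.fs, envelope_points=101)
        assert all(len(e) == 101 for e in feats["envelope_vlat"])
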
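"""ERP pipeline: filtering, epoching, rejection, control subtraction,
component amplitudes."""

import numpy as np
import pandas as pd
import pytest

from rhythmtag import erp
from rhythmtag import stimuli as st
from rhythmtag import synthetic as syn
from rhythmtag.containers import SampledRecording

FS = 500.0
CHS = ["T7", "T8", "O1", "Oz", "O2", "Cz"]


def _recording(data):
    return SampledRecording(data, FS, CHS[: data.shape[0]])


def test_preprocess_removes_dc_and_attenuates_50hz():
    t = np.arange(int(60 * FS)) / FS
    x = 10.0 + np.sin(2 * np.pi * 50.0 * t)
    rec = _recording(np.tile(x, (2, 1)) * np.array([[1.0], [0.5]]))
    out = erp.preprocess(rec, rereference=False)
    mid = slice(int(10 * FS), int(50 * FS))
    assert abs(out.data[0, mid].mean()) < 0.05  # DC gone
    in_amp = np.abs(np.fft.rfft(rec.data[0, mid]))
    out_amp = np.abs(np.fft.rfft(out.data[0, mid]))
    f = np.fft.rfftfreq(rec.data[0, mid].size, 1 / FS)
    i50 = np.argmin(np.abs(f - 50.0))
    assert out_amp[i50] < in_amp[i50] / 10.0  # > 20 dB down at 50 Hz
    with pytest.raises(ValueError):
        erp.preprocess(rec, lp_hz=300.0)


def test_preprocess_near_idempotent_in_passband():
    rng = np.random.default_rng(0)
    t = np.arange(int(60 * FS)) / FS
    x = np.sin(2 * np.pi * 5.0 * t) + 0.5 * np.sin(2 * np.pi * 12.0 * t)
    rec = _recording(x[None, :])
    once = erp.preprocess(rec, rereference=False)
    twice = erp.preprocess(once, rereference=False)
    mid = slice(int(10 * FS), int(50 * FS))
    assert np.allclose(twice.data[0, mid], once.data[0, mid], atol=0.02)


def test_average_reference_zero_mean():
    rng = np.random.default_rng(1)
    rec = _recording(rng.standard_normal((4, int(60 * FS))))
    out = erp.preprocess(rec)
    assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-10)


def test_epoch_window_and_baseline():
    rng = np.random.default_rng(2)
    rec = _recording(rng.standard_normal((3, int(30 * FS))) + 5.0)
    events = [5000.0, 12000.0, 20000.0]
    eps = erp.epoch_events(rec, events)
    assert eps.data.shape == (3, 3, 350)  # 700 ms at 2 ms steps
    assert eps.times_ms[0] == -200.0
    assert eps.times_ms[-1] == pytest.approx(498.0)
    bmask = (eps.times_ms >= -200) & (eps.times_ms < 0)
    assert np.allclose(eps.data[:, :, bmask].mean(axis=2), 0.0, atol=1e-12)


def test_epoch_drops_out_of_bounds_events():
    rec = _recording(np.zeros((2, int(10 * FS))))
    with pytest.warns(UserWarning, match="dropping"):
        eps = erp.epoch_events(rec, [50.0, 5000.0, 9950.0])
    assert len(eps) == 1


def _epochs(data, labels=None):
    n, c, t = data.shape
    times = np.arange(-100, -100 + t) * 2.0
    return erp.EpochSet(data, times, CHS[:c], labels if labels is not None else pd.DataFrame(index=range(n)))


def test_reject_amplitude_threshold():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((20, 3, 350))
    data[4, 1, 100] = 150.0
    kept, report = erp.reject_artifacts(_epochs(data), jp_sd=1e9)
    assert report["n_rejected_amplitude"] == 1
    assert len(kept) == 19


def test_reject_identical_epochs_keeps_all():
    data = np.tile(np.sin(np.linspace(0, 3, 350)), (30, 3, 1))
    kept, report = erp.reject_artifacts(_epochs(data))
    assert len(kept) == 30
    assert report["n_rejected_jointprob"] == 0


def test_reject_high_variance_epoch_by_joint_probability():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((101, 3, 350))
    data[57] *= 10.0  # wild epoch, still under the ±100 µV threshold
    kept, report = erp.reject_artifacts(_epochs(data))
    assert report["rejected_mask"][57]
    assert report["n_rejected_amplitude"] == 0


def test_reject_monotone_in_threshold():
    rng = np.random.default_rng(5)
    data = 14.0 * rng.standard_normal((60, 3, 350))
    masks = []
    for thr in (200.0, 100.0, 50.0):
        _, report = erp.reject_artifacts(_epochs(data), amp_uv=thr, jp_sd=1e9)
        masks.append(report["rejected_mask"])
    assert set(np.flatnonzero(masks[0])) <= set(np.flatnonzero(masks[1]))
    assert set(np.flatnonzero(masks[1])) <= set(np.flatnonzero(masks[2]))


def test_reject_all_epochs_is_an_error():
    data = np.full((5, 2, 350), 200.0)
    with pytest.raises(ValueError, match="rejected"):
        erp.reject_artifacts(_epochs(data))


def test_mean_amplitude_constant_and_ramp():
    times = np.arange(0, 500, 2.0)
    const = np.full((3, len(times)), 2.5)
    assert erp.mean_amplitude(const, times, CHS[:3], (110, 130), ("T7", "T8")) == pytest.approx(2.5)
    ramp = np.tile(times / 500.0, (3, 1))
    got = erp.mean_amplitude(ramp, times, CHS[:3], (250, 400), ("O1", "Oz", "O2"))
    assert got == pytest.approx(0.65, abs=0.003)
    with pytest.raises(ValueError):
        erp.mean_amplitude(const, times, CHS[:3], (110, 130), ("F3",))


def test_control_subtraction_linearity_and_null():
    """Identical target and control statistics give a near-zero difference,
    and adding a constant to everything cancels exactly."""
    seq = st.build_sequence("high", "high", measure_id=1, seed=0, n_measures=40)
    sched = st.schedule_targets("1a", "sound", seed=0, n_slots=40, targets_per_class=4)
    tl = st.build_timeline(seq, sched)
    rec = syn.gen_eeg(tl, syn.EEGParams(channels=tuple(CHS), visual_n1_amp=0.0,
                                        visual_p3_amp=0.0, visual_n1_regularity_effect=0.0,
                                        visual_p3_regularity_effect=0.0,
                                        note_p1_amp=0.0, noise_scale=0.0, white_scale=0.0),
                      seed=1)
    targets = tl[tl.event_type == "target"]
    eps = erp.epoch_events(rec, targets.time_ms.to_numpy(), targets.reset_index())
    diff, _ = erp.control_subtract(eps, rec, tl, seed=2)
    assert np.allclose(diff, 0.0, atol=1e-12)

    shifted = rec.copy()
    shifted.data = rec.data + 7.3
    shifted.annotations = tl
    eps2 = erp.epoch_events(shifted, targets.time_ms.to_numpy(), targets.reset_index())
    diff2, _ = erp.control_subtract(eps2, shifted, tl, seed=2)
    assert np.allclose(diff2, diff, atol=1e-10)


def test_control_subtraction_recovers_injected_visual_kernel():
    seq = st.build_sequence("high", "high", measure_id=2, seed=1, n_measures=60)
    sched = st.schedule_targets("1a", "sound", seed=1, n_slots=60, targets_per_class=10)
    tl = st.build_timeline(seq, sched)
    params = syn.EEGParams(channels=tuple(CHS), noise_scale=0.3, white_scale=0.1,
                           visual_n1_amp=-3.0, visual_n1_regularity_effect=0.0)
    rec = syn.gen_eeg(tl, params, seed=3)
    targets = tl[tl.event_type == "target"]
    eps = erp.epoch_events(rec, targets.time_ms.to_numpy(), targets.reset_index())
    diff, _ = erp.control_subtract(eps, rec, tl, seed=4)
    n1 = erp.mean_amplitude(diff, eps.times_ms, eps.ch_names, (150, 170), ("O1", "Oz", "O2"))
    assert n1 < -1.0  # injected negativity recovered in the N1 window


def test_n1_regularity_effect_sign_recovered():
    """High background regularity yields the smaller (more positive) N1."""
    amps = {"high": [], "low": []}
    for p in range(8):
        for reg in ("high", "low"):
            rec = syn.gen_condition_recording(
                "high", reg, seed=100 + p, n_measures=45,
                eeg_params=syn.EEGParams(channels=tuple(CHS), noise_scale=0.5),
            )
            tl = rec.annotations
            targets = tl[tl.event_type == "target"]
            eps = erp.epoch_events(rec, targets.time_ms.to_numpy(), targets.reset_index())
            diff, _ = erp.control_subtract(eps, rec, tl, seed=p)
            amps[reg].append(
                erp.mean_amplitude(diff, eps.times_ms, eps.ch_names, (150, 170),
                                   ("O1", "Oz", "O2"))
            )
    assert np.mean(amps["high"]) > np.mean(amps["low"])


def test_erp_pipeline_table(short_recording):
    table = erp.erp_pipeline(short_recording, seed=0)
    assert set(table.component) == {"P1", "N1", "P3"}
    p1 = table.set_index("component").amplitude_uv
    assert p1["P1"] > 0  # auditory positivity at measure onset
    assert p1["P3"] > 0
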
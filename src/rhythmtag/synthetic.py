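"""Synthetic tapping, EEG and behavioral data with the statistical
structure the analysis pipeline assumes.

The generators emulate the study conditions, not biophysics: tapping times
are von Mises-distributed around the 750 ms beat (more concentrated when
metricality is high; default concentrations calibrated so the expected mean
resultant length is ≈0.41 high and ≈0.12 low); EEG is a sum of note-evoked
kernels on temporal channels, visual target-evoked kernels on occipital
channels (N1 depending on background regularity), optional steady-state
components at the measure (1/3 Hz) and beat (4/3 Hz) frequencies, 1/f^α
plus white Gaussian noise, and optional injected artifact segments that
exercise both rejection rules; reaction times carry additive regularity and
metricality main effects. Identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seed import rng_for
from .containers import SampledRecording
from .stimuli import (
    BEAT_PERIOD_MS,
    MEASURE_DURATION_MS,
    TargetSchedule,
    build_sequence,
    build_timeline,
    schedule_targets,
)

DEFAULT_EEG_CHANNELS = (
    "Fz", "Cz", "Pz", "C3", "C4",
    "T7", "T8", "TP7", "TP8",
    "O1", "Oz", "O2",
)
TEMPORAL_CHANNELS = ("T7", "T8", "TP7", "TP8")
OCCIPITAL_CHANNELS = ("O1", "Oz", "O2")


# -- tapping -----------------------------------------------------------------

@dataclass
class TappingParams:
    """von Mises tapping model on the 750 ms beat circle.

    κ defaults solve I₁(κ)/I₀(κ) = R̄ for the calibration goals
    R̄ ≈ 0.41 (high metricality) and ≈ 0.12 (low).
    """

    kappa_high: float = 0.9
    kappa_low: float = 0.24
    mu_deg: float = 0.0
    loops_per_block: int = 40
    beats_per_measure: int = 4

    def __post_init__(self):
        if self.kappa_low < 0 or self.kappa_high < self.kappa_low:
            raise ValueError("need kappa_high > kappa_low >= 0")


@dataclass
class TapDataset:
    taps: pd.DataFrame  # participant, metricality, measure_id, tap_time_ms
    params: TappingParams


def gen_tapping(
    params: TappingParams | None = None,
    seed: int = 0,
    n_participants: int = 16,
    measure_ids=range(1, 6),
) -> TapDataset:
    """Simulated tap times for the looped-measure tapping task.

    Each participant taps once per beat in each looped block (one block per
    measure and metricality level); tap phases are von Mises around the
    beat and times are quantized to 1 ms.
    """
    params = params or TappingParams()
    n_beats = params.beats_per_measure * params.loops_per_block
    frames = []
    for p in range(n_participants):
        for metricality, kappa in (("high", params.kappa_high), ("low", params.kappa_low)):
            for mid in measure_ids:
                rng = rng_for(seed, "tapping", p, metricality, mid)
                theta = rng.vonmises(np.deg2rad(params.mu_deg), kappa, size=n_beats)
                beats = (np.arange(1, n_beats + 1)) * BEAT_PERIOD_MS
                t = beats + theta / (2 * np.pi) * BEAT_PERIOD_MS
                t = np.sort(np.round(t))  # 1 ms resolution, non-decreasing
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": p,
                            "metricality": metricality,
                            "measure_id": mid,
                            "tap_time_ms": t,
                        }
                    )
                )
    return TapDataset(pd.concat(frames, ignore_index=True), params)


# -- EEG ---------------------------------------------------------------------

@dataclass
class EEGParams:
    """Amplitudes in µV; kernel latencies in ms."""

    rate_hz: float = 500.0
    channels: tuple = DEFAULT_EEG_CHANNELS
    # auditory response to each note, temporal channels
    note_p1_amp: float = 1.5
    note_p1_latency_ms: float = 118.0
    # visual target response, occipital channels
    visual_n1_amp: float = -2.0
    visual_n1_regularity_effect: float = 0.8   # added when regularity is high
    visual_n1_latency_ms: float = 160.0
    visual_p3_amp: float = 2.5
    visual_p3_regularity_effect: float = 0.5
    visual_p3_latency_ms: float = 320.0
    # extra steady-state components on both ROIs (cortical amplification)
    ss_meter_amp: float = 0.0
    ss_beat_amp: float = 0.0
    # background noise
    noise_alpha: float = 1.0
    noise_scale: float = 1.0
    white_scale: float = 0.2
    # artifact injection
    artifact_rate_per_min: float = 0.0


def _gamma_bump(rate_hz: float, latency_ms: float, shape: float = 8.0,
                length_ms: float | None = None) -> np.ndarray:
    """Unit-peak gamma-shaped kernel peaking at ``latency_ms``."""
    theta = latency_ms / (shape - 1.0)
    length_ms = length_ms or latency_ms * 3.0
    t = np.arange(int(round(length_ms / 1000.0 * rate_hz))) * 1000.0 / rate_hz
    k = t ** (shape - 1.0) * np.exp(-t / theta)
    return k / k.max()


def _one_over_f(rng, n: int, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^α Gaussian noise via spectral shaping."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n)
    f[0] = np.inf  # no DC
    spec *= f ** (-alpha / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_eeg(
    timeline: pd.DataFrame,
    params: EEGParams | None = None,
    seed: int = 0,
    duration_ms: float | None = None,
) -> SampledRecording:
    """Synthetic multichannel EEG aligned to a stimulus event timeline.

    An empty timeline yields a noise-only recording.
    """
    params = params or EEGParams()
    fs = params.rate_hz
    if duration_ms is None:
        if len(timeline):
            duration_ms = (float(timeline.measure_index.max()) + 1) * MEASURE_DURATION_MS
        else:
            duration_ms = 30_000.0
    n = int(round(duration_ms / 1000.0 * fs))
    ch_names = list(params.channels)
    data = np.zeros((len(ch_names), n))

    # background noise
    for i in range(len(ch_names)):
        rng = rng_for(seed, "eeg-noise", i)
        if params.noise_scale > 0:
            data[i] += params.noise_scale * _one_over_f(rng, n, params.noise_alpha)
        if params.white_scale > 0:
            data[i] += params.white_scale * rng.standard_normal(n)

    temporal = [i for i, c in enumerate(ch_names) if c in TEMPORAL_CHANNELS]
    occipital = [i for i, c in enumerate(ch_names) if c in OCCIPITAL_CHANNELS]
    roi = sorted(set(temporal) | set(occipital))

    def add_kernel(idx_channels, t_ms, kernel, amp):
        i0 = int(round(t_ms / 1000.0 * fs))
        if i0 >= n or i0 < 0:
            return
        seg = kernel[: n - i0]
        for ch in idx_channels:
            data[ch, i0 : i0 + len(seg)] += amp * seg

    if len(timeline):
        note_kernel = _gamma_bump(fs, params.note_p1_latency_ms)
        for t in timeline.loc[timeline.event_type == "note", "time_ms"]:
            add_kernel(temporal, t, note_kernel, params.note_p1_amp)

        n1_kernel = _gamma_bump(fs, params.visual_n1_latency_ms, shape=20.0,
                                length_ms=260.0)
        p3_kernel = _gamma_bump(fs, params.visual_p3_latency_ms, shape=12.0,
                                length_ms=700.0)
        targets = timeline[timeline.event_type == "target"]
        for row in targets.itertuples(index=False):
            reg_high = isinstance(row.condition, str) and row.condition.endswith("highR")
            n1 = params.visual_n1_amp + (params.visual_n1_regularity_effect if reg_high else 0.0)
            p3 = params.visual_p3_amp + (params.visual_p3_regularity_effect if reg_high else 0.0)
            add_kernel(occipital, row.time_ms, n1_kernel, n1)
            add_kernel(occipital, row.time_ms, p3_kernel, p3)

    if params.ss_meter_amp or params.ss_beat_amp:
        t = np.arange(n) / fs
        ss = params.ss_meter_amp * np.cos(2 * np.pi * t / 3.0) + (
            params.ss_beat_amp * np.cos(2 * np.pi * t * 4.0 / 3.0)
        )
        for ch in roi:
            data[ch] += ss

    if params.artifact_rate_per_min > 0:
        rng = rng_for(seed, "eeg-artifacts")
        n_art = rng.poisson(params.artifact_rate_per_min * duration_ms / 60_000.0)
        for k in range(n_art):
            i0 = int(rng.integers(0, max(1, n - int(fs))))
            if k % 2 == 0:  # high-amplitude square pulse on one channel
                ch = int(rng.integers(len(ch_names)))
                width = int(0.25 * fs)
                data[ch, i0 : i0 + width] += rng.choice([-1.0, 1.0]) * rng.uniform(120.0, 200.0)
            else:  # high-variance segment on all channels
                width = int(fs)
                data[:, i0 : i0 + width] += 8.0 * rng.standard_normal(
                    (len(ch_names), min(width, n - i0))
                )

    return SampledRecording(
        data, fs, ch_names, annotations=timeline, meta={"params": params, "seed": seed}
    )


# -- behavior ----------------------------------------------------------------

@dataclass
class BehaviorParams:
    """Additive RT model: RT = base − β_reg·[high reg] − β_met·[high met] + ε."""

    base_rt_ms: float = 380.0
    beta_regularity_ms: float = 20.0
    beta_metricality_ms: float = 10.0
    sigma_trial_ms: float = 90.0
    sigma_subject_ms: float = 30.0
    rt_floor_ms: float = 120.0
    hit_rate: float = 0.95
    fa_rate: float = 0.02

    def __post_init__(self):
        if not (0 <= self.hit_rate <= 1 and 0 <= self.fa_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


def gen_behavior(
    schedule: TargetSchedule,
    params: BehaviorParams | None = None,
    seed: int = 0,
    metricality: str = "high",
    regularity: str = "high",
    participant: int = 0,
) -> pd.DataFrame:
    """Trial table for one participant × phase × background condition.

    Background effects apply only during sound phases. Rows cover every
    measure slot (targets and nontargets); ``response`` marks hits on
    targets and false alarms on nontargets; RT is recorded for responses.
    """
    params = params or BehaviorParams()
    rng = rng_for(seed, "behavior", participant, schedule.phase, metricality, regularity)
    subject_off = rng_for(seed, "behavior-subject", participant).normal(
        0.0, params.sigma_subject_ms
    )
    sound = schedule.phase == "sound"
    mean_rt = params.base_rt_ms + subject_off
    if sound:
        mean_rt -= params.beta_regularity_ms * (regularity == "high")
        mean_rt -= params.beta_metricality_ms * (metricality == "high")

    by_measure = dict(
        zip(schedule.entries.measure_index, zip(schedule.entries.position_class,
                                                schedule.entries.offset_ms))
    )
    slots = np.arange(schedule.n_slots)
    is_target = np.isin(slots, schedule.entries.measure_index)
    p_resp = np.where(is_target, params.hit_rate, params.fa_rate)
    response = rng.random(schedule.n_slots) < p_resp
    rt = np.maximum(
        params.rt_floor_ms, mean_rt + rng.normal(0.0, params.sigma_trial_ms, schedule.n_slots)
    )
    rt[~response] = np.nan

    return pd.DataFrame(
        {
            "participant": participant,
            "phase": schedule.phase,
            "metricality": metricality if sound else "none",
            "regularity": regularity if sound else "none",
            "measure_index": slots,
            "position_class": [by_measure.get(m, ("none", np.nan))[0] for m in slots],
            "offset_ms": [by_measure.get(m, ("none", np.nan))[1] for m in slots],
            "is_target": is_target,
            "response": response,
            "rt_ms": rt,
        }
    )


def gen_behavior_dataset(
    n_participants: int = 64,
    params: BehaviorParams | None = None,
    seed: int = 0,
    phases=("sound",),
    n_slots: int | None = None,
) -> pd.DataFrame:
    """Full study trial table: every participant × phase × condition.

    Participants cycle through the four scheduling groups; each
    participant × condition gets its own seeded schedule.
    """
    params = params or BehaviorParams()
    groups = ("1a", "1b", "2a", "2b")
    frames = []
    for p in range(n_participants):
        group = groups[p % 4]
        for phase in phases:
            conds = (
                [("high", "high"), ("high", "low"), ("low", "high"), ("low", "low")]
                if phase == "sound"
                else [("none", "none")]
            )
            for met, reg in conds:
                sched = schedule_targets(
                    group, phase, seed=rng_for(seed, "sched", p, phase, met, reg).integers(2**31),
                    n_slots=n_slots,
                )
                frames.append(
                    gen_behavior(sched, params, seed, met, reg, participant=p)
                )
    return pd.concat(frames, ignore_index=True)


# -- convenience: full per-condition stimulus + EEG --------------------------

def gen_condition_recording(
    metricality: str,
    regularity: str,
    group: str = "1a",
    seed: int = 0,
    n_measures: int = 180,
    eeg_params: EEGParams | None = None,
) -> SampledRecording:
    """Timeline plus synthetic EEG for one sound-phase condition block."""
    seq = build_sequence(metricality, regularity, seed=seed, n_measures=n_measures)
    sched = schedule_targets(
        group, "sound", seed=seed,
        n_slots=n_measures,
        targets_per_class=2 * max(1, n_measures // 12),  # 30 per class at 180
    )
    timeline = build_timeline(seq, sched)
    return gen_eeg(timeline, eeg_params, seed=seed)


def save_recording_fif(recording: SampledRecording, path) -> None:
    """Write a recording to FIF via MNE (µV → V)."""
    recording.to_mne().save(path, overwrite=True, verbose="error")
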
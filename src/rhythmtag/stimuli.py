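"""Metrical rhythm construction, sequencing, target scheduling and rendering.

The stimulus grammar: a 3000 ms measure spans four 750 ms beats, the fourth
beat acoustically silent. The first note falls on beat 1 (0 ms) and the last
note 375 ms after beat 3 (1875 ms), leaving a constant 1125 ms silent period
before the next measure. High-metricality measures use inter-onset intervals
in ratios 1:2:4:6 of a 187.5 ms unit (the beat's quarter subdivision) and
acoustically mark beats 1–3. Low-metricality measures keep the same onset
count and endpoints but use intervals in ratios 7:24:38:60 of an 18.75 ms
tick (≈ 1:3.43:5.43:8.57 of the 131.25 ms smallest interval), which provably
keeps every interior onset off the 750 ms beat grid.

Visual targets are scheduled in the silent window around the fourth beat:
on-beat (0 ms), metrical off-beat (±187.5 ms) or nonmetrical off-beat
(metrical ± 56.25 ms, i.e. ±131.25 / ±243.75 ms), with the offset menu per
participant group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import accumulate, permutations

import numpy as np
import pandas as pd
import scipy.io.wavfile

from ._seed import rng_for
from .containers import SampledRecording

# -- design constants (ms) ---------------------------------------------------
MEASURE_DURATION_MS = 3000.0
BEAT_PERIOD_MS = 750.0
BEAT_GRID_MS = (0.0, 750.0, 1500.0, 2250.0)
SILENT_BEAT_MS = 2250.0            # fourth, acoustically silent beat
LAST_ONSET_MS = 1875.0             # 375 ms after the third beat
SILENT_GAP_MS = 1125.0             # last onset -> next measure onset
HIGH_UNIT_MS = 187.5               # high-metricality interval unit (beat / 4)
LOW_UNIT_MS = 131.25               # smallest low-metricality interval
LOW_TICK_MS = LOW_UNIT_MS / 7.0    # 18.75 ms; low intervals are 7/24/38/60 ticks
HIGH_RATIOS = (1, 2, 4, 6)
LOW_RATIO_TICKS = (7, 24, 38, 60)  # /7 -> 1 : 3.43 : 5.43 : 8.57
METRICAL_OFFSET_MS = 187.5
NONMETRICAL_DELTA_MS = 56.25       # printed as 56.3
TARGET_FLASH_MS = 100.0

N_MEASURES_SOUND = 180
N_SLOTS_SILENCE = 60               # 3 min of 3 s slots
TARGETS_PER_CLASS_SOUND = 30
TARGETS_PER_CLASS_SILENCE = 10

METRICALITIES = ("high", "low")
REGULARITIES = ("high", "low")
GROUPS = ("1a", "1b", "2a", "2b")
PHASES = ("initial_silence", "sound", "post_sound_silence")
POSITION_CLASSES = ("on_beat", "off_metrical", "off_nonmetrical")

#: per-group menu of target offsets (ms relative to the silent fourth beat)
GROUP_OFFSETS_MS = {
    "1a": {"off_metrical": (-187.5, 187.5), "off_nonmetrical": (-131.25, 131.25)},
    "1b": {"off_metrical": (-187.5, 187.5), "off_nonmetrical": (-243.75, 243.75)},
    "2a": {"off_metrical": (-187.5,), "off_nonmetrical": (-243.75, -131.25)},
    "2b": {"off_metrical": (187.5,), "off_nonmetrical": (131.25, 243.75)},
}

_HIGH_TOTAL_UNITS = 10  # 1875 ms / 187.5 ms
#: unique low-metricality interval multisets (ticks of 18.75 ms) per onset count
_LOW_TICK_MULTISETS = {
    4: (38, 38, 24),
    6: (38, 24, 24, 7, 7),
    8: (24, 24, 24, 7, 7, 7, 7),
}
ALLOWED_ONSET_COUNTS = tuple(sorted(_LOW_TICK_MULTISETS))


# -- domain types ------------------------------------------------------------

@dataclass(frozen=True)
class MeasureSpec:
    """Note onsets of one 3000 ms measure plus metricality metadata."""

    onsets_ms: tuple
    metricality: str
    measure_id: int
    duration_ms: float = MEASURE_DURATION_MS
    beat_grid_ms: tuple = BEAT_GRID_MS

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(np.asarray(self.onsets_ms, dtype=float))

    @property
    def n_onsets(self) -> int:
        return len(self.onsets_ms)

    def validate(self) -> None:
        on = np.asarray(self.onsets_ms, dtype=float)
        if self.duration_ms != MEASURE_DURATION_MS:
            raise ValueError("measure duration must be 3000 ms")
        if on[0] != 0.0 or not np.isclose(on[-1], LAST_ONSET_MS):
            raise ValueError("first onset must be 0 ms and last 1875 ms")
        iv = np.diff(on)
        if self.metricality == "high":
            allowed = HIGH_UNIT_MS * np.asarray(HIGH_RATIOS, dtype=float)
            if not {750.0, 1500.0} <= set(np.round(on, 6)):
                raise ValueError("beats 2-3 must be acoustically marked")
        else:
            allowed = LOW_TICK_MS * np.asarray(LOW_RATIO_TICKS, dtype=float)
            interior = on[1:-1]
            if np.any(np.isclose(interior[:, None], np.asarray(BEAT_GRID_MS)).any(axis=1)):
                raise ValueError("interior low-metricality onsets must be off the beat grid")
        if not np.all(np.isclose(iv[:, None], allowed[None, :]).any(axis=1)):
            raise ValueError(f"inter-onset interval outside allowed set {allowed}")


@dataclass(frozen=True)
class SequenceSpec:
    """Order of measures within one 9 min sound phase."""

    metricality: str
    regularity: str
    measure_order: tuple
    seed: int = 0

    @property
    def n_measures(self) -> int:
        return len(self.measure_order)

    @property
    def condition(self) -> str:
        return f"{self.metricality}M_{self.regularity}R"


@dataclass
class TargetSchedule:
    """Visual target assignments for one phase of one participant group.

    ``entries`` columns: measure_index, position_class, offset_ms.
    """

    entries: pd.DataFrame
    group: str
    phase: str
    n_slots: int


@dataclass
class NoteParams:
    """Rendering parameters for one note (timbre unspecified upstream)."""

    freq_hz: float = 500.0
    duration_ms: float = 100.0
    decay_ms: float = 30.0
    peak: float = 0.9


@dataclass
class RenderedStimulus:
    audio: SampledRecording
    timeline: pd.DataFrame
    note_params: NoteParams


# -- measure composition -----------------------------------------------------

@lru_cache(maxsize=None)
def _high_compositions() -> tuple:
    """All interval sequences (units of 187.5 ms) for a high-metrical measure.

    A valid composition sums to 10 units with prefix sums passing through 4
    and 8 (beats 2 and 3 acoustically marked) and has a low-metricality
    counterpart of equal onset count.
    """
    found = []

    def extend(prefix, total):
        for part in HIGH_RATIOS:
            t = total + part
            if t > _HIGH_TOTAL_UNITS:
                continue
            seq = prefix + (part,)
            if t == _HIGH_TOTAL_UNITS:
                sums = set(accumulate(seq))
                if {4, 8} <= sums and len(seq) + 1 in _LOW_TICK_MULTISETS:
                    found.append(seq)
            else:
                extend(seq, t)

    extend((), 0)
    return tuple(sorted(found))


def compose_measure(
    metricality: str,
    measure_id: int,
    seed: int = 0,
    n_onsets: int | None = None,
    max_attempts: int = 1000,
) -> MeasureSpec:
    """Compose one measure by seeded constrained randomization.

    Paired high/low measures (same ``measure_id`` and ``seed``) share their
    onset count; compositions are exemplars of the constraint system, not
    reproductions of any particular printed melody.
    """
    if metricality not in METRICALITIES:
        raise ValueError(f"metricality must be one of {METRICALITIES}")
    if not 1 <= int(measure_id) <= 5:
        raise ValueError("measure_id must be in 1..5")
    if n_onsets is None:
        n_onsets = int(rng_for(seed, "measure-size", measure_id).choice(ALLOWED_ONSET_COUNTS))
    if n_onsets not in _LOW_TICK_MULTISETS:
        raise ValueError(f"onset count must be one of {ALLOWED_ONSET_COUNTS}")

    rng = rng_for(seed, "measure", metricality, measure_id)
    if metricality == "high":
        pool = [c for c in _high_compositions() if len(c) + 1 == n_onsets]
        comp = pool[int(rng.integers(len(pool)))]
        onsets = HIGH_UNIT_MS * np.concatenate([[0.0], np.cumsum(comp)])
    else:
        ticks = np.array(_LOW_TICK_MULTISETS[n_onsets])
        for _ in range(max_attempts):
            rng.shuffle(ticks)
            interior = np.cumsum(ticks)[:-1]
            # 750/1500 ms are at 40/80 ticks; unreachable by 7a+24b+38c, so
            # this always succeeds on the first try (kept as a guard).
            if not np.any(np.isin(interior, (40, 80))):
                break
        else:
            raise RuntimeError("could not place interior onsets off the beat grid")
        onsets = LOW_TICK_MS * np.concatenate([[0.0], np.cumsum(ticks)])

    spec = MeasureSpec(tuple(onsets), metricality, int(measure_id))
    spec.validate()
    return spec


def measure_set(metricality: str, seed: int = 0) -> dict:
    """The five composed measures of one metricality level."""
    return {mid: compose_measure(metricality, mid, seed=seed) for mid in range(1, 6)}


# -- sequencing --------------------------------------------------------------

def build_sequence(
    metricality: str,
    regularity: str,
    measure_id: int | None = None,
    seed: int = 0,
    n_measures: int = N_MEASURES_SOUND,
) -> SequenceSpec:
    """Order measures for one sound phase.

    High regularity repeats a single measure throughout; low regularity plays
    all five measures of the metricality level in balanced pseudo-random
    order.
    """
    if metricality not in METRICALITIES or regularity not in REGULARITIES:
        raise ValueError("metricality and regularity must be 'high' or 'low'")
    if regularity == "high":
        if measure_id is None:
            measure_id = int(rng_for(seed, "seq-measure", metricality).integers(1, 6))
        if not 1 <= measure_id <= 5:
            raise ValueError("measure_id must be in 1..5")
        order = np.full(n_measures, measure_id, dtype=int)
    else:
        order = np.resize(np.arange(1, 6), n_measures)
        rng_for(seed, "seq-order", metricality).shuffle(order)
    return SequenceSpec(metricality, regularity, tuple(int(m) for m in order), seed)


# -- target scheduling -------------------------------------------------------

def schedule_targets(
    group: str,
    phase: str,
    seed: int = 0,
    n_slots: int | None = None,
    targets_per_class: int | None = None,
) -> TargetSchedule:
    """Assign visual targets to measures for one phase.

    Sound phases place 30 targets per position class in 90 of 180 measures;
    silence phases place 10 per class in 30 of 60 slots. Target measures are
    drawn uniformly without replacement, at most one target per measure, and
    the position/offset order is randomized.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    sound = phase == "sound"
    if n_slots is None:
        n_slots = N_MEASURES_SOUND if sound else N_SLOTS_SILENCE
    if targets_per_class is None:
        targets_per_class = TARGETS_PER_CLASS_SOUND if sound else TARGETS_PER_CLASS_SILENCE

    classes, offsets = ["on_beat"] * targets_per_class, [0.0] * targets_per_class
    for cls in ("off_metrical", "off_nonmetrical"):
        menu = GROUP_OFFSETS_MS[group][cls]
        if targets_per_class % len(menu):
            raise ValueError("targets per class must divide evenly over the offset menu")
        for off in menu:
            classes.extend([cls] * (targets_per_class // len(menu)))
            offsets.extend([off] * (targets_per_class // len(menu)))

    n_targets = len(classes)
    if n_targets > n_slots:
        raise ValueError("more targets than available measures")
    rng = rng_for(seed, "targets", group, phase)
    measures = np.sort(rng.choice(n_slots, size=n_targets, replace=False))
    order = rng.permutation(n_targets)
    entries = pd.DataFrame(
        {
            "measure_index": measures,
            "position_class": np.asarray(classes)[order],
            "offset_ms": np.asarray(offsets)[order],
        }
    )
    return TargetSchedule(entries, group, phase, int(n_slots))


def counterbalance_orders() -> pd.DataFrame:
    """Enumerate block orders from nesting one factor in the other.

    For each nesting (metricality in regularity and vice versa), the
    superordinate levels appear in both orders and the nested levels in both
    orders independently per superordinate level. Emits the full enumeration
    (16 assignments); its cardinality is reported, not forced.
    """
    levels = ("high", "low")
    rows = []
    for nesting in ("metricality_in_regularity", "regularity_in_metricality"):
        super_f = "regularity" if nesting == "metricality_in_regularity" else "metricality"
        nested_f = "metricality" if super_f == "regularity" else "regularity"
        for super_order in permutations(levels):
            for nested_first in permutations(levels):
                for nested_second in permutations(levels):
                    blocks = []
                    for s_level, nested in zip(super_order, (nested_first, nested_second)):
                        for n_level in nested:
                            cond = {super_f: s_level, nested_f: n_level}
                            blocks.append(f"{cond['metricality']}M_{cond['regularity']}R")
                    rows.append(
                        {
                            "nesting": nesting,
                            "superordinate_order": super_order,
                            "nested_orders": (nested_first, nested_second),
                            "block_order": tuple(blocks),
                        }
                    )
    return pd.DataFrame(rows)


# -- timeline and audio rendering --------------------------------------------

_EVENT_COLUMNS = [
    "time_ms",
    "event_type",
    "position_class",
    "offset_ms",
    "measure_index",
    "measure_id",
    "condition",
    "duration_ms",
]


def build_timeline(
    sequence: SequenceSpec | None = None,
    schedule: TargetSchedule | None = None,
    measures: dict | None = None,
) -> pd.DataFrame:
    """Absolute-time event list (measure/beat/note/target) for one phase.

    Times are in ms from phase start; measure-local times are half-open
    [0, 3000). A silence phase (``sequence=None``) keeps only target events.
    """
    if sequence is None and schedule is None:
        raise ValueError("need a sequence, a schedule, or both")
    rows = []
    if sequence is not None:
        if measures is None:
            measures = measure_set(sequence.metricality, seed=sequence.seed)
        cond = sequence.condition
        for i, mid in enumerate(sequence.measure_order):
            t0 = i * MEASURE_DURATION_MS
            rows.append((t0, "measure", "", np.nan, i, mid, cond, np.nan))
            for b in BEAT_GRID_MS:
                rows.append((t0 + b, "beat", "", np.nan, i, mid, cond, np.nan))
            for onset in measures[mid].onsets_ms:
                rows.append((t0 + onset, "note", "", np.nan, i, mid, cond, np.nan))
        n_slots = sequence.n_measures
    else:
        cond = "silence"
        n_slots = schedule.n_slots
    if schedule is not None:
        if schedule.entries["measure_index"].max() >= n_slots:
            raise ValueError("schedule refers to measures beyond the sequence")
        for e in schedule.entries.itertuples(index=False):
            t = e.measure_index * MEASURE_DURATION_MS + SILENT_BEAT_MS + e.offset_ms
            rows.append(
                (t, "target", e.position_class, e.offset_ms, e.measure_index,
                 np.nan, cond, TARGET_FLASH_MS)
            )
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return df.sort_values(["time_ms", "event_type"], kind="stable").reset_index(drop=True)


def note_kernel(params: NoteParams, rate_hz: float) -> np.ndarray:
    n = int(round(params.duration_ms / 1000.0 * rate_hz))
    t = np.arange(n) / rate_hz
    return np.sin(2 * np.pi * params.freq_hz * t) * np.exp(-t / (params.decay_ms / 1000.0))


def render_audio(
    sequence: SequenceSpec | None = None,
    schedule: TargetSchedule | None = None,
    note_params: NoteParams | None = None,
    rate_hz: float = 44100.0,
    measures: dict | None = None,
) -> RenderedStimulus:
    """Render one phase to audio plus its event timeline.

    Silence phases (no sequence, or a schedule whose phase is not ``sound``)
    produce zero-amplitude audio of the phase duration while the timeline
    retains the target events.
    """
    if rate_hz < 8000:
        raise ValueError("rate_hz must be at least 8000")
    note_params = note_params or NoteParams()
    silent = sequence is None or (schedule is not None and schedule.phase != "sound")
    timeline = build_timeline(None if silent else sequence, schedule, measures)
    if sequence is not None:
        n_slots = sequence.n_measures
    else:
        n_slots = schedule.n_slots
    n_samples = int(round(n_slots * MEASURE_DURATION_MS / 1000.0 * rate_hz))
    audio = np.zeros(n_samples)
    if not silent:
        kernel = note_kernel(note_params, rate_hz)
        onsets = timeline.loc[timeline.event_type == "note", "time_ms"].to_numpy()
        if len(onsets) > 1:
            min_ioi = np.diff(np.sort(onsets)).min()
            if note_params.duration_ms > min_ioi:
                warnings.warn(
                    "note duration exceeds the smallest inter-onset interval; "
                    "overlapping notes are summed"
                )
        for t in onsets:
            i = int(round(t / 1000.0 * rate_hz))
            seg = kernel[: max(0, n_samples - i)]
            audio[i : i + len(seg)] += seg
        peak = np.abs(audio).max()
        if peak > 0:
            audio *= note_params.peak / peak
    rec = SampledRecording(audio[None, :], rate_hz, ["audio"], annotations=timeline)
    return RenderedStimulus(rec, timeline, note_params)


# -- external formats --------------------------------------------------------

def write_wav(path, stimulus_or_recording, dtype: str = "float32") -> None:
    rec = getattr(stimulus_or_recording, "audio", stimulus_or_recording)
    data = rec.data[0] if rec.data.shape[0] == 1 else rec.data.T
    scipy.io.wavfile.write(path, int(rec.rate_hz), data.astype(dtype))


def read_wav(path) -> SampledRecording:
    rate, data = scipy.io.wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    else:
        data = data.T
    if data.dtype != float:
        data = data.astype(float)
    return SampledRecording(data, float(rate), [f"audio{i}" for i in range(data.shape[0])])


def write_events(path, timeline: pd.DataFrame, dialect: str = "tsv") -> None:
    """Write an event table (tab-separated, or a BIDS-events-like CSV)."""
    if dialect == "tsv":
        timeline.to_csv(path, sep="\t", index=False, na_rep="n/a")
    elif dialect == "bids":
        df = timeline.copy()
        df.insert(0, "onset", df.pop("time_ms") / 1000.0)
        df.insert(1, "duration", df.pop("duration_ms").fillna(0.0) / 1000.0)
        df = df.rename(columns={"event_type": "trial_type"})
        df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    else:
        raise ValueError("dialect must be 'tsv' or 'bids'")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if "onset" in df.columns:  # BIDS dialect
        df = df.rename(columns={"trial_type": "event_type"})
        df.insert(0, "time_ms", df.pop("onset") * 1000.0)
        df["duration_ms"] = df.pop("duration") * 1000.0
    return df
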
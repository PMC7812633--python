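"""Shared in-memory containers for sampled signals and spectra."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class SampledRecording:
    """Uniformly sampled multichannel signal with optional event annotations.

    ``data`` is ``(n_channels, n_samples)``; amplitudes are in the caller's
    units (µV for EEG, arbitrary for audio). ``annotations`` is an event
    table with at least ``time_ms`` and ``event_type`` columns.
    """

    data: np.ndarray
    rate_hz: float
    ch_names: list[str]
    annotations: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {self.data.shape[0]} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy(self) -> "SampledRecording":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            annotations=None if self.annotations is None else self.annotations.copy(),
            meta=dict(self.meta),
        )

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def to_mne(self, ch_type: str = "eeg"):
        """Convert to an :class:`mne.io.RawArray` (EEG scaled µV → V)."""
        import mne

        info = mne.create_info(list(self.ch_names), self.rate_hz, ch_type)
        scale = 1e-6 if ch_type == "eeg" else 1.0
        raw = mne.io.RawArray(self.data * scale, info, verbose="error")
        if self.annotations is not None and len(self.annotations):
            onset = self.annotations["time_ms"].to_numpy() / 1000.0
            desc = self.annotations["event_type"].astype(str).to_numpy()
            dur = (
                self.annotations["duration_ms"].fillna(0.0).to_numpy() / 1000.0
                if "duration_ms" in self.annotations
                else np.zeros(len(onset))
            )
            keep = onset < self.duration_s
            raw.set_annotations(
                mne.Annotations(onset[keep], dur[keep], desc[keep]), verbose="error"
            )
        return raw


@dataclass
class EnvelopeSpectrum:
    """Amplitude spectrum of a (modelled) response envelope.

    ``amplitude`` is indexed by ``freqs_hz``; ``provenance`` records the
    processing chain (config, input id, raw / baseline-corrected / z-scored).
    """

    freqs_hz: np.ndarray
    amplitude: np.ndarray
    resolution_hz: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.freqs_hz.shape != self.amplitude.shape:
            raise ValueError("frequency and amplitude grids differ in shape")
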
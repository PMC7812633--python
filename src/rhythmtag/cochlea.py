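"""Stimulus-driven cochlear reference model.

Audio is down-sampled to an intermediate 5000 Hz rate, passed through a
128-channel fourth-order gammatone filterbank with center frequencies
uniformly spaced on the ERB-rate scale (Glasberg & Moore constants,
ERB(f) = 24.7·(4.37 f/1000 + 1)), transduced by the Meddis inner-hair-cell
reservoir model (canonical published constants), down-sampled to the EEG
rate (500 Hz), Hilbert-transformed to an amplitude envelope, and Fourier
analyzed in 30 s windows at 0.0333 Hz resolution. Amplitude spectra are
averaged across the cochlear channels, yielding the stimulus-driven
reference against which EEG frequency tagging is compared.

Order of operations is fixed: filterbank → hair cell → downsample →
Hilbert → FFT → channel average (→ baseline correction downstream). One
second is discarded at each edge before the FFT windows are cut, to keep
Hilbert edge effects out of the spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.signal

from .containers import EnvelopeSpectrum
from .tagging import EPOCH_S, amplitude_spectrum

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

# Glasberg & Moore (ERB-rate) constants as used by the Patterson-Holdsworth
# filterbank design.
EAR_Q = 9.26449
MIN_BW = 24.7

#: Meddis hair-cell constants (canonical published parameter set).
MEDDIS_CONSTANTS = dict(
    A=5.0, B=300.0, g=2000.0, y=5.05, l=2500.0, r=6580.0, x=66.31, M=1.0, h=50000.0
)


def erb_bandwidth(freq_hz):
    """Equivalent rectangular bandwidth ERB(f) = 24.7·(4.37 f/1000 + 1)."""
    return MIN_BW * (4.37 * np.asarray(freq_hz, dtype=float) / 1000.0 + 1.0)


def erb_space(low_hz: float, high_hz: float, n_channels: int) -> np.ndarray:
    """Center frequencies uniformly spaced on the ERB-rate scale (ascending)."""
    c = EAR_Q * MIN_BW
    i = np.arange(1, n_channels + 1)
    cf = -c + np.exp(i * (-np.log(high_hz + c) + np.log(low_hz + c)) / n_channels) * (
        high_hz + c
    )
    return cf[::-1]


@dataclass
class CochlearConfig:
    n_channels: int = 128
    fmin_hz: float = 100.0
    fmax_hz: float | None = None          # default: intermediate Nyquist
    intermediate_rate_hz: float = 5000.0
    output_rate_hz: float = 500.0
    haircell: str = "meddis"
    #: linear gain applied before filtering; maps unit-scale rendered audio
    #: into the hair-cell model's adaptive operating range (A = 5)
    input_gain: float = 30.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        if self.fmax_hz is None:
            self.fmax_hz = self.intermediate_rate_hz / 2.0
        ratio = self.intermediate_rate_hz / self.output_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("output rate must divide the intermediate rate")

    def center_freqs(self) -> np.ndarray:
        return erb_space(self.fmin_hz, self.fmax_hz, self.n_channels)

    def provenance(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "fmin_hz": self.fmin_hz,
            "fmax_hz": self.fmax_hz,
            "intermediate_rate_hz": self.intermediate_rate_hz,
            "output_rate_hz": self.output_rate_hz,
            "haircell": self.haircell,
            "input_gain": self.input_gain,
            "haircell_constants": dict(MEDDIS_CONSTANTS),
        }


def resample(signal, source_rate_hz: float, target_rate_hz: float) -> np.ndarray:
    """Anti-aliased polyphase resampling (downsampling only)."""
    if target_rate_hz > source_rate_hz:
        raise ValueError("upsampling is not supported")
    if target_rate_hz == source_rate_hz:
        return np.asarray(signal, dtype=float)
    frac = Fraction(int(round(target_rate_hz * 1000)), int(round(source_rate_hz * 1000)))
    return scipy.signal.resample_poly(
        np.asarray(signal, dtype=float), frac.numerator, frac.denominator, axis=-1
    )


def gammatone_filterbank(signal, rate_hz: float, config: CochlearConfig) -> np.ndarray:
    """Apply the 4th-order gammatone filterbank; returns (n_channels, n)."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("gammatone_filterbank expects a single-channel signal")
    cfs = config.center_freqs()
    if np.any(cfs >= rate_hz / 2.0):
        raise ValueError("center frequency at or above Nyquist")
    out = np.empty((len(cfs), len(x)))
    for j, fc in enumerate(cfs):
        b, a = scipy.signal.gammatone(fc, "iir", fs=rate_hz)
        out[j] = scipy.signal.lfilter(b, a, x)
    return out


def meddis_spontaneous_output() -> float:
    """Analytic zero-input fixed point of the hair-cell model (output units)."""
    k = MEDDIS_CONSTANTS
    kt = k["g"] * k["A"] / (k["A"] + k["B"])
    c = k["M"] * k["y"] * kt / (k["l"] * kt + k["y"] * (k["l"] + k["r"]))
    return k["h"] * c


def _meddis_kernel(x, dt, A, B, gdt, ydt, ldt, rdt, xdt, M, h, c0, q0, w0, out):
    n_ch, n = x.shape
    for ch in range(n_ch):
        c = c0
        q = q0
        w = w0
        for i in range(n):
            st = x[ch, i] + A
            if st < 0.0:
                st = 0.0
            kt = gdt * st / (st + B)
            replenish = ydt * (M - q)
            if replenish < 0.0:
                replenish = 0.0
            eject = kt * q
            loss = ldt * c
            reuptake = rdt * c
            reprocess = xdt * w
            q += replenish - eject + reprocess
            c += eject - loss - reuptake
            w += reuptake - reprocess
            v = h * c
            out[ch, i] = v if v > 0.0 else 0.0


if njit is not None:
    _meddis_kernel = njit(cache=True, fastmath=False)(_meddis_kernel)


def meddis_haircell(signal, rate_hz: float) -> np.ndarray:
    """Meddis inner-hair-cell transduction (firing-probability output).

    Per-channel reservoir dynamics (free transmitter / cleft / reprocessing
    pools) with the canonical constants; the state starts at the zero-input
    fixed point, so silence yields the spontaneous output level.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to the hair-cell model")
    k = MEDDIS_CONSTANTS
    dt = 1.0 / rate_hz
    kt0 = k["g"] * k["A"] / (k["A"] + k["B"])
    c0 = k["M"] * k["y"] * kt0 / (k["l"] * kt0 + k["y"] * (k["l"] + k["r"]))
    q0 = c0 * (k["l"] + k["r"]) / kt0
    w0 = c0 * k["r"] / k["x"]
    out = np.empty_like(x)
    _meddis_kernel(
        x, dt, k["A"], k["B"], k["g"] * dt, k["y"] * dt, k["l"] * dt,
        k["r"] * dt, k["x"] * dt, k["M"], k["h"], c0, q0, w0, out,
    )
    return out if np.asarray(signal).ndim > 1 else out[0]


def envelope_spectrum(
    channels,
    config: CochlearConfig,
    epoch_s: float = EPOCH_S,
    edge_trim_s: float = 1.0,
    input_rate_hz: float | None = None,
) -> EnvelopeSpectrum:
    """Channel-averaged amplitude spectrum of the Hilbert response envelope.

    Input is the multichannel hair-cell output at the intermediate rate;
    each channel is down-sampled to the output rate, Hilbert-transformed,
    trimmed by ``edge_trim_s`` at each edge, cut into ``epoch_s`` windows
    and Fourier transformed; amplitude spectra are averaged across epochs
    and channels.
    """
    x = np.atleast_2d(np.asarray(channels, dtype=float))
    rate_in = config.intermediate_rate_hz if input_rate_hz is None else input_rate_hz
    fs = config.output_rate_hz
    accum = None
    n_epochs = 0
    for ch in x:
        env = np.abs(scipy.signal.hilbert(resample(ch, rate_in, fs)))
        trim = int(round(edge_trim_s * fs))
        env = env[trim : len(env) - trim if trim else None]
        n_per = int(round(epoch_s * fs))
        n_ep = len(env) // n_per
        if n_ep == 0:
            raise ValueError("signal shorter than one analysis window after edge trimming")
        segs = env[: n_ep * n_per].reshape(n_ep, n_per)
        freqs, amps = amplitude_spectrum(segs, fs)
        mean_amp = amps.mean(axis=0)
        accum = mean_amp if accum is None else accum + mean_amp
        n_epochs = n_ep
    amplitude = accum / x.shape[0]
    return EnvelopeSpectrum(
        freqs,
        amplitude,
        resolution_hz=1.0 / epoch_s,
        provenance={
            "config": config.provenance(),
            "n_epochs": n_epochs,
            "n_channels_averaged": x.shape[0],
            "processing": "raw",
        },
    )


def cochlear_reference(
    audio,
    rate_hz: float,
    config: CochlearConfig | None = None,
    epoch_s: float = EPOCH_S,
    edge_trim_s: float = 1.0,
    input_id: str | None = None,
) -> EnvelopeSpectrum:
    """Full cochlear pipeline from stimulus audio to the envelope spectrum.

    Channels are processed one at a time (filter → hair cell → downsample →
    Hilbert → FFT) to keep memory proportional to a single channel.
    """
    config = config or CochlearConfig()
    x = np.asarray(audio, dtype=float)
    if x.ndim == 2:
        if x.shape[0] != 1:
            raise ValueError("cochlear_reference expects mono audio")
        x = x[0]
    x5k = config.input_gain * resample(x, rate_hz, config.intermediate_rate_hz)
    cfs = config.center_freqs()
    if np.any(cfs >= config.intermediate_rate_hz / 2.0):
        raise ValueError("center frequency at or above Nyquist")
    accum = None
    n_epochs = 0
    for fc in cfs:
        b, a = scipy.signal.gammatone(fc, "iir", fs=config.intermediate_rate_hz)
        hc = meddis_haircell(scipy.signal.lfilter(b, a, x5k), config.intermediate_rate_hz)
        spec = envelope_spectrum(hc[None, :], config, epoch_s, edge_trim_s)
        accum = spec.amplitude if accum is None else accum + spec.amplitude
        n_epochs = spec.provenance["n_epochs"]
        freqs = spec.freqs_hz
    return EnvelopeSpectrum(
        freqs,
        accum / len(cfs),
        resolution_hz=1.0 / epoch_s,
        provenance={
            "config": config.provenance(),
            "input_id": input_id,
            "n_epochs": n_epochs,
            "n_channels_averaged": int(len(cfs)),
            "processing": "raw",
        },
    )
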
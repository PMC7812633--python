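"""EEG frequency tagging: amplitude spectra, baseline correction and
harmonic-normalized z-scores at the measure (1/3 Hz) and beat (4/3 Hz)
frequencies.

Continuous recordings are cut into 30 s epochs (0.0333 Hz resolution; the
epoch is an exact multiple of the 3 s measure so the target frequencies are
bin-centered and need no leakage correction). Epoch amplitude spectra are
averaged per condition, corrected by subtracting the mean of surrounding
bins (±2..±4, i.e. 0.0667–0.1333 Hz to each side), and normalized against
the first 30 harmonics of 1/3 Hz. The z-scored cochlear-model spectrum is
subtracted from the z-scored EEG so that positive differences denote EEG
activity exceeding the stimulus-driven auditory response model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from ._seed import rng_for
from .containers import SampledRecording

EPOCH_S = 30.0
FREQ_RESOLUTION_HZ = 1.0 / EPOCH_S
METER_FREQ_HZ = 1.0 / 3.0
BEAT_FREQ_HZ = 4.0 / 3.0
N_HARMONICS = 30

ROIS = {
    "temporal": ("T7", "T8", "TP7", "TP8"),
    "occipital": ("O1", "Oz", "O2"),
}


def epoch_continuous(recording, rate_hz: float | None = None, epoch_s: float = EPOCH_S):
    """Cut a continuous recording into consecutive non-overlapping epochs.

    Returns an ``(n_epochs, n_channels, n_samples)`` array; the remainder
    shorter than one epoch is dropped. A recording shorter than one epoch
    yields an empty list with a warning.
    """
    if isinstance(recording, SampledRecording):
        data, rate_hz = recording.data, recording.rate_hz
    else:
        if rate_hz is None:
            raise ValueError("rate_hz required for a bare array")
        data = np.atleast_2d(np.asarray(recording, dtype=float))
    n_per = int(round(epoch_s * rate_hz))
    n_epochs = data.shape[1] // n_per
    if n_epochs == 0:
        warnings.warn("recording shorter than one epoch; returning no epochs")
        return np.empty((0, data.shape[0], n_per))
    trimmed = data[:, : n_epochs * n_per]
    return trimmed.reshape(data.shape[0], n_epochs, n_per).transpose(1, 0, 2)


def amplitude_spectrum(epoch, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum scaled so a unit sinusoid at a bin → 1.

    Works on the last axis; returns ``(freqs_hz, amplitude)``.
    """
    x = np.asarray(epoch, dtype=float)
    n = x.shape[-1]
    amp = np.abs(np.fft.rfft(x, axis=-1)) / n
    amp[..., 1:] *= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return freqs, amp


def baseline_correct(amplitude, inner: int = 2, outer: int = 4):
    """Subtract from each bin the mean amplitude of surrounding bins.

    Neighbors are bins at offsets ±inner..±outer (±2..±4 at 1/30 Hz spacing
    = 0.0667–0.1333 Hz to each side). Edge bins use the neighbors that
    exist; bins with fewer than two usable neighbors become NaN.
    """
    a = np.asarray(amplitude, dtype=float)
    n = a.shape[-1]
    total = np.zeros_like(a)
    count = np.zeros(n)
    for off in list(range(-outer, -inner + 1)) + list(range(inner, outer + 1)):
        src = np.arange(n) + off
        ok = (src >= 0) & (src < n)
        total[..., ok] += a[..., src[ok]]
        count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = a - total / count
    corrected[..., count < 2] = np.nan
    return corrected


def harmonic_bins(freqs_hz, f0: float = METER_FREQ_HZ, n_harmonics: int = N_HARMONICS):
    """Bin indices of k·f0 for k = 1..n_harmonics (f0 counts as 1st harmonic)."""
    freqs = np.asarray(freqs_hz, dtype=float)
    res = freqs[1] - freqs[0]
    idx = []
    for k in range(1, n_harmonics + 1):
        i = int(round(k * f0 / res))
        if i >= len(freqs) or abs(freqs[i] - k * f0) > res / 2:
            raise ValueError(f"harmonic {k}·{f0:.4g} Hz is not on the spectral grid")
        idx.append(i)
    return np.asarray(idx)


def harmonic_zscore(
    freqs_hz,
    amplitude,
    f0: float = METER_FREQ_HZ,
    n_harmonics: int = N_HARMONICS,
    targets=(METER_FREQ_HZ, BEAT_FREQ_HZ),
    ddof: int = 1,
) -> dict:
    """z-score target-frequency amplitudes against the harmonic set of f0.

    The normalization set is {k·f0, k=1..30} (target bins included). Returns
    ``{target_hz: z}``. A zero-spread harmonic set is degenerate and raises,
    except in the all-equal case where the target deviation is exactly zero
    (z = 0 by continuity).
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    res = freqs[1] - freqs[0]
    idx = harmonic_bins(freqs, f0, n_harmonics)
    harm = amp[..., idx]
    mu = harm.mean(axis=-1)
    sd = harm.std(axis=-1, ddof=ddof)
    out = {}
    for f in targets:
        i = int(round(f / res))
        if i >= len(freqs) or abs(freqs[i] - f) > res / 2:
            raise ValueError(f"target {f:.4g} Hz is not on the spectral grid")
        dev = amp[..., i] - mu
        zero = sd == 0
        if np.any(zero):
            dev_at_zero = dev[zero] if np.ndim(sd) else dev
            if not np.all(dev_at_zero == 0):
                raise ValueError("degenerate spectrum: harmonic amplitudes have zero spread")
            z = np.where(zero, 0.0, dev / np.where(zero, 1.0, sd))
        else:
            z = dev / sd
        out[f] = float(z) if np.ndim(z) == 0 else z
    return out


def match_trials(epochs_by_condition: dict, seed: int = 0) -> dict:
    """Down-sample every condition to the minimum epoch count.

    Selection is without replacement, seeded, preserving chronological
    order of the retained epochs.
    """
    counts = {c: len(v) for c, v in epochs_by_condition.items()}
    if any(n == 0 for n in counts.values()):
        empty = [c for c, n in counts.items() if n == 0]
        raise ValueError(f"conditions without epochs: {empty}")
    n_min = min(counts.values())
    out = {}
    for cond, items in epochs_by_condition.items():
        if len(items) == n_min:
            out[cond] = list(items)
        else:
            rng = rng_for(seed, "match-trials", cond)
            keep = np.sort(rng.choice(len(items), size=n_min, replace=False))
            out[cond] = [items[i] for i in keep]
    return out


def spectrum_zscores(freqs_hz, amplitude, targets=(METER_FREQ_HZ, BEAT_FREQ_HZ)) -> dict:
    """Baseline-correct then harmonic-z-score one averaged amplitude spectrum."""
    corrected = baseline_correct(amplitude)
    return harmonic_zscore(freqs_hz, corrected, targets=targets)


def tagging_pipeline(
    eeg_by_condition: dict,
    cochlear_by_condition: dict,
    rois: dict = ROIS,
    seed: int = 0,
    epoch_s: float = EPOCH_S,
    targets=(METER_FREQ_HZ, BEAT_FREQ_HZ),
    participant=None,
    roi_aggregate: str = "spectrum_mean",
) -> pd.DataFrame:
    """Per-condition, per-region EEG-vs-cochlear tagging z-scores.

    Steps: epoch each condition's EEG, match epoch counts across conditions,
    average epoch amplitude spectra, average spectra over ROI channels
    (``roi_aggregate='spectrum_mean'``, the default: z of the ROI-mean
    spectrum; ``'z_mean'`` averages per-channel z instead), baseline-correct,
    z-score against the 1/3 Hz harmonic set, and subtract the cochlear-model
    z. Returns a long table with z_eeg, z_cochlear and z_diff.
    """
    if roi_aggregate not in ("spectrum_mean", "z_mean"):
        raise ValueError("roi_aggregate must be 'spectrum_mean' or 'z_mean'")
    conditions = list(eeg_by_condition)
    missing = [c for c in conditions if c not in cochlear_by_condition]
    if missing:
        raise ValueError(f"no cochlear spectrum for conditions: {missing}")

    epochs = {c: list(epoch_continuous(eeg_by_condition[c], epoch_s=epoch_s)) for c in conditions}
    epochs = match_trials(epochs, seed=seed)

    rows = []
    for cond in conditions:
        rec = eeg_by_condition[cond]
        stack = np.asarray(epochs[cond])  # (n_ep, ch, t)
        freqs, amps = amplitude_spectrum(stack, rec.rate_hz)
        mean_amp = amps.mean(axis=0)  # (ch, F)

        coch = cochlear_by_condition[cond]
        if len(coch.freqs_hz) != len(freqs) or not np.allclose(coch.freqs_hz, freqs):
            raise ValueError("EEG and cochlear spectra are on different frequency grids")
        z_coch = spectrum_zscores(coch.freqs_hz, coch.amplitude, targets)

        for region, chans in rois.items():
            pick = [rec.ch_names.index(ch) for ch in chans if ch in rec.ch_names]
            if not pick:
                raise ValueError(f"no channels of region '{region}' in the recording")
            if roi_aggregate == "spectrum_mean":
                z_eeg = spectrum_zscores(freqs, mean_amp[pick].mean(axis=0), targets)
            else:
                per_ch = [spectrum_zscores(freqs, mean_amp[i], targets) for i in pick]
                z_eeg = {f: float(np.mean([d[f] for d in per_ch])) for f in targets}
            for f in targets:
                rows.append(
                    {
                        "participant": participant,
                        "condition": cond,
                        "region": region,
                        "frequency_hz": f,
                        "n_epochs": stack.shape[0],
                        "z_eeg": z_eeg[f],
                        "z_cochlear": z_coch[f],
                        "z_diff": z_eeg[f] - z_coch[f],
                    }
                )
    return pd.DataFrame(rows)


def tagging_tests(results: pd.DataFrame, value: str = "z_diff") -> pd.DataFrame:
    """One-sample t-tests of the tagging score against zero.

    Scores are averaged across conditions within participant, then tested
    per region × frequency; Bonferroni correction over the tests.
    """
    per = (
        results.groupby(["participant", "region", "frequency_hz"], sort=True)[value]
        .mean()
        .reset_index()
    )
    cells = list(per.groupby(["region", "frequency_hz"], sort=True))
    m = len(cells)
    rows = []
    for (region, f), sub in cells:
        x = sub[value].to_numpy()
        if len(x) < 2:
            raise ValueError("tagging_tests requires at least two participants")
        if np.ptp(x) == 0:
            if x[0] == 0:
                t, p = 0.0, 1.0
            else:
                raise ValueError("degenerate scores: nonzero constant with zero variance")
        else:
            t, p = scipy.stats.ttest_1samp(x, 0.0)
        rows.append(
            {
                "region": region,
                "frequency_hz": f,
                "n": len(x),
                "mean": float(np.mean(x)),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, m * p)),
            }
        )
    return pd.DataFrame(rows)
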
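"""Magnitude-squared coherence of ROI time courses.

Welch-averaged cross- and auto-spectra (default: 24-sample Hann segments
with 50% overlap, suited to 50-frame scans) give the coherence
``|Pxy|^2 / (Pxx * Pyy)`` in [0, 1] per frequency. The cohort spectrum
averages coherence over all region pairs within subject, then across
subjects, with an interquartile band across subjects; the two highest
separated local maxima are reported as peaks (a low-frequency neural peak
near 0.04 Hz and an aliased cardiac peak are the expected pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from ._utils import triu_pairs

__all__ = [
    "CoherenceSpectrum",
    "coherence_pair",
    "coherence_matrix",
    "cohort_mean_coherence",
    "alias_frequency",
]


@dataclass
class CoherenceSpectrum:
    """Cohort coherence spectrum with dispersion and detected peaks."""

    freqs_hz: np.ndarray
    mean: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    peaks: list  # [(frequency_hz, height), ...] sorted by height descending


def _check_segments(n_frames: int, segment_len: int, overlap: int) -> int:
    if not 0 <= overlap < segment_len:
        raise ValueError("overlap must satisfy 0 <= overlap < segment_len")
    if segment_len > n_frames:
        raise ValueError("segment_len exceeds the series length")
    step = segment_len - overlap
    n_seg = 1 + (n_frames - segment_len) // step
    if n_seg < 2:
        raise ValueError(
            "fewer than 2 Welch segments; the coherence estimate would be the "
            "trivial identically-1 artifact"
        )
    return n_seg


def coherence_pair(
    x, y, tr_s: float = 1.0, segment_len: int = 24, overlap: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence of two series (frequencies, coherence)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    _check_segments(x.size, segment_len, overlap)
    freqs, coh = scipy.signal.coherence(
        x, y, fs=1.0 / tr_s, window="hann", nperseg=segment_len, noverlap=overlap
    )
    return freqs, coh


def coherence_matrix(
    data: np.ndarray, tr_s: float = 1.0, segment_len: int = 24, overlap: int = 12
):
    """All-pairs coherence from one Welch pass (freqs, (n_freq, R, R) array).

    Matches :func:`scipy.signal.coherence` conventions (Hann window,
    per-segment constant detrend) but computes every region pair from a
    single short-time FFT, which the per-pair scipy call cross-checks in the
    test suite.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be frames x regions")
    frames = data.shape[0]
    _check_segments(frames, segment_len, overlap)
    step = segment_len - overlap
    starts = range(0, frames - segment_len + 1, step)
    win = scipy.signal.get_window("hann", segment_len)
    specs = []
    for s in starts:
        seg = data[s : s + segment_len]
        seg = seg - seg.mean(axis=0)
        specs.append(np.fft.rfft(win[:, None] * seg, axis=0))
    f_all = np.stack(specs)  # (n_seg, n_freq, R)
    cross = np.einsum("sfi,sfj->fij", f_all, f_all.conj())
    auto = np.einsum("fii->fi", cross).real
    denom = auto[:, :, None] * auto[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(cross) ** 2 / denom, 0.0)
    freqs = np.fft.rfftfreq(segment_len, tr_s)
    return freqs, coh.real


def _find_peaks(freqs, values, n_peaks: int = 2, min_separation_hz: float = 0.05):
    cand = []
    for i in range(values.size):
        left_ok = i == 0 or values[i] >= values[i - 1]
        right_ok = i == values.size - 1 or values[i] >= values[i + 1]
        if left_ok and right_ok:
            cand.append((float(values[i]), float(freqs[i])))
    cand.sort(reverse=True)
    chosen = []
    for height, freq in cand:
        if all(abs(freq - f0) >= min_separation_hz for f0, _ in chosen):
            chosen.append((freq, height))
        if len(chosen) == n_peaks:
            break
    return chosen


def cohort_mean_coherence(
    series_list,
    tr_s: float = 1.0,
    segment_len: int = 24,
    overlap: int = 12,
    n_peaks: int = 2,
    min_separation_hz: float = 0.05,
) -> CoherenceSpectrum:
    """Cohort-average all-pairs coherence with IQR band and peak extraction."""
    if len(series_list) < 1:
        raise ValueError("need at least one subject")
    per_subject = []
    freqs = None
    for data in series_list:
        f, coh = coherence_matrix(data, tr_s, segment_len, overlap)
        i, j = triu_pairs(coh.shape[1])
        per_subject.append(coh[:, i, j].mean(axis=1))
        freqs = f
    stack = np.vstack(per_subject)  # subjects x freqs
    keep = freqs > 0  # the grid spans (0, Nyquist]
    freqs = freqs[keep]
    stack = stack[:, keep]
    mean = stack.mean(axis=0)
    q25 = np.percentile(stack, 25, axis=0)
    q75 = np.percentile(stack, 75, axis=0)
    peaks = _find_peaks(freqs, mean, n_peaks, min_separation_hz)
    return CoherenceSpectrum(freqs_hz=freqs, mean=mean, q25=q25, q75=q75, peaks=peaks)


def alias_frequency(true_hz: float, fs_hz: float) -> float:
    """Apparent frequency after sampling at ``fs_hz``: |f - fs*round(f/fs)|.

    E.g. a 2.4 Hz fetal heartbeat sampled once per second appears at 0.4 Hz.
    """
    if fs_hz <= 0:
        raise ValueError("sampling frequency must be positive")
    return float(abs(true_hz - fs_hz * round(true_hz / fs_hz)))
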
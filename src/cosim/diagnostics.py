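"""Regime analysis of simulation output.

Instantaneous population firing rate, Welch power spectra, spectrograms and
dominant-peak extraction, used to classify the three canonical network
regimes: asynchronous (A, flat rate, featureless spectrum), irregular
synchronous (IS, a broad low-frequency rate peak) and regular bursting
(RB, a sharp low-frequency peak plus a high-frequency intra-burst peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .errors import ContractError, ParameterError
from .spiking import SpikeBlock
from .transforms import spikes_to_rate_array

__all__ = [
    "PeakSet",
    "instantaneous_rate",
    "welch_psd",
    "psd_peaks",
    "dominant_frequency",
    "spectrogram",
    "classify_regime",
]


@dataclass
class PeakSet:
    """Spectral peaks (frequency Hz, power, prominence), power-descending."""

    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    band: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: -p[1])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)

    def __bool__(self) -> bool:
        return bool(self.peaks)


def instantaneous_rate(block: SpikeBlock, n_neurons: int, bin_ms: float = 1.0) -> np.ndarray:
    """Population rate (Hz) in consecutive bins of ``bin_ms`` across the
    block; identical to the spikes-to-rate transform with bin-width windows."""
    return spikes_to_rate_array(block, n_neurons, bin_ms)


def welch_psd(
    series: np.ndarray, fs: float, segment_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram: Hann window, ``segment_s``-second segments, 50%
    overlap, constant detrend."""
    series = np.asarray(series, dtype=float)
    nperseg = min(int(round(segment_s * fs)), series.size)
    freqs, psd = sps.welch(
        series, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs, psd


def psd_peaks(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 250.0),
    prominence_frac: float = 0.2,
    floor_ratio: float = 4.0,
    segment_s: float = 2.0,
) -> PeakSet:
    """Prominent spectral peaks of a time series within a frequency band.

    A peak qualifies if its prominence is at least ``prominence_frac`` times
    the maximum in-band power *and* its power stands at least
    ``floor_ratio`` above a local median baseline (median filter over
    ~25 bins on each side).  The baseline guard rejects the chi-square
    fluctuations of a featureless spectrum -- whose largest wiggle is
    always "prominent" relative to itself -- while narrow genuine lines
    tower over their local surroundings.
    """
    series = np.asarray(series, dtype=float)
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ParameterError(f"invalid band {band}")
    if f_hi > fs / 2:
        raise ParameterError(
            f"band upper edge {f_hi} Hz exceeds the Nyquist frequency {fs / 2} Hz"
        )
    if series.size < 2 * fs * 1.0:
        raise ContractError("need at least ~2 s of data for a stable Welch estimate")
    freqs, psd = welch_psd(series, fs, segment_s=segment_s)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if sel.sum() < 3:
        raise ParameterError("sampling rate too low to resolve the requested band")
    f_band, p_band = freqs[sel], psd[sel]
    if p_band.max() <= 0:
        return PeakSet(peaks=[], band=band)
    # light 3-bin smoothing knocks down single-bin chi-square wiggles
    # without moving a line by more than one bin
    if p_band.size >= 5:
        p_band = np.convolve(p_band, np.ones(3) / 3.0, mode="same")
    p_max = p_band.max()
    # baseline window ~100 Hz: wider than genuine (even burst-broadened)
    # spectral lines, so a real peak towers over it, while the gentle
    # broadband shaping of an asynchronous network does not
    k = min(201, p_band.size)
    baseline = ndimage.median_filter(p_band, size=k, mode="nearest")
    baseline = np.maximum(baseline, np.median(p_band) * 0.1)
    idx, props = sps.find_peaks(p_band, prominence=prominence_frac * p_max)
    peaks = [
        (float(f_band[i]), float(p_band[i]), float(prom))
        for i, prom in zip(idx, props["prominences"])
        if p_band[i] >= floor_ratio * baseline[i]
    ]
    return PeakSet(peaks=peaks, band=band)


def dominant_frequency(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float],
    prominence_frac: float = 0.2,
    floor_ratio: float = 4.0,
    segment_s: float = 2.0,
) -> float | None:
    """Location of the most prominent in-band spectral peak, refined as the
    power-weighted centroid of the contiguous half-maximum region around it.

    For a narrow line this coincides with the peak bin; for a broad peak
    (e.g. the irregular slow oscillation of an adapting network) it
    estimates the bump centre, which is far more stable across noise
    realizations than the single maximal bin.  Returns None when no peak
    qualifies.
    """
    peaks = psd_peaks(
        series, fs, band=band, prominence_frac=prominence_frac,
        floor_ratio=floor_ratio, segment_s=segment_s,
    )
    if not peaks:
        return None
    f_peak = peaks.peaks[0][0]
    freqs, psd = welch_psd(np.asarray(series, dtype=float), fs, segment_s=segment_s)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f_band, p_band = freqs[sel], psd[sel]
    if p_band.size >= 5:
        p_band = np.convolve(p_band, np.ones(3) / 3.0, mode="same")
    i = int(np.argmin(np.abs(f_band - f_peak)))
    half = p_band[i] / 2.0
    lo = i
    while lo > 0 and p_band[lo - 1] >= half:
        lo -= 1
    hi = i
    while hi < p_band.size - 1 and p_band[hi + 1] >= half:
        hi += 1
    w = p_band[lo:hi + 1]
    return float(np.sum(f_band[lo:hi + 1] * w) / np.sum(w))


def spectrogram(
    series: np.ndarray, fs: float, segment_s: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time spectrum (freqs, times, power matrix), Hann window."""
    series = np.asarray(series, dtype=float)
    nperseg = min(int(round(segment_s * fs)), series.size)
    return sps.spectrogram(
        series, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )


def classify_regime(
    rate_series: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 250.0),
    prominence_frac: float = 0.2,
    floor_ratio: float = 4.0,
    cv_threshold: float = 0.3,
    high_freq_boundary: float = 100.0,
    smooth_ms: float = 20.0,
) -> str:
    """Classify an excitatory-rate time series as 'A', 'IS' or 'RB'.

    RB: at least two prominent peaks including one above the high-frequency
    boundary (the intra-burst peak).  A: no prominent peak and a low
    coefficient of variation of the (smoothed) rate -- a flat mean rate.
    IS: otherwise, i.e. a low-frequency peak or large irregular rate
    fluctuations without the high-frequency signature.

    The CV is computed after smoothing with a short moving average so that
    Poisson bin noise (which scales with the rate) does not masquerade as
    slow fluctuation; both criteria are invariant to rate scaling.
    """
    rate_series = np.asarray(rate_series, dtype=float)
    f_lo, f_hi = band[0], min(band[1], 0.99 * fs / 2)
    # the two bands are analysed separately: a dominant slow peak would
    # otherwise mask the (much weaker) intra-burst high-frequency peak
    # under the relative-prominence rule
    low = psd_peaks(
        rate_series, fs, band=(f_lo, min(high_freq_boundary, f_hi)),
        prominence_frac=prominence_frac, floor_ratio=floor_ratio,
    )
    high = PeakSet(peaks=[], band=(high_freq_boundary, f_hi))
    if f_hi > high_freq_boundary:
        high = psd_peaks(
            rate_series, fs, band=(high_freq_boundary, f_hi),
            prominence_frac=prominence_frac, floor_ratio=floor_ratio,
        )
    k = max(1, int(round(smooth_ms * fs / 1000.0)))
    smooth = np.convolve(rate_series, np.ones(k) / k, mode="valid")
    mean = smooth.mean()
    cv = smooth.std() / mean if mean > 0 else 0.0
    if low and high:
        return "RB"
    # an irregular-synchronous rate has, by definition, large slow
    # fluctuations; a weak spectral wiggle with a flat rate does not count
    return "IS" if cv >= cv_threshold else "A"
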
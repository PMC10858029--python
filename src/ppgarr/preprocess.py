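"""PPG preprocessing chain: bandpass, smoothing, baseline removal, normalization, segmentation.

The chain prepares a raw PPG record for pulse delineation and feature
extraction.  Stages, in order:

1. zero-phase Butterworth bandpass (0.05-30 Hz by default) — removes DC and
   out-of-band noise without shifting landmark timing;
2. centred moving-average smoothing (50 ms window);
3. wavelet baseline-wander removal — multilevel DWT with the approximation
   band zeroed at a depth chosen so the approximation covers only
   frequencies below the configured cutoff;
4. amplitude normalization (min-max to [0, 1] per record, or z-score);
5. segmentation into fixed-length non-overlapping windows (10 s).

All per-sample stages preserve signal length, so landmark indices remain
comparable across stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "Waveform",
    "PreprocConfig",
    "Segment",
    "bandpass",
    "smooth",
    "remove_baseline",
    "baseline_depth",
    "normalize",
    "segment_signal",
    "preprocess_record",
]


@dataclass
class Waveform:
    """A uniformly sampled real-valued signal."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < 2:
            raise ValueError("waveform must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class PreprocConfig:
    band_low_hz: float = 0.05
    band_high_hz: float = 30.0
    smooth_window_s: float = 0.05
    wavelet_name: str = "db4"
    # approximation band [0, fs/2^(L+1)] must stay below the slowest
    # physiological fundamental (30 bpm = 0.5 Hz), hence 0.25 not 0.5
    baseline_cutoff_hz: float = 0.25
    norm_mode: str = "minmax"
    segment_len_s: float = 10.0
    per_segment_norm: bool = False

    def __post_init__(self) -> None:
        if self.segment_len_s <= 0:
            raise ValueError("segment_len_s must be positive")
        if self.norm_mode not in ("minmax", "zscore"):
            raise ValueError("norm_mode must be 'minmax' or 'zscore'")


@dataclass
class Segment:
    """A fixed-length preprocessed window — the unit of feature extraction."""

    samples: np.ndarray
    fs: float
    source_record_id: str = ""
    start_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def bandpass(w: Waveform, low_hz: float = 0.05, high_hz: float = 30.0, order: int = 4) -> Waveform:
    """Zero-phase Butterworth bandpass via forward-backward filtering."""
    nyq = w.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < low < high < fs/2 (= {nyq})")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=w.fs, output="sos")
    # the low-frequency pole has a time constant ~ 1/low_hz; extend the
    # reflect padding accordingly or the startup transient leaks inward
    padlen = int(min(w.samples.size - 1, round(0.5 * w.fs / low_hz)))
    filtered = sps.sosfiltfilt(sos, w.samples, padlen=padlen)
    return Waveform(filtered, w.fs)


def smooth(w: Waveform, window_s: float = 0.05) -> Waveform:
    """Centred moving average; window rounded up to an odd sample count.

    Edges are handled by shrinking the window to the available samples, so
    the output is the same length as the input and constants are preserved.
    """
    n = w.samples.size
    win = round(window_s * w.fs)
    if win < 1:
        win = 1
    if win % 2 == 0:
        win += 1
    if win > n:
        raise ValueError("smoothing window longer than the signal")
    if win == 1:
        return Waveform(w.samples.copy(), w.fs)
    half = win // 2
    csum = np.concatenate([[0.0], np.cumsum(w.samples)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return Waveform(out, w.fs)


def baseline_depth(fs: float, cutoff_hz: float) -> int:
    """Smallest decomposition depth whose approximation band fits under cutoff.

    L is the least integer with fs / 2**(L+1) <= cutoff_hz: zeroing the
    level-L approximation then removes only content below the cutoff.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    return max(1, math.ceil(math.log2(fs / cutoff_hz)) - 1)


def remove_baseline(w: Waveform, wavelet_name: str = "db4", cutoff_hz: float = 0.25) -> Waveform:
    """Remove baseline wander by zeroing the deep wavelet approximation band."""
    level = baseline_depth(w.fs, cutoff_hz)
    if w.samples.size < 2**level:
        raise ValueError(
            f"signal too short ({w.samples.size} samples) for decomposition depth {level}"
        )
    coeffs = pywt.wavedec(w.samples, wavelet_name, level=level)
    coeffs[0] = np.zeros_like(coeffs[0])
    rec = pywt.waverec(coeffs, wavelet_name)
    return Waveform(rec[: w.samples.size], w.fs)


def normalize(w: Waveform, mode: str = "minmax") -> Waveform:
    """Amplitude normalization; constant input maps to all zeros."""
    x = w.samples
    if mode == "minmax":
        lo, hi = x.min(), x.max()
        out = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    elif mode == "zscore":
        sd = x.std()
        out = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    else:
        raise ValueError("mode must be 'minmax' or 'zscore'")
    return Waveform(out, w.fs)


def segment_signal(
    w: Waveform,
    segment_len_s: float = 10.0,
    record_id: str = "",
    label: str = "",
) -> list[Segment]:
    """Cut into consecutive non-overlapping windows; trailing remainder dropped."""
    seg_n = round(segment_len_s * w.fs)
    if seg_n < 1 or w.samples.size < seg_n:
        raise ValueError("waveform shorter than one segment")
    n_segs = w.samples.size // seg_n
    return [
        Segment(
            w.samples[i * seg_n : (i + 1) * seg_n].copy(),
            w.fs,
            source_record_id=record_id,
            start_s=i * seg_n / w.fs,
            label=label,
        )
        for i in range(n_segs)
    ]


def preprocess_record(
    w: Waveform,
    cfg: PreprocConfig = PreprocConfig(),
    record_id: str = "",
    label: str = "",
) -> list[Segment]:
    """Full chain: bandpass -> smooth -> baseline removal -> normalize -> segment."""
    if np.ptp(w.samples) == 0:
        # constant record: DC removal leaves exactly zero; skip the filters
        # so numerical residue is not inflated by min-max normalization
        zeros = Waveform(np.zeros_like(w.samples), w.fs)
        return segment_signal(zeros, cfg.segment_len_s, record_id, label)
    out = bandpass(w, cfg.band_low_hz, cfg.band_high_hz)
    out = smooth(out, cfg.smooth_window_s)
    out = remove_baseline(out, cfg.wavelet_name, cfg.baseline_cutoff_hz)
    out = normalize(out, cfg.norm_mode)
    segments = segment_signal(out, cfg.segment_len_s, record_id, label)
    if cfg.per_segment_norm:
        segments = [
            replace(s, samples=normalize(Waveform(s.samples, s.fs), cfg.norm_mode).samples)
            for s in segments
        ]
    return segments
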
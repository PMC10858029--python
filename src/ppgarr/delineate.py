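"""Pulse delineation: valley / systolic-peak detection and dicrotic-notch localization.

Valleys delimit individual pulses (one heartbeat each); the systolic peak is
the global maximum between consecutive valleys; the dicrotic notch is found
from derivative landmarks on the post-systolic limb.  A quality mask flags
pulses with implausible timing or amplitude, which is how disorganised
(VF-like) activity is recognised as unanalyzable.

Index conventions are 0-based.  Pulses tile the inter-valley span with a
shared-endpoint rule: each valley sample belongs both to the pulse it ends
and to the pulse it starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import Segment

__all__ = [
    "DelineateConfig",
    "PulseMarkers",
    "Pulse",
    "detect_valleys",
    "detect_peaks",
    "locate_notch",
    "delineate_segment",
    "segment_pulses",
    "quality_mask",
]

#: per-pulse sentinel for "no notch found"
NO_NOTCH = -1


@dataclass(frozen=True)
class DelineateConfig:
    min_spacing_s: float = 0.25
    prominence_frac: float = 0.3
    slope_prom_frac: float = 0.05
    pi_bounds_s: tuple[float, float] = (0.25, 2.4)
    min_amp_frac: float = 0.10
    dip_prom_frac: float = 0.25
    min_valid_pulses: int = 3


DEFAULT_CONFIG = DelineateConfig()


@dataclass
class PulseMarkers:
    """Landmark indices for one segment: valleys, peaks and notch bounds.

    All arrays are segment-relative sample indices; ``notch_start_idx`` and
    ``notch_end_idx`` use -1 for pulses without a detectable notch.
    """

    valley_idx: np.ndarray
    peak_idx: np.ndarray
    notch_start_idx: np.ndarray
    notch_end_idx: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.valley_idx = np.asarray(self.valley_idx, dtype=int)
        self.peak_idx = np.asarray(self.peak_idx, dtype=int)
        self.notch_start_idx = np.asarray(self.notch_start_idx, dtype=int)
        self.notch_end_idx = np.asarray(self.notch_end_idx, dtype=int)
        if self.valley_idx.size and np.any(np.diff(self.valley_idx) <= 0):
            raise ValueError("valley indices must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return max(0, self.valley_idx.size - 1)


@dataclass
class Pulse:
    """One delineated pulse cut from its parent segment."""

    samples: np.ndarray
    fs: float
    onset_idx_in_segment: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 3:
            raise ValueError("a pulse needs at least 3 samples")


def detect_valleys(
    seg: Segment,
    min_spacing_s: float = DEFAULT_CONFIG.min_spacing_s,
    prominence_frac: float = DEFAULT_CONFIG.prominence_frac,
) -> np.ndarray:
    """Prominence-gated local-minima search.

    Only minima whose prominence exceeds ``prominence_frac`` of the
    segment's amplitude range are kept, with a refractory spacing of
    ``min_spacing_s``.  The signal is padded at the left end so a pulse
    onset falling exactly on the segment start is detectable; a boundary at
    the segment end belongs to the following segment's first sample.
    """
    if min_spacing_s <= 0:
        raise ValueError("min_spacing_s must be positive")
    x = seg.samples
    rng = float(x.max() - x.min())
    if rng == 0:
        return np.array([], dtype=int)
    xp = np.concatenate([[x[0] + rng], x])
    distance = max(1, round(min_spacing_s * seg.fs))
    idx, _ = sps.find_peaks(-xp, prominence=prominence_frac * rng, distance=distance)
    return idx - 1


def detect_peaks(seg: Segment, valleys: np.ndarray) -> np.ndarray:
    """One systolic peak per inter-valley span: the global maximum strictly inside."""
    valleys = np.asarray(valleys, dtype=int)
    if valleys.size < 2:
        return np.array([], dtype=int)
    peaks = []
    for a, b in zip(valleys[:-1], valleys[1:]):
        inner = seg.samples[a + 1 : b]
        peaks.append(a + 1 + int(np.argmax(inner)))
    return np.array(peaks, dtype=int)


def _light_smooth(x: np.ndarray, fs: float) -> np.ndarray:
    win = max(3, round(0.02 * fs))
    if win % 2 == 0:
        win += 1
    if win >= x.size:
        return x
    kernel = np.ones(win) / win
    return np.convolve(np.pad(x, win // 2, mode="edge"), kernel, mode="valid")


def locate_notch(
    pulse: np.ndarray | Pulse,
    peak_idx: int,
    fs: float | None = None,
    slope_prom_frac: float = DEFAULT_CONFIG.slope_prom_frac,
) -> tuple[int, int] | None:
    """Locate the dicrotic notch on the post-systolic limb, or return None.

    A genuine notch implies a re-acceleration of the waveform after the
    systolic decline: the first derivative must show an interior local
    maximum after the peak.  When one exists, the notch start is placed at
    the maximum of the second derivative (onset of the concavity change)
    between the peak and that re-acceleration point, and the notch end at
    the following minimum of |first derivative| — the diastolic crest, or
    the end of the inflection when the diastolic wave is only a shoulder.
    A smooth monotone decline (no diastolic wave) yields None.
    """
    if isinstance(pulse, Pulse):
        fs = pulse.fs
        x = pulse.samples
    else:
        x = np.asarray(pulse, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a raw array")
    n = x.size
    if not (0 < peak_idx < n - 1):
        raise ValueError("peak index must lie strictly inside the pulse")
    sm = _light_smooth(x, fs)
    d1 = np.gradient(sm)
    d2 = np.gradient(d1)
    # interior local maxima of d1 after the peak = re-acceleration candidates
    search = d1[peak_idx + 1 : n - 1]
    if search.size < 3:
        return None
    gate = slope_prom_frac * float(np.max(np.abs(d1)))
    cand, _ = sps.find_peaks(search, prominence=max(gate, 1e-12))
    if cand.size == 0:
        return None
    m = peak_idx + 1 + int(cand[0])
    # notch start: strongest concave-up curvature between peak and the
    # re-acceleration point
    lo = peak_idx + 1
    notch_start = lo + int(np.argmax(d2[lo : m + 1]))
    # notch end: first local minimum of |d1| at or after m (zero crossing at
    # the diastolic crest, or the flattest point of a shoulder)
    absd1 = np.abs(d1)
    notch_end = m
    for j in range(m, n - 1):
        if absd1[j] <= absd1[j - 1] and absd1[j] <= absd1[j + 1]:
            notch_end = j
            break
    if notch_end < notch_start:
        notch_end = notch_start
    return notch_start, notch_end


def delineate_segment(seg: Segment, cfg: DelineateConfig = DEFAULT_CONFIG) -> PulseMarkers:
    """Run valley, peak and notch detection on one segment."""
    valleys = detect_valleys(seg, cfg.min_spacing_s, cfg.prominence_frac)
    peaks = detect_peaks(seg, valleys)
    ns_idx, ne_idx = [], []
    for j in range(peaks.size):
        a, b = valleys[j], valleys[j + 1]
        res = locate_notch(seg.samples[a : b + 1], peaks[j] - a, seg.fs, cfg.slope_prom_frac)
        if res is None:
            ns_idx.append(NO_NOTCH)
            ne_idx.append(NO_NOTCH)
        else:
            ns_idx.append(a + res[0])
            ne_idx.append(a + res[1])
    return PulseMarkers(valleys, peaks, np.array(ns_idx), np.array(ne_idx), seg.fs)


def segment_pulses(seg: Segment, markers: PulseMarkers) -> list[Pulse]:
    """Cut one Pulse per consecutive valley pair (shared-endpoint tiling)."""
    pulses = []
    v = markers.valley_idx
    for j in range(markers.n_pulses):
        a, b = int(v[j]), int(v[j + 1])
        pulses.append(Pulse(seg.samples[a : b + 1].copy(), seg.fs, a))
    return pulses


def quality_mask(
    markers: PulseMarkers,
    seg: Segment,
    cfg: DelineateConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, bool]:
    """Per-pulse validity flags plus a segment-level analyzable flag.

    A pulse is rejected when its interval falls outside the physiological
    band, its amplitude is small relative to the segment range, or it
    contains a prominent interior trough (several oscillation cycles inside
    one "pulse" — the signature of disorganised VF-like activity surviving
    the spacing gate).  A segment is analyzable iff enough pulses are valid.
    """
    v = markers.valley_idx
    n_pulses = markers.n_pulses
    flags = np.zeros(n_pulses, dtype=bool)
    seg_range = float(seg.samples.max() - seg.samples.min())
    lo_pi, hi_pi = cfg.pi_bounds_s
    for j in range(n_pulses):
        a, b = int(v[j]), int(v[j + 1])
        pi = (b - a) / markers.fs
        if not (lo_pi <= pi <= hi_pi):
            continue
        pulse = seg.samples[a : b + 1]
        amp = float(pulse.max() - pulse.min())
        if seg_range > 0 and amp < cfg.min_amp_frac * seg_range:
            continue
        interior = pulse[1:-1]
        if interior.size >= 3 and amp > 0:
            troughs, _ = sps.find_peaks(-interior, prominence=cfg.dip_prom_frac * amp)
            if troughs.size > 0:
                continue
        flags[j] = True
    analyzable = int(flags.sum()) >= cfg.min_valid_pulses
    return flags, analyzable
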
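"""41-feature descriptor of a PPG segment.

The feature vector spans three families:

* morphological (26 slots) — per-pulse landmark measures (systolic/diastolic
  amplitudes and areas, systolic/diastolic times, pulse and peak-to-peak
  intervals, FWHM, notch time) aggregated over the segment's valid pulses by
  mean and sample standard deviation, plus the means of six shape ratios;
* statistical (7 slots) — moments, RMS, IQR and amplitude-histogram entropy
  of the raw segment samples;
* spectral (8 slots) — Welch-PSD descriptors: dominant frequency, implied
  heart rate, band powers, relative cardiac power, spectral entropy and
  centroid.

Segments without enough valid pulses (notably VF) receive fixed imputed
values for the morphological slots so every segment yields exactly 41
finite values and remains classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .delineate import (
    NO_NOTCH,
    DelineateConfig,
    DEFAULT_CONFIG,
    PulseMarkers,
    delineate_segment,
    quality_mask,
)
from .preprocess import Segment

__all__ = [
    "PulseFeatures",
    "FEATURE_NAMES",
    "MORPH_NAMES",
    "STAT_NAMES",
    "SPEC_NAMES",
    "pulse_measures",
    "aggregate_morphology",
    "statistical_features",
    "spectral_features",
    "feature_vector",
    "extract_features",
    "build_feature_table",
]

# Base per-pulse measures, in canonical order.
_BASE_MEASURES = ("sa", "da", "sys_area", "dia_area", "st", "dt", "pi", "ppi", "fwhm", "nt")
_RATIO_NAMES = (
    "ratio_da_sa",
    "ratio_dia_sys_area",
    "ratio_dt_st",
    "ratio_st_pi",
    "ratio_fwhm_pi",
    "ratio_sa_st",
)

MORPH_NAMES = tuple(
    f"{m}_{s}" for m in _BASE_MEASURES for s in ("mean", "sd")
) + tuple(f"{r}_mean" for r in _RATIO_NAMES)
STAT_NAMES = ("amp_mean", "amp_sd", "amp_skew", "amp_kurtosis", "amp_rms", "amp_iqr", "amp_entropy")
SPEC_NAMES = (
    "dom_freq_hz",
    "hr_est_bpm",
    "bp_0p5_2_hz",
    "bp_2_5_hz",
    "bp_5_10_hz",
    "rel_cardiac_power",
    "spec_entropy",
    "spec_centroid_hz",
)
#: Canonical ordered names of the 41 features.
FEATURE_NAMES: tuple[str, ...] = MORPH_NAMES + STAT_NAMES + SPEC_NAMES
assert len(FEATURE_NAMES) == 41


@dataclass
class PulseFeatures:
    """Landmark measures of one pulse; NaN encodes 'not available'."""

    sa: float  # systolic amplitude (peak minus onset)
    da: float  # diastolic amplitude (diastolic crest minus onset; 0 if no notch)
    sys_area: float  # area from onset to notch start, onset-baseline subtracted
    dia_area: float  # area from notch start to pulse end
    st: float  # systolic time: onset -> peak (s)
    dt: float  # diastolic time: peak -> pulse end (s)
    pi: float  # pulse interval: onset -> next onset (s)
    ppi: float  # peak-to-peak interval to the next pulse (s); NaN for the last pulse
    fwhm: float  # full width at half the systolic amplitude (s)
    nt: float  # notch time from onset (s); NaN when no notch


def _fwhm(x: np.ndarray, peak_rel: int, half_level: float, fs: float) -> float:
    """Width of the contiguous region around the peak where x >= half_level.

    Crossing positions are linearly interpolated between samples.
    """
    n = x.size
    # walk left
    i = peak_rel
    while i > 0 and x[i - 1] >= half_level:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        y0, y1 = x[i - 1], x[i]
        left = (i - 1) + (half_level - y0) / (y1 - y0)
    # walk right
    j = peak_rel
    while j < n - 1 and x[j + 1] >= half_level:
        j += 1
    if j == n - 1:
        right = float(n - 1)
    else:
        y0, y1 = x[j], x[j + 1]
        right = j + (y0 - half_level) / (y0 - y1)
    return (right - left) / fs


def pulse_measures(
    pulse: np.ndarray,
    peak_idx: int,
    notch_start_idx: int,
    notch_end_idx: int,
    fs: float,
    next_peak_dt_s: float = np.nan,
) -> PulseFeatures:
    """Compute the per-pulse landmark measures.

    ``pulse`` spans onset valley to the next valley inclusive; all indices
    are pulse-relative; ``notch_*_idx`` use -1 when no notch was found.
    ``next_peak_dt_s`` is the peak-to-peak interval supplied by the caller
    (NaN for the last pulse of a segment).
    """
    x = np.asarray(pulse, dtype=float)
    n = x.size
    if not (0 < peak_idx < n - 1):
        raise ValueError("peak index must lie strictly inside the pulse")
    onset_val = float(x[0])
    sa = float(x[peak_idx]) - onset_val
    pi = (n - 1) / fs
    st = peak_idx / fs
    dt = pi - st
    baseline = x - onset_val
    if notch_start_idx == NO_NOTCH:
        da = 0.0
        nt = np.nan
        sys_area = float(np.trapezoid(baseline, dx=1.0 / fs))
        dia_area = 0.0
    else:
        if not (peak_idx <= notch_start_idx <= notch_end_idx < n):
            raise ValueError("notch indices out of order")
        da = float(x[notch_end_idx]) - onset_val
        nt = notch_start_idx / fs
        sys_area = float(np.trapezoid(baseline[: notch_start_idx + 1], dx=1.0 / fs))
        dia_area = float(np.trapezoid(baseline[notch_start_idx:], dx=1.0 / fs))
    fwhm = _fwhm(x, peak_idx, onset_val + sa / 2.0, fs)
    return PulseFeatures(sa, da, sys_area, dia_area, st, dt, pi, next_peak_dt_s, fwhm, nt)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    """NaN-aware mean and sample SD (n-1); empty or singleton SD = 0."""
    v = values[~np.isnan(values)]
    if v.size == 0:
        return 0.0, 0.0
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return mean, sd


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = ~np.isnan(num) & ~np.isnan(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    out[~ok] = np.nan
    return out


def aggregate_morphology(pulse_feats: list[PulseFeatures]) -> np.ndarray:
    """Aggregate per-pulse measures into the 26 morphological slots.

    Mean and sample SD per base measure (NaN-coded values excluded from
    their own statistics), then the means of the six shape ratios.
    """
    if not pulse_feats:
        raise ValueError("aggregate_morphology requires at least one pulse")
    cols = {m: np.array([getattr(p, m) for p in pulse_feats], dtype=float) for m in _BASE_MEASURES}
    out: list[float] = []
    for m in _BASE_MEASURES:
        mean, sd = _mean_sd(cols[m])
        out.extend([mean, sd])
    ratios = [
        _safe_ratio(cols["da"], cols["sa"]),
        _safe_ratio(cols["dia_area"], cols["sys_area"]),
        _safe_ratio(cols["dt"], cols["st"]),
        _safe_ratio(cols["st"], cols["pi"]),
        _safe_ratio(cols["fwhm"], cols["pi"]),
        _safe_ratio(cols["sa"], cols["st"]),
    ]
    for r in ratios:
        out.append(_mean_sd(r)[0])
    return np.array(out)


def statistical_features(seg: Segment, n_bins: int = 16) -> np.ndarray:
    """Mean, SD, skewness, excess kurtosis, RMS, IQR and histogram entropy."""
    x = seg.samples
    if x.size == 0:
        raise ValueError("empty segment")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd == 0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess (Fisher)
    rms = float(np.sqrt(np.mean(x**2)))
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log(p)).sum())
    return np.array([float(x.mean()), sd, skew, kurt, rms, iqr, entropy])


def _band_power(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def spectral_features(seg: Segment, welch_window_s: float = 4.0) -> np.ndarray:
    """Welch-PSD descriptors (Hann taper, 50% overlap).

    Dominant frequency is searched in [0.5, 10] Hz; band powers, relative
    cardiac power, spectral entropy and centroid are computed on the
    [0.05, 15] Hz support.
    """
    x = seg.samples
    fs = seg.fs
    if x.size < round(2.0 * fs):
        raise ValueError("segment too short for spectral features (< 2 s)")
    nperseg = min(x.size, round(welch_window_s * fs))
    f, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    dom_mask = (f >= 0.5) & (f <= 10.0)
    dom_freq = float(f[dom_mask][np.argmax(psd[dom_mask])])
    hr_est = 60.0 * dom_freq
    bp1 = _band_power(f, psd, 0.5, 2.0)
    bp2 = _band_power(f, psd, 2.0, 5.0)
    bp3 = _band_power(f, psd, 5.0, 10.0)
    total = _band_power(f, psd, 0.05, 15.0)
    cardiac = _band_power(f, psd, 0.5, 5.0)
    rel_cardiac = cardiac / total if total > 0 else 0.0
    wide = (f >= 0.05) & (f <= 15.0)
    pw = psd[wide]
    if pw.sum() > 0:
        p = pw / pw.sum()
        pnz = p[p > 0]
        spec_entropy = float(-(pnz * np.log(pnz)).sum())
        centroid = float((f[wide] * p).sum())
    else:
        spec_entropy = 0.0
        centroid = 0.0
    return np.array([dom_freq, hr_est, bp1, bp2, bp3, rel_cardiac, spec_entropy, centroid])


def _imputed_morphology(seg_duration_s: float) -> np.ndarray:
    """Fixed morphological slots for unanalyzable segments.

    Amplitude- and area-like slots and all SDs are 0; the interval slots
    (PI, PPI) take the segment duration — an out-of-physiological-band
    constant that marks 'no organised pulses'.
    """
    out = np.zeros(len(MORPH_NAMES))
    names = list(MORPH_NAMES)
    out[names.index("pi_mean")] = seg_duration_s
    out[names.index("ppi_mean")] = seg_duration_s
    return out


def _morphology_from_markers(
    seg: Segment, markers: PulseMarkers, valid: np.ndarray
) -> np.ndarray:
    v = markers.valley_idx
    peak_times = markers.peak_idx / markers.fs
    feats: list[PulseFeatures] = []
    for j in range(markers.n_pulses):
        if not valid[j]:
            continue
        a, b = int(v[j]), int(v[j + 1])
        ppi = peak_times[j + 1] - peak_times[j] if j + 1 < markers.n_pulses else np.nan
        ns = markers.notch_start_idx[j]
        ne = markers.notch_end_idx[j]
        feats.append(
            pulse_measures(
                seg.samples[a : b + 1],
                int(markers.peak_idx[j]) - a,
                int(ns) - a if ns != NO_NOTCH else NO_NOTCH,
                int(ne) - a if ne != NO_NOTCH else NO_NOTCH,
                markers.fs,
                ppi,
            )
        )
    return aggregate_morphology(feats)


def feature_vector(
    seg: Segment,
    markers: PulseMarkers | None = None,
    cfg: DelineateConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """The full ordered 41-value descriptor of one segment.

    Delineation is run when markers are not supplied.  Morphological slots
    are imputed when the segment is not analyzable; statistical and spectral
    slots are always computed from the samples.
    """
    if markers is None:
        markers = delineate_segment(seg, cfg)
    valid, analyzable = quality_mask(markers, seg, cfg)
    if analyzable:
        morph = _morphology_from_markers(seg, markers, valid)
    else:
        morph = _imputed_morphology(seg.duration_s)
    vec = np.concatenate([morph, statistical_features(seg), spectral_features(seg)])
    assert vec.size == 41 and np.all(np.isfinite(vec))
    return vec


def extract_features(
    segments: list[Segment],
    cfg: DelineateConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature table for a list of segments: provenance + label + 41 columns."""
    rows = []
    for seg in segments:
        vec = feature_vector(seg, cfg=cfg)
        row = {"record_id": seg.source_record_id, "start_s": seg.start_s, "label": seg.label}
        row.update(dict(zip(FEATURE_NAMES, vec)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["record_id", "start_s", "label", *FEATURE_NAMES])


def build_feature_table(
    records,
    preproc_cfg=None,
    delineate_cfg: DelineateConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Preprocess + delineate + featurize a list of synthetic records."""
    from .preprocess import PreprocConfig, Waveform, preprocess_record

    preproc_cfg = preproc_cfg or PreprocConfig()
    frames = []
    for rec in records:
        segs = preprocess_record(
            Waveform(rec.samples, rec.fs), preproc_cfg, rec.record_id or "", rec.label
        )
        frames.append(extract_features(segs, delineate_cfg))
    return pd.concat(frames, ignore_index=True)
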
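"""Synthetic photoplethysmogram (PPG) generator with rhythm-class conditioning.

Produces labelled PPG-like records for five rhythm classes — normal sinus
rhythm, bradycardia, tachycardia, ventricular tachycardia (VT) and
ventricular flutter/fibrillation (VF) — together with ground-truth beat
onsets, so that downstream pulse delineation can be validated against a
known answer.

Pulsatile classes are built beat by beat: each pulse is the sum of a
systolic Gaussian wave and a diastolic wave (Gaussian rise to the crest,
exponential windkessel-like runoff after it), which reproduces the systolic
peak / dicrotic notch / diastolic wave geometry while keeping the waveform
falling until the next upstroke.  Pulses are laid down on disjoint
consecutive supports, and sinusoidal baseline wander plus white noise are
added on top.
VT is distinguished by a high rate, a strongly diminished diastolic wave and
large beat-to-beat amplitude variability.  VF has no organised pulses at
all: it is modelled as a low-amplitude oscillation whose instantaneous
frequency random-walks inside a 4-7 Hz band with slow amplitude modulation.

Every generator output is a pure function of its arguments including the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "PULSATILE_LABELS",
    "RhythmSpec",
    "NoiseSpec",
    "PulseShape",
    "SynthRecord",
    "DatasetManifest",
    "DEFAULT_SPECS",
    "DEFAULT_NOISE",
    "NOISE_FREE",
    "make_pulse",
    "synth_pulsatile_record",
    "synth_vf_record",
    "synth_record",
    "generate_records",
    "generate_dataset",
]

CLASS_LABELS = ("normal", "bradycardia", "tachycardia", "vt", "vf")
PULSATILE_LABELS = ("normal", "bradycardia", "tachycardia", "vt")


@dataclass(frozen=True)
class PulseShape:
    """Relative geometry of the two Gaussian component waves of one pulse.

    Positions and widths are fractions of the pulse interval, so the same
    morphology is produced at any heart rate.
    """

    systolic_center_frac: float = 0.20
    systolic_width_frac: float = 0.08
    diastolic_center_frac: float = 0.45
    diastolic_width_frac: float = 0.12
    runoff_tau_frac: float = 0.23

    def __post_init__(self) -> None:
        if self.systolic_width_frac <= 0 or self.diastolic_width_frac <= 0:
            raise ValueError("component widths must be positive")
        if self.runoff_tau_frac <= 0:
            raise ValueError("runoff time constant must be positive")


DEFAULT_SHAPE = PulseShape()


@dataclass(frozen=True)
class RhythmSpec:
    """Class-conditional generation parameters for one rhythm class.

    notch_rel_amp is the diastolic-wave amplitude relative to the systolic
    one (A2/A1); jitter fractions are standard deviations of the
    multiplicative beat-to-beat variability.  vf_freq_range_hz is used only
    for the vf class.
    """

    class_label: str
    hr_range_bpm: tuple[float, float]
    pi_jitter_frac: float = 0.0
    amp_jitter_frac: float = 0.0
    notch_rel_amp: float = 0.45
    vf_freq_range_hz: tuple[float, float] = (4.0, 7.0)
    vf_amp_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        lo, hi = self.hr_range_bpm
        if lo <= 0 or hi < lo:
            raise ValueError("hr_range_bpm must satisfy 0 < lo <= hi")
        if not (0.0 <= self.notch_rel_amp <= 1.0):
            raise ValueError("notch_rel_amp must lie in [0, 1]")
        if not (0.0 <= self.pi_jitter_frac < 0.5 and 0.0 <= self.amp_jitter_frac < 0.5):
            raise ValueError("jitter fractions must lie in [0, 0.5)")
        flo, fhi = self.vf_freq_range_hz
        if flo <= 0 or fhi < flo:
            raise ValueError("vf_freq_range_hz must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances: baseline wander, white noise, optional spikes.

    wander_amp_frac is relative to the record's nominal systolic amplitude
    (1.0 for pulsatile classes, vf_amp_scale for VF).  snr_db = None disables
    the white-noise term entirely.
    """

    snr_db: float | None = 20.0
    wander_freq_hz: float = 0.2
    wander_amp_frac: float = 0.5
    spike_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.wander_freq_hz < 0.5):
            raise ValueError("wander_freq_hz must lie in (0, 0.5)")
        if self.wander_amp_frac < 0 or self.spike_rate_per_min < 0:
            raise ValueError("wander amplitude and spike rate must be >= 0")


DEFAULT_NOISE = NoiseSpec()
#: Disturbance-free variant used for delineation ground-truth checks.
NOISE_FREE = NoiseSpec(snr_db=None, wander_amp_frac=0.0)

DEFAULT_SPECS: dict[str, RhythmSpec] = {
    "normal": RhythmSpec("normal", (60.0, 100.0), 0.04, 0.05, 0.45),
    "bradycardia": RhythmSpec("bradycardia", (30.0, 50.0), 0.04, 0.05, 0.45),
    "tachycardia": RhythmSpec("tachycardia", (110.0, 140.0), 0.03, 0.05, 0.45),
    "vt": RhythmSpec("vt", (140.0, 220.0), 0.06, 0.20, 0.10),
    "vf": RhythmSpec("vf", (60.0, 100.0), 0.0, 0.0, 0.0, (4.0, 7.0), 0.3),
}


@dataclass
class SynthRecord:
    """One synthetic record: waveform, sampling rate, label and ground truth."""

    samples: np.ndarray
    fs: float
    duration_s: float
    label: str
    beat_onsets_s: np.ndarray
    seed: int
    record_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.beat_onsets_s = np.asarray(self.beat_onsets_s, dtype=float)
        if len(self.samples) != round(self.fs * self.duration_s):
            raise ValueError("sample count inconsistent with fs * duration")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.beat_onsets_s.size:
            if np.any(np.diff(self.beat_onsets_s) <= 0):
                raise ValueError("beat onsets must be strictly increasing")
            if self.beat_onsets_s[0] < 0 or self.beat_onsets_s[-1] >= self.duration_s:
                raise ValueError("beat onsets must lie in [0, duration)")


@dataclass
class DatasetManifest:
    """Index of a generated dataset: one entry per record plus bookkeeping."""

    records: list[dict]
    global_seed: int
    per_class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r["record_id"] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("record ids must be unique")
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r["label"]] = counts.get(r["label"], 0) + 1
        if not self.per_class_counts:
            self.per_class_counts = counts
        elif self.per_class_counts != counts:
            raise ValueError("per_class_counts inconsistent with records")

    def to_dict(self) -> dict:
        return {
            "global_seed": self.global_seed,
            "per_class_counts": dict(sorted(self.per_class_counts.items())),
            "records": self.records,
        }


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def make_pulse(
    pi_s: float,
    a1: float,
    a2: float,
    fs: float,
    shape: PulseShape = DEFAULT_SHAPE,
) -> np.ndarray:
    """Build one PPG pulse of duration ``pi_s`` as a two-Gaussian sum.

    The systolic wave (amplitude ``a1``) is centred at 0.20*PI and the
    diastolic wave (amplitude ``a2``) at 0.45*PI by default; both component
    widths scale with the pulse interval, so the shape is rate-invariant.
    Past its crest the diastolic wave decays exponentially (time constant
    ``runoff_tau_frac``*PI) — the windkessel-like diastolic runoff that
    keeps the waveform falling until the next upstroke, so the inter-pulse
    trough is V-shaped rather than flat.  The values at the pulse
    boundaries stay below 5% of a1, keeping the foot sharp when pulses are
    concatenated.
    """
    if pi_s <= 0:
        raise ValueError("pi_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = round(pi_s * fs)
    t = np.arange(n) / fs
    sys_wave = a1 * _gauss(t, shape.systolic_center_frac * pi_s, shape.systolic_width_frac * pi_s)
    c2 = shape.diastolic_center_frac * pi_s
    dia_wave = a2 * _gauss(t, c2, shape.diastolic_width_frac * pi_s)
    tail = t > c2
    dia_wave[tail] = a2 * np.exp(-(t[tail] - c2) / (shape.runoff_tau_frac * pi_s))
    return sys_wave + dia_wave


def _add_disturbances(
    clean: np.ndarray,
    fs: float,
    noise: NoiseSpec,
    ref_amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add baseline wander, white noise at the requested SNR, and spikes."""
    n = clean.size
    t = np.arange(n) / fs
    out = clean.copy()
    if noise.wander_amp_frac > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += noise.wander_amp_frac * ref_amp * np.sin(2.0 * np.pi * noise.wander_freq_hz * t + phase)
    if noise.snr_db is not None:
        p_signal = float(np.mean(clean**2))
        if p_signal > 0:
            sigma = np.sqrt(p_signal / 10.0 ** (noise.snr_db / 10.0))
            out += rng.normal(0.0, sigma, n)
    if noise.spike_rate_per_min > 0:
        n_spikes = rng.poisson(noise.spike_rate_per_min * n / fs / 60.0)
        for _ in range(n_spikes):
            i = rng.integers(0, n)
            out[i] += rng.choice([-1.0, 1.0]) * 2.0 * ref_amp
    return out


def synth_pulsatile_record(
    spec: RhythmSpec,
    noise: NoiseSpec = DEFAULT_NOISE,
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed: int = 0,
    shape: PulseShape = DEFAULT_SHAPE,
) -> SynthRecord:
    """Generate a pulsatile record (any class except vf).

    The base heart rate is drawn once per record, uniformly within the
    class's HR range; individual pulse intervals jitter multiplicatively
    around 60/HR.  Pulses are placed on consecutive disjoint supports and
    only complete pulses are emitted, so the last beat onset always leaves
    room for a full pulse before the record end.
    """
    if spec.class_label == "vf":
        raise ValueError("use synth_vf_record for the vf class")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    hr = rng.uniform(*spec.hr_range_bpm)
    mean_pi = 60.0 / hr
    n_total = round(duration_s * fs)
    samples = np.zeros(n_total)
    onsets_s: list[float] = []
    cursor = 0
    while True:
        pi = mean_pi * (1.0 + rng.normal(0.0, spec.pi_jitter_frac)) if spec.pi_jitter_frac > 0 else mean_pi
        pi = float(np.clip(pi, 0.5 * mean_pi, 1.5 * mean_pi))
        n_pulse = round(pi * fs)
        if n_pulse < 3 or cursor + n_pulse > n_total:
            break
        amp = 1.0 + rng.normal(0.0, spec.amp_jitter_frac) if spec.amp_jitter_frac > 0 else 1.0
        amp = float(np.clip(amp, 0.2, 2.0))
        pulse = make_pulse(n_pulse / fs, amp, amp * spec.notch_rel_amp, fs, shape)
        samples[cursor : cursor + len(pulse)] = pulse
        onsets_s.append(cursor / fs)
        cursor += n_pulse
    samples = _add_disturbances(samples, fs, noise, ref_amp=1.0, rng=rng)
    return SynthRecord(samples, fs, duration_s, spec.class_label, np.array(onsets_s), seed)


def synth_vf_record(
    spec: RhythmSpec,
    noise: NoiseSpec = DEFAULT_NOISE,
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed: int = 0,
    am_depth: float = 0.3,
    am_freq_hz: float = 0.3,
) -> SynthRecord:
    """Generate a ventricular flutter/fibrillation record.

    The waveform is a quasi-sinusoidal oscillation whose instantaneous
    frequency performs a reflected random walk inside
    ``spec.vf_freq_range_hz``, with slow sinusoidal amplitude modulation
    (envelope between (1 - am_depth) and 1 times ``spec.vf_amp_scale``).
    No beat onsets are annotated: VF has no organised pulses.
    """
    if spec.class_label != "vf":
        raise ValueError("synth_vf_record requires a vf RhythmSpec")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    flo, fhi = spec.vf_freq_range_hz
    if fhi > flo:
        # Reflected random walk for the instantaneous frequency: drift scale
        # chosen so the band is traversed over a few seconds.
        step = (fhi - flo) * 0.5 / fs
        walk = flo + np.cumsum(rng.normal(0.0, step, n)) + rng.uniform(0.0, fhi - flo)
        span = fhi - flo
        walk = np.abs((walk - flo) % (2 * span) - span) + flo  # reflect into [flo, fhi]
        freq = walk
    else:
        freq = np.full(n, flo)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    phase = phase0 + 2.0 * np.pi * np.cumsum(freq) / fs
    envelope = 1.0 - 0.5 * am_depth * (1.0 + np.sin(2.0 * np.pi * am_freq_hz * t + rng.uniform(0.0, 2.0 * np.pi)))
    samples = spec.vf_amp_scale * envelope * np.sin(phase)
    samples = _add_disturbances(samples, fs, noise, ref_amp=spec.vf_amp_scale, rng=rng)
    return SynthRecord(samples, fs, duration_s, "vf", np.array([]), seed)


def synth_record(
    spec: RhythmSpec,
    noise: NoiseSpec = DEFAULT_NOISE,
    duration_s: float = 300.0,
    fs: float = 250.0,
    seed: int = 0,
) -> SynthRecord:
    """Dispatch to the pulsatile or VF generator based on the class label."""
    if spec.class_label == "vf":
        return synth_vf_record(spec, noise, duration_s, fs, seed)
    return synth_pulsatile_record(spec, noise, duration_s, fs, seed)


def _record_seed(global_seed: int, index: int) -> int:
    """Reproducible, platform-stable per-record seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_records(
    per_class_n: int,
    duration_s: float = 300.0,
    fs: float = 250.0,
    global_seed: int = 0,
    specs: dict[str, RhythmSpec] | None = None,
    noise: NoiseSpec = DEFAULT_NOISE,
) -> list[SynthRecord]:
    """Generate ``per_class_n`` records per class, in memory.

    Record ids are ``<label>_<k>``; per-record seeds are derived from the
    global seed via a SeedSequence so the streams are independent yet fully
    reproducible.
    """
    if per_class_n < 1:
        raise ValueError("per_class_n must be >= 1")
    specs = dict(DEFAULT_SPECS) if specs is None else specs
    missing = set(CLASS_LABELS) - set(specs)
    if missing:
        raise ValueError(f"specs missing classes: {sorted(missing)}")
    records: list[SynthRecord] = []
    index = 0
    for label in CLASS_LABELS:
        for k in range(per_class_n):
            seed = _record_seed(global_seed, index)
            rec = synth_record(specs[label], noise, duration_s, fs, seed)
            rec.record_id = f"{label}_{k:03d}"
            records.append(rec)
            index += 1
    return records


def generate_dataset(
    out_dir: str | Path,
    per_class_n: int,
    duration_s: float = 300.0,
    fs: float = 250.0,
    global_seed: int = 0,
    specs: dict[str, RhythmSpec] | None = None,
    noise: NoiseSpec = DEFAULT_NOISE,
) -> DatasetManifest:
    """Generate a balanced dataset and write it to ``out_dir``.

    Each record is stored as a two-column text waveform (time_s, amplitude)
    plus a CSV sidecar of ground-truth beat onsets; a JSON manifest indexes
    the whole dataset.
    """
    from . import io as ppgio  # local import to avoid a cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_records(per_class_n, duration_s, fs, global_seed, specs, noise)
    entries = []
    for rec in records:
        wave_path = out_dir / f"{rec.record_id}.txt"
        onset_path = out_dir / f"{rec.record_id}.onsets.csv"
        ppgio.write_two_column(wave_path, rec.samples, rec.fs)
        ppgio.write_onsets(onset_path, rec.beat_onsets_s)
        entries.append(
            {
                "record_id": rec.record_id,
                "label": rec.label,
                "seed": rec.seed,
                "path": wave_path.name,
                "onsets_path": onset_path.name,
            }
        )
    manifest = DatasetManifest(entries, global_seed)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
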
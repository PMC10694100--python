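"""Synthetic circular-mapping-catheter recordings with known beat classes.

The simulator emulates what the discrimination task actually exploits, not
tissue biophysics.  Each beat is a superposition of Gabor atoms
(Gaussian-envelope sinusoids):

* the **atrial farfield** (FF) is a broad, low-frequency atom (default
  80 Hz centre, 70 ms support) present on *all* eight bipoles with a mild
  spatial decay away from a random reference bipole — distant sources look
  almost the same everywhere on the loop;
* the **pulmonary-vein nearfield** (NF) is a short, sharp atom (default
  220 Hz centre, 58 ms support) on one active bipole with a steep decay to
  its ring neighbours — a local source has high spatial resolution;
* **combined** beats superimpose both, the NF delayed relative to the FF
  onset (default 36 ms, annotated duration about 94 ms), as seen at the
  start of a cryoballoon freeze before conduction into the vein slows;
* white noise plus a common-mode 50 Hz mains component sit on top.

A freeze cycle strings beats together with a growing NF delay and, from the
isolation beat on, pure farfield — the temporal pattern used to ground-truth
the labels clinically.  Per-patient and per-beat RNG substreams make
datasets reproducible and extensible from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    VEINS,
    BeatAnnotation,
    Recording,
    read_annotations,
    read_recording,
    write_annotations,
    write_recording_csv,
    write_recording_edf,
)

__all__ = [
    "WaveletParams",
    "CombinedParams",
    "NoiseParams",
    "BeatModelParams",
    "FreezeCycleParams",
    "overlap_heavy_params",
    "generate_beat",
    "generate_freeze_cycle",
    "generate_dataset",
    "load_dataset",
    "DEFAULT_CLASS_MIX",
]

#: class mix of the reference clinical dataset (163 FF-only, 83 NF-only,
#: 89 combined of 335 beats)
DEFAULT_CLASS_MIX = {"atrial-FF": 163 / 335, "PV-NF": 83 / 335, "combined": 89 / 335}


@dataclass
class WaveletParams:
    """One Gabor atom: centre frequency, support and ring-decay profile.

    ``duration_ms`` is the atom's support (+-3 sigma of the Gaussian
    envelope); ``spatial_decay_per_channel`` multiplies the amplitude per
    ring step away from the source bipole.
    """

    center_freq_hz: float
    duration_ms: float
    amplitude_mv: float
    spatial_decay_per_channel: float
    active_channel: Optional[int] = None

    def validate(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if not (0 < self.spatial_decay_per_channel <= 1):
            raise ValueError("spatial_decay_per_channel must lie in (0, 1]")
        if self.amplitude_mv < 0:
            raise ValueError("amplitude_mv must be non-negative")


@dataclass
class CombinedParams:
    nf_delay_ms: float = 36.0  # FF onset to NF onset; 36 + 58 = 94 ms window
    overlap: bool = True


@dataclass
class NoiseParams:
    white_rms_mv: float = 0.02
    mains_50hz_mv: float = 0.01
    mains_freq_hz: float = 50.0


@dataclass
class BeatModelParams:
    """Everything needed to synthesise one beat of any class."""

    ff: WaveletParams = field(
        default_factory=lambda: WaveletParams(80.0, 70.0, 0.3, 0.95)
    )
    nf: WaveletParams = field(
        default_factory=lambda: WaveletParams(220.0, 58.0, 0.5, 0.4)
    )
    combined: CombinedParams = field(default_factory=CombinedParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    amplitude_jitter_sigma: float = 0.35  # log-normal sigma of per-beat gain
    duration_jitter_sigma: float = 0.12  # log-normal sigma of per-beat duration
    n_channels: int = 8
    fs: float = 2000.0
    pre_ms: float = 120.0  # quiet margin before the beat (noise-gate baseline)
    post_ms: float = 120.0

    def validate(self) -> None:
        self.ff.validate()
        self.nf.validate()
        if self.combined.nf_delay_ms < 0:
            raise ValueError("nf_delay_ms must be non-negative")
        if self.n_channels < 3:
            raise ValueError("need at least 3 bipoles on the loop")


def overlap_heavy_params(base: BeatModelParams | None = None) -> BeatModelParams:
    """The hard difficulty: weak nearfield fully buried in the farfield.

    The NF amplitude drops to a fifth of the default, its delay is centred
    at zero so FF and NF superimpose temporally, and per-beat gain jitter
    widens — the class-conditional high-band power distributions then
    overlap instead of separating cleanly.
    """
    base = base or BeatModelParams()
    return replace(
        base,
        nf=replace(base.nf, amplitude_mv=base.nf.amplitude_mv * 0.2),
        combined=replace(base.combined, nf_delay_ms=0.0),
        amplitude_jitter_sigma=0.6,
    )


def _ring_distance(i: np.ndarray, j: int, k: int) -> np.ndarray:
    d = np.abs(i - j)
    return np.minimum(d, k - d)


def _gabor(
    t: np.ndarray, t0_ms: float, wp: WaveletParams, phase: float, gain: float
) -> np.ndarray:
    """Gaussian-envelope sinusoid centred mid-support, truncated at +-3 sigma."""
    center = t0_ms + wp.duration_ms / 2.0
    sigma = wp.duration_ms / 6.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    env[np.abs(t - center) > 3.0 * sigma] = 0.0
    return gain * wp.amplitude_mv * env * np.sin(
        2e-3 * np.pi * wp.center_freq_hz * (t - t0_ms) + phase
    )


def generate_beat(
    class_label: str,
    params: BeatModelParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, float, int]:
    """Synthesise one multichannel beat segment.

    Returns ``(samples, onset_ms, offset_ms, nf_channel)`` where ``samples``
    has shape ``(n_channels, n)`` and the onset/offset tightly delimit the
    deterministic (wavelet) support of the beat within the segment.  The RNG
    consumes the same draws for every class, so e.g. a ``combined`` beat
    with FF amplitude forced to zero is sample-identical to the ``PV-NF``
    beat from the same generator state (the model is purely additive).
    """
    params = params or BeatModelParams()
    params.validate()
    rng = rng or np.random.default_rng()
    if class_label not in ("PV-NF", "atrial-FF", "combined"):
        raise ValueError(f"unknown beat class {class_label!r}")
    if class_label in ("PV-NF", "combined") and params.nf.amplitude_mv == 0:
        raise ValueError(f"{class_label} beat requires a nonzero nearfield amplitude")
    if class_label == "atrial-FF" and params.ff.amplitude_mv == 0:
        raise ValueError("atrial-FF beat requires a nonzero farfield amplitude")

    k = params.n_channels
    # identical draw sequence for every class (see docstring)
    ff_ref = int(rng.integers(k))
    ff_phase = float(rng.uniform(0, 2 * np.pi))
    nf_chan = (
        int(params.nf.active_channel)
        if params.nf.active_channel is not None
        else int(rng.integers(k))
    )
    if params.nf.active_channel is not None:
        rng.integers(k)  # keep the stream aligned
    nf_phase = float(rng.uniform(0, 2 * np.pi))
    # farfield and nearfield sources jitter independently: they arise from
    # different tissue with independent fibre geometry and contact
    gain_ff = float(rng.lognormal(0.0, params.amplitude_jitter_sigma))
    gain_nf = float(rng.lognormal(0.0, params.amplitude_jitter_sigma))
    dur_jit = float(rng.lognormal(0.0, params.duration_jitter_sigma))
    mains_phase = float(rng.uniform(0, 2 * np.pi))

    ff = replace(params.ff, duration_ms=params.ff.duration_ms * dur_jit)
    nf = replace(params.nf, duration_ms=params.nf.duration_ms * dur_jit)
    # the PV activation trails the atrial one by the same physiologic delay
    # whether or not a farfield is superimposed; this keeps the model purely
    # additive across classes for a fixed generator state
    delay = params.combined.nf_delay_ms
    ff_amp = ff.amplitude_mv if class_label in ("atrial-FF", "combined") else 0.0
    nf_amp = nf.amplitude_mv if class_label in ("PV-NF", "combined") else 0.0

    onset_ms = params.pre_ms + (delay if class_label == "PV-NF" else 0.0)
    support_end = {
        "atrial-FF": params.pre_ms + ff.duration_ms,
        "PV-NF": params.pre_ms + delay + nf.duration_ms,
        "combined": params.pre_ms + max(ff.duration_ms, delay + nf.duration_ms),
    }[class_label]
    total_ms = params.pre_ms + max(ff.duration_ms, delay + nf.duration_ms) + params.post_ms
    n = int(round(total_ms * params.fs / 1000.0))
    t = np.arange(n) / params.fs * 1000.0  # ms

    chan = np.arange(k)
    ff_gain = gain_ff * ff_amp / max(params.ff.amplitude_mv, 1e-30) \
        * params.ff.spatial_decay_per_channel ** _ring_distance(chan, ff_ref, k)
    nf_gain = gain_nf * nf_amp / max(params.nf.amplitude_mv, 1e-30) \
        * params.nf.spatial_decay_per_channel ** _ring_distance(chan, nf_chan, k)

    samples = np.zeros((k, n))
    ff_wave = _gabor(t, params.pre_ms, ff, ff_phase, 1.0)
    nf_wave = _gabor(t, params.pre_ms + delay, nf, nf_phase, 1.0)
    samples += ff_gain[:, None] * ff_wave[None, :]
    samples += nf_gain[:, None] * nf_wave[None, :]
    if params.noise.mains_50hz_mv > 0:
        samples += params.noise.mains_50hz_mv * np.sin(
            2e-3 * np.pi * params.noise.mains_freq_hz * t + mains_phase
        )[None, :]
    if params.noise.white_rms_mv > 0:
        samples += rng.normal(0.0, params.noise.white_rms_mv, size=(k, n))
    return samples, onset_ms, support_end, nf_chan


@dataclass
class FreezeCycleParams:
    """One cryoballoon freeze: combined beats with a growing NF delay, then
    pure atrial farfield from the isolation beat on."""

    n_beats: int = 10
    beat_interval_ms: float = 700.0
    initial_nf_delay_ms: float = 20.0
    delay_increment_per_beat_ms: float = 8.0
    isolation_beat_index: int = 6
    vein: str = "LSPV"
    patient_id: str = "P000"
    record_id: str = "freeze000"

    def validate(self) -> None:
        if not (0 <= self.isolation_beat_index <= self.n_beats):
            raise ValueError("isolation_beat_index must lie in [0, n_beats]")
        if self.delay_increment_per_beat_ms < 0:
            raise ValueError("delays must be non-decreasing over the cycle")


def generate_freeze_cycle(
    fp: FreezeCycleParams,
    bp: BeatModelParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, list[BeatAnnotation]]:
    """Simulate a freeze cycle as one recording plus its beat annotations."""
    fp.validate()
    bp = bp or BeatModelParams()
    rng = rng or np.random.default_rng()
    fs = bp.fs
    interval_n = int(round(fp.beat_interval_ms * fs / 1000.0))
    total_n = interval_n * fp.n_beats
    samples = np.zeros((bp.n_channels, total_n))
    annotations: list[BeatAnnotation] = []
    for i in range(fp.n_beats):
        if i < fp.isolation_beat_index:
            label, phase = "combined", "during"
            delay = fp.initial_nf_delay_ms + i * fp.delay_increment_per_beat_ms
            params_i = replace(bp, combined=replace(bp.combined, nf_delay_ms=delay))
        else:
            label, phase = "atrial-FF", "after"
            params_i = bp
        seg, onset_ms, offset_ms, _ = generate_beat(label, params_i, rng)
        if seg.shape[1] > interval_n:
            raise ValueError(
                f"beat support ({seg.shape[1] / fs * 1000:.0f} ms) exceeds the "
                f"beat interval ({fp.beat_interval_ms} ms)"
            )
        start = i * interval_n
        samples[:, start : start + seg.shape[1]] += seg
        shift_ms = start / fs * 1000.0
        annotations.append(
            BeatAnnotation(
                record_id=fp.record_id,
                patient_id=fp.patient_id,
                vein=fp.vein,
                phase=phase,
                onset_ms=shift_ms + onset_ms,
                offset_ms=shift_ms + offset_ms,
                label=label,
            )
        )
    rec = Recording(
        record_id=fp.record_id,
        fs=fs,
        channels=[f"CMC{j + 1}-{j + 2}" for j in range(bp.n_channels)],
        samples=samples,
    )
    return rec, annotations


def _exact_counts(mix: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder rounding of a class mix to exact integer counts."""
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"class_mix must sum to 1, got {sum(mix.values()):.6f}")
    raw = {c: p * total for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = total - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _normalise_mix(class_mix: dict[str, float]) -> dict[str, float]:
    """Accept either the three beat classes or a {nearfield, farfield} mix
    (nearfield split between PV-NF and combined as in the reference data)."""
    if set(class_mix) <= {"nearfield", "farfield"}:
        nf = class_mix.get("nearfield", 0.0)
        pv_frac = 83 / 172  # PV-NF share of nearfield-positive reference beats
        return {
            "atrial-FF": class_mix.get("farfield", 0.0),
            "PV-NF": nf * pv_frac,
            "combined": nf * (1 - pv_frac),
        }
    unknown = set(class_mix) - {"PV-NF", "atrial-FF", "combined"}
    if unknown:
        raise ValueError(f"unknown class_mix keys {sorted(unknown)}")
    return dict(class_mix)


@dataclass
class DatasetPaths:
    directory: Path
    annotations: Path
    recordings: list[Path]
    params: Path


def generate_dataset(
    out_dir: str | Path,
    n_patients: int = 28,
    beats_per_patient: int = 12,
    class_mix: dict[str, float] | None = None,
    difficulty: str = "separated",
    seed: int = 0,
    params: BeatModelParams | None = None,
    write_edf: bool = False,
) -> DatasetPaths:
    """Write a labelled multi-patient dataset to disk.

    One recording per patient (CSV+JSON dialect; EDF optionally as well),
    a single ``annotations.csv``, and the effective generator parameters as
    JSON.  ``difficulty`` is ``"separated"`` (defaults) or
    ``"overlap_heavy"`` (see :func:`overlap_heavy_params`).  Patients are
    independent RNG substreams of the master seed; identical seeds yield
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if difficulty == "separated":
        params = params or BeatModelParams()
    elif difficulty == "overlap_heavy":
        params = overlap_heavy_params(params)
    else:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    mix = _normalise_mix(class_mix or DEFAULT_CLASS_MIX)

    total = n_patients * beats_per_patient
    counts = _exact_counts(mix, total)
    labels = np.array(
        sum(([c] * n for c, n in sorted(counts.items())), []), dtype=object
    )
    master = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    assign_rng.shuffle(labels)

    interval_ms = 700.0
    interval_n = int(round(interval_ms * params.fs / 1000.0))
    annotations: list[BeatAnnotation] = []
    rec_paths: list[Path] = []
    patient_seeds = master.spawn(n_patients)
    for p in range(n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        patient_id = f"P{p:03d}"
        record_id = f"{patient_id}r0"
        samples = np.zeros((params.n_channels, interval_n * beats_per_patient))
        vein = None
        for b in range(beats_per_patient):
            label = str(labels[p * beats_per_patient + b])
            if b % 3 == 0:  # the catheter is repositioned every few beats
                vein = str(rng.choice(VEINS))
            if label == "atrial-FF":
                phase = str(rng.choice(("before", "during", "after")))
            else:
                phase = str(rng.choice(("before", "during")))
            seg, onset_ms, offset_ms, _ = generate_beat(label, params, rng)
            start = b * interval_n
            samples[:, start : start + seg.shape[1]] += seg
            shift_ms = start / params.fs * 1000.0
            dist = (
                float(np.round(rng.lognormal(np.log(8.0), 0.5), 1))
                if vein == "LSPV"
                else None
            )
            annotations.append(
                BeatAnnotation(
                    record_id=record_id,
                    patient_id=patient_id,
                    vein=vein,
                    phase=phase,
                    onset_ms=shift_ms + onset_ms,
                    offset_ms=shift_ms + offset_ms,
                    label=label,
                    laa_lspv_distance_mm=dist,
                )
            )
        rec = Recording(
            record_id=record_id,
            fs=params.fs,
            channels=[f"CMC{j + 1}-{j + 2}" for j in range(params.n_channels)],
            samples=samples,
        )
        path = write_recording_csv(rec, out_dir / f"{record_id}.csv")
        rec_paths.append(path)
        if write_edf:
            write_recording_edf(rec, out_dir / f"{record_id}.edf")

    ann_path = write_annotations(annotations, out_dir / "annotations.csv")
    params_path = out_dir / "generator_params.json"
    params_path.write_text(
        json.dumps(
            {
                "difficulty": difficulty,
                "seed": seed,
                "n_patients": n_patients,
                "beats_per_patient": beats_per_patient,
                "class_mix": mix,
                "params": dataclasses.asdict(params),
            },
            indent=2,
        )
        + "\n"
    )
    return DatasetPaths(out_dir, ann_path, rec_paths, params_path)


def load_dataset(directory: str | Path) -> tuple[dict[str, Recording], list[BeatAnnotation]]:
    """Read back a dataset directory written by :func:`generate_dataset`."""
    directory = Path(directory)
    recordings = {}
    for path in sorted(directory.glob("*.csv")):
        if path.name == "annotations.csv":
            continue
        rec = read_recording(path, format="csv")
        recordings[rec.record_id] = rec
    beats = read_annotations(
        directory / "annotations.csv",
        recording_durations={rid: r.duration_ms for rid, r in recordings.items()},
    )
    return recordings, beats
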
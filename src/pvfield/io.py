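"""Recording and beat-annotation I/O.

Signals travel either as EDF (the clinical interchange format) or as a
self-describing CSV dialect used for fixtures: one ``sample_index`` column
plus one column per bipole in millivolts, with a sidecar JSON file carrying
``{"record_id", "fs", "channel_names"}``.  Beat annotations are a flat CSV,
one row per delimited electrogram.

Channel order in a :class:`Recording` is the catheter-adjacency order of the
circular mapping catheter (CMC); downstream neighbour logic is defined solely
by this order, circularly closed.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "BeatAnnotation",
    "VEINS",
    "PHASES",
    "LABELS",
    "NEARFIELD_LABELS",
    "read_recording",
    "write_recording_csv",
    "write_recording_edf",
    "read_annotations",
    "write_annotations",
    "beat_sample_slice",
]

VEINS = ("LSPV", "LIPV", "RSPV", "RIPV")
PHASES = ("before", "during", "after")
LABELS = ("PV-NF", "atrial-FF", "combined")
#: labels counted as "nearfield component present" in the binary task
NEARFIELD_LABELS = ("PV-NF", "combined")


@dataclass
class Recording:
    """Multichannel bipolar electrogram block.

    Parameters
    ----------
    record_id : str
        Opaque identifier linking annotations to this recording.
    fs : float
        Sampling rate in Hz.
    channels : sequence of str
        Bipole names in catheter-adjacency order (circularly closed).
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel time series in millivolts.
    """

    record_id: str
    fs: float
    channels: Sequence[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(self.channels) < 2:
            raise ValueError("a bipolar recording needs at least 2 channels")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            ch = self.channels[int(np.argwhere(bad)[0, 0])]
            raise ValueError(f"non-finite amplitude in channel {ch!r}")
        self.channels = list(self.channels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def neighbors(self, index: int) -> tuple[int, int]:
        """Circular ring neighbours ``(i-1 mod K, i+1 mod K)`` of a bipole."""
        k = self.n_channels
        return ((index - 1) % k, (index + 1) % k)

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class BeatAnnotation:
    """One manually delimited electrogram on one recording.

    ``onset_ms``/``offset_ms`` are milliseconds from the first sample of the
    recording.  ``label`` follows the three-class scheme: ``PV-NF`` (local
    pulmonary-vein nearfield only), ``atrial-FF`` (atrial farfield only) or
    ``combined`` (superimposed farfield and nearfield).  After electrical
    isolation (phase ``after``) a nearfield component is absent by
    definition, so ``PV-NF`` and ``combined`` are invalid there.
    """

    record_id: str
    patient_id: str
    vein: str
    phase: str
    onset_ms: float
    offset_ms: float
    label: str
    laa_lspv_distance_mm: Optional[float] = None

    def validate(self, recording_duration_ms: Optional[float] = None) -> None:
        if self.vein not in VEINS:
            raise ValueError(f"unknown vein {self.vein!r} (expected one of {VEINS})")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r} (expected one of {PHASES})")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} (expected one of {LABELS})")
        if not (0 <= self.onset_ms < self.offset_ms):
            raise ValueError(
                f"need 0 <= onset < offset, got onset={self.onset_ms}, "
                f"offset={self.offset_ms}"
            )
        if recording_duration_ms is not None and self.offset_ms > recording_duration_ms:
            raise ValueError(
                f"offset {self.offset_ms} ms beyond recording end "
                f"({recording_duration_ms} ms)"
            )
        if self.phase == "after" and self.label in NEARFIELD_LABELS:
            raise ValueError(
                f"label {self.label!r} invalid in phase 'after': the nearfield "
                "is absent after isolation by definition"
            )
        if self.laa_lspv_distance_mm is not None and self.laa_lspv_distance_mm < 0:
            raise ValueError("laa_lspv_distance_mm must be non-negative")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def nearfield_present(self) -> bool:
        return self.label in NEARFIELD_LABELS


def beat_sample_slice(beat: BeatAnnotation, fs: float) -> slice:
    """Half-open sample window of a beat: floor(onset*fs) to ceil(offset*fs)."""
    start = int(np.floor(beat.onset_ms * fs / 1000.0))
    stop = int(np.ceil(beat.offset_ms * fs / 1000.0))
    return slice(start, stop)


# ---------------------------------------------------------------------------
# CSV + sidecar-JSON fixture dialect
# ---------------------------------------------------------------------------


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV plus a sidecar JSON metadata file.

    Floats are serialised with ``repr`` round-trip precision so that
    write -> read is bit-stable for all finite inputs.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {"sample_index": np.arange(rec.n_samples, dtype=int)}
        | {name: rec.samples[i] for i, name in enumerate(rec.channels)}
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {"record_id": rec.record_id, "fs": rec.fs, "channel_names": list(rec.channels)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def _read_recording_csv(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar metadata file {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta or meta["fs"] is None:
        raise ValueError(f"missing sampling rate in {sidecar}")
    frame = pd.read_csv(path, float_precision="round_trip")
    names = meta.get("channel_names")
    if names is None:
        names = [c for c in frame.columns if c != "sample_index"]
    missing = [c for c in names if c not in frame.columns]
    if missing:
        raise ValueError(f"channel {missing[0]!r} named in sidecar missing from CSV")
    if frame[names].isna().any().any():
        bad = frame[names].isna().any()
        ch = bad.index[bad.argmax()]
        raise ValueError(f"ragged channel lengths: channel {ch!r} has missing samples")
    samples = frame[names].to_numpy(dtype=float).T
    return Recording(
        record_id=str(meta.get("record_id", path.stem)),
        fs=float(meta["fs"]),
        channels=names,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _read_recording_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e3  # mne loads in volts; store millivolts
    return Recording(
        record_id=path.stem,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        samples=data,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a single-data-record EDF file.

    The writer emits plain EDF (one data record covering the whole signal,
    16-bit samples, physical unit mV).  Amplitude resolution is the physical
    range divided by 2^16, which is far below electrogram noise floors.
    """
    path = Path(path)
    k, n = rec.n_channels, rec.n_samples
    header_bytes = 256 * (1 + k)
    duration = n / rec.fs
    head = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field(f"Startdate X X X X {rec.record_id}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(header_bytes, 8),
            _edf_field("", 44),
            _edf_field(1, 8),  # one data record
            _edf_field(f"{duration:.6g}", 8),
            _edf_field(k, 4),
        ]
    )
    phys_min = np.minimum(rec.samples.min(axis=1), -1e-3)
    phys_max = np.maximum(rec.samples.max(axis=1), 1e-3)
    dig_min, dig_max = -32768, 32767
    per_sig = b"".join(
        [
            b"".join(_edf_field(c, 16) for c in rec.channels),
            b"".join(_edf_field("", 80) for _ in range(k)),
            b"".join(_edf_field("mV", 8) for _ in range(k)),
            b"".join(_edf_field(f"{lo:.6g}", 8) for lo in phys_min),
            b"".join(_edf_field(f"{hi:.6g}", 8) for hi in phys_max),
            b"".join(_edf_field(dig_min, 8) for _ in range(k)),
            b"".join(_edf_field(dig_max, 8) for _ in range(k)),
            b"".join(_edf_field("", 80) for _ in range(k)),
            b"".join(_edf_field(n, 8) for _ in range(k)),
            b"".join(_edf_field("", 32) for _ in range(k)),
        ]
    )
    # re-read the formatted physical range so the digital scaling matches the
    # truncated ASCII header fields exactly
    lo_hdr = np.array([float(f"{lo:.6g}") for lo in phys_min])
    hi_hdr = np.array([float(f"{hi:.6g}") for hi in phys_max])
    gain = (dig_max - dig_min) / (hi_hdr - lo_hdr)
    digital = np.rint((rec.samples - lo_hdr[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(head + per_sig)
        fh.write(digital.tobytes())  # channel-sequential within the record
    return path


def read_recording(path: str | Path, format: Optional[str] = None) -> Recording:
    """Read a recording from EDF or the CSV+JSON fixture dialect.

    Parameters
    ----------
    path : path-like
        Signal file.
    format : {"edf", "csv"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return _read_recording_csv(path)
    if format == "edf":
        return _read_recording_edf(path)
    raise ValueError(f"unknown recording format {format!r} (expected 'edf' or 'csv')")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "record_id",
    "patient_id",
    "vein",
    "phase",
    "onset_ms",
    "offset_ms",
    "label",
    "laa_lspv_distance_mm",
]


def read_annotations(
    path: str | Path,
    recording_durations: Optional[dict[str, float]] = None,
) -> list[BeatAnnotation]:
    """Read and validate a beat-annotation CSV.

    The whole file is rejected (with offending row numbers, 1-based counting
    the header) if any row violates an annotation invariant.

    Parameters
    ----------
    recording_durations : dict, optional
        ``record_id -> duration in ms``; when given, offsets are checked
        against the recording end as well.
    """
    frame = pd.read_csv(Path(path), dtype={"record_id": str, "patient_id": str})
    required = [c for c in _ANNOTATION_COLUMNS if c != "laa_lspv_distance_mm"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation file missing columns {missing}")
    beats: list[BeatAnnotation] = []
    errors: list[str] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        dist = getattr(row, "laa_lspv_distance_mm", None)
        if dist is not None and (isinstance(dist, float) and np.isnan(dist)):
            dist = None
        beat = BeatAnnotation(
            record_id=str(row.record_id),
            patient_id=str(row.patient_id),
            vein=str(row.vein),
            phase=str(row.phase),
            onset_ms=float(row.onset_ms),
            offset_ms=float(row.offset_ms),
            label=str(row.label),
            laa_lspv_distance_mm=None if dist is None else float(dist),
        )
        dur = None
        if recording_durations is not None:
            dur = recording_durations.get(beat.record_id)
        try:
            beat.validate(recording_duration_ms=dur)
        except ValueError as exc:
            errors.append(f"row {pos}: {exc}")
        beats.append(beat)
    if errors:
        raise ValueError("invalid annotation rows:\n" + "\n".join(errors))
    return beats


def write_annotations(beats: Sequence[BeatAnnotation], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "record_id": b.record_id,
                "patient_id": b.patient_id,
                "vein": b.vein,
                "phase": b.phase,
                "onset_ms": b.onset_ms,
                "offset_ms": b.offset_ms,
                "label": b.label,
                "laa_lspv_distance_mm": (
                    "" if b.laa_lspv_distance_mm is None else b.laa_lspv_distance_mm
                ),
            }
            for b in beats
        ],
        columns=_ANNOTATION_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    return path
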
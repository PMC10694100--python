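"""Single-beat feature extraction for nearfield/farfield discrimination.

A local pulmonary-vein nearfield (NF) deflection is "sharp": its energy sits
in the upper half of the 0-300 Hz acquisition band, while the atrial farfield
(FF) is broad and low-frequency.  Six features capture this per beat:

==========================  ===================================================
``p_hf``                    spectral power in the 150-300 Hz band (mV^2), the
                            maximum over a 35 ms window slid across the beat,
                            on the bipole where that maximum is largest
``p_lf``                    power in 0-150 Hz at the same window position
``p_hf_rel``                p_hf / (p_lf + p_hf), the relative high band
``p_hf_neighbor_ratio``     p_hf of the selected bipole over the larger drop
                            to its two ring neighbours (local sources decay
                            faster across the loop than distant ones)
``v_max``                   peak-to-peak amplitude within the beat (mV)
``slew_rate_prop``          fraction of beat samples with |dV/dt| > 0.15 V/s
==========================  ===================================================

Spectra use a zero-padded discrete Fourier transform: a 35 ms window at
2 kHz (70 samples) is padded to ``fs / freq_resolution`` samples (200), which
puts the DFT bins exactly on a 10 Hz grid.  Band power is the sum of
squared bin magnitudes (one-sided, 0..Nyquist) over bins inside the band,
normalised by the number of *un-padded* samples.  Band-edge convention: the
150 Hz bin belongs to the high band and the 300 Hz bin is included, i.e.
LF = [0, 150), HF = [150, 300].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BeatAnnotation, Recording, beat_sample_slice
from .preprocess import NoiseGateConfig, assess_noise

__all__ = [
    "SpectralConfig",
    "SpectralFeatureSet",
    "TemporalFeatureSet",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_TABLE_COLUMNS",
    "DEFAULT_SLEW_THRESHOLD_V_PER_S",
    "sliding_band_powers",
    "extract_spectral_features",
    "extract_temporal_features",
    "extract_feature_vector",
    "extract_feature_table",
]

#: canonical order of the six classifier features
FEATURE_NAMES = [
    "p_hf",
    "p_lf",
    "p_hf_rel",
    "p_hf_neighbor_ratio",
    "v_max",
    "slew_rate_prop",
]

#: deterministic column order of the feature table CSV
FEATURE_TABLE_COLUMNS = FEATURE_NAMES + [
    "selected_channel",
    "duration_ms",
    "record_id",
    "patient_id",
    "vein",
    "phase",
    "label",
    "laa_lspv_distance_mm",
]

DEFAULT_SLEW_THRESHOLD_V_PER_S = 0.15

_NEIGHBOR_POWER_FLOOR = 1e-12  # mV^2; keeps the ratio finite on silent bipoles


@dataclass
class SpectralConfig:
    """Sliding-window band-power settings.

    ``freq_resolution_hz`` fixes the zero-padding length
    ``nfft = fs / freq_resolution_hz`` (200 samples at the 2 kHz / 10 Hz
    defaults) and must divide both band edges so the bands align with bins.
    """

    window_ms: float = 35.0
    freq_resolution_hz: float = 10.0
    band_split_hz: float = 150.0
    band_max_hz: float = 300.0
    window_step_ms: float = 5.0
    taper: str = "rectangular"

    def validate(self, fs: Optional[float] = None) -> None:
        if not (0 < self.band_split_hz < self.band_max_hz):
            raise ValueError("need 0 < band_split_hz < band_max_hz")
        for edge in (self.band_split_hz, self.band_max_hz):
            if abs(edge / self.freq_resolution_hz - round(edge / self.freq_resolution_hz)) > 1e-9:
                raise ValueError(
                    f"freq_resolution_hz={self.freq_resolution_hz} does not divide "
                    f"band edge {edge}"
                )
        if self.window_step_ms <= 0 or self.window_step_ms > self.window_ms:
            raise ValueError("need 0 < window_step_ms <= window_ms")
        if self.taper not in ("rectangular", "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if fs is not None:
            if self.band_max_hz > fs / 2:
                raise ValueError(
                    f"band_max_hz={self.band_max_hz} above Nyquist ({fs / 2})"
                )
            nfft = fs / self.freq_resolution_hz
            if abs(nfft - round(nfft)) > 1e-9:
                raise ValueError("fs / freq_resolution_hz must be an integer")

    def nfft(self, fs: float) -> int:
        return int(round(fs / self.freq_resolution_hz))

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return max(1, int(round(self.window_step_ms * fs / 1000.0)))


@dataclass
class SpectralFeatureSet:
    p_hf: float
    p_lf: float
    p_hf_rel: float
    p_hf_neighbor_ratio: float
    selected_channel: int
    window_start_ms: float
    channel_p_hf: np.ndarray  # channel-level P_HF (max over windows), all bipoles
    neighbor_floored: bool = False


@dataclass
class TemporalFeatureSet:
    v_max: float
    slew_rate_prop: float
    slew_threshold: float
    duration_ms: float


@dataclass
class FeatureVector:
    """The six features of one accepted beat plus its clinical metadata."""

    p_hf: float
    p_lf: float
    p_hf_rel: float
    p_hf_neighbor_ratio: float
    v_max: float
    slew_rate_prop: float
    selected_channel: int
    duration_ms: float
    record_id: str
    patient_id: str
    vein: str
    phase: str
    label: str
    laa_lspv_distance_mm: Optional[float] = None

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_TABLE_COLUMNS}

    def features(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def _taper(cfg: SpectralConfig, n: int) -> np.ndarray:
    if cfg.taper == "hann":
        return np.hanning(n)
    return np.ones(n)


def _band_powers(window: np.ndarray, fs: float, cfg: SpectralConfig) -> tuple[float, float]:
    """One-sided zero-padded DFT band powers (p_lf, p_hf) of one window."""
    n = window.size
    nfft = cfg.nfft(fs)
    if n > nfft:
        raise ValueError(
            f"window of {n} samples exceeds the zero-padding length {nfft}; "
            "lower window_ms or freq_resolution_hz"
        )
    spec = np.abs(np.fft.rfft(window * _taper(cfg, n), n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    lf = spec[(freqs >= 0) & (freqs < cfg.band_split_hz)].sum() / n
    hf = spec[(freqs >= cfg.band_split_hz) & (freqs <= cfg.band_max_hz)].sum() / n
    return float(lf), float(hf)


def sliding_band_powers(
    segment: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> list[tuple[float, float, float]]:
    """Band powers of a window slid from beat onset to offset.

    Returns ``(window_start_ms, p_lf, p_hf)`` for every window position that
    fits fully inside the segment (step ``window_step_ms``).  A segment
    shorter than the window yields a single window covering the whole
    (zero-padded) segment.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate(fs)
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or segment.size == 0:
        raise ValueError("segment must be a non-empty 1-D array")
    w = cfg.window_samples(fs)
    step = cfg.step_samples(fs)
    if segment.size <= w:
        lf, hf = _band_powers(segment, fs, cfg)
        return [(0.0, lf, hf)]
    out = []
    for start in range(0, segment.size - w + 1, step):
        lf, hf = _band_powers(segment[start : start + w], fs, cfg)
        out.append((start / fs * 1000.0, lf, hf))
    return out


def extract_spectral_features(
    rec: Recording, beat: BeatAnnotation, cfg: SpectralConfig | None = None
) -> SpectralFeatureSet:
    """Four spectral features with best-bipole selection.

    Per bipole, the channel-level ``P_HF`` is the maximum high-band power
    over the sliding windows — the sharp nearfield transient is caught
    wherever it occurs inside the beat.  The bipole with the highest
    channel-level ``P_HF`` is retained (ties break to the lowest index);
    ``p_lf`` and ``p_hf_rel`` are read at its maximising window.  The
    neighbour ratio compares the retained ``P_HF`` with the channel-level
    ``P_HF`` of the two ring neighbours and keeps the larger ratio: a source
    directly under the loop decays steeply across neighbouring bipoles,
    distant atrial sources hardly at all.
    """
    cfg = cfg or SpectralConfig()
    if rec.n_channels < 3:
        raise ValueError("neighbour ratio needs at least 3 bipoles on the loop")
    win = beat_sample_slice(beat, rec.fs)
    if win.start < 0 or win.stop > rec.n_samples:
        raise ValueError("beat window outside the recording")
    channel_p_hf = np.empty(rec.n_channels)
    best: list[tuple[float, float, float]] = []  # (start_ms, p_lf, p_hf) per channel
    for i in range(rec.n_channels):
        powers = sliding_band_powers(rec.samples[i, win], rec.fs, cfg)
        hf_values = [p[2] for p in powers]
        j = int(np.argmax(hf_values))  # earliest window on ties
        channel_p_hf[i] = hf_values[j]
        best.append(powers[j])
    sel = int(np.argmax(channel_p_hf))  # lowest channel index on ties
    start_ms, p_lf, p_hf = best[sel]
    total = p_lf + p_hf
    p_hf_rel = p_hf / total if total > 0 else 0.0
    left, right = rec.neighbors(sel)
    floored = bool(
        channel_p_hf[left] < _NEIGHBOR_POWER_FLOOR
        or channel_p_hf[right] < _NEIGHBOR_POWER_FLOOR
    )
    ratio = max(
        p_hf / max(channel_p_hf[left], _NEIGHBOR_POWER_FLOOR),
        p_hf / max(channel_p_hf[right], _NEIGHBOR_POWER_FLOOR),
    )
    return SpectralFeatureSet(
        p_hf=p_hf,
        p_lf=p_lf,
        p_hf_rel=float(p_hf_rel),
        p_hf_neighbor_ratio=float(ratio),
        selected_channel=sel,
        window_start_ms=beat.onset_ms + start_ms,
        channel_p_hf=channel_p_hf,
        neighbor_floored=floored,
    )


def extract_temporal_features(
    rec: Recording,
    beat: BeatAnnotation,
    selected_channel: int,
    slew_threshold: float = DEFAULT_SLEW_THRESHOLD_V_PER_S,
) -> TemporalFeatureSet:
    """Peak-to-peak amplitude and steep-slew-rate proportion of one bipole.

    ``v_max`` is max - min over the beat window (mV) — the EP-lab convention
    for bipolar amplitude.  The derivative uses central differences (one-
    sided at the endpoints), converted from mV/sample to V/s.
    """
    if slew_threshold <= 0:
        raise ValueError("slew_threshold must be positive")
    win = beat_sample_slice(beat, rec.fs)
    seg = rec.samples[selected_channel, win]
    if seg.size < 3:
        raise ValueError("beat too short for a derivative (need >= 3 samples)")
    v_max = float(seg.max() - seg.min())
    dvdt = np.gradient(seg) * rec.fs * 1e-3  # mV/sample -> V/s
    prop = float(np.mean(np.abs(dvdt) > slew_threshold))
    return TemporalFeatureSet(
        v_max=v_max,
        slew_rate_prop=prop,
        slew_threshold=slew_threshold,
        duration_ms=beat.duration_ms,
    )


def extract_feature_vector(
    rec: Recording,
    beat: BeatAnnotation,
    spectral_cfg: SpectralConfig | None = None,
    slew_threshold: float = DEFAULT_SLEW_THRESHOLD_V_PER_S,
) -> FeatureVector:
    """All six features of one beat, with metadata attached. Inputs are not
    mutated; the beat is assumed to have passed the noise gate."""
    spectral = extract_spectral_features(rec, beat, spectral_cfg)
    temporal = extract_temporal_features(
        rec, beat, spectral.selected_channel, slew_threshold
    )
    return FeatureVector(
        p_hf=spectral.p_hf,
        p_lf=spectral.p_lf,
        p_hf_rel=spectral.p_hf_rel,
        p_hf_neighbor_ratio=spectral.p_hf_neighbor_ratio,
        v_max=temporal.v_max,
        slew_rate_prop=temporal.slew_rate_prop,
        selected_channel=spectral.selected_channel,
        duration_ms=temporal.duration_ms,
        record_id=beat.record_id,
        patient_id=beat.patient_id,
        vein=beat.vein,
        phase=beat.phase,
        label=beat.label,
        laa_lspv_distance_mm=beat.laa_lspv_distance_mm,
    )


def extract_feature_table(
    recordings: dict[str, Recording],
    beats: Sequence[BeatAnnotation],
    spectral_cfg: SpectralConfig | None = None,
    slew_threshold: float = DEFAULT_SLEW_THRESHOLD_V_PER_S,
    noise_gate: NoiseGateConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Feature table for a set of annotated beats, one row per accepted beat.

    Beats failing the noise gate are dropped (pass ``noise_gate=None`` to
    skip gating).  Returns ``(table, n_rejected)``; column order is
    :data:`FEATURE_TABLE_COLUMNS`.
    """
    rows = []
    n_rejected = 0
    for beat in beats:
        rec = recordings.get(beat.record_id)
        if rec is None:
            raise KeyError(f"no recording with record_id {beat.record_id!r}")
        if noise_gate is not None:
            if not assess_noise(rec, beat, noise_gate).accepted:
                n_rejected += 1
                continue
        rows.append(extract_feature_vector(rec, beat, spectral_cfg, slew_threshold).as_row())
    table = pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)
    return table, n_rejected
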
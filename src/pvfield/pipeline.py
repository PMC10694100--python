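"""End-to-end convenience: synthetic dataset -> filtered recordings ->
noise-gated six-feature table.

This is the composition every experiment repeats; keeping it in one place
guarantees the same preprocessing order (band-pass + notch, then the noise
gate, then feature extraction) everywhere.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import pandas as pd

from .features import SpectralConfig, extract_feature_table
from .preprocess import FilterConfig, NoiseGateConfig, apply_standard_filters
from .synthetic import BeatModelParams, generate_dataset, load_dataset

__all__ = ["synthetic_feature_table"]


def synthetic_feature_table(
    difficulty: str = "separated",
    seed: int = 0,
    n_patients: int = 28,
    beats_per_patient: int = 12,
    directory: Optional[str | Path] = None,
    params: Optional[BeatModelParams] = None,
    class_mix: Optional[dict] = None,
    filter_cfg: Optional[FilterConfig] = None,
    noise_gate: Optional[NoiseGateConfig] = NoiseGateConfig(),
    spectral_cfg: Optional[SpectralConfig] = None,
) -> pd.DataFrame:
    """Generate a synthetic dataset and return its feature table.

    The dataset is written to ``directory`` (a temporary directory when
    omitted), read back through the standard I/O path, band-pass/notch
    filtered, noise-gated and feature-extracted — i.e. the exact pipeline a
    clinical recording would traverse.
    """
    if directory is None:
        with tempfile.TemporaryDirectory() as tmp:
            return synthetic_feature_table(
                difficulty, seed, n_patients, beats_per_patient, tmp,
                params, class_mix, filter_cfg, noise_gate, spectral_cfg,
            )
    generate_dataset(
        directory,
        n_patients=n_patients,
        beats_per_patient=beats_per_patient,
        class_mix=class_mix,
        difficulty=difficulty,
        seed=seed,
        params=params,
    )
    recordings, beats = load_dataset(directory)
    recordings = {
        rid: apply_standard_filters(rec, filter_cfg) for rid, rec in recordings.items()
    }
    table, _ = extract_feature_table(
        recordings, beats, spectral_cfg=spectral_cfg, noise_gate=noise_gate
    )
    return table
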
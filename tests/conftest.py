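import numpy as np
import pytest

from pvfield.io import BeatAnnotation, Recording
from pvfield.pipeline import synthetic_feature_table

FS = 2000.0


def make_recording(samples, fs=FS, record_id="rec0"):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    return Recording(
        record_id=record_id,
        fs=fs,
        channels=[f"ch{i}" for i in range(samples.shape[0])],
        samples=samples,
    )


def make_beat(onset_ms, offset_ms, label="PV-NF", phase="during", **kw):
    defaults = dict(record_id="rec0", patient_id="P000", vein="LSPV")
    defaults.update(kw)
    return BeatAnnotation(
        onset_ms=onset_ms, offset_ms=offset_ms, label=label, phase=phase, **defaults
    )


@pytest.fixture(scope="session")
def separated_table(tmp_path_factory):
    """Full-pipeline feature table for the cleanly separated difficulty."""
    d = tmp_path_factory.mktemp("ds_separated")
    return synthetic_feature_table(
        "separated", seed=3, n_patients=28, beats_per_patient=12, directory=d
    )


@pytest.fixture(scope="session")
def overlap_table(tmp_path_factory):
    """Full-pipeline feature table for the overlap-heavy difficulty."""
    d = tmp_path_factory.mktemp("ds_overlap")
    return synthetic_feature_table(
        "overlap_heavy", seed=3, n_patients=28, beats_per_patient=12, directory=d
    )
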
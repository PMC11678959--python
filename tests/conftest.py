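import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sleepif import features, synthetic
from sleepif.edfwriter import write_edf, write_edf_annotations

FS = 100.0
START = dt.datetime(2000, 1, 1, 22, 0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_channel_edf(tmp_path):
    """10 s, 2-channel, 100 Hz EDF file (a 10 Hz tone and white noise)."""
    n = 1000
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * 10 * t)
    y = np.random.default_rng(0).normal(size=n)
    path = tmp_path / "two_channel.edf"
    write_edf(path, [x, y], FS, ["EEG Fpz-Cz", "EEG Pz-Oz"], start_time=START)
    return path, {"EEG Fpz-Cz": x, "EEG Pz-Oz": y}


@pytest.fixture
def mixed_rate_edf(tmp_path):
    """EDF with one 100 Hz and one 1 Hz channel."""
    path = tmp_path / "mixed.edf"
    write_edf(path, [np.zeros(1000), np.arange(10.0)], [100, 1], ["fast", "slow"])
    return path


def make_hypnogram_edf(path, annotations, duration_s):
    write_edf_annotations(path, annotations, duration_s, start_time=START)
    return path


@pytest.fixture
def hypnogram_edf(tmp_path):
    """EDF+ hypnogram: W (90 s) then stage 2 (60 s)."""
    path = tmp_path / "hyp.edf"
    return make_hypnogram_edf(
        path, [(0.0, 90.0, "Sleep stage W"), (90.0, 60.0, "Sleep stage 2")], 150.0
    )


@pytest.fixture
def feature_table(rng):
    """Small synthetic 22-feature table with plausible values."""
    n = 6
    data = {
        "subject_id": ["S0"] * n,
        "recording_id": ["S0r1"] * n,
        "epoch_index": np.arange(n),
    }
    for c in features.FEATURE_COLUMNS:
        data[c] = rng.normal(10.0, 1.0, size=n)
    data["label"] = ["W", "N1", "N2", "N3", "REM", "W"]
    data["epoch_start_time"] = [
        START + dt.timedelta(seconds=30 * i) for i in range(n)
    ]
    return pd.DataFrame(data)


def gaussian_stage_table(
    subject_id, n_per_stage=12, sep=6.0, noise=1.0, seed=0, start=START
):
    """Feature table with Gaussian class-conditional features, linearly
    separable by stage for ``sep >> noise``.

    The stage means are shared across subjects (fixed seed); ``seed`` only
    varies the per-subject noise, so subject-wise CV can generalize.
    """
    rng = np.random.default_rng(2**20)  # shared class geometry
    stage_means = {
        s: rng.normal(0.0, sep, size=len(features.FEATURE_COLUMNS))
        for s in ("W", "N1", "N2", "N3", "REM")
    }
    rows = []
    idx = 0
    srng = np.random.default_rng(seed + 1)
    for stage, mu in stage_means.items():
        for _ in range(n_per_stage):
            rows.append((stage, mu + srng.normal(0.0, noise, size=len(mu)), idx))
            idx += 1
    data = {
        "subject_id": [subject_id] * len(rows),
        "recording_id": [f"{subject_id}r1"] * len(rows),
        "epoch_index": [r[2] for r in rows],
    }
    for j, c in enumerate(features.FEATURE_COLUMNS):
        data[c] = [r[1][j] for r in rows]
    data["label"] = [r[0] for r in rows]
    data["epoch_start_time"] = [
        start + dt.timedelta(seconds=30 * r[2]) for r in rows
    ]
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def short_recording():
    """Shared 10-min synthetic recording with hypnogram and IF ground truth."""
    stages = synthetic.markov_hypnogram(synthetic.DEFAULT_TRANSITIONS, 20, seed=3)
    rec, hyp, truth = synthetic.simulate_recording(
        stages, fs=FS, seed=3, subject_id="S0", recording_id="S0r1",
        start_time=START,
    )
    return rec, hyp, truth
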
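"""EDF/EDF+ input and feature-table/metrics output.

Reading goes through :mod:`mne`'s native EDF reader. Hypnogram files are EDF+
annotation files in the Sleep-EDFx dialect: variable-duration annotations with
descriptions like ``"Sleep stage W"``, ``"Sleep stage 1"`` ... ``"Sleep stage
4"``, ``"Sleep stage R"``, ``"Movement time"`` and ``"Sleep stage ?"``, which
are expanded here into consecutive 30 s epochs.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

EPOCH_LEN_S = 30
"""Length of a hypnogram scoring epoch in seconds."""


@dataclasses.dataclass
class MultichannelRecording:
    """A uniformly sampled multichannel recording.

    ``samples`` is an (n_channels, n_samples) float array in the file's
    physical units; all channels share the sampling rate ``fs`` (Hz).
    """

    subject_id: str
    recording_id: str
    fs: float
    channels: list[str]
    samples: np.ndarray
    start_time: _dt.datetime

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("one row of samples per channel required")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


@dataclasses.dataclass
class Hypnogram:
    """Sequence of 30 s sleep-stage labels aligned to a recording.

    ``raw_labels`` holds the original annotation strings; ``labels`` is filled
    by :func:`sleepif.features.map_labels` (``None`` until then).
    """

    raw_labels: list[str]
    epoch_start_times: list[_dt.datetime]
    epoch_len_s: int = EPOCH_LEN_S
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.raw_labels) != len(self.epoch_start_times):
            raise ValueError("one start time per epoch required")
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError(f"epoch length must be {EPOCH_LEN_S} s")

    def __len__(self) -> int:
        return len(self.raw_labels)


def read_signals(
    path,
    wanted_channels: Sequence[str],
    subject_id: str = "",
    recording_id: str = "",
) -> MultichannelRecording:
    """Read selected channels of an EDF/EDF+ file.

    Raises if the file or any wanted channel is missing, or if the wanted
    channels do not share one sampling rate.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, include=list(wanted_channels), preload=True,
                              verbose="error")
    missing = [c for c in wanted_channels if c not in raw.ch_names]
    if missing:
        raise KeyError(f"channels {missing} not found in {path}")
    # mne resamples mixed-rate EDF channels to the highest rate on load; detect
    # mixed rates from the raw header instead of trusting the resampled data.
    with open(path, "rb") as f:
        hdr = f.read(256)
        nsig = int(hdr[252:256])
        sig_hdr = f.read(256 * nsig)
    labels = [sig_hdr[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(nsig)]
    spr_off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * nsig
    spr = [
        int(sig_hdr[spr_off + 8 * i : spr_off + 8 * (i + 1)].decode("ascii").strip() or 0)
        for i in range(nsig)
    ]
    rec_dur = float(hdr[244:252].decode("ascii").strip())
    rates = {labels[i]: spr[i] / rec_dur for i in range(nsig)}
    wanted_rates = {rates[c] for c in wanted_channels if c in rates}
    if len(wanted_rates) > 1:
        raise ValueError(
            f"wanted channels have mixed sampling rates: "
            f"{ {c: rates[c] for c in wanted_channels} }"
        )

    order = [raw.ch_names.index(c) for c in wanted_channels]
    data = raw.get_data()[order] * 1e6  # mne loads EEG in volts; back to uV
    meas = raw.info["meas_date"]
    start = (
        meas.replace(tzinfo=None) if meas is not None else _dt.datetime(2000, 1, 1)
    )
    return MultichannelRecording(
        subject_id=subject_id,
        recording_id=recording_id or os.path.basename(str(path)),
        fs=float(wanted_rates.pop()),
        channels=list(wanted_channels),
        samples=data,
        start_time=start,
    )


def read_hypnogram(path, recording_duration_s: float) -> Hypnogram:
    """Read an EDF+ hypnogram file into consecutive 30 s epochs.

    Each annotation's duration must be a multiple of 30 s; annotations must
    tile the time axis without overlap. Epochs beyond ``recording_duration_s``
    are truncated (the final annotation of Sleep-EDFx files commonly overruns
    the signal file).
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ann = mne.read_annotations(path)
    try:
        raw_start = mne.io.read_raw_edf(path, preload=False, verbose="error").info[
            "meas_date"
        ]
        start = raw_start.replace(tzinfo=None) if raw_start else _dt.datetime(2000, 1, 1)
    except Exception:
        start = _dt.datetime(2000, 1, 1)

    order = np.argsort(ann.onset, kind="stable")
    raw_labels: list[str] = []
    starts: list[_dt.datetime] = []
    prev_end = None
    for i in order:
        onset, dur, desc = float(ann.onset[i]), float(ann.duration[i]), ann.description[i]
        if abs(dur / EPOCH_LEN_S - round(dur / EPOCH_LEN_S)) > 1e-6 or dur <= 0:
            raise ValueError(
                f"annotation {desc!r} at {onset:g}s has duration {dur:g}s, "
                f"not a positive multiple of {EPOCH_LEN_S}s"
            )
        if prev_end is not None and onset < prev_end - 1e-6:
            raise ValueError(f"overlapping annotations at {onset:g}s")
        prev_end = onset + dur
        for k in range(int(round(dur / EPOCH_LEN_S))):
            t0 = onset + k * EPOCH_LEN_S
            if t0 + EPOCH_LEN_S > recording_duration_s + 1e-6:
                break
            raw_labels.append(desc)
            starts.append(start + _dt.timedelta(seconds=t0))
    return Hypnogram(raw_labels=raw_labels, epoch_start_times=starts)


def write_feature_table(path, table: pd.DataFrame) -> None:
    """Write an epoch feature table as tab-separated text (round-trip safe)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t")
    if "epoch_start_time" in df.columns:
        df["epoch_start_time"] = pd.to_datetime(df["epoch_start_time"])
    return df


def write_metrics(path, metrics: dict) -> None:
    """Write classification metrics as JSON."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as f:
        json.dump(metrics, f, indent=2, default=_default)
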
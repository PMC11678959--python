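"""Minimal EDF / EDF+ writer.

Serializes synthetic multichannel recordings and hypnogram annotation files so
that the rest of the package (and its tests) can exercise the EDF reading path
without any external data. Signals are stored as 16-bit integers with a
per-channel symmetric physical range, which bounds the round-trip error at
~3e-5 of the channel's peak amplitude. Not a general-purpose EDF exporter.
"""

from __future__ import annotations

import datetime as _dt
from typing import Sequence

import numpy as np

__all__ = ["write_edf", "write_edf_annotations"]


def _field(value, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def _phys_range(x: np.ndarray) -> float:
    pmax = float(np.max(np.abs(x))) if x.size else 0.0
    if pmax == 0.0:
        pmax = 1.0
    # round to 5 significant digits so the header string and the scale used
    # for quantization are identical
    return float(f"{pmax:.5g}")


def write_edf(
    path,
    signals: Sequence[np.ndarray],
    fs: float,
    labels: Sequence[str],
    start_time: _dt.datetime | None = None,
    annotations: Sequence[tuple[float, float, str]] | None = None,
    physical_dim: str = "uV",
) -> None:
    """Write an EDF (or EDF+C, if ``annotations`` is given) file.

    Parameters
    ----------
    signals
        Equal-length 1-D arrays, one per channel, in ``physical_dim`` units.
    fs
        Sampling rate in Hz (one value, or one per channel). Record duration
        is 1 s, so rates must be positive integers.
    labels
        Channel labels, at most 16 ASCII characters each.
    start_time
        Clock time of the first sample (default 2000-01-01 22:00:00).
    annotations
        Optional ``(onset_s, duration_s, text)`` triples stored in an
        ``EDF Annotations`` channel.
    """
    if start_time is None:
        start_time = _dt.datetime(2000, 1, 1, 22, 0, 0)
    signals = [np.asarray(s, dtype=float) for s in signals]
    if len(signals) != len(labels):
        raise ValueError("one label per signal required")
    fs_list = [fs] * len(signals) if np.isscalar(fs) else list(fs)
    fs_ints = [int(round(f)) for f in fs_list]
    if len(fs_ints) != len(signals) or any(
        fi != f or fi <= 0 for fi, f in zip(fs_ints, fs_list)
    ):
        raise ValueError("write_edf requires positive integer sampling rates")
    durations = {len(s) / fi for s, fi in zip(signals, fs_ints)}
    if len(durations) > 1:
        raise ValueError("all signals must span the same duration")

    n_records = max(1, int(np.ceil(durations.pop()))) if signals else 1

    digitized, pmaxs = [], []
    for s in signals:
        pmax = _phys_range(s)
        pmaxs.append(pmax)
        d = np.clip(np.round(s / pmax * 32767.0), -32768, 32767).astype("<i2")
        digitized.append(d)

    tal_extra = b""
    if annotations is not None:
        for onset, dur, text in annotations:
            tal_extra += f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00".encode("utf-8")
    # annotation channel sized to hold every TAL inside the first record
    ann_samples = max(60, (len(tal_extra) + 40) // 2 + 1) if annotations is not None else 0

    has_ann = annotations is not None
    nsig = len(signals) + (1 if has_ann else 0)

    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field("Startdate X X X X", 80)
    header += _field(start_time.strftime("%d.%m.%y"), 8)
    header += _field(start_time.strftime("%H.%M.%S"), 8)
    header += _field(256 * (nsig + 1), 8)
    header += _field("EDF+C" if has_ann else "", 44)
    header += _field(n_records, 8)
    header += _field("1", 8)
    header += _field(nsig, 4)

    cols: list[tuple[list[str], int]] = [
        (list(labels) + (["EDF Annotations"] if has_ann else []), 16),
        ([""] * nsig, 80),                                            # transducer
        ([physical_dim] * len(signals) + ([""] if has_ann else []), 8),
        ([f"{-p:.5g}" for p in pmaxs] + (["-1"] if has_ann else []), 8),
        ([f"{p:.5g}" for p in pmaxs] + (["1"] if has_ann else []), 8),
        (["-32768"] * nsig, 8),
        (["32767"] * nsig, 8),
        ([""] * nsig, 80),                                            # prefilter
        ([str(fi) for fi in fs_ints] + ([str(ann_samples)] if has_ann else []), 8),
    ]
    for values, width in cols:
        for v in values:
            header += _field(v, width)
    header += b" " * (32 * nsig)  # reserved

    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            for d, fi in zip(digitized, fs_ints):
                chunk = d[rec * fi : (rec + 1) * fi]
                if len(chunk) < fi:
                    chunk = np.concatenate(
                        [chunk, np.zeros(fi - len(chunk), dtype="<i2")]
                    )
                f.write(chunk.tobytes())
            if has_ann:
                tal = f"+{rec:d}\x14\x14\x00".encode("ascii")
                if rec == 0:
                    tal += tal_extra
                tal = tal.ljust(2 * ann_samples, b"\x00")
                f.write(tal)


def write_edf_annotations(
    path,
    annotations: Sequence[tuple[float, float, str]],
    duration_s: float,
    start_time: _dt.datetime | None = None,
) -> None:
    """Write an EDF+ file that carries only stage annotations (a hypnogram
    file in the style of the Sleep-EDFx ``*-Hypnogram`` files)."""
    n = int(np.ceil(duration_s))
    write_edf(
        path,
        [np.zeros(n)],
        1,
        ["marker"],
        start_time=start_time,
        annotations=annotations,
    )
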
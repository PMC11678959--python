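"""Epoch featurization: per-band IF/IE tracks -> 30 s feature table.

Each labeled 30 s epoch yields 22 features: mean instantaneous frequency (Hz)
and mean instantaneous envelope (signal units) for each of the five rhythm
bands on both EEG channels (20), plus the EOG pair (2). IE is taken from the
pre-normalization envelope; IF from the Kalman track of the normalized signal.
Invalid samples (unconverged, clipped or real-pole) are excluded from the
means; an epoch in which any feature has under 50% valid samples is dropped
and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_edf import EPOCH_LEN_S, Hypnogram

logger = logging.getLogger(__name__)

__all__ = [
    "EEG_ROLES",
    "BAND_NAMES",
    "FEATURE_COLUMNS",
    "KEY_COLUMNS",
    "STAGE_MAP",
    "MASKED_LABELS",
    "map_labels",
    "epoch_average",
    "build_feature_table",
]

EEG_ROLES = ("FpzCz", "PzOz")
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{role}_{band}_{kind}"
    for role in EEG_ROLES
    for band in BAND_NAMES
    for kind in ("IF", "IE")
) + ("EOG_IF", "EOG_IE")
"""Fixed feature-column order (22 columns); stable across runs."""

KEY_COLUMNS = ("subject_id", "recording_id", "epoch_index")

STAGE_MAP = {
    "sleep stage w": "W",
    "sleep stage 1": "N1",
    "sleep stage 2": "N2",
    "sleep stage 3": "N3",
    "sleep stage 4": "N3",
    "sleep stage r": "REM",
}
MASKED_LABELS = {"movement time", "sleep stage ?"}


def map_labels(raw_labels) -> tuple[list[str | None], np.ndarray]:
    """Map Sleep-EDFx annotation strings to AASM-style stages.

    W -> W, stages 1/2 -> N1/N2, 3 and 4 merge into N3, R -> REM. Movement
    time and unscored epochs are masked out (label ``None``, keep=False).
    Unrecognized strings raise.
    """
    labels: list[str | None] = []
    keep = np.ones(len(raw_labels), dtype=bool)
    for i, raw in enumerate(raw_labels):
        key = str(raw).strip().lower()
        if key in MASKED_LABELS:
            labels.append(None)
            keep[i] = False
        elif key in STAGE_MAP:
            labels.append(STAGE_MAP[key])
        else:
            raise ValueError(f"unrecognized hypnogram label {raw!r}")
    return labels, keep


def epoch_average(
    series: np.ndarray,
    fs: float,
    epoch_len_s: float = EPOCH_LEN_S,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a per-sample series over non-overlapping complete epochs.

    Only samples flagged valid contribute. Returns (means, valid_fraction),
    one entry per complete window; a trailing partial window is dropped. An
    epoch with no valid samples gets a NaN mean.
    """
    spe = fs * epoch_len_s
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("fs * epoch_len_s must be integral")
    spe = int(round(spe))
    series = np.asarray(series, dtype=float)
    n_ep = len(series) // spe
    if valid is None:
        valid = np.isfinite(series)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(series)
    s = series[: n_ep * spe].reshape(n_ep, spe)
    v = valid[: n_ep * spe].reshape(n_ep, spe)
    cnt = v.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(cnt > 0, np.where(v, s, 0.0).sum(axis=1) / np.maximum(cnt, 1),
                         np.nan)
    return means, cnt / spe


def build_feature_table(
    if_tracks: dict,
    ie_series: dict,
    hypnogram: Hypnogram,
    fs: float,
    subject_id: str,
    recording_id: str,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Assemble the 22-feature, per-30 s-epoch table for one recording.

    ``if_tracks`` maps (role, band) -> (if_hz array, valid array); ``ie_series``
    maps (role, band) -> envelope array, with role in {FpzCz, PzOz, EOG} and
    band "eog" for the EOG role. Row count is the smaller of the number of
    complete 30 s windows and the number of hypnogram labels; masked epochs
    (movement/unscored) and epochs failing the validity rule are dropped.
    """
    pairs = [(r, b) for r in EEG_ROLES for b in BAND_NAMES] + [("EOG", "eog")]
    missing = [p for p in pairs if p not in if_tracks or p not in ie_series]
    if missing:
        raise ValueError(f"missing tracks for {missing}")
    lengths = {len(if_tracks[p][0]) for p in pairs} | {len(ie_series[p]) for p in pairs}
    if len(lengths) != 1:
        raise ValueError(f"track-length mismatch: {sorted(lengths)}")

    cols: dict[str, np.ndarray] = {}
    fracs: dict[str, np.ndarray] = {}
    for role, band in pairs:
        prefix = "EOG" if role == "EOG" else f"{role}_{band}"
        f_hz, f_valid = if_tracks[(role, band)]
        cols[f"{prefix}_IF"], fracs[f"{prefix}_IF"] = epoch_average(
            f_hz, fs, valid=f_valid
        )
        cols[f"{prefix}_IE"], fracs[f"{prefix}_IE"] = epoch_average(ie_series[(role, band)], fs)

    labels, keep = map_labels(hypnogram.raw_labels)
    n_rows = min(len(next(iter(cols.values()))), len(labels))

    frac_mat = np.vstack([fracs[c][:n_rows] for c in FEATURE_COLUMNS])
    feat_mat = np.vstack([cols[c][:n_rows] for c in FEATURE_COLUMNS])
    enough_valid = (frac_mat >= min_valid_fraction).all(axis=0)
    finite = np.isfinite(feat_mat).all(axis=0)
    row_ok = keep[:n_rows] & enough_valid & finite
    n_dropped = int((~(enough_valid & finite) & keep[:n_rows]).sum())
    if n_dropped:
        logger.info(
            "%s/%s: dropped %d/%d epochs with <%d%% valid samples",
            subject_id, recording_id, n_dropped, n_rows,
            int(100 * min_valid_fraction),
        )

    idx = np.flatnonzero(row_ok)
    data = {
        "subject_id": [subject_id] * len(idx),
        "recording_id": [recording_id] * len(idx),
        "epoch_index": idx,
    }
    for j, c in enumerate(FEATURE_COLUMNS):
        data[c] = feat_mat[j, idx]
    data["label"] = [labels[i] for i in idx]
    data["epoch_start_time"] = [hypnogram.epoch_start_times[i] for i in idx]
    return pd.DataFrame(data)
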
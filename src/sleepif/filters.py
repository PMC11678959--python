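"""Zero-phase FIR band-pass filter bank for the EEG rhythm bands.

The five classical rhythm bands (delta 0.5-4, theta 4-8, alpha 8-13, beta
13-30, gamma 30-50 Hz) plus a broad 0.5-20 Hz EOG band. Filters are
windowed-sinc (Hamming) linear-phase FIR designs applied forward-backward, so
the effective magnitude response is the square of the single-pass response and
the group delay is zero — inter-band time alignment is preserved.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "BandDefinition",
    "FIRFilterSpec",
    "EEG_BANDS",
    "EOG_BAND",
    "design_fir_bandpass",
    "apply_zero_phase",
    "decompose_bands",
]

MAX_TAPS = 1001


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with lower/upper cutoffs in Hz."""

    name: str
    fl: float
    fh: float

    def __post_init__(self) -> None:
        if not (0 < self.fl < self.fh):
            raise ValueError(f"need 0 < fl < fh, got ({self.fl}, {self.fh})")


EEG_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)
EOG_BAND = BandDefinition("eog", 0.5, 20.0)


@dataclasses.dataclass(frozen=True)
class FIRFilterSpec:
    """Designed linear-phase FIR taps for one band at one sampling rate."""

    band: BandDefinition
    taps: np.ndarray
    design_fs: float

    @property
    def n_taps(self) -> int:
        return len(self.taps)

    def response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Single-pass magnitude response at the given frequencies (Hz)."""
        _, h = _sig.freqz(self.taps, worN=2 * np.pi * np.asarray(freqs_hz) / self.design_fs)
        return np.abs(h)


def default_order(fl: float, fs: float) -> int:
    """Default FIR order: ≈3 cycles of the lower cutoff, even, ≤ MAX_TAPS-1."""
    order = int(np.ceil(3.0 * fs / fl))
    order += order % 2
    return min(order, MAX_TAPS - 1)


def design_fir_bandpass(
    band: BandDefinition, fs: float, order: int | None = None
) -> FIRFilterSpec:
    """Design a Hamming-window linear-phase band-pass FIR for ``band``.

    ``order`` (even; taps = order + 1) defaults to :func:`default_order`.
    ``fh`` must be strictly below fs/2; :func:`decompose_bands` applies a
    Nyquist guard for bands (gamma at fs=100) whose nominal edge touches it.
    """
    if band.fh >= fs / 2:
        raise ValueError(
            f"band {band.name}: upper cutoff {band.fh} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    if order is None:
        order = default_order(band.fl, fs)
    if order % 2:
        raise ValueError("FIR order must be even (type-I linear phase)")
    min_order = int(np.ceil(fs / band.fl))
    if order < min_order:
        raise ValueError(
            f"order {order} too small for fl={band.fl} Hz at fs={fs} Hz "
            f"(need ≥ {min_order})"
        )
    taps = _sig.firwin(
        order + 1, [band.fl, band.fh], pass_zero=False, window="hamming", fs=fs
    )
    return FIRFilterSpec(band=band, taps=taps, design_fs=fs)


def apply_zero_phase(x: np.ndarray, spec: FIRFilterSpec) -> np.ndarray:
    """Filter forward and backward (zero phase, squared magnitude response).

    Edges are reflect-padded by 3x the tap count to suppress start/end
    transients. Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * spec.n_taps:
        raise ValueError(
            f"signal too short for zero-phase filtering: need > {3 * spec.n_taps} "
            f"samples, got {len(x)}"
        )
    return _sig.filtfilt(spec.taps, [1.0], x, padtype="even", padlen=3 * spec.n_taps)


def decompose_bands(
    rec,
    eeg_channels: Sequence[str],
    eog_channel: str,
    eeg_bands: Sequence[BandDefinition] = EEG_BANDS,
    eog_band: BandDefinition = EOG_BAND,
    nyquist_guard: float = 0.99,
) -> Mapping[tuple[str, str], np.ndarray]:
    """Band-limit a recording into (channel, band) -> signal sequences.

    Each EEG channel is split into the five rhythm bands; the EOG channel gets
    the single broad band. A band whose upper edge reaches Nyquist (gamma at
    fs=100) is *designed* at ``nyquist_guard * fs/2`` while keeping its name.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    guard = nyquist_guard * rec.fs / 2

    def _design(band: BandDefinition) -> FIRFilterSpec:
        if band.fh >= rec.fs / 2:
            band = BandDefinition(band.name, band.fl, guard)
        return design_fir_bandpass(band, rec.fs)

    for ch in eeg_channels:
        x = rec.channel(ch)
        for band in eeg_bands:
            out[(ch, band.name)] = apply_zero_phase(x, _design(band))
    out[(eog_channel, eog_band.name)] = apply_zero_phase(
        rec.channel(eog_channel), _design(eog_band)
    )
    return out
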
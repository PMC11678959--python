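"""Ground-truthed signal generators.

Two layers: (i) pure TVAR(2) processes driven by prescribed pole-radius /
pole-angle trajectories, with the exact model-based IF as ground truth; and
(ii) "sleep-like" multichannel recordings in which each EEG rhythm band is a
TVAR(2) component whose center frequency, amplitude and Q-factor depend on a
Markov-generated stage sequence. The recordings emulate the statistical
structure the tracking method assumes — band-limited dominant oscillations
with stage-dependent power and frequency over a 1/f background — not real EEG
morphology (no spindles, K-complexes or artifacts).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io_edf import EPOCH_LEN_S, Hypnogram, MultichannelRecording
from .tvar_kalman import spectral_peak_track

__all__ = [
    "STAGES",
    "PoleSchedule",
    "StageProfile",
    "DEFAULT_PROFILE",
    "DEFAULT_TRANSITIONS",
    "simulate_tvar2",
    "simulate_tvar2_random_walk",
    "markov_hypnogram",
    "simulate_recording",
]

STAGES = ("W", "N1", "N2", "N3", "REM")

_STAGE_TO_RAW = {
    "W": "Sleep stage W",
    "N1": "Sleep stage 1",
    "N2": "Sleep stage 2",
    "N3": "Sleep stage 3",
    "REM": "Sleep stage R",
}


@dataclasses.dataclass
class PoleSchedule:
    """Per-sample pole radius/angle trajectory of a TVAR(2) process."""

    radius: np.ndarray
    angle: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.radius = np.asarray(self.radius, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.radius.shape != self.angle.shape:
            raise ValueError("radius and angle must have equal length")
        if np.any(self.radius >= 1.0) or np.any(self.radius <= 0.0):
            raise ValueError("pole radius must lie strictly inside the unit circle")
        if np.any(self.angle <= 0.0) or np.any(self.angle >= np.pi):
            raise ValueError("pole angle must lie in (0, pi)")

    def coefficients(self) -> np.ndarray:
        """(n, 2) array of (c1, c2) = (2 r cos(phi), -r^2)."""
        return np.column_stack(
            [2.0 * self.radius * np.cos(self.angle), -self.radius**2]
        )

    def true_if_hz(self) -> np.ndarray:
        """Ground-truth spectral-peak IF of the scheduled model."""
        _, if_hz, _, _, _ = spectral_peak_track(self.coefficients(), self.fs)
        return if_hz


def _simulate_tvar(C: np.ndarray, noise: np.ndarray) -> np.ndarray:
    c1 = C[:, 0].tolist()
    c2 = C[:, 1].tolist()
    v = noise.tolist()
    y = [0.0] * len(v)
    y[0] = v[0]
    y[1] = c1[1] * y[0] + v[1]
    for n in range(2, len(v)):
        y[n] = c1[n] * y[n - 1] + c2[n] * y[n - 2] + v[n]
    return np.asarray(y)


def simulate_tvar2(
    schedule: PoleSchedule, obs_noise_var: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Simulate y_n = c1(n) y_{n-1} + c2(n) y_{n-2} + v_n along a pole schedule.

    Returns the signal and a ground-truth dict with the true coefficient
    array ``c`` (n, 2) and the true spectral-peak IF ``if_hz`` (Hz).
    """
    rng = np.random.default_rng(seed)
    C = schedule.coefficients()
    v = rng.normal(0.0, np.sqrt(obs_noise_var), size=len(C))
    y = _simulate_tvar(C, v)
    return y, {"c": C, "if_hz": schedule.true_if_hz(), "fs": schedule.fs}


def simulate_tvar2_random_walk(
    c0: np.ndarray,
    q: np.ndarray,
    r: float,
    n: int,
    seed: int = 0,
    stability_margin: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an AR(2) observation whose coefficients follow a random walk.

    This is exactly the state-space model the tracking filter assumes:
    c_{n+1} = c_n + w_n with w ~ N(0, diag(q)), y_n = h_n^T c_n + v_n with
    v ~ N(0, r). Coefficient increments that would leave the stability region
    (with ``stability_margin``) are reflected back, so ``q`` should be small
    enough that reflections are rare. Returns (y, c_true (n, 2)).
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q, dtype=float).reshape(2)
    C = np.empty((n, 2))
    c = np.asarray(c0, dtype=float).reshape(2).copy()
    m = stability_margin
    for k in range(n):
        C[k] = c
        c = c + rng.normal(0.0, np.sqrt(q))
        # reflect into the (margin-shrunk) stability triangle
        if c[1] < -1.0 + m:
            c[1] = 2.0 * (-1.0 + m) - c[1]
        if c[1] > 1.0 - m:
            c[1] = 2.0 * (1.0 - m) - c[1]
        if c[0] + c[1] > 1.0 - m:
            c[0] = 2.0 * (1.0 - m - c[1]) - c[0]
        if c[1] - c[0] > 1.0 - m:
            c[0] = 2.0 * (c[1] - 1.0 + m) - c[0]
    v = rng.normal(0.0, np.sqrt(r), size=n)
    y = _simulate_tvar(C, v)
    return y, C


def markov_hypnogram(
    transition_matrix: np.ndarray,
    n_epochs: int,
    seed: int = 0,
    start: str = "W",
    stages: Sequence[str] = STAGES,
) -> list[str]:
    """Sample a stage-label sequence from a first-order Markov chain."""
    P = np.asarray(transition_matrix, dtype=float)
    k = len(stages)
    if P.shape != (k, k) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be row-stochastic over the stages")
    rng = np.random.default_rng(seed)
    state = list(stages).index(start)
    out = []
    for _ in range(n_epochs):
        out.append(stages[state])
        state = rng.choice(k, p=P[state])
    return out


# Rough nightly dynamics: sticky stages, W->N1->N2->{N3,REM} progression.
DEFAULT_TRANSITIONS = np.array(
    [
        # W     N1    N2    N3    REM
        [0.80, 0.15, 0.03, 0.01, 0.01],
        [0.10, 0.60, 0.25, 0.02, 0.03],
        [0.03, 0.05, 0.75, 0.12, 0.05],
        [0.01, 0.02, 0.17, 0.78, 0.02],
        [0.05, 0.05, 0.10, 0.02, 0.78],
    ]
)


@dataclasses.dataclass(frozen=True)
class BandState:
    """One band's oscillator parameters in one stage."""

    center_hz: float
    amplitude: float
    radius: float = 0.95


@dataclasses.dataclass
class StageProfile:
    """Per-stage oscillator parameters for the five EEG bands and the EOG.

    ``eeg``: stage -> band name -> BandState; ``eog``: stage -> BandState.
    ``noise_floor`` is the 1/f background amplitude as a fraction of the
    summed component RMS. Center frequencies must sit inside their band.
    """

    eeg: Mapping[str, Mapping[str, BandState]]
    eog: Mapping[str, BandState]
    noise_floor: float = 0.05
    eog_noise_floor: float = 0.05

    def validate(self, band_edges: Mapping[str, tuple[float, float]]) -> None:
        for stage, bands in self.eeg.items():
            for name, bs in bands.items():
                fl, fh = band_edges[name]
                if not (fl < bs.center_hz < fh):
                    raise ValueError(
                        f"{stage}/{name}: center {bs.center_hz} Hz outside ({fl}, {fh})"
                    )


def _default_profile() -> StageProfile:
    B = BandState
    # Low bands get a higher Q (pole radius): an AR(2) resonance exists off
    # zero frequency only when cos(angle) < 2r/(1+r^2), so slow oscillators
    # must sit close to the unit circle to have a well-defined spectral peak.
    eeg = {
        #          delta                    theta              alpha               beta               gamma
        "W":   {"delta": B(1.8, 0.8, 0.99), "theta": B(6.0, 0.5), "alpha": B(10.5, 1.5), "beta": B(20.0, 1.2), "gamma": B(38.0, 1.0)},
        "N1":  {"delta": B(1.4, 1.0, 0.99), "theta": B(5.5, 1.3), "alpha": B(9.0, 0.7),  "beta": B(16.0, 0.6), "gamma": B(35.0, 0.3)},
        "N2":  {"delta": B(2.2, 1.3, 0.99), "theta": B(6.5, 1.0), "alpha": B(12.0, 1.0), "beta": B(14.0, 0.4), "gamma": B(33.0, 0.15)},
        "N3":  {"delta": B(1.6, 2.5, 0.99), "theta": B(4.5, 0.5), "alpha": B(8.5, 0.3),  "beta": B(15.0, 0.2), "gamma": B(32.0, 0.1)},
        "REM": {"delta": B(2.8, 0.8, 0.99), "theta": B(7.0, 0.8), "alpha": B(9.5, 0.5),  "beta": B(22.0, 1.1), "gamma": B(36.0, 0.5)},
    }
    # The broad 0.5-20 Hz EOG band admits far more background power than a
    # narrow rhythm band, so the slow eye-movement oscillator needs a very
    # high Q to remain the dominant spectral peak after normalization.
    eog = {
        "W": B(3.0, 1.5, 0.99),
        "N1": B(2.2, 1.0, 0.99),
        "N2": B(1.9, 0.4, 0.99),
        "N3": B(1.8, 0.3, 0.99),
        "REM": B(2.6, 1.3, 0.99),
    }
    return StageProfile(eeg=eeg, eog=eog)


DEFAULT_PROFILE = _default_profile()


def _ar2_stationary_std(C: np.ndarray) -> np.ndarray:
    """Stationary std of an AR(2) process with unit-variance driving noise."""
    c1, c2 = C[:, 0], C[:, 1]
    var = (1.0 - c2) / ((1.0 + c2) * ((1.0 - c2) ** 2 - c1**2))
    return np.sqrt(np.maximum(var, 1e-12))


def _stage_component(
    stage_per_sample: list[str],
    params: Mapping[str, BandState],
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One TVAR(2) component following per-stage parameters.

    Stage transitions in angle, radius and amplitude are smoothed over 1 s.
    Returns (signal, true IF in Hz).
    """
    n = len(stage_per_sample)
    centers = np.array([params[s].center_hz for s in stage_per_sample])
    radii = np.array([params[s].radius for s in stage_per_sample])
    amps = np.array([params[s].amplitude for s in stage_per_sample])
    w = max(3, int(round(fs)))
    angle = uniform_filter1d(2 * np.pi * centers / fs, w, mode="nearest")
    radius = uniform_filter1d(radii, w, mode="nearest")
    amp = uniform_filter1d(amps, w, mode="nearest")
    sched = PoleSchedule(radius=radius, angle=angle, fs=fs)
    C = sched.coefficients()
    y = _simulate_tvar(C, rng.normal(size=n))
    y = y / _ar2_stationary_std(C) * amp
    return y, sched.true_if_hz()


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f amplitude spectrum."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    pink = np.fft.irfft(spec / np.sqrt(f), n)
    return pink / np.std(pink)


def simulate_recording(
    stage_sequence: Sequence[str],
    fs: float = 100.0,
    seed: int = 0,
    profile: StageProfile = DEFAULT_PROFILE,
    subject_id: str = "synth",
    recording_id: str = "synth-rec",
    start_time: _dt.datetime | None = None,
    band_edges: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[MultichannelRecording, Hypnogram, dict]:
    """Synthesize a 2-EEG + 1-EOG recording following a stage sequence.

    Each EEG channel is the sum over the five rhythm bands of a TVAR(2)
    component with stage-dependent center frequency, amplitude and pole
    radius, plus 1/f background noise; the second EEG channel uses the same
    profile at 80% amplitude with independent noise. The EOG channel is a
    single band-limited component. Returns the recording, the matching
    Hypnogram (raw Sleep-EDFx-style labels), and a ground-truth dict mapping
    (channel_role, band) -> true IF (Hz, per sample).
    """
    if band_edges is None:
        band_edges = {
            "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0), "gamma": (30.0, 50.0),
        }
    profile.validate(band_edges)
    if start_time is None:
        start_time = _dt.datetime(2000, 1, 1, 23, 0, 0)
    rng = np.random.default_rng(seed)
    spe = int(round(fs * EPOCH_LEN_S))
    stage_per_sample: list[str] = []
    for s in stage_sequence:
        stage_per_sample.extend([s] * spe)
    n = len(stage_per_sample)

    truth: dict[tuple[str, str], np.ndarray] = {}
    channels, names = [], []
    for role, gain in (("FpzCz", 1.0), ("PzOz", 0.8)):
        x = np.zeros(n)
        comp_rms = 0.0
        for band in band_edges:
            y, if_true = _stage_component(stage_per_sample, {
                s: dataclasses.replace(profile.eeg[s][band],
                                       amplitude=gain * profile.eeg[s][band].amplitude)
                for s in profile.eeg
            }, fs, rng)
            x += y
            comp_rms += float(np.std(y))
            truth[(role, band)] = if_true
        x += profile.noise_floor * comp_rms * _pink_noise(n, rng)
        channels.append(x)
        names.append(role)

    eog, eog_if = _stage_component(stage_per_sample, profile.eog, fs, rng)
    eog += profile.eog_noise_floor * float(np.std(eog)) * _pink_noise(n, rng)
    channels.append(eog)
    names.append("EOG")
    truth[("EOG", "eog")] = eog_if

    rec = MultichannelRecording(
        subject_id=subject_id,
        recording_id=recording_id,
        fs=fs,
        channels=names,
        samples=np.vstack(channels),
        start_time=start_time,
    )
    hyp = Hypnogram(
        raw_labels=[_STAGE_TO_RAW[s] for s in stage_sequence],
        epoch_start_times=[
            start_time + _dt.timedelta(seconds=EPOCH_LEN_S * i)
            for i in range(len(stage_sequence))
        ],
    )
    return rec, hyp, truth
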
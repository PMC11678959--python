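"""TVAR(2) coefficient tracking with a Kalman filter / RTS smoother.

A narrow-band, envelope-normalized signal y_n is modeled as a second-order
autoregression with slowly drifting coefficients,

    y_n = c1(n) y_{n-1} + c2(n) y_{n-2} + v_n,      v_n ~ N(0, r)

and the coefficient vector c_n = (c1, c2)^T is taken to follow a random walk
with diagonal process covariance Q = diag(q1, q2). The forward Kalman filter
(Joseph-stabilized covariance update) tracks c_n causally; the
Rauch-Tung-Striebel fixed-interval smoother refines the whole track offline.

The spectral peak of the fitted TVAR(2) transfer function
H(z;n) = 1 / (1 - c1 z^-1 - c2 z^-2) sits at

    omega0(n) = arccos( c1 (c2 - 1) / (4 c2) ),     IF(n) = fs * omega0 / (2*pi)

which is the model-based instantaneous frequency. Complex-conjugate poles of
radius r and angle phi correspond to c1 = 2 r cos(phi), c2 = -r^2; the radius
measures how oscillatory (high-Q) the band is.

Filter consistency is monitored by the sliding-window ratio of the realized to
the predicted innovation variance (lambda); it fluctuates around 1 when the
noise covariances are set correctly, which is also the calibration criterion
used by :func:`tune_rho`.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KFConfig",
    "KFTrace",
    "TVARTrack",
    "yule_walker_ar2",
    "kf_forward",
    "rts_smooth",
    "coeffs_to_spectral_peak",
    "spectral_peak_track",
    "if_confidence",
    "track_if",
    "tune_rho",
]

START = 2  # first sample with two predecessors; the recursion starts here
DEFAULT_P0_SCALE = 100.0
DEFAULT_WARMUP_S = 30.0


@dataclasses.dataclass
class KFConfig:
    """Noise model and initialization of the coefficient-tracking filter.

    ``rho`` is the per-coefficient process/measurement noise ratio
    (q1/r, q2/r); the state estimates depend on the noises only through this
    ratio, while ``r_abs`` (the absolute measurement-noise variance) pins the
    scale of the innovation monitor. ``P0`` should deliberately overestimate
    the initial coefficient uncertainty (default 100*I).
    """

    mu0: np.ndarray
    P0: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_P0_SCALE * np.eye(2)
    )
    rho: np.ndarray = dataclasses.field(default_factory=lambda: np.array([1e-5, 1e-5]))
    r_abs: float = 1.0
    monitor_window_s: float = 10.0

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(2)
        self.P0 = np.asarray(self.P0, dtype=float).reshape(2, 2)
        self.rho = np.asarray(self.rho, dtype=float).reshape(2)
        if not np.allclose(self.P0, self.P0.T):
            raise ValueError("P0 must be symmetric")
        if np.any(np.linalg.eigvalsh(self.P0) <= 0):
            raise ValueError("P0 must be positive definite")
        if np.any(self.rho <= 0) or self.r_abs <= 0 or self.monitor_window_s <= 0:
            raise ValueError("rho, r_abs and monitor_window_s must be positive")

    @property
    def q(self) -> np.ndarray:
        """Diagonal of the process-noise covariance Q = rho * r_abs."""
        return self.rho * self.r_abs


@dataclasses.dataclass
class KFTrace:
    """Full forward-pass record (priors, posteriors, gains, innovations)."""

    c_prior: np.ndarray     # (n, 2)
    c_post: np.ndarray      # (n, 2)
    P_prior: np.ndarray     # (n, 2, 2)
    P_post: np.ndarray      # (n, 2, 2)
    gain: np.ndarray        # (n, 2)
    innovation: np.ndarray  # (n,)
    innov_var_pred: np.ndarray  # (n,) h^T P^- h + r
    lam: np.ndarray         # (n,) innovation monitor, NaN before START
    fs: float
    cfg: KFConfig


@dataclasses.dataclass
class TVARTrack:
    """Per-sample model-based IF track with uncertainty and pole geometry."""

    c: np.ndarray            # (n, 2) smoothed (or filtered) coefficients
    P: np.ndarray            # (n, 2, 2)
    omega0: np.ndarray       # radians/sample
    if_hz: np.ndarray
    sigma_if: np.ndarray     # delta-method std of if_hz
    pole_radius: np.ndarray
    pole_angle: np.ndarray
    valid: np.ndarray        # spectral peak well-defined and model stable
    warmed_up: np.ndarray    # past the initial convergence window
    lam: np.ndarray
    fs: float
    smoothed: bool


def yule_walker_ar2(x: np.ndarray) -> np.ndarray:
    """Offline AR(2) fit (c1, c2) by the Yule-Walker method.

    Uses biased autocovariances (statsmodels ``method="mle"``); the sign
    convention matches y_n = c1 y_{n-1} + c2 y_{n-2} + v_n.
    """
    from statsmodels.regression.linear_model import yule_walker

    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if np.var(x) == 0:
        raise ValueError("constant (zero-variance) signal has no AR structure")
    coeffs, _sigma = yule_walker(x, order=2, method="mle", demean=True)
    return np.asarray(coeffs, dtype=float)


def lambda_monitor(innovation: np.ndarray, innov_var_pred: np.ndarray, L: int,
                   start: int = START) -> np.ndarray:
    """Sliding-window ratio of realized to predicted innovation variance.

    lambda_n averages e_k^2 / (h_k^T P_k^- h_k + r) over the trailing window
    of length ``L`` (shorter near the start); NaN before ``start``.
    """
    n = len(innovation)
    lam = np.full(n, np.nan)
    ratio = np.zeros(n)
    ratio[start:] = innovation[start:] ** 2 / innov_var_pred[start:]
    csum = np.concatenate([[0.0], np.cumsum(ratio)])
    for_idx = np.arange(start, n)
    lo = np.maximum(for_idx - L + 1, start)
    lam[start:] = (csum[for_idx + 1] - csum[lo]) / (for_idx + 1 - lo)
    return lam


def kf_forward(x: np.ndarray, cfg: KFConfig, fs: float) -> KFTrace:
    """Forward Kalman filter for the random-walk TVAR(2) coefficient model.

    The regressor at sample n is h_n = (x_{n-1}, x_{n-2})^T, so the recursion
    starts at n = 2; samples 0 and 1 carry the initial state. The covariance
    posterior uses the Joseph form, which keeps it symmetric PSD.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")

    q1, q2 = cfg.q
    r = cfg.r_abs
    c_prior = np.empty((n, 2))
    c_post = np.empty((n, 2))
    P_prior = np.empty((n, 2, 2))
    P_post = np.empty((n, 2, 2))
    gain = np.zeros((n, 2))
    innov = np.zeros(n)
    ivar = np.full(n, r)

    c1, c2 = float(cfg.mu0[0]), float(cfg.mu0[1])
    p11, p12, p22 = float(cfg.P0[0, 0]), float(cfg.P0[0, 1]), float(cfg.P0[1, 1])
    c_prior[:START] = c_post[:START] = (c1, c2)
    P_prior[:START] = P_post[:START] = [[p11, p12], [p12, p22]]

    xf = x.tolist()  # plain floats: the scalar loop is ~3x faster than ndarray indexing
    for k in range(START, n):
        # time update (the first step uses the initial prior as-is)
        if k > START:
            p11 += q1
            p22 += q2
        h1 = xf[k - 1]
        h2 = xf[k - 2]
        c_prior[k, 0] = c1
        c_prior[k, 1] = c2
        P_prior[k, 0, 0] = p11
        P_prior[k, 0, 1] = P_prior[k, 1, 0] = p12
        P_prior[k, 1, 1] = p22

        ph1 = p11 * h1 + p12 * h2
        ph2 = p12 * h1 + p22 * h2
        s = h1 * ph1 + h2 * ph2 + r
        k1 = ph1 / s
        k2 = ph2 / s
        e = xf[k] - (h1 * c1 + h2 * c2)
        c1 += k1 * e
        c2 += k2 * e

        # Joseph form: P+ = (I - k h^T) P- (I - k h^T)^T + r k k^T
        a11 = 1.0 - k1 * h1
        a12 = -k1 * h2
        a21 = -k2 * h1
        a22 = 1.0 - k2 * h2
        b11 = a11 * p11 + a12 * p12
        b12 = a11 * p12 + a12 * p22
        b21 = a21 * p11 + a22 * p12
        b22 = a21 * p12 + a22 * p22
        p11 = b11 * a11 + b12 * a12 + r * k1 * k1
        np12 = b11 * a21 + b12 * a22 + r * k1 * k2
        p21 = b21 * a11 + b22 * a12 + r * k2 * k1
        p12 = 0.5 * (np12 + p21)
        p22 = b21 * a21 + b22 * a22 + r * k2 * k2

        c_post[k, 0] = c1
        c_post[k, 1] = c2
        P_post[k, 0, 0] = p11
        P_post[k, 0, 1] = P_post[k, 1, 0] = p12
        P_post[k, 1, 1] = p22
        gain[k, 0] = k1
        gain[k, 1] = k2
        innov[k] = e
        ivar[k] = s

    L = max(1, int(round(cfg.monitor_window_s * fs)))
    lam = lambda_monitor(innov, ivar, L)
    return KFTrace(c_prior, c_post, P_prior, P_post, gain, innov, ivar, lam, fs, cfg)


def rts_smooth(trace: KFTrace) -> tuple[np.ndarray, np.ndarray]:
    """Rauch-Tung-Striebel fixed-interval smoother over a forward trace.

    Returns (smoothed states (n,2), smoothed covariances (n,2,2)); the final
    sample equals the forward posterior. A singular one-step-ahead prior
    covariance is regularized with 1e-12*I (with a warning).
    """
    n = len(trace.innovation)
    cs = trace.c_post.copy()
    Ps = trace.P_post.copy()
    warned = False
    # scalar-unrolled 2x2 recursion (hot path: one step per sample)
    cpo = trace.c_post
    cpr = trace.c_prior
    Po = trace.P_post
    Pr = trace.P_prior
    s1, s2 = float(cpo[n - 1, 0]), float(cpo[n - 1, 1])
    sp11, sp12, sp22 = (
        float(Po[n - 1, 0, 0]),
        float(Po[n - 1, 0, 1]),
        float(Po[n - 1, 1, 1]),
    )
    for k in range(n - 2, -1, -1):
        a = Pr[k + 1, 0, 0]
        b = Pr[k + 1, 0, 1]
        d = Pr[k + 1, 1, 1]
        det = a * d - b * b
        if abs(det) < 1e-300:
            if not warned:
                warnings.warn("singular prior covariance in RTS pass; adding 1e-12 jitter")
                warned = True
            a += 1e-12
            d += 1e-12
            det = a * d - b * b
        # S = P_post[k] @ inv(P_prior[k+1])
        p11, p12, p22 = Po[k, 0, 0], Po[k, 0, 1], Po[k, 1, 1]
        S11 = (p11 * d - p12 * b) / det
        S12 = (-p11 * b + p12 * a) / det
        S21 = (p12 * d - p22 * b) / det
        S22 = (-p12 * b + p22 * a) / det
        dc1 = s1 - cpr[k + 1, 0]
        dc2 = s2 - cpr[k + 1, 1]
        s1 = cpo[k, 0] + S11 * dc1 + S12 * dc2
        s2 = cpo[k, 1] + S21 * dc1 + S22 * dc2
        # D = P_smooth[k+1] - P_prior[k+1]; P_smooth[k] = P_post[k] + S D S^T
        d11 = sp11 - a
        d12 = sp12 - b
        d22 = sp22 - d
        t11 = S11 * d11 + S12 * d12
        t12 = S11 * d12 + S12 * d22
        t21 = S21 * d11 + S22 * d12
        t22 = S21 * d12 + S22 * d22
        sp11 = p11 + t11 * S11 + t12 * S12
        x12 = p12 + t11 * S21 + t12 * S22
        x21 = p12 + t21 * S11 + t22 * S12
        sp12 = 0.5 * (x12 + x21)
        sp22 = p22 + t21 * S21 + t22 * S22
        cs[k, 0] = s1
        cs[k, 1] = s2
        Ps[k, 0, 0] = sp11
        Ps[k, 0, 1] = Ps[k, 1, 0] = sp12
        Ps[k, 1, 1] = sp22
    return cs, Ps


def coeffs_to_spectral_peak(c, fs: float):
    """Spectral peak and pole geometry of one AR(2) coefficient pair.

    Returns (omega0, if_hz, pole_radius, pole_angle, valid). ``valid`` is
    False when |c2| is numerically zero, when the arccos argument had to be
    clipped, when the poles are real (no oscillatory component), or when the
    stability conditions (c2 + c1 < 1, c2 - c1 < 1, |c2| < 1) fail.
    """
    o, f, r, a, v = spectral_peak_track(np.asarray(c, dtype=float).reshape(1, 2), fs)
    return o[0], f[0], r[0], a[0], bool(v[0])


def spectral_peak_track(C: np.ndarray, fs: float):
    """Vectorized :func:`coeffs_to_spectral_peak` over an (n, 2) array."""
    C = np.asarray(C, dtype=float)
    c1, c2 = C[:, 0], C[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = c1 * (c2 - 1.0) / (4.0 * c2)
    tiny = np.abs(c2) < 1e-6
    g = np.where(tiny, np.nan, g)
    clipped = np.abs(g) > 1.0
    omega0 = np.arccos(np.clip(g, -1.0, 1.0))
    if_hz = fs * omega0 / (2.0 * np.pi)

    disc = c1 * c1 + 4.0 * c2
    real_poles = disc >= 0
    # complex-conjugate pair: radius sqrt(-c2), angle from the pole's real/imag parts
    with np.errstate(invalid="ignore"):
        radius = np.where(real_poles, np.sqrt(np.abs(c2)), np.sqrt(np.maximum(-c2, 0.0)))
        angle = np.where(
            real_poles, 0.0, np.arctan2(np.sqrt(np.maximum(-disc, 0.0)) / 2.0, c1 / 2.0)
        )
    unstable = (c2 + c1 >= 1.0) | (c2 - c1 >= 1.0) | (np.abs(c2) >= 1.0)
    valid = ~(tiny | clipped | real_poles | unstable) & np.isfinite(g)
    return omega0, if_hz, radius, angle, valid


def if_confidence(c: np.ndarray, P: np.ndarray, fs: float) -> float:
    """Delta-method standard deviation of the model-based IF (Hz).

    First-order propagation of the coefficient covariance P through the
    arccos spectral-peak map; requires a valid (complex-pole, unclipped)
    spectral peak.
    """
    s = _sigma_if_track(np.asarray(c, float).reshape(1, 2),
                        np.asarray(P, float).reshape(1, 2, 2), fs)
    return float(s[0])


def _sigma_if_track(C: np.ndarray, P: np.ndarray, fs: float) -> np.ndarray:
    c1, c2 = C[:, 0], C[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = c1 * (c2 - 1.0) / (4.0 * c2)
        dg1 = (c2 - 1.0) / (4.0 * c2)           # dg/dc1
        dg2 = c1 / (4.0 * c2 * c2)              # dg/dc2
        dom = -1.0 / np.sqrt(1.0 - g * g)       # domega0/dg
        g1 = dom * dg1
        g2 = dom * dg2
        var = (
            g1 * g1 * P[:, 0, 0] + 2.0 * g1 * g2 * P[:, 0, 1] + g2 * g2 * P[:, 1, 1]
        )
    with np.errstate(invalid="ignore"):
        return fs / (2.0 * np.pi) * np.sqrt(np.maximum(var, 0.0))


def track_if(
    x_norm: np.ndarray,
    cfg: KFConfig,
    fs: float,
    smooth: bool = True,
    warmup_s: float = DEFAULT_WARMUP_S,
) -> TVARTrack:
    """Track the model-based IF of an envelope-normalized band signal.

    Runs the forward filter, optionally the RTS smoother, then converts the
    per-sample coefficients to spectral-peak frequency, pole geometry and
    delta-method confidence. Samples inside the initial ``warmup_s`` window
    are reported but flagged ``warmed_up=False``.
    """
    trace = kf_forward(x_norm, cfg, fs)
    if smooth:
        C, P = rts_smooth(trace)
    else:
        C, P = trace.c_post, trace.P_post
    omega0, if_hz, radius, angle, valid = spectral_peak_track(C, fs)
    valid = valid.copy()
    valid[:START] = False
    sigma = _sigma_if_track(C, P, fs)
    sigma = np.where(valid, sigma, np.nan)
    warmed = np.arange(len(x_norm)) >= int(round(warmup_s * fs))
    return TVARTrack(
        c=C, P=P, omega0=omega0, if_hz=if_hz, sigma_if=sigma,
        pole_radius=radius, pole_angle=angle, valid=valid, warmed_up=warmed,
        lam=trace.lam, fs=fs, smoothed=smooth,
    )


def tune_rho(
    x_norm: np.ndarray,
    fs: float,
    grid=(1e-7, 1e-6, 1e-5, 1e-4, 1e-3),
    calib_s: float = 60.0,
    monitor_window_s: float = 10.0,
    r_abs: float = 1.0,
) -> KFConfig:
    """Calibrate the noise ratio on the leading ``calib_s`` seconds.

    For each candidate ratio the forward filter is run and the absolute noise
    scale is fixed analytically: multiplying q, r and P0 jointly by the
    achieved mean innovation monitor leaves the gains (hence the states and
    innovations) unchanged and scales the monitor inversely, so the rescaled
    filter has mean lambda = 1 by construction. Among the candidates, the one
    with the whitest innovations (smallest |lag-1 autocorrelation|, computed
    after the monitor window) wins; ties break toward the smaller ratio.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty candidate grid")
    L = int(round(monitor_window_s * fs))
    n_cal = int(round(calib_s * fs))
    if n_cal > len(x_norm):
        n_cal = len(x_norm)
    if n_cal < 3 * L:
        raise ValueError(
            f"calibration segment ({n_cal} samples) shorter than 3 monitor windows ({3 * L})"
        )
    seg = np.asarray(x_norm, dtype=float)[:n_cal]
    mu0 = yule_walker_ar2(seg)

    best = None
    for rho in sorted(grid):
        cfg = KFConfig(
            mu0=mu0, rho=np.array([rho, rho]), r_abs=r_abs,
            monitor_window_s=monitor_window_s,
        )
        trace = kf_forward(seg, cfg, fs)
        sel = slice(START + L, None)  # past the first full monitor window
        lam_mean = float(np.nanmean(trace.lam[sel]))
        e = trace.innovation[sel]
        e = e - e.mean()
        denom = float(e @ e)
        acf1 = abs(float(e[1:] @ e[:-1]) / denom) if denom > 0 else np.inf
        if best is None or acf1 < best[0] - 1e-12:
            best = (acf1, rho, lam_mean)
    _, rho_star, lam_mean = best
    scale = lam_mean if lam_mean > 0 else 1.0
    logger.info("tune_rho: selected rho=%.3g, lambda rescale %.3g", rho_star, scale)
    return KFConfig(
        mu0=mu0,
        P0=DEFAULT_P0_SCALE * scale * np.eye(2),
        rho=np.array([rho_star, rho_star]),
        r_abs=r_abs * scale,
        monitor_window_s=monitor_window_s,
    )
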
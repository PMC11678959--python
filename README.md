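# sleepif

Model-based instantaneous-frequency (IF) tracking of EEG rhythms and automated
sleep staging.

Sleep stages (W, N1, N2, N3, REM) manifest in the EEG as shifts in the dominant
frequency and amplitude of the classical rhythm bands — delta (0.5–4 Hz), theta
(4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz) and gamma (30–50 Hz). Non-parametric
IF estimators such as the Hilbert phase derivative are badly degraded by
background cerebral activity. `sleepif` instead models each narrow band as a
**time-varying autoregression of order 2**,

```
y_n = c1(n) y_{n-1} + c2(n) y_{n-2} + v_n,          v_n ~ N(0, r)
```

whose coefficient vector c_n = (c1, c2)ᵀ follows a random walk with process
covariance Q = diag(q1, q2). A **Kalman filter** (Joseph-stabilized) tracks
c_n; a **Rauch–Tung–Striebel fixed-interval smoother** refines the track
offline. The TVAR(2) spectrum peaks at

```
omega0(n) = arccos( c1(n) [c2(n) − 1] / [4 c2(n)] ),    IF(n) = fs·omega0(n) / 2π
```

which serves as the model-based IF, with a delta-method confidence band
sigma_IF propagated from the state covariance, and the pole radius
r(n) = √(−c2) as a per-sample oscillation-quality (Q-factor) measure. Filter
calibration is monitored by the sliding-window ratio λ of realized to
predicted innovation variance, which fluctuates around 1 when q/r is right;
`tune_rho` selects the ratio on a leading calibration segment by innovation
whiteness and pins the absolute scale by rescaling to mean λ = 1.

For staging, each 30 s epoch is summarized by 22 features — mean IF and mean
instantaneous envelope (IE, the analytic-signal modulus) for 5 bands × 2 EEG
channels (Fpz–Cz, Pz–Oz) plus one broad-band (0.5–20 Hz) EOG pair — and
classified either directly into the five stages (one-step) or W/NREM/REM first
and then N1/N2/N3 within NREM (two-step), with class weights from typical
sleep-architecture proportions, under subject-wise 10-fold cross-validation
evaluated on the 22:00–08:00 window.

A synthetic-data module generates TVAR(2) processes with prescribed pole
trajectories and multichannel "sleep-like" recordings with Markov-chain
hypnograms, so the whole pipeline is testable end to end with known ground
truth and no external data.

## Worked example

Track a frequency ramp whose pole angle sweeps 10 → 20 Hz over 60 s
(pole radius 0.97, fs = 100 Hz):

```python
import numpy as np
from sleepif import analytic
from sleepif.synthetic import PoleSchedule, simulate_tvar2
from sleepif.tvar_kalman import KFConfig, track_if, yule_walker_ar2

fs, n = 100.0, 6000
schedule = PoleSchedule(radius=np.full(n, 0.97),
                        angle=np.linspace(0.2 * np.pi, 0.4 * np.pi, n), fs=fs)
y, truth = simulate_tvar2(schedule, seed=0)

dec = analytic.analytic_decompose(y, fs)          # IE + Hilbert IF
y_norm = analytic.normalize_by_envelope(y, dec)   # flatten amplitude
cfg = KFConfig(mu0=yule_walker_ar2(y_norm), rho=np.array([1e-5, 1e-5]))
track = track_if(y_norm, cfg, fs, smooth=True)    # KF + RTS smoother
```

Comparing both IF estimates to the scheduled truth on the middle 80%:

```
true IF range      : 9.99 -> 20.00 Hz
Kalman-smoother IF : RMSE 0.230 Hz
Hilbert IF         : RMSE 3.916 Hz
mean sigma_IF      : 0.561 Hz
median pole radius : 0.938 (true 0.970)
```

The smoothed model-based IF follows the ramp to within a quarter Hz while the
raw Hilbert IF is an order of magnitude noisier; `sigma_if` gives a usable
per-sample confidence band and the pole radius stays near the generating
Q-factor.

## Command line

The `sleepif` entry point mirrors the pipeline stages:

```sh
sleepif simulate --minutes 10 --seed 1 --out-prefix night1    # synthetic EDF + hypnogram + truth
sleepif track night1-PSG.edf --channel "EEG Fpz-Cz" --band alpha --out alpha.tsv
sleepif features night1-PSG.edf night1-Hypnogram.edf --out night1.tsv
sleepif stage night1.tsv ... --scheme two_step --classifier lgbm --out metrics.json
sleepif tune night1-PSG.edf --band alpha                      # rho calibration report
sleepif print-config > pipeline.yaml                          # all defaults, editable
```

`features` consumes real Sleep-EDFx `*-PSG.edf` / `*-Hypnogram.edf` pairs with
the default channel mapping; R&K stage labels are mapped to AASM (S3/S4 → N3,
movement/unscored epochs dropped).

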
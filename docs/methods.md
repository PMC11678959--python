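# Methods

## Signal model

Each EEG rhythm band is assumed to carry, at any instant, a single dominant
oscillatory component. After zero-phase band-pass filtering, the band signal
y_n is modeled as a time-varying autoregression of order 2,

    y_n = c1(n) y_{n-1} + c2(n) y_{n-2} + v_n,     v_n ~ N(0, r),

equivalently a two-pole filter driven by white noise. Complex-conjugate poles
r_p e^{±jφ} correspond to c1 = 2 r_p cos φ, c2 = −r_p²: the pole angle sets
the resonance frequency, the radius its sharpness (Q-factor). The squared
magnitude response

    |H(e^{jω}; n)|² = [ (1 + c1² + c2²) + 2 c1 (c2 − 1) cos ω − 2 c2 cos 2ω ]⁻¹

peaks at ω0(n) = arccos( c1(c2−1) / (4c2) ), and IF(n) = fs·ω0/2π is the
model-based instantaneous frequency. Order 2 is deliberate: one oscillatory
degree of freedom per band, so the per-band IF is unambiguous and the
parameters stay physically interpretable.

**Peak existence.** The arccos argument lies in [−1, 1] only when
cos φ < 2 r_p/(1 + r_p²); below that bound (slow, low-Q oscillations) the
AR(2) spectrum is monotone (low-pass) and has no off-zero peak. Such samples,
samples with real poles (c1² + 4c2 ≥ 0), with |c2| < 1e−6, or violating the
stability conditions (c2 ± c1 < 1, |c2| < 1) are flagged invalid rather than
clamped or projected; downstream epoch averages ignore them. Stability is
monitored, never enforced.

## Tracking

With state c_n = (c1, c2)ᵀ, random-walk dynamics c_{n+1} = c_n + w_n
(w ~ N(0, Q), Q = diag(q1, q2)) and observation row h_n = (y_{n−1}, y_{n−2}),
the forward Kalman filter runs from n = 2 (the first sample with two
predecessors). The covariance posterior uses the Joseph form
P⁺ = (I − k hᵀ) P⁻ (I − k hᵀ)ᵀ + r k kᵀ, which keeps P symmetric positive
semidefinite; the inner loops are hand-unrolled 2×2 scalar arithmetic (≈5 µs
per sample per pass in CPython), so whole-night recordings are tractable
without compiled extensions.

Offline tracks are refined by the fixed-interval Rauch–Tung–Striebel smoother
(smoother gain S_n = P_n⁺ [P_{n+1}⁻]⁻¹; a singular prior covariance gets
1e−12·I jitter with a warning). The smoother is the default for feature
extraction; the causal filter remains selectable (`smooth=False`).

Initialization: μ0 from an offline Yule–Walker AR(2) fit (biased
autocovariances, via statsmodels) on the signal, P0 = 100·I — a deliberate
one-to-two-orders-of-magnitude overestimate so the filter forgets the initial
condition quickly. The first 30 s of every track are flagged not-yet-converged
(`warmed_up=False`): still reported, excluded from epoch features.

**Confidence band.** σ_IF is first-order (delta-method) propagation of the
state covariance through the arccos peak map: with g = c1(c2−1)/(4c2),
∂g/∂c1 = (c2−1)/(4c2), ∂g/∂c2 = c1/(4c2²), ∂ω0/∂g = −1/√(1−g²), and
σ_IF = (fs/2π)·√(∇ω0ᵀ P ∇ω0). Against a 10⁵-draw Monte-Carlo push-through at
P = 1e−4·I the approximation agrees to better than 10% (tested); it degrades
as |g| → 1, where the samples are near the invalid boundary anyway.

## Noise calibration

The state estimates depend on (Q, r) only through the ratio ρ = diag(Q)/r, so
a single scalar per band is tuned. Consistency is monitored by

    λ_n = (1/L) Σ_{k=n−L+1..n} e_k² / (h_kᵀ P_k⁻ h_k + r),

the ratio of realized to predicted innovation variance over a sliding window
(default 10 s; the window length is not dictated by the model and is exposed
in config). For a correctly specified filter E[λ] = 1.

`tune_rho` calibrates on the leading segment (default 60 s) in two stages:
(i) for each candidate ρ on a log grid, run the filter once and rescale
(q, r, P0) jointly by the achieved mean λ — gains are invariant under joint
scaling while λ scales inversely, so the rescaled filter has mean λ = 1 by
construction without a second pass; (ii) select the candidate with the
smallest |lag-1 innovation autocorrelation| (whitest innovations), ties toward
the smaller ρ. On simulated data whose true ratio lies on a 100×-spaced grid
the selection recovers it in ≥80% of seeded runs; neighboring 10×-spaced
candidates produce nearly equally white innovations and are not reliably
distinguished on short calibration segments — a known identifiability limit,
which is why the default grid spans 1e−7…1e−3 but production use should
prefer coarse grids. P0 scales with the λ rescale so that ratio invariance is
exact rather than asymptotic (documented deviation from keeping P0 in fixed
coefficient units).

When `tune=False`, the pipeline default is ρ = 1e−7 for all bands: per-band
frequencies drift slowly at the 30 s feature scale, and small ρ both smooths
the track and keeps the slow bands (delta, EOG) away from the real-pole
boundary, where coefficient jitter would otherwise invalidate samples.

## Pipeline and features

1. Zero-phase forward–backward FIR band-pass filtering. Windowed-sinc
   (Hamming) designs; default order = smallest even integer ≥ 3·fs/f_low
   (≈3 cycles of the lower cutoff), capped at 1001 taps; reflect padding of
   3× tap count suppresses edge transients. The gamma band is designed with
   its upper edge at 0.99·fs/2 when the nominal 50 Hz touches Nyquist
   (fs = 100), while keeping its nominal name. EEG channels get the five
   rhythm bands; the EOG channel one broad 0.5–20 Hz band.
2. Analytic decomposition per band: IE = |y + jH{y}|, IP unwrapped, Hilbert
   IF = scaled first phase difference. Phase differences are wrapped into
   [0, 2π) then folded to [0, fs/2] (real signals have symmetric spectra);
   the first sample copies the second. IE is captured *before* normalization.
3. Envelope normalization ȳ = y/max(A, ε) with ε = 1e−8 × median envelope —
   the division is undefined at zero envelope; sub-ε samples are flagged
   invalid. Normalization flattens amplitude to ≈1, removing the envelope's
   bias on frequency estimation (it deliberately alters the signal's apparent
   bandwidth, which is why pole-radius fidelity is assessed on the raw
   signal).
4. KF/RTS IF tracking on the normalized signal (per band).
5. Non-overlapping 30 s epoch means of IF and IE over valid samples. 22
   features per epoch: (FpzCz, PzOz) × (delta…gamma) × (IF, IE) + EOG (IF,
   IE), in a fixed documented column order. An epoch with <50% valid samples
   in any feature is dropped and logged. The epoch grid is anchored at the
   recording's first sample (Sleep-EDFx convention); hypnogram labels map
   R&K → AASM (S3/S4 → N3; movement time and unscored epochs removed, not
   re-labeled).

## Staging

`SleepStageClassifier` (scikit-learn estimator) offers `one_step` (5-class)
and `two_step` (W/NREM/REM, then N1/N2/N3 on rows predicted NREM; final
probabilities compose multiplicatively, p(N_i) = p(NREM)·p2(N_i) — the
composition rule is a design choice). Imbalance is handled by per-class
sample weights ∝ target/empirical proportion with targets from typical
healthy-adult architecture (N1 5%, N2 45%, N3 25%, REM 25%; within NREM
20/66/14%). Wake has no published target proportion and keeps a neutral
weight (target = empirical). Backends: logistic regression and linear SVM
(scaled pipelines), XGBoost, LightGBM; the test suite uses only the
deterministic logistic backend.

Cross-validation is subject-wise: all recordings of a subject share a fold;
fold sizes differ by at most one (78 subjects → eight folds of 8 and two of
7 — exactly eight per fold for ten folds is arithmetically impossible).
Training uses all epochs of training subjects; evaluation keeps only epochs
starting in [22:00, 08:00). Reported: per-fold accuracy, macro-F1 and Cohen's
κ (mean ± sd across folds; per-fold macro-F1 averages over the stages present
in that fold so absent rare stages do not contribute zeros), row-normalized
confusion (mean ± sd across folds), and pooled per-class sensitivity,
precision *and* specificity — precision is reported alongside specificity
because the two are easily conflated in the literature and they differ
sharply on imbalanced stages.

## Synthetic data

The generator produces what the method assumes, with exact ground truth:

- `simulate_tvar2`: a TVAR(2) process along a prescribed pole
  radius/angle schedule; true IF is the closed-form peak of the scheduled
  coefficients. `simulate_tvar2_random_walk` draws the coefficients from the
  filter's own random-walk model (increments reflected at the stability
  boundary with a 0.02 margin, so the process-noise variance must be small
  enough that reflections are rare).
- `markov_hypnogram`: first-order Markov stage sequences (default transition
  matrix: sticky stages, W→N1→N2→{N3, REM} progression).
- `simulate_recording`: two EEG channels (second at 80% amplitude with
  independent noise) as sums of five per-band TVAR(2) oscillators whose
  center frequency, amplitude and pole radius depend on the stage (defaults:
  gamma/beta strong in W, beta high again in REM, theta raised in N1, delta
  dominant in N3; EOG amplitude high in W/REM), plus 1/f background noise at
  5% of the summed component RMS (the EOG band, being broad, gets its own 5%
  floor), stage transitions smoothed over 1 s. Slow oscillators (delta, EOG)
  use pole radius 0.99 and centers ≥1.4 Hz: in-band background lowers the
  *tracked* radius to ≈0.9, and below ≈1.4 Hz the fitted model's spectral
  peak stops existing (see Peak existence) — placing the defaults inside that
  bound keeps the generated truth recoverable, which is the generator's
  purpose. All generators are bit-reproducible given (parameters, seed).

What the generator does **not** emulate: real EEG morphology (spindles,
K-complexes, artifacts, 1/f-embedded broadband bursts), inter-subject
variability of rhythm frequencies, or EOG saccade waveforms. Passing the
staging sanity checks therefore demonstrates that the pipeline preserves
stage-discriminative IF/IE structure end to end — not that the published
real-data accuracy is reproduced. The problem sizes in the tests (10–30 min
recordings, 12 synthetic subjects, 20-seed property checks) were chosen as
the smallest that make the statistical assertions stable.

## Numerical choices and edge cases

- arccos argument clipped to [−1, 1]; clipped samples flagged invalid.
- All-zero band signal: zero envelope, whole track invalid.
- 2×2 inversions use the closed-form adjugate; |det| < 1e−300 triggers the
  jitter path.
- Feature tables are TSV with 17-significant-digit floats (lossless float64
  round trip); metrics are JSON.
- EDF I/O: reading via mne; a minimal EDF/EDF+ writer (16-bit, per-channel
  symmetric physical range, ≈3e−5 relative quantization error) serializes
  synthetic recordings and hypnogram annotation files. It is not a
  general-purpose EDF exporter.

## Known limitations

- TVAR(2) tracks exactly one dominant component per band; multi-component
  bands (e.g. spindle + slow wave inside one band) violate the model.
- Delta-band IF is biased toward the band's power-weighted center when the
  oscillator is weak relative to in-band background — visible in the
  generator's low-amplitude stages and expected on real data.
- The whiteness-based ρ selection cannot separate 10×-spaced candidates on
  short calibration segments (see Noise calibration).
- The two-step probability composition assumes step-1 and step-2 errors are
  independent.
- No artifact handling; movement epochs are dropped only via hypnogram
  labels.
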
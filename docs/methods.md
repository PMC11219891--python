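# Methods

This note records the models, parameter choices and numerical decisions
behind ecgkit, and what the synthetic test bed does and does not show.

## Synthetic ECG model

A beat is a sum of five Gaussian bumps, one per wave (P, Q, R, S, T), each
parameterised by amplitude (mV), centre offset from the R peak (s) and
width (s). This closed form is deliberately minimal: it reproduces the
morphology distinctions the downstream stages rely on (P presence, QRS
width, T polarity, R amplitude) without a dynamical model of the cardiac
cycle. Two classes ship by default:

- **N** (normal): P 0.15 mV at −200 ms, narrow R of 1.0 mV, upright T;
- **V** (ventricular ectopic): no P wave, broad high R (σ 34 ms vs 11 ms),
  deep slurred S, discordant (negative) T, and a premature coupling
  interval drawn uniformly in 0.3–0.5 s.

Rhythms are regular (default RR 0.8 s with optional Gaussian jitter,
σ 20 ms) with ectopics inserted at a per-beat probability (default 0.18 in
the pipeline configuration, enough for both classes to populate train and
test splits at ~200 beats).

Noise is additive: a baseline sinusoid (amplitude 0.3 mV at 0.3 Hz by
default; the model range is 0–1 Hz), mains interference at 50 or 60 Hz
with 1/h-scaled harmonics (default 0.15 mV, 2 harmonics), and white
Gaussian noise (default σ 0.03 mV). One top-level seed derives an
independent sub-stream per component, so enabling one component never
changes another's draw. Acquisition is modelled by mid-tread uniform
quantization: step `range/2^bits` (11 bits over 10 mV ⇒ ~4.9 µV), values
clipped at the rails with a warning. Quantization is idempotent.

What the generator does **not** emulate: respiration-modulated heart-rate
variability, electrode-motion artefacts (step/impulse transients), muscle
noise with its non-white spectrum, multi-lead projection geometry, or the
beat-to-beat morphology variability of real recordings. Tests passing on
this bed therefore demonstrate correctness of the algorithms under their
stated models, not clinical-grade detection/classification performance on
real archives.

## Denoising filters

All combs derive from the integer running-sum kernel
`(1 − z⁻ᴺ)/(1 − z⁻¹)` (zeros at multiples of fs/N, the z = 1 pole cancels
the DC zero, DC gain N). Coefficients are stored as integers; the 1/N or
1/M normalisations are carried in a symbolic scale factor applied once at
the output, so the recursion itself uses exact integer arithmetic.

- **Baseline high-pass:** `z^(−M/2) − (1/M)(1 − z⁻ᴹ)/(1 − z⁻¹)` with
  M = round(fs / 2 Hz) evened (240 at 480 Hz). DC gain is exactly zero;
  at 50 Hz the deviation from unity is the comb sidelobe
  `1/(M sin(πf/fs))` ≈ 1.3 %. The equivalent FIR has h[k] = −1/M except
  h[M/2] = 1 − 1/M.
- **Power-line comb:** N = round(fs / f_mains); when fs/f_mains is not an
  integer (e.g. 360 Hz with 50 Hz mains) the zero lands at fs/N instead
  and a warning is logged rather than silently retuning — the construction
  is kept, the mismatch surfaced.
- **Comb order:** the default cascade uses the first-order comb. The
  second-order variant (squared moving sum) doubles the notch multiplicity
  but its passband droop at 40 Hz (≈0.06 vs ≈0.24 amplitude at
  N = 10) distorts QRS energy enough to pull the 5–40 Hz band correlation
  of a clean record below 0.99; first order preserves it. Order 2 remains
  available via `comb_order=2`.
- **Delay compensation** is an integer-sample shift by the nominal group
  delay (M/2 for the high-pass, (N−1)/2·order for the combs), not
  forward–backward filtering, preserving the causal cascade. With the
  defaults every stage delay is an integer.
- **Stability:** the recursive comb forms have on-circle poles that are
  exactly cancelled (verified by polynomial division); uncancelled
  on-or-outside-circle poles trigger a warning.

FIR design: the window method computes the ideal impulse response of a
piecewise-constant desired amplitude in closed form (differences of
sampled sincs per band) and tapers it; the minimax design runs Remez
exchange (50 iterations max) and symmetrises the returned taps. The
degenerate full-band constant spec is represented exactly by a scaled
centred impulse. The amplitude (zero-phase) response used in the weighted
error is the complex response with the linear-phase carrier removed.

## Beat processing

R detection is the standard derivative–squaring–integration chain:
gradient, square, 150 ms moving integration, threshold at 25 % of the
integrated signal's maximum (relative, hence amplitude-invariant), 200 ms
refractory, then refinement to the raw-signal extremum within ±80 ms. The
RR filter drops any beat closer than 400 ms to the previously *retained*
beat (greedy, hence idempotent); the later beat of a short pair is treated
as the spurious one. Beat windows span 0.25 s before to 0.40 s after R
(234 samples at 360 Hz), sample counts by floor; edge beats are dropped
with a warning. The first beat's preceding RR is a NaN marker and is
median-imputed at the feature-matrix stage.

## Clustering and retention

Features are standardized per column before distances (mixed units would
otherwise dominate). Density clustering uses standard semantics: a point
with ≥ min_pts neighbours within eps (self included) is core; clusters are
maximal density-reachable sets grown breadth-first in row order, making
the border-point tie-break deterministic (first core cluster to reach a
border point claims it). Default min_pts 4; eps defaults to the knee of
the sorted 4-NN distance curve. CBCR discards, within each cluster, beats
farther from the medoid than `min(mean + k·std, max)` of member–medoid
distances (k = 3), plus all noise-labelled beats; the medoid itself is
never discarded. NCC pruning computes mean-removed, norm-scaled
cross-correlation over all lags, takes the signed value at the lag of
largest magnitude (so an inverted waveform scores −1, not a small positive
sidelobe), and retains beats scoring ≥ 0.6 against their cluster medoid.
Zero-variance windows have undefined NCC and are pruned with a warning.
The pipeline order is PCA → DBSCM → CBCR → NCC; each step is callable
independently.

## Wavelet analysis

The decomposition is the two-channel pyramid (conjugate filter pair +
dyadic downsampling), default db4 at 4 levels for 360 Hz beat windows.
Boundary handling is **periodic** ("periodization"): with an orthogonal
basis this keeps the transform orthogonal, so reconstruction is exact and
coefficient energy equals signal energy — the property the band-identity
checks (`x_{m−1} = x_m + d_m`, `x_0 = x_M + Σ d_m`, reconstructed by
linearity from zeroed coefficient sets) rest on. Energy equality is exact
when 2^levels divides the signal length; other lengths incur internal
padding and are reconstructed exactly but not energy-isometric.
Half-sample symmetric extension was considered and rejected for exactly
that reason: its redundant boundary coefficients break the energy
identity.

The eleven statistical parameters are fixed as: mean, median, std,
variance, RMS, skewness, kurtosis (population conventions; Pearson
normalisation for kurtosis), min, max, peak-to-peak, energy, with a
degenerate flag for constant windows. The set is versioned in one place so
an alternative eleven can be swapped in. Fiducial landmarks use a 10 ms
smoothed derivative: QRS onset/offset are the first/last crossings of 10 %
of the local derivative extremum within ±60/+80 ms of R; P and T peaks are
amplitude extrema in −280…−80 ms and +120…+420 ms windows, requiring
deviation above 2 % of the R amplitude. Missing landmarks yield NaN
markers, never zeros. The normalised sum-of-products autocorrelation uses
unbiased scaling `r(l)·N/((N−l)·r(0))` so a periodic signal scores ~1 at
its period.

## Classifiers

The kernel machine minimises `½‖w‖² + P Σ ξ_s²` subject to residuals
within an ε-tube plus slack. In the dual, with β_s the difference of the
two tube multipliers, the problem reduces to a strongly concave
maximisation of `−½βᵀKβ + bᵀβ − ε‖β‖₁ − ‖β‖²/(2P)` under Σβ = 0.

- ε = 0 (default): one (N+1)-dimensional linear KKT solve — a
  least-squares kernel machine. This is the pipeline's fast path.
- ε > 0: Gauss–Southwell pairwise coordinate ascent. Feasible directions
  are (+e_i, −e_j); the pair with the largest directional derivative is
  maximised exactly (the 1-D restriction is piecewise quadratic with kinks
  where β_i or β_j crosses zero). Stopping: maximum feasible directional
  derivative ≤ 1e−8 (the KKT condition), cap 10⁴·N updates, with a guard
  for stalls at machine precision. Sum-zero holds exactly by construction.

The bias is the KKT multiplier (ε = 0) or the mean of the stationarity
residual over active coordinates (ε > 0). Classification encodes classes
as ±1, thresholds f(a) at zero, and uses |f(a)| as confidence.

The decision tree is greedy CART on Gini impurity with max depth 4 and
min leaf 2 in the pipeline. Zero-gain splits are permitted when a node is
impure (XOR-style targets need two levels before any impurity decreases);
consequently greedy training accuracy is bounded below by the majority
vote and is exactly optimal whenever a single pure split exists, but it is
*not* guaranteed to match an exhaustive depth-2 search on adversarial
data — the tests assert the attainable bounds.

The hybrid model holds exactly two members of different types (enforced at
construction). Correct-classification fusion is logical OR. For per-beat
decisions the default binary rule flags a beat positive when either member
does (positive-class recall therefore dominates both members'); a
confidence rule (take the more confident member on disagreement) is
available for multi-class use.

## Evaluation conventions

Zero-denominator metrics return NaN, never 0. Precision is TP/(TP+FP); a
`paper_literal` audit flag reproduces the TP/(TP+FN) variant seen in some
prints. Error rate is the misclassification fraction 1 − accuracy; RMSE on
±1 targets is also available so either reading of "error" can be formed.
Kurtosis is reported in the Pearson convention (normal → 3) with the
excess value behind a flag, matching the platykurtic/leptokurtic
terminology used for score distributions. Kappa with a single shared class
is 1 for perfect agreement, NaN otherwise.

## Pipeline and problem sizes

The default experiment is a 180 s record at 360 Hz (~200 beats after
retention), 60/40 stratified train/test split over beats, RBF kernel with
σ = √p, P = 10, ε = 0. Reports are JSON with sorted keys; two runs with
the same configuration and seed are byte-identical. The acceptance script
uses this default task plus ten 60 s runs for the feature-fusion
comparison, keeping the whole script under a minute on one CPU. The
participant-fraction sweeps are modelled as train-fraction sweeps over
beats of the synthetic task; no numeric reproduction of external-database
benchmark tables is claimed, since those depend on data not bundled here.

## Known limitations

- The Gaussian-bump generator makes beat classes more separable than real
  inter-patient data; classifier metrics near 1.0 on the default task
  reflect that, and the meaningful checks are the comparative and
  invariance properties, not the absolute numbers.
- The comb notch requires fs/f_mains near an integer to land exactly on
  the mains line; at 360 Hz/50 Hz the zero sits at 51.4 Hz (logged).
- Fiducial detection assumes R-centred windows and monophasic P/T bumps;
  biphasic waves would need a richer landmark model.
- The ε > 0 dual solver is O(N²) per update sweep and intended for
  desk-scale N (hundreds of beats), not archive-scale training.
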
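# Methods

## Problem setting

Implanted responsive-neurostimulation (RNS) devices log the hourly number
of interictal epileptiform activity (IEA) detections over years. These
counts carry a strong circadian rhythm and slower multidien (3–45 day)
cycles, and seizure-like "long events" (LEs) concentrate on the rising
phase of the multidien cycles. `havokrisk` models the slow dynamics of
such a series as a chaotic attractor reconstructed by delay embedding,
approximates it with an intermittently forced linear system, and uses
either the delay coordinates or classical multidien phase/amplitude
features to detect and forecast event risk.

## Preprocessing

Device detection thresholds are retuned at office visits, which shifts
the count scale discontinuously. Each inter-visit block is therefore
z-scored independently (population s.d.; blocks with fewer than two
usable samples or zero variance map to zeros and are logged). The first
five months (5 × 30.44 d) are discarded as the implant stabilization
period. Telemetry gaps up to 24 h are linearly interpolated (and stay
flagged in the gap mask); longer gaps abort with an instruction to split
the record, because the Hankel embedding requires an unbroken uniform
grid. Finally a zero-phase FIR low-pass (order 100, Hamming window,
cutoff 1/72 h⁻¹, applied forward–backward) dampens the circadian band so
that the leading embedding modes capture multidien structure. The
forward–backward pass squares the magnitude response: ≈ −114 dB at 24 h,
< 1 dB loss at 240 h.

## Delay embedding

The filtered series x(t) is stacked into a Hankel matrix H (d = 100 rows,
each row one hour delayed; H[i, j] = x[i + j]) and factored by economy
SVD, H = U S Vᵀ. Columns of V are the delay-coordinate time series; row t
of V is aligned with the window starting at sample t (recorded as
`time_offset`). SVD signs are fixed deterministically by making the
largest-magnitude element of each u_r positive. The dominant period of
each u_r (largest nonzero-frequency FFT bin, parabolically refined)
decreases with r for the modes above the numerical noise floor; on the
smooth low-passed synthetic series, modes with σ_r ≲ 10⁻⁵ σ_1 carry no
meaningful frequency and are excluded from that diagnostic.

The forcing amplitude envelope is the trailing line length: the sum of 72
absolute hourly first differences ending at t. It is causal by
construction (it must flag forcing that *precedes* events) and is
z-scored over the post-warm-up span, so "normalized line length > 0"
means above its mean.

## Forced linear model

The leading r − 1 coordinates follow the discrete-time model

    V(t+1) = A V(t) + B V_r(t)

with the low-energy coordinate V_r as exogenous forcing. A and B are
estimated by plain least squares on the stacked regressor
[V_1 … V_{r−1}, V_r](t) over a six-month training window (4,380 h =
365.25/2 × 24, rounded; calendar-free). No regularization is applied; the
condition number of the regressor is recorded and rank deficiency raises
with the offending columns named. Forward simulation starts from the last
training-span state (recorded in the system metadata) and is driven by
the known future forcing or a surrogate; accuracy is the per-dimension
inverse mean squared error (1/MSE), reported for V_1–V_3. A sweep of the
forcing index r = 4…22 locates the most predictive system size.

The forcing can be streamed without recomputing the SVD: since
V = Hᵀ U diag(S)⁻¹, the sliding inner product of the series with u_r
divided by σ_r equals V_r exactly on the training span (verified to
10⁻⁸). For forecasting features the output is end-aligned (index t uses
samples t − d + 1 … t only), which costs a d − 1 sample warm-up but
guarantees no look-ahead; the start-aligned variant is the default
because it is the exact algebraic identity.

## Multidien baseline

A continuous wavelet transform (analytic Morlet, ω₀ = 6, 16 voices per
octave, cone-of-influence samples excluded per scale) gives the
time-averaged power on a log-spaced 3–45-day period grid. The strongest
local maximum in 3–11 days and the strongest strictly slower local
maximum in 7–45 days are selected (parabolic refinement in log-period;
bands with no interior maximum fall back to the band maximum and are
flagged degraded). Each peak is band-passed with an order-100 FIR over
[P − 1 d, P + 1 d] — interpreted in the period domain, since ±(1 day)⁻¹
in frequency is ill-defined for slow peaks — zero-phase for detection,
single-pass causal (group delay 50 h) for forecasting. Phase and
amplitude come from the analytic signal (Hilbert transform, phase 0 at
cycle peaks).

## Risk detection and forecasting

Features are either one delay coordinate plus its instantaneous phase, or
the multidien amplitude/phase set; phases enter as (sin, cos) pairs.
Labels binarize the LE record at lag x ∈ {0 … 7} days (0 = detection).
Daily resolution averages features over each day before scoring and
labels a day positive if it contains any event. Models: a bagging
ensemble of regression trees with minimum leaf size 8 (default, 20
estimators), and an RBF support-vector regressor on standardized
features. Training uses the first six months after the trim; AUC is
computed on the remaining span. The analysis is repeated 50 times; bagged
trees are re-seeded per repetition, while the deterministic SVR is
retrained on a random 90 % subsample of training rows so its repetitions
also vary (a design choice of this package).

## Null models and inference

Two surrogates: a single global permutation of the hourly event record
(preserves event mass, destroys all temporal structure), and Fourier
phase randomization of a series (preserves the amplitude spectrum bin-
wise, destroys phase coupling). Empirical-vs-null comparisons report a
Welch two-tailed t-test and an add-one permutation p-value
(1 + #{null ≥ observed}) / (1 + n), with both Bonferroni and
Benjamini–Hochberg corrections available. The pipeline's significance
flag uses the Bonferroni-corrected permutation p: because all repetitions
share one data draw, their variance understates the data-level AUC
variance and a replicate t-test is anti-conservative, whereas the
shuffled-null permutation test is calibrated by construction. With the
default 50-replicate null the smallest attainable permutation p is 1/51,
so Bonferroni-corrected detection across six coordinates is deliberately
conservative. The t-test itself is calibrated on independent groups
(type-I rate ≈ 5 %, verified by simulation).

## Synthetic patients

The generator emulates the statistical structure the analysis assumes,
not the biophysics. Hourly counts are Gamma-mixed Poisson
(negative-binomial-like; variance μ + φμ², default dispersion φ = 0.1)
with log-intensity = log(baseline 20 counts/h) + circadian cosine
(amplitude 0.6) + one or two multidien cosines (defaults 7 d / 0.35 and
20 d / 0.6) whose amplitude is slowly modulated by a standardized Lorenz
driver (gain 0.3; one hour advances the Lorenz clock by 0.003 time units,
so lobe residences span one to several weeks). Office visits every 90
days apply a log-normal per-block gain (s.d. 0.2); the first five months
double the dispersion so the preprocessing trim is exercised. LEs are
Bernoulli with hourly probability 0.01 × 4^[rising], where "rising" means
the slowest planted cycle's phase lies in (−π, 0) (phase 0 at the peak,
matching the Hilbert convention); the odds multiplier is a free synthetic
parameter, not a claim about patients. Patient-labeled seizures are a 30 %
thinning of LE hours, mimicking under-reporting.

What the generator does **not** emulate: real telemetry gaps and
drop-outs, stimulation feedback on the cycles, detector-parameter drift
within blocks, non-stationary cycle periods, and patient heterogeneity
beyond its parameters. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted structure, not clinical
performance on RNS data.

The Lorenz fixture (σ = 10, ρ = 28, β = 8/3, RK4 at dt = 0.002 over
300 time units by default) provides ground truth for the forced-linear
decomposition: the forcing coordinate of its delay embedding bursts just
before the trajectory switches lobes (sign changes of x). The validation
uses dt = 0.005 with embedding depth 40 and r = 15, where the burst falls
inside the 25-sample pre-switch window used by the enrichment statistic.

## Problem sizes and numerical choices

Validation analyses use synthetic records at the generator's default
duration of 730 days (≈ 13,800 usable hours after the five-month trim:
six months training, the rest test); the cycle-peak-recovery check uses
540-day records, which already identify both planted peaks. Unit tests
use smaller fixtures. Seed-median statements use 20 seeds,
50 empirical repetitions and 50-replicate
nulls for the structured detection analysis, 8 repetitions per seed for
the false-positive calibration (only the replicate mean enters the
permutation test), and 100 permutations for the Lorenz enrichment test.
Degenerate inputs are handled deterministically throughout: constant
blocks → zeros, zero-variance regressor columns → named error, single-
class spans → NaN AUC flags, σ_r < 10⁻¹² → non-identifiable-mode error,
non-finite simulated states → flagged divergence index with partial
output.

## Known limitations

- Clinical headline numbers from restricted patient data are not
  reproducible here; all quantitative claims are about synthetic records
  and analytic fixtures.
- The multidien periodogram peaks are estimated once per record (on the
  full preprocessed span for detection); per-window re-estimation is not
  implemented.
- No continuous-time HAVOK variant, no eigenvalue-based stability
  redesign, no rolling retraining, and no circular event-locking
  statistics.
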
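# Methods

## The whitening model

An observed node or voxel series Y(t), t = 1..T, sampled every TR
seconds, is modelled as a stationary Gaussian process.  A whitening
transform for a correlation model with autocorrelations ρ(h) is the
symmetric inverse square root of the T×T Toeplitz matrix
Σ = [ρ(|j−k|)], computed by eigendecomposition,
Σ^(−1/2) = V diag(λ^(−1/2)) Vᵀ.  The symmetric (rather than Cholesky)
root is used so that the composite of several iterations is a
well-defined matrix product ∏ᵢ (Σ̂⁽ᴷ⁻ⁱ⁺¹⁾)^(−1/2).

Each IDAR iteration:

1. **Model selection.**  Candidate AR models for the current series are
   compared by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k = number of
   free coefficients + 2 (mean and innovation variance).  The candidate
   pool is (a) the stepwise winner over contiguous orders — hill-climbs
   by ±1 from starts {p_max, p_max/2, p_max/4}, moving only on strictly
   lower AICc; (b) a sparse high-lag model on lags
   {1..p_winner} ∪ {p_max/2, 3p_max/4, p_max}, fit by conditional least
   squares with the skipped lags pinned at zero (rejected if its implied
   AR polynomial is non-stationary); and (c) the white-noise model AR(0).
   Contiguous fits use Levinson–Durbin on the biased sample
   autocovariance, which guarantees stationarity.
2. **Whitening.**  The selected model's theoretical ACF (Yule–Walker for
   lags 1..p, then the AR recursion) fills the Toeplitz matrix, which is
   regularized (below) and inverted to a square root; the demeaned
   series is multiplied by the factor and rescaled to the input's sample
   standard deviation.
3. **Stopping.**  The loop stops when the selected model is AR(0)
   (`white_fit`), when the Ljung-Box/Holm adequacy test passes
   (`adequacy_pass`), or after `max_iter` iterations (default 5).

### Likelihood comparability

Conditional Gaussian likelihoods of AR models condition on their first
p observations, so models of different orders are fit on different
effective samples; comparing their AICc values naively favours high
orders by roughly (log 2πσ² + 1) per conditioned-out observation.  All
selection routines therefore condition every candidate — including
AR(0) and the sparse models — on a common window of p_max initial
observations (n_effective = T − p_max), the convention used by standard
AR order-selection code.  A standalone `fit_ar` call conditions on
max(lag_set).

AICc retains its well-known nonzero overfitting probability (~25–35%
over a large candidate set at these sample sizes): on pure white noise
the stepwise search returns a nonzero order in roughly a third of
replicates.  Those spurious fits are weak — their implied
autocorrelations stay below ≈0.1 — so the resulting extra whitening
pass is essentially harmless, and the adequacy criterion is unaffected.

### Correlation-matrix regularization

High-order fits on short series can make Σ̂ numerically singular.
Regularization is by banding: entries with |j−k| ≥ T−10 are zeroed,
then |j−k| ≥ T−20, and so on, re-checking the condition number after
each step, until it falls below 1×10⁸.  A matrix that is not positive
definite is treated as having infinite condition number, so banding
continues past it.  When the bandwidth would collapse to ≤ 1 (or T ≤ 10),
eigenvalue flooring takes over: eigenvalues below λ_max/10⁸ are raised
to that floor and the model is marked `floored`.  In practice banding
repairs indefinite matrices whose ACF misbehaves at long lags, while
extreme near-unit-root AR(1) matrices (φ ≳ 0.999999) go to the flooring
fallback.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| p_max | ⌊10 s / TR⌋, capped at ⌊T/5⌋, ≥ 1 | maximum AR lag; 10 s is the span over which hemodynamic correlation plausibly persists; the T/5 cap protects short series |
| max_iter | 5 | IDAR iteration cap; empirically sufficient even for short TR |
| alpha | 0.05 | level of the Ljung-Box/Holm adequacy family and of the Wald test |
| cond_threshold | 1×10⁸ | condition-number ceiling for Σ̂ |
| band_step | 10 | number of autocorrelation bands zeroed per banding step |
| snr | 0.1 | task-regressor mean as a fraction of the resting-series SD |

Non-integer quotients (p_max/2, p_max/4, 20/TR, 15 s/TR) are rounded to
the nearest integer (floored where the quantity is a maximum lag), with
a floor of 1.

## Adequacy evaluation

For a whitened series, Ljung-Box statistics
Q(h) = T(T+2) Σ_{k≤h} ρ̂(k)²/(T−k) are computed at every lag
h = 1..⌊20/TR⌋ (capped at ⌊T/4⌋ for short series) and referred to
χ²(h); the per-lag p-values are Holm-adjusted as one family, and the
series is declared inadequately whitened when the smallest adjusted
p-value is below 0.05.  A whitening method succeeds on a dataset when
fewer than 5% of its series are flagged.  The Holm family is the lag
family within one series; no correction is applied across series,
matching the per-series adequacy definition.

## Task simulation and the whitened GLM

The boxcar paradigm divides the run into 30-s blocks: a 15-s task epoch
(round(15/TR) samples) followed by 15 s of rest.  Each task epoch is A
or B with equal probability; A has twice B's intensity.  The boxcar is
convolved with a canonical double-gamma HRF — gamma-density components
with modes at 6 s (peak) and 16 s (undershoot), undershoot ratio 1/6,
32-s support, unit peak — and the regressor X is scaled so that
mean(X) = snr·sd(Y_rest).  The contrast-to-noise ratio is reported as
(max X − min X)/sd(Y_rest).  The task run is Y_ts = Y_rest + X.

The association test premultiplies Y, X and the intercept column by the
whitening transform estimated from the outcome series under test (task
outcome for power, resting outcome for type-I error), runs OLS on the
transformed model, and refers the Wald statistic β̂₁/SE(β̂₁) to a t
distribution with T − 2 degrees of freedom.  Power is the rejection
fraction over task outcomes, type-I error the rejection fraction over
resting (null) outcomes, and accuracy = (true rejections + true
non-rejections)/(2N).

## Synthetic data: what it emulates, and what it does not

The generators stand in for private resting-state recordings at
TR 2.5 s (long-TR, node-averaged) and TR 0.49 s (short-TR):

- `white`, `ar`, `arma11` — i.i.d. Gaussian and stationary AR/ARMA
  series (scipy `lfilter`, burn-in of 10p + 100 samples discarded).
- `stacked` — W·ε with W the ordered product of symmetric square roots
  of AR Toeplitz correlation matrices.  Its correlation W·Wᵀ is not a
  single-AR structure, reproducing the regime where one-shot AR
  whitening leaves residual correlation; the default study condition is
  AR(1) φ=0.8 ∘ AR(1) φ=0.5 at T=600, TR=0.49 s.
- `gen_dataset` — independent (subject, node) series with per-series
  seeds derived from the master seed via `SeedSequence`.

All innovations are Gaussian, matching the Gaussian working likelihood.
The generators do **not** model spatial structure, motion or
physiological artifacts, scanner drift, HRF variability across regions,
or the empirical short-TR correlation shape beyond "slow-decaying and
not single-AR"; the stacked surrogate is a stand-in, not a validated
model of real short-TR noise.  Passing tests therefore demonstrate the
statistical machinery under its stated assumptions, not performance on
real acquisitions.

## Numerical choices and degenerate inputs

- Stationarity is checked via the roots of the monic reciprocal AR
  polynomial (all inside the unit circle, tolerance 1e−10).
- Series are demeaned once before whitening; each iteration's factor
  (with its variance-rescale folded in) is stored so the whitened series
  equals composite · (y − ȳ) exactly, and sequential and composite
  application agree to 1e−8.
- The whitened series is rescaled to the input's sample SD so that
  amplitudes remain comparable across methods for SNR scaling; the Wald
  statistic is invariant to this rescale.
- Constant series are rejected for fitting and ACF computation;
  zero-variance sliding windows yield NaN; an AICc with
  n − k − 1 ≤ 0 is +∞ (model unselectable).
- ARMA(1,1) is fit by Nelder–Mead conditional sum of squares in a
  tanh-transformed unconstrained space, initialized by a two-stage
  Hannan–Rissanen regression; on optimizer failure the Hannan–Rissanen
  estimate is returned flagged non-converged.

## Problem sizes in the validation suite

The statistical acceptance checks use 200 white-noise series (T=500)
for adequacy calibration, 200 stacked series (T=600, TR=0.49 s) for the
whitening-success comparison, 500 AR(2) series (T=1000, TR=0.5 s) for
type-I error, 200 series for the oracle-transform calibration check,
and 100 replicates per order (T=2000) for AICc order recovery.  These
sizes put two-binomial-SE bands of ±2–3 percentage points around the
5% operating points while keeping the full suite at a few minutes on a
single CPU.

## Known limitations

- Type-I error of the whitened GLM is controlled only approximately:
  estimating the whitening transform from the series being tested
  introduces a small variance bias (measured level ≈ 0.054 at nominal
  0.05 over 1000 replicates of the AR(2)/T=1000 condition).  Residual
  mild anticonservativeness is inherent to same-data pre-whitening.
- AICc's overfitting tail means white series are sometimes (weakly)
  whitened once rather than left untouched.
- Banding a positive-definite Toeplitz matrix can itself break positive
  definiteness; the infinite-condition-number convention plus the
  flooring fallback guarantee a positive-definite output, but floored
  matrices are no longer exactly unit-diagonal.
- Each series is whitened independently; no pooling of AR structure
  across nodes or subjects.
- No exact-likelihood (Kalman) ARMA estimation and no alternative
  covariance regularizers.
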
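# idar — iterative data-adaptive AR pre-whitening for fMRI-like time series

Serially correlated noise is the rule, not the exception, in BOLD fMRI
time series, and it breaks every downstream analysis that assumes
independent observations: GLM task tests reject far too often, and
resting-state models (graphical models, GARCH, sliding-window
connectivity) inherit spurious structure.  Pre-whitening — multiplying
the series by the inverse square root of its estimated correlation
matrix — is the standard remedy, but the fixed low-order models used by
mainstream packages (a global AR(1) in SPM/FSL, a voxel-wise ARMA(1,1)
in AFNI) misrepresent the slowly decaying correlation of short-TR
(≤ 0.5 s) acquisitions, and even a single high-order AR model often
leaves significant residual autocorrelation.

`idar` implements **IDAR** (Iterative Data-adaptive AR) whitening:

1. Fit an AR model to the current series, with the lag order selected by
   the small-sample-corrected Akaike criterion (AICc) via a stepwise
   search started at p_max, p_max/2 and p_max/4 (p_max = ⌊10 s / TR⌋),
   plus a sparse "regularized" candidate that adds high-order lags
   {p_max/2, 3p_max/4, p_max} to the stepwise winner without paying for
   a full AR(p_max) fit.
2. Build the fitted model's T×T Toeplitz correlation matrix
   Σ̂ = [ρ̂(|j−k|)], band it (zeroing the trailing 10 autocorrelation
   bands, repeatedly) until its condition number falls below 1×10⁸, and
   whiten: Y⁽ⁱ⁾ = (Σ̂⁽ⁱ⁾)^(−1/2) Y⁽ⁱ⁻¹⁾.
3. Repeat on the whitened series (at most 5 iterations), because a
   *product* of AR correlation structures — typical of short-TR data —
   is not itself an AR structure, so one pass is often not enough.  The
   composite transform is ∏ᵢ (Σ̂⁽ᴷ⁻ⁱ⁺¹⁾)^(−1/2).

Whitening adequacy is judged as in the fMRI whitening literature:
Ljung-Box portmanteau tests at lags 1..⌊20/TR⌋, Holm-adjusted; a series
is *inadequately whitened* if the smallest adjusted p-value is < 0.05,
and a whitening procedure succeeds on a dataset when < 5% of series are
flagged.  The package also ships the evaluation harness for simulated
task fMRI: boxcar block designs (30-s blocks, 15-s task epochs, A/B
intensities 2u/u) convolved with a canonical double-gamma HRF, scaled to
SNR 0.1, and the whitened GLM `Y = β₀ + β₁X + ε` with a Wald test of
β₁ — yielding power, type-I error and accuracy per whitening method.

Baselines included for comparison: `ar1`, `arma11`, `idar-iter1` (the
single-iteration variant, equivalent to one-shot data-adaptive
high-order AR whitening), and `none`.

## Worked example

```python
import idar
from idar.synthetic import GeneratorSpec, gen_stacked

# short-TR analog: product of AR(1) phi=0.8 and AR(1) phi=0.5 structures
specs = (GeneratorSpec("ar", (0.8,)), GeneratorSpec("ar", (0.5,)))
y = gen_stacked(specs, T=600, seed=11, tr=0.49)

print(idar.sample_acf(y, 1)[1])        # 0.907  -- heavy serial correlation
res = idar.idar(y)                     # iterative whitening
print(res.iterations)                  # 1
print(res.stop_reason)                 # adequacy_pass
print([list(f.lag_set) for f in res.fits])   # [[1, 2, 10, 15, 20]]
print(res.adequacy.min_adjusted_p)     # 1.0   -- no residual correlation
print(idar.sample_acf(res.whitened, 1)[1])   # 0.004

base = idar.baseline_whiten(y, method="ar1")
print(base.adequacy.min_adjusted_p)    # 3.99e-20 -- AR(1) whitening fails
print(base.adequacy.inadequate)        # True
```

The stacked series starts with lag-1 autocorrelation 0.91.  IDAR selects
a sparse high-order AR model (lags 1, 2, 10, 15, 20), whitens in one
iteration, and the Ljung-Box/Holm family finds nothing left (smallest
adjusted p = 1.0).  The AR(1) baseline applied to the same series leaves
gross residual correlation (adjusted p ≈ 4×10⁻²⁰): exactly the failure
mode of low-order whitening on short-TR-like data.

## Command line

```bash
idar generate --kind ar --phi 0.5,0.25 --T 600 --tr 0.49 --seed 11 --out series.tsv
idar whiten --input series.tsv --tr 0.49 --method idar --out white.tsv --report report.json
idar evaluate --input white.tsv --tr 0.49
idar simulate-task --rest series.tsv --tr 0.49 --snr 0.1 --seed 5 --out task.tsv
idar experiment --rest series.tsv --tr 0.49 --methods none,ar1,arma11,idar-iter1,idar --out summary.csv
```

Matrices are plain TSV/CSV (rows = time points, header row of series
labels); reports are JSON with the full configuration and seeds.

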
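# Methods

## Signal model

An inversion-recovery (IR) acquisition samples one voxel's longitudinal
magnetisation at N inversion times TI_i. The discrete multiexponential
model is

    y(TI_i) = Σ_{j=1..J} A_j (1 − 2 exp(−TI_i / T1_j)),

with nonnegative amplitudes A_j and relaxation times T1_j > 0 (ms).
Components are stored in canonical ascending-T1 order. Magnitude-mode
imaging retains |y| only, so fitting either uses the absolute-value model
directly (MUL, TOM) or first restores polarity (ILT).

The default inversion-time grid is 100–5000 ms in steps of 100 ms (N = 50),
matching a standard IR-EPI relaxometry protocol.

## Polarity restoration

For a complex voxel signal the null index is estimated from the crossing of
|Re| and |Im|: the first index where their difference changes sign, resolved
to the nearer of the two bracketing samples. Samples strictly preceding the
null index are negated; the sample at the null keeps its magnitude. When no
crossing exists (e.g. a noiseless, purely real signal) the global
minimum-magnitude index is used instead and a warning is emitted — the
automated replacement for a manual visual-inspection step.

A consequence of the "strictly preceding" rule: when the true null falls
just *after* the nearest sampled TI (as for T1 = 641 ms on the default
grid, null at 444 ms), that one sample keeps the wrong sign even without
noise. The deviation is pinned in the test suite; it is an inherent property
of minimum-based restoration, not a numerical defect.

Magnitude-only signals (composite datasets) are restored about the global
minimum of the magnitude curve, the only estimator available without phase.

## Synthetic composite phantom

The generator emulates composite ground-truth construction from a physical
relaxometry phantom:

1. Per region of interest (ROI), a 6 × 6 block of single-component voxels.
   Each voxel draws T1 ~ Normal(mean, dispersion · mean), truncated
   positive. Component means are {641, 1039, 1540, 2733} ms.
2. The noiseless signed signal (phase 0, real axis) receives independent
   Gaussian noise on the real and imaginary channels with per-channel SD
   σ = max|noiseless| / 10^(SNR_dB/20). The default SNR is 30 dB — the
   noise floor considered attainable in whole-brain 3-T IR relaxometry,
   i.e. the *hardest realistic* condition, deliberately harsher than a
   dedicated phantom acquisition.
3. Each ROI block is polarity-restored per voxel, blocks are summed
   voxel-wise (positional pairing), and only magnitudes are retained.

Ten combinations are generated: six two-component, three three-component,
one four-component dataset, 36 voxels each (216/108/36 voxels pooled by
class). With zero dispersion the dataset-level mean T1 ratio (mean over
voxels of consecutive sorted-pair ratios) reproduces the design values
exactly, e.g. 2733/641 → 4.26 and mean(1039/641, 2733/1039) → 2.13.

Defaults and why:

* `t1_dispersion_frac = 0.01` — a small within-ROI spread standing in for
  the natural per-voxel variation of a liquid phantom compartment; 0 is
  allowed and used for the exact ratio checks. At 1% the sampled mean ratio
  of a 36-voxel dataset has an SE of ~0.01, so rounded ratios occasionally
  move by one ULP; only the zero-dispersion ratios are exact by design.
* `amplitude = 1` for every ROI — components enter with equal weights.
* phase 0 — the simplest complex model consistent with Re/Im-crossing
  restoration; noise supplies the imaginary channel.
* SNR is defined per ROI voxel against its own noiseless peak; summing ROIs
  therefore *raises* the composite SNR slightly (noise adds in quadrature,
  signal adds linearly), mirroring the noise-suppressing cumulation of the
  emulated procedure.

What the generator does **not** model: field inhomogeneity, inversion
efficiency < 1, slice profiles, EPI artifacts, k-space-domain addition,
per-voxel amplitude variation, Rician noise correlations beyond those
induced by taking magnitudes. Passing tests therefore bound the *best case*
for real acquisitions: estimators that fail here will not do better on
scanner data.

## Fitting methods

**ILT.** The signed signal, scaled to unit maximum absolute value, is
inverted onto a candidate grid of 100 linearly spaced T1 values from 50 to
5000 ms via nonnegative least squares (`scipy.optimize.nnls`) applied to
the kernel A_ij = 1 − 2 exp(−TI_i/T1_j). The grid starts at 50 ms because
the kernel is singular at T1 = 0. Bins with weight > 0.075 are grouped into
maximal contiguous runs; each run becomes one component (weight-weighted
mean T1, summed amplitude rescaled to signal units). Thresholding the
normalised spectrum makes 0.075 scale-free. The literal
every-bin-is-a-component reading is available via `merge_runs=False`. Note
that run merging makes the component count non-monotone in the threshold: a
higher threshold can cut the bridge bin between two peaks.

A structural caveat measured by the test suite: a true T1 that falls
between grid points is typically represented by two *non-adjacent* spectral
lines (NNLS solutions sit on vertices of the constraint set), and the minor
line can survive the threshold. On two-component data at the default
settings ILT therefore averages slightly *above* two detected components
(~2.1) regardless of SNR.

**MUL.** Bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`) on the residuals
y − |model|, with an analytic Jacobian (sign(model) · ∂model). Bounds
default to T1 ∈ [50, 5000] ms and A ∈ [0, 2·max|y|]. 32 starting points
drawn uniformly within bounds (the start sequence for n starts is a prefix
of that for n+1 under the same seed, so the best SSE is non-increasing in
the number of starts); the minimal-SSE solution is returned. J is fixed by
the caller.

**TOM.** Same objective and bounds; for each J = 2 … j_max (default 4) a
single start with T1 entries equally spaced over 700–2200 ms (the commonly
reported cortical gray/white-matter range at 3 T) jittered by ±10%, and
amplitudes max|y|/J. The J with minimal SSE is selected; ties within 1e−12
go to the smaller J. Because SSE decreases with model order, TOM
systematically overestimates the count (≈2.8 on two-component data), and
because its start concentrates in the plausible tissue range it exhibits
self-bias: on data whose true T1s lie far outside that range a single
TOM-style start is beaten by the multistart fit.

Solver tolerances are 1e−8 (xtol/ftol/gtol) with at most 2000 evaluations.
The absolute value makes the objective non-smooth at signal nulls; the
kinks lie on a measure-zero set and the trust-region solver steps through
them reliably in practice.

## Evaluation

Because the model is additive, estimate order is arbitrary: estimates are
aligned to truth by exhaustive permutation search (J ≤ 5) minimising the
summed T1 relative error over truth slots with nonzero amplitude, ties
resolved lexicographically. When the assumed model order exceeds the true
one, both sides are padded with zero-amplitude components (T1 undefined);
a padded estimate slot paired with a real truth component costs a constant
1.0, which cannot bias which real pairings win.

Error metrics, all in percent:

* T1 relative error, 100·|est − truth|/truth, for every truth component
  with nonzero amplitude; a truth component the method failed to estimate
  is scored at 100% (the undefined-pair cost) rather than dropped —
  otherwise a method that reports fewer components would be rewarded for
  under-reporting.
* Amplitude relative error where the truth amplitude is nonzero; for
  zero-amplitude truth slots a *maximum mean error*,
  100·|est − truth| / max(truth amplitudes in the voxel), which stays
  defined at zero truth and reduces to the relative error at the voxel
  maximum.

Summaries group mean errors by method × true component count and report
mean estimated components per dataset. The dependence of the per-voxel mean
T1 error on the dataset mean T1 ratio is quantified by ordinary least
squares (statsmodels OLS) over voxel-level observations, reporting slope,
intercept, R² and the two-sided slope p-value.

## Problem sizes

The structural checks run the full ten-dataset suite once. The
trend analysis runs 20 replicate suites of the four two-component
combinations spanning ratios 1.48–4.26 (2 880 voxels per method), with MUL
at 8 starts per voxel — the package's scaled-down study size, which already
yields slope p-values below 1e−10. The component-count analysis runs the
six two-component datasets (216 voxels) once with ILT and TOM.

## Known limitations

* Minimum-based polarity restoration cannot recover the sign of the sample
  at the estimated null; see above.
* The evaluation conventions for unmatched components and the max-mean-error
  normaliser are declared package conventions; other choices would shift
  absolute error levels (not the directional findings).
* ILT component counting is sensitive to the grid/threshold geometry;
  reported counts should be read jointly with the spectrum itself.
* No Rician-likelihood fitting: magnitude noise is treated as Gaussian by
  the NLS objective, which biases low-SNR samples near signal nulls.
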
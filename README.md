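# t1relax

Multiexponential inversion-recovery *T*<sub>1</sub> relaxometry: synthetic
composite phantom suites with known ground truth, three multiexponential
fitting methods, and quantitative evaluation of how well each recovers the
underlying relaxation components.

## The problem

A voxel of cortical tissue mixes several compartments (cortical layers,
CSF), each with its own spin–lattice relaxation time *T*<sub>1</sub>. An
inversion-recovery (IR) acquisition samples the signal at inversion times
TI, and a *J*-component model describes it as

    y(TI_i) = Σ_j  A_j (1 − 2 e^{−TI_i / T1_j}),

with amplitudes *A<sub>j</sub>* and relaxation times *T*<sub>1*j*</sub>.
Estimating several *T*<sub>1</sub> values from one decay curve
(multiexponential analysis) is notoriously ill-posed: success depends on the
noise level, the number of components, and the ratio of adjacent
*T*<sub>1</sub> values. This package quantifies those limits for three
standard approaches:

* **ILT** — linear inversion onto a dense candidate-*T*<sub>1</sub> grid
  under a nonnegativity constraint (NNLS); components are read off the
  weight spectrum by thresholding (0.075 on the unit-max-normalised signal)
  and merging contiguous runs of surviving bins.
* **MUL** — bounded nonlinear least squares of the absolute-value model with
  a fixed *J*, restarted from many random points; the best SSE wins.
* **TOM** — the same bounded objective fitted sequentially for
  *J* = 2 … *J*<sub>max</sub> from a single semi-random start sampling the
  gray/white-matter *T*<sub>1</sub> range (700–2200 ms); the *J* with
  minimal SSE is selected.

Ground truth comes from a synthetic composite phantom: 6 × 6 blocks of
single-component complex IR voxels (means drawn from
{641, 1039, 1540, 2733} ms) with complex Gaussian noise at a configurable
SNR (default 30 dB), polarity-restored per voxel, summed across regions,
and reduced to magnitude — ten composite datasets (six two-, three three-
and one four-component) with exactly known per-voxel components.

Intended users: quantitative-MRI methodologists who want a reproducible
benchmark for multiexponential *T*<sub>1</sub> estimators.

## Worked example

```python
import t1relax as tr

truth = tr.ComponentSet(amplitudes=[1.0, 1.0], t1_ms=[641.0, 2733.0])
model = tr.MultiExpIR.simulate(truth, tr.DEFAULT_TI_MS, snr_db=30.0, seed=7)
res = model.fit("mul", J=2, n_starts=32, seed=0)
print(res.summary())
```

```
Multiexponential IR fit
==============================================
method:          mul
n_components:    2
SSE:             0.0938629
converged:       True
starts used:     32
----------------------------------------------
component     amplitude     T1 [ms]
        1        0.9325       555.0
        2        1.1278      2766.5
==============================================
```

Even at a well-separated ratio of 4.3 and 30 dB SNR, the short component
comes back 13% low (555 vs 641 ms) — the central point the benchmark makes:
noise at realistic levels substantially perturbs multiexponential
*T*<sub>1</sub> estimates.

The full study runs from the shell:

```bash
t1relax run-all --seed 0 --out results/run0
```

which generates the ten composite datasets, fits every voxel with all three
methods, aligns estimates to truth and writes error tables
(`errors_by_components.csv`), component-count tables, and the OLS regression
of error on the dataset mean *T*<sub>1</sub> ratio (`regression.csv`).

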
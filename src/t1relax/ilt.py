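"""Continuous-spectrum T1 estimation by nonnegative least squares (ILT).

The signed IR signal is modelled as a nonnegative weighting of IR kernels
evaluated on a dense grid of candidate T1 values,

    y(TI_i) = sum_j g(T1_j) * (1 - 2 exp(-TI_i / T1_j)) + e_i,

a discretised Fredholm integral equation of the first kind. The weight
spectrum g >= 0 solves ``argmin_{g>=0} 1/2 |A g - y|^2`` by NNLS. Discrete
components are then read off the spectrum by thresholding: grid bins with
weight above the threshold are grouped into maximal contiguous runs, each
run contributing one component (weight-weighted mean T1, summed amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .models import ComponentSet, InversionRecoveryCurve

__all__ = [
    "DEFAULT_THRESHOLD",
    "T1Spectrum",
    "default_t1_grid",
    "build_kernel",
    "fit_ilt",
    "extract_components",
]

#: Spectrum weight threshold for component extraction, applied to the
#: spectrum of a unit-max-normalised signal (scale-free).
DEFAULT_THRESHOLD = 0.075


@dataclass(frozen=True)
class T1Spectrum:
    """Nonnegative weights over a candidate T1 grid, plus fit metadata."""

    t1_grid_ms: np.ndarray
    weights: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    residual: float = 0.0
    scale: float = 1.0  # signal units per unit weight (undoes normalisation)

    def __post_init__(self) -> None:
        grid = np.asarray(self.t1_grid_ms, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if grid.shape != w.shape or grid.ndim != 1:
            raise ValueError("grid and weights must be 1-D and equal length")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("t1_grid_ms must be strictly increasing and positive")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "t1_grid_ms", grid)
        object.__setattr__(self, "weights", w)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t1_ms": self.t1_grid_ms, "weight": self.weights})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def default_t1_grid(
    n: int = 100, lo_ms: float = 50.0, hi_ms: float = 5000.0, spacing: str = "linear"
) -> np.ndarray:
    """Candidate T1 grid: 100 points over (0, 5000] ms, starting at 50 ms."""
    if spacing == "linear":
        return np.linspace(lo_ms, hi_ms, n)
    if spacing == "log":
        return np.geomspace(lo_ms, hi_ms, n)
    raise ValueError("spacing must be 'linear' or 'log'")


def build_kernel(ti_ms, t1_grid_ms) -> np.ndarray:
    """IR transformation kernel ``A_ij = 1 - 2 exp(-TI_i / T1_j)``."""
    ti = np.asarray(ti_ms, dtype=float)
    grid = np.asarray(t1_grid_ms, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("candidate T1 grid must be strictly positive")
    if np.any(ti < 0):
        raise ValueError("inversion times must be nonnegative")
    return 1.0 - 2.0 * np.exp(-ti[:, None] / grid[None, :])


def fit_ilt(
    curve: InversionRecoveryCurve,
    t1_grid_ms: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    normalize: bool = True,
) -> T1Spectrum:
    """NNLS inversion of a polarity-restored IR curve onto the T1 grid.

    The signal is scaled to unit maximum absolute value before inversion
    (so the extraction threshold is scale-free); the scale is kept on the
    spectrum so extracted amplitudes return to signal units.
    """
    if curve.representation == "complex":
        raise ValueError("fit_ilt expects a polarity-restored (signed_real) curve")
    y = np.asarray(curve.values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite samples")
    grid = default_t1_grid() if t1_grid_ms is None else np.asarray(t1_grid_ms, dtype=float)
    scale = float(np.max(np.abs(y))) if normalize else 1.0
    if scale == 0.0:
        return T1Spectrum(grid, np.zeros_like(grid), threshold, 0.0, 1.0)
    kernel = build_kernel(curve.ti_ms, grid)
    weights, residual = scipy.optimize.nnls(kernel, y / scale)
    return T1Spectrum(grid, weights, threshold, float(residual), scale)


def extract_components(
    spectrum: T1Spectrum, merge_runs: bool = True
) -> tuple[ComponentSet, int]:
    """Threshold the spectrum into discrete components.

    Bins with weight strictly above the threshold form maximal contiguous
    runs; each run becomes one component with T1 the weight-weighted mean of
    its bins and amplitude the sum of its weights (rescaled to signal
    units). With ``merge_runs=False`` every surviving bin is its own
    component (the literal non-zero-kernel count). An empty result is
    legitimate: count 0.
    """
    above = spectrum.weights > spectrum.threshold
    if not above.any():
        return ComponentSet(np.empty(0), np.empty(0)), 0
    idx = np.flatnonzero(above)
    if merge_runs:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = np.split(idx, splits)
    else:
        runs = [np.array([i]) for i in idx]
    t1s, amps = [], []
    for run in runs:
        w = spectrum.weights[run]
        t1s.append(float(np.average(spectrum.t1_grid_ms[run], weights=w)))
        amps.append(float(w.sum() * spectrum.scale))
    return ComponentSet(np.array(amps), np.array(t1s)), len(runs)
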
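"""Model/Results front end for multiexponential IR fitting.

``MultiExpIR`` wraps one voxel's inversion-recovery signal and dispatches
to the three fitting back ends:

* ``ilt`` — nonnegative least squares on a candidate T1 grid, thresholded
  into components (needs a polarity-restored signal);
* ``mul`` — multistart bounded nonlinear least squares with fixed J;
* ``tom`` — sequential-J bounded fit, J selected by SSE.

``fit`` returns a :class:`MultiExpIRResults` carrying the estimated
component set, goodness of fit, fitted values and a ``summary()`` table,
in the style of statsmodels results objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ilt as _ilt
from . import nls as _nls
from .models import (
    ComponentSet,
    InversionRecoveryCurve,
    ir_signal,
    magnitude_ir_signal,
    restore_polarity,
    restore_polarity_magnitude,
)

__all__ = ["MultiExpIR", "MultiExpIRResults"]


class MultiExpIR:
    """Multiexponential inversion-recovery T1 model for one voxel signal.

    Parameters
    ----------
    endog : array-like
        The measured signal over the inversion-time grid.
    ti_ms : array-like
        Inversion times in ms, strictly increasing.
    representation : str
        ``"magnitude"`` (default), ``"signed_real"`` or ``"complex"``.
    """

    def __init__(self, endog, ti_ms, representation: str = "magnitude"):
        self.curve = InversionRecoveryCurve(ti_ms, endog, representation)

    @classmethod
    def from_curve(cls, curve: InversionRecoveryCurve) -> "MultiExpIR":
        obj = cls.__new__(cls)
        obj.curve = curve
        return obj

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, ti_col: str = "ti_ms", value_col: str = "value"
    ) -> "MultiExpIR":
        values = df[value_col].to_numpy(dtype=float)
        rep = "magnitude" if np.all(values >= 0) else "signed_real"
        return cls(values, df[ti_col].to_numpy(dtype=float), rep)

    @property
    def endog(self) -> np.ndarray:
        return self.curve.values

    @property
    def ti_ms(self) -> np.ndarray:
        return self.curve.ti_ms

    def _signed_curve(self) -> InversionRecoveryCurve:
        """Polarity-restored view of the data, as the ILT back end needs."""
        if self.curve.representation == "complex":
            return restore_polarity(self.curve)
        if self.curve.representation == "magnitude":
            return restore_polarity_magnitude(self.curve)
        return self.curve

    def _magnitude_curve(self) -> InversionRecoveryCurve:
        values = np.abs(self.curve.values)
        return InversionRecoveryCurve(self.curve.ti_ms, values, "magnitude")

    def fit(self, method: str = "mul", **kwargs) -> "MultiExpIRResults":
        """Fit the voxel with one of the three back ends.

        Keyword arguments are forwarded: ``t1_grid_ms``, ``threshold`` for
        ilt; ``J``, ``bounds``, ``n_starts``, ``seed`` for mul; ``j_max``,
        ``bounds``, ``seed`` for tom.
        """
        if method == "ilt":
            spectrum = _ilt.fit_ilt(self._signed_curve(), **kwargs)
            components, count = _ilt.extract_components(spectrum)
            sse = float(
                np.sum(
                    (
                        self._magnitude_curve().values
                        - (magnitude_ir_signal(components, self.ti_ms) if count else 0.0)
                    )
                    ** 2
                )
            )
            return MultiExpIRResults(
                self, "ilt", components, sse, count, spectrum=spectrum
            )
        if method == "mul":
            res = _nls.fit_mul(self._magnitude_curve(), **kwargs)
        elif method == "tom":
            res = _nls.fit_tom(self._magnitude_curve(), **kwargs)
        else:
            raise ValueError("method must be one of 'ilt', 'mul', 'tom'")
        return MultiExpIRResults(
            self,
            res.method,
            res.components,
            res.sse,
            res.n_components,
            converged=res.converged,
            n_starts_used=res.n_starts_used,
            candidate_sse=res.candidate_sse,
        )

    @classmethod
    def simulate(
        cls,
        components: ComponentSet,
        ti_ms,
        snr_db: float = np.inf,
        seed: int | None = None,
        representation: str = "magnitude",
    ) -> "MultiExpIR":
        """Synthesize a model instance from known components, optionally noisy.

        Noise is complex Gaussian per channel at the given SNR (dB relative
        to the peak noiseless magnitude), then reduced to the requested
        representation.
        """
        ti = np.asarray(ti_ms, dtype=float)
        signal = ir_signal(components, ti).astype(complex)
        if np.isfinite(snr_db):
            rng = np.random.default_rng(seed)
            sigma = float(np.max(np.abs(signal))) / 10.0 ** (snr_db / 20.0)
            signal = signal + sigma * (
                rng.standard_normal(ti.size) + 1j * rng.standard_normal(ti.size)
            )
        if representation == "complex":
            return cls(signal, ti, "complex")
        if representation == "magnitude":
            return cls(np.abs(signal), ti, "magnitude")
        return cls.from_curve(restore_polarity(InversionRecoveryCurve(ti, signal, "complex")))


class MultiExpIRResults:
    """Estimates and diagnostics of one multiexponential IR fit."""

    def __init__(
        self,
        model: MultiExpIR,
        method: str,
        components: ComponentSet,
        sse: float,
        n_components: int,
        *,
        spectrum=None,
        converged: bool = True,
        n_starts_used: int = 1,
        candidate_sse: dict | None = None,
    ):
        self.model = model
        self.method = method
        self.components = components
        self.sse = float(sse)
        self.n_components = int(n_components)
        self.spectrum = spectrum
        self.converged = bool(converged)
        self.n_starts_used = int(n_starts_used)
        self.candidate_sse = dict(candidate_sse or {})

    @property
    def params(self) -> pd.DataFrame:
        """Estimated components as a table (ascending T1)."""
        return pd.DataFrame(
            {"amplitude": self.components.amplitudes, "t1_ms": self.components.t1_ms}
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.n_components == 0:
            return np.zeros(self.model.ti_ms.size)
        return magnitude_ir_signal(self.components, self.model.ti_ms)

    @property
    def resid(self) -> np.ndarray:
        return np.abs(np.asarray(self.model.endog)) - self.fittedvalues

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Multiexponential IR fit",
            "=" * 46,
            f"method:          {self.method}",
            f"n_components:    {self.n_components}",
            f"SSE:             {self.sse:.6g}",
            f"converged:       {self.converged}",
            f"starts used:     {self.n_starts_used}",
            "-" * 46,
            f"{'component':>9}  {'amplitude':>12}  {'T1 [ms]':>10}",
        ]
        for j in range(self.n_components):
            lines.append(
                f"{j + 1:>9}  {self.components.amplitudes[j]:>12.4f}  "
                f"{self.components.t1_ms[j]:>10.1f}"
            )
        if self.candidate_sse:
            lines.append("-" * 46)
            lines.append(
                "candidate SSE by J: "
                + ", ".join(f"{J}: {s:.4g}" for J, s in sorted(self.candidate_sse.items()))
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data vs fitted magnitude curve (and spectrum, for ILT fits)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ti = self.model.ti_ms
        ax.plot(ti, np.abs(np.asarray(self.model.endog)), "k.", label="data (magnitude)")
        ax.plot(ti, self.fittedvalues, "r-", label=f"{self.method} fit")
        ax.set_xlabel("inversion time [ms]")
        ax.set_ylabel("signal")
        ax.legend()
        return ax
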
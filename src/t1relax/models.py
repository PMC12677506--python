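"""Inversion-recovery multiexponential signal models and polarity restoration.

The basic object is a single voxel's inversion-recovery (IR) curve: the MR
signal sampled at ``N`` inversion times ``TI_i``. Under a multiexponential
model the signed signal is

    y(TI_i) = sum_j A_j * (1 - 2 * exp(-TI_i / T1_j)),

where each component ``j`` has amplitude ``A_j`` (signal units) and
longitudinal relaxation time ``T1_j`` (ms). Magnitude-mode imaging only
retains ``|y|``; *polarity restoration* re-signs a complex acquisition so
that samples before the null point are negative again.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSet",
    "InversionRecoveryCurve",
    "PolarityRestorationWarning",
    "ir_signal",
    "magnitude_ir_signal",
    "restore_polarity",
    "restore_polarity_magnitude",
]

REPRESENTATIONS = ("complex", "signed_real", "magnitude")


class PolarityRestorationWarning(UserWarning):
    """No real/imaginary crossing found; fell back to the minimum-magnitude index."""


@dataclass(frozen=True)
class ComponentSet:
    """Amplitudes and T1 decay constants of a discrete multiexponential model.

    Components are stored in canonical order: ascending ``t1_ms``. A slot may
    carry ``t1_ms = NaN`` only when its amplitude is exactly zero -- such
    "zero components" arise when padding an estimate or a ground truth to a
    common model order; NaN slots sort last.
    """

    amplitudes: np.ndarray
    t1_ms: np.ndarray

    def __post_init__(self) -> None:
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        t1 = np.atleast_1d(np.asarray(self.t1_ms, dtype=float))
        if amp.shape != t1.shape or amp.ndim != 1:
            raise ValueError("amplitudes and t1_ms must be 1-D and equal length")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be nonnegative")
        defined = ~np.isnan(t1)
        if np.any(t1[defined] <= 0):
            raise ValueError("t1_ms must be positive where defined")
        if np.any(~defined & (amp != 0)):
            raise ValueError("t1_ms may be NaN only for zero-amplitude slots")
        order = np.argsort(t1, kind="stable")  # NaN sorts last
        object.__setattr__(self, "amplitudes", amp[order])
        object.__setattr__(self, "t1_ms", t1[order])

    def __len__(self) -> int:
        return self.amplitudes.size

    @property
    def n_components(self) -> int:
        return len(self)


@dataclass(frozen=True)
class InversionRecoveryCurve:
    """One voxel's IR signal over a strictly increasing inversion-time grid."""

    ti_ms: np.ndarray
    values: np.ndarray
    representation: str = "signed_real"

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_ms, dtype=float)
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        dtype = complex if self.representation == "complex" else float
        values = np.asarray(self.values, dtype=dtype)
        if ti.ndim != 1 or values.shape != ti.shape:
            raise ValueError("ti_ms and values must be 1-D and equal length")
        if np.any(np.diff(ti) <= 0):
            raise ValueError("ti_ms must be strictly increasing")
        if self.representation == "magnitude" and np.any(values < 0):
            raise ValueError("magnitude representation requires nonnegative values")
        object.__setattr__(self, "ti_ms", ti)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.ti_ms.size

    def to_frame(self) -> pd.DataFrame:
        if self.representation == "complex":
            return pd.DataFrame(
                {"ti_ms": self.ti_ms, "re": self.values.real, "im": self.values.imag}
            )
        return pd.DataFrame({"ti_ms": self.ti_ms, "value": self.values})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "InversionRecoveryCurve":
        df = pd.read_csv(path_or_buf)
        if {"re", "im"}.issubset(df.columns):
            return cls(df["ti_ms"].to_numpy(), df["re"].to_numpy() + 1j * df["im"].to_numpy(), "complex")
        values = df["value"].to_numpy(dtype=float)
        rep = "magnitude" if np.all(values >= 0) else "signed_real"
        return cls(df["ti_ms"].to_numpy(), values, rep)


def ir_signal(components: ComponentSet, ti_ms) -> np.ndarray:
    """Signed multiexponential IR signal ``sum_j A_j (1 - 2 exp(-TI/T1_j))``.

    Zero-amplitude NaN slots contribute nothing. An entirely empty component
    set is a degenerate model and raises.
    """
    ti = np.asarray(ti_ms, dtype=float)
    if len(components) == 0:
        raise ValueError("degenerate model: component set is empty")
    if np.any(ti < 0):
        raise ValueError("inversion times must be nonnegative")
    amp = components.amplitudes
    t1 = components.t1_ms
    live = ~np.isnan(t1)
    if not np.any(live):
        return np.zeros_like(ti)
    kernels = 1.0 - 2.0 * np.exp(-ti[:, None] / t1[None, live])
    return kernels @ amp[live]


def magnitude_ir_signal(components: ComponentSet, ti_ms) -> np.ndarray:
    """``|ir_signal|`` element-wise: the magnitude-mode forward model."""
    return np.abs(ir_signal(components, ti_ms))


def _null_index(values: np.ndarray) -> int | None:
    """Index of the signal null from the crossing of |Re| and |Im|.

    Returns the first index where ``|Re| - |Im|`` changes sign, resolved to
    the nearer of the two bracketing samples; ``None`` when no crossing
    exists (e.g. a purely real signal).
    """
    d = np.abs(values.real) - np.abs(values.imag)
    sign = np.sign(d)
    zeros = np.flatnonzero(sign == 0)  # exact equality is itself a crossing
    change = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    candidates = []
    if zeros.size:
        candidates.append(int(zeros[0]))
    if change.size:
        i = int(change[0])
        candidates.append(i if abs(d[i]) <= abs(d[i + 1]) else i + 1)
    return min(candidates) if candidates else None


def restore_polarity(curve: InversionRecoveryCurve) -> InversionRecoveryCurve:
    """Re-sign a complex IR curve: samples before the null become negative.

    The null index is taken from the crossing of the real- and
    imaginary-part magnitudes; samples strictly preceding it are negated,
    the sample at the null itself is not. When no crossing exists the
    global minimum-magnitude index is used and a
    :class:`PolarityRestorationWarning` is emitted.
    """
    if curve.representation != "complex":
        raise ValueError("restore_polarity expects a complex curve")
    mag = np.abs(curve.values)
    idx = _null_index(curve.values)
    if idx is None:
        idx = int(np.argmin(mag))
        warnings.warn(
            "no real/imaginary crossing found; using the minimum-magnitude index",
            PolarityRestorationWarning,
            stacklevel=2,
        )
    signed = mag.copy()
    signed[:idx] *= -1.0
    return InversionRecoveryCurve(curve.ti_ms, signed, "signed_real")


def restore_polarity_magnitude(curve: InversionRecoveryCurve) -> InversionRecoveryCurve:
    """Re-sign a magnitude-only IR curve about its minimum.

    Without phase information the null can only be located at the global
    minimum of the magnitude signal; samples strictly preceding it are
    negated. Used when a polarity-restored signal is required but only
    magnitude data exist (e.g. composite datasets, which retain magnitudes
    only).
    """
    if curve.representation != "magnitude":
        raise ValueError("restore_polarity_magnitude expects a magnitude curve")
    idx = int(np.argmin(curve.values))
    signed = np.asarray(curve.values, dtype=float).copy()
    signed[:idx] *= -1.0
    return InversionRecoveryCurve(curve.ti_ms, signed, "signed_real")
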
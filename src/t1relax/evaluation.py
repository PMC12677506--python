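"""Scoring of multiexponential fits against known ground truth.

Because the multiexponential model is additive, the solver's component
order is arbitrary: estimates are first *aligned* to the ground truth by
the permutation that minimises the summed T1 relative error. When the
expected model order exceeds the true one, both sides are padded with
zero-amplitude components (undefined T1), so that spurious extra
components are scored through their amplitudes.

Per-component errors:

* T1 and amplitude relative error, ``100 |est - truth| / |truth|``;
* for zero-amplitude truth slots the relative error is undefined, so a
  *maximum mean error* is used instead: ``100 |est - truth| / max(truth
  amplitudes in the voxel)``.

Dataset-level summaries group errors by method and true component count,
and an OLS regression quantifies how the mean T1 error depends on the
dataset's mean T1 ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import ComponentSet

__all__ = [
    "EvaluationRecord",
    "RegressionSummary",
    "align_components",
    "relative_error_pct",
    "augment_zero_component",
    "max_mean_error_pct",
    "evaluate_voxel",
    "records_to_frame",
    "summarize",
    "error_vs_ratio_regression",
]

#: Cost charged when a zero-amplitude (undefined-T1) estimate slot is paired
#: with a real truth component. Constant across permutations, so it never
#: biases which real pairings win; it only keeps the cost total defined.
_UNDEFINED_PAIR_COST = 1.0


@dataclass(frozen=True)
class EvaluationRecord:
    """Aligned per-voxel errors for one method on one composite voxel."""

    combination_id: str
    voxel_index: int
    method: str
    aligned_pairs: tuple[tuple[float, float, float, float], ...]  # (true T1, est T1, true A, est A)
    rel_err_t1_pct: tuple[float, ...]
    rel_err_a_pct: tuple[float, ...]
    n_est_components: int
    dataset_t1_ratio: float

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.rel_err_t1_pct) or any(e < 0 for e in self.rel_err_a_pct):
            raise ValueError("percentage errors must be nonnegative")


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of relative error (%) on the dataset mean T1 ratio."""

    method: str
    slope_pct_per_ratio: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")


def relative_error_pct(est: float, truth: float) -> float:
    """``100 |est - truth| / |truth|``; undefined for zero truth."""
    if truth == 0:
        raise ValueError("relative error undefined for zero truth; use max_mean_error_pct")
    return 100.0 * abs(est - truth) / abs(truth)


def max_mean_error_pct(est_amp: float, truth_amp: float, truth_amplitudes) -> float:
    """Amplitude error normalised by the voxel's maximum true amplitude.

    Reduces to the relative error when ``truth_amp`` is itself the voxel
    maximum; remains defined for zero-amplitude truth slots.
    """
    amps = np.asarray(truth_amplitudes, dtype=float)
    peak = float(np.max(amps))
    if peak == 0:
        raise ValueError("all truth amplitudes are zero; normaliser undefined")
    return 100.0 * abs(est_amp - truth_amp) / peak


def augment_zero_component(components: ComponentSet, expected_J: int) -> ComponentSet:
    """Pad a component set to ``expected_J`` slots with zero amplitudes.

    The padded slots carry no T1 (NaN); they model an assumed component that
    is actually absent (truth side) or was not estimated (estimate side).
    """
    if expected_J < len(components):
        raise ValueError("expected_J must be >= the current number of components")
    pad = expected_J - len(components)
    if pad == 0:
        return components
    return ComponentSet(
        np.r_[components.amplitudes, np.zeros(pad)],
        np.r_[components.t1_ms, np.full(pad, np.nan)],
    )


def _pair_cost(true_t1: float, true_amp: float, est_t1: float) -> float:
    if true_amp == 0 or np.isnan(true_t1):
        return 0.0  # zero truth slot: amplitude errors handled separately
    if np.isnan(est_t1):
        return _UNDEFINED_PAIR_COST
    return abs(est_t1 - true_t1) / true_t1


def align_components(
    estimate: ComponentSet, truth: ComponentSet
) -> tuple[tuple[int, ...], float]:
    """Best one-to-one assignment of estimate slots to truth slots.

    Exhaustively searches permutations (model orders are small) for the one
    minimising the total T1 relative error over truth slots with nonzero
    amplitude; ties go to the lexicographically smallest permutation.
    Returns ``(perm, cost)`` where ``perm[k]`` is the estimate slot paired
    with truth slot ``k``.
    """
    J = len(truth)
    if len(estimate) != J:
        raise ValueError("estimate and truth must have equal length; pad first")
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(J)):
        cost = sum(
            _pair_cost(truth.t1_ms[k], truth.amplitudes[k], estimate.t1_ms[perm[k]])
            for k in range(J)
        )
        if cost < best_cost:  # strict: lexicographic order wins ties
            best_perm, best_cost = perm, cost
    return best_perm, float(best_cost)


def evaluate_voxel(
    estimate: ComponentSet,
    truth: ComponentSet,
    *,
    combination_id: str,
    voxel_index: int,
    method: str,
    dataset_t1_ratio: float,
    expected_J: int | None = None,
) -> EvaluationRecord:
    """Align one voxel's estimate to its truth and compute per-slot errors.

    ``expected_J`` > the true order appends a zero-amplitude truth component
    (the "assumed extra component" condition); estimates with fewer slots
    than needed are padded the same way. T1 relative errors are collected
    for every truth slot with nonzero amplitude: a matched estimate
    contributes its relative error, a missing one (zero-amplitude padding)
    the 100% undefined-pair cost. Amplitude errors use the relative error
    where the truth amplitude is nonzero and the max-mean-error normaliser
    otherwise.
    """
    n_est = len(estimate)
    expected = expected_J if expected_J is not None else len(truth)
    truth_p = augment_zero_component(truth, max(expected, n_est))
    est_p = augment_zero_component(estimate, len(truth_p))
    perm, _ = align_components(est_p, truth_p)

    pairs, t1_errs, a_errs = [], [], []
    for k in range(len(truth_p)):
        tt1, ta = float(truth_p.t1_ms[k]), float(truth_p.amplitudes[k])
        et1, ea = float(est_p.t1_ms[perm[k]]), float(est_p.amplitudes[perm[k]])
        pairs.append((tt1, et1, ta, ea))
        if ta > 0 and not np.isnan(tt1):
            if np.isnan(et1):
                # a true component with no estimated counterpart: scored at
                # the undefined-pair cost, so under-reporting is not rewarded
                t1_errs.append(100.0 * _UNDEFINED_PAIR_COST)
            else:
                t1_errs.append(relative_error_pct(et1, tt1))
        if ta > 0:
            a_errs.append(relative_error_pct(ea, ta))
        else:
            a_errs.append(max_mean_error_pct(ea, ta, truth_p.amplitudes))
    return EvaluationRecord(
        combination_id=combination_id,
        voxel_index=voxel_index,
        method=method,
        aligned_pairs=tuple(pairs),
        rel_err_t1_pct=tuple(t1_errs),
        rel_err_a_pct=tuple(a_errs),
        n_est_components=n_est,
        dataset_t1_ratio=dataset_t1_ratio,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Flatten evaluation records to one row per voxel."""
    rows = []
    for r in records:
        rows.append(
            {
                "combination_id": r.combination_id,
                "voxel_index": r.voxel_index,
                "method": r.method,
                "n_true_components": sum(1 for (_, _, ta, _) in r.aligned_pairs if ta > 0),
                "n_slots": len(r.aligned_pairs),
                "n_est_components": r.n_est_components,
                "dataset_t1_ratio": round(r.dataset_t1_ratio, 2),
                "mean_rel_err_t1_pct": float(np.mean(r.rel_err_t1_pct))
                if r.rel_err_t1_pct
                else np.nan,
                "mean_rel_err_a_pct": float(np.mean(r.rel_err_a_pct))
                if r.rel_err_a_pct
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize(records) -> dict[str, pd.DataFrame]:
    """Group mean errors by method and true component count.

    Returns tables: ``errors_by_components`` (mean T1 and amplitude error
    plus voxel counts per method x true-component-count group) and
    ``component_counts`` (mean estimated components per dataset x method).
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)
    errors = (
        df.groupby(["method", "n_true_components"])
        .agg(
            n_voxels=("voxel_index", "size"),
            mean_rel_err_t1_pct=("mean_rel_err_t1_pct", "mean"),
            mean_rel_err_a_pct=("mean_rel_err_a_pct", "mean"),
        )
        .reset_index()
    )
    counts = (
        df.groupby(["method", "combination_id", "dataset_t1_ratio"])
        .agg(mean_est_components=("n_est_components", "mean"), n_voxels=("voxel_index", "size"))
        .reset_index()
    )
    return {"errors_by_components": errors, "component_counts": counts}


def error_vs_ratio_regression(records) -> dict[str, RegressionSummary]:
    """Per-method OLS of per-voxel mean T1 relative error on the T1 ratio."""
    df = records_to_frame(records).dropna(subset=["mean_rel_err_t1_pct"])
    out: dict[str, RegressionSummary] = {}
    for method, sub in df.groupby("method"):
        if sub["dataset_t1_ratio"].nunique() < 3:
            raise ValueError("regression needs >= 3 distinct T1 ratio values")
        X = sm.add_constant(sub["dataset_t1_ratio"].to_numpy())
        fit = sm.OLS(sub["mean_rel_err_t1_pct"].to_numpy(), X).fit()
        out[method] = RegressionSummary(
            method=method,
            slope_pct_per_ratio=float(fit.params[1]),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared),
            p_value=float(fit.pvalues[1]),
            n=int(fit.nobs),
        )
    return out
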
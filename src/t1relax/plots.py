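"""Report figures: error vs T1 ratio, estimates vs truth, component counts."""

from __future__ import annotations

import numpy as np

from .evaluation import records_to_frame


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_error_vs_ratio(records, regression=None, method=None, ax=None):
    """Per-voxel mean T1 error against the dataset T1 ratio, with OLS line."""
    ax = _ax(ax)
    df = records_to_frame(records).dropna(subset=["mean_rel_err_t1_pct"])
    if method is not None:
        df = df[df["method"] == method]
    ax.plot(df["dataset_t1_ratio"], df["mean_rel_err_t1_pct"], "o", alpha=0.4)
    if regression is not None:
        xs = np.linspace(df["dataset_t1_ratio"].min(), df["dataset_t1_ratio"].max(), 50)
        ax.plot(xs, regression.intercept + regression.slope_pct_per_ratio * xs, "r-")
    ax.set_xlabel("mean T1 ratio")
    ax.set_ylabel("relative T1 error [%]")
    if method:
        ax.set_title(method)
    return ax


def plot_estimates_vs_truth(records, method=None, ax=None):
    """Strip plot of aligned estimated T1 values over their truth values."""
    ax = _ax(ax)
    for r in records:
        if method is not None and r.method != method:
            continue
        for true_t1, est_t1, true_a, _ in r.aligned_pairs:
            if true_a > 0 and not (np.isnan(true_t1) or np.isnan(est_t1)):
                ax.plot(true_t1, est_t1, "k.", alpha=0.3)
    lims = ax.get_xlim()
    ax.plot(lims, lims, "b--", lw=1)
    ax.set_xlabel("true T1 [ms]")
    ax.set_ylabel("estimated T1 [ms]")
    if method:
        ax.set_title(method)
    return ax


def plot_component_counts(records, ax=None):
    """Mean estimated number of components per dataset, by method."""
    ax = _ax(ax)
    df = records_to_frame(records)
    grouped = (
        df.groupby(["method", "dataset_t1_ratio"])["n_est_components"].mean().reset_index()
    )
    for method, sub in grouped.groupby("method"):
        ax.plot(sub["dataset_t1_ratio"], sub["n_est_components"], "o-", label=method)
    ax.set_xlabel("mean T1 ratio")
    ax.set_ylabel("mean estimated components per voxel")
    ax.legend()
    return ax
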
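"""Graphics for assay precision and design, with machine-readable sidecars.

Every figure writer also emits the plotted points/curves as a TSV next to
the image (same stem, ``.points.tsv`` / ``.curve.tsv``), so graphical
claims can be tested without parsing pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .correlation import replicate_correlation
from .errors import ParameterError
from .power import fraction_powered

QUANTILES = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class SmoothedQuantiles:
    """Kernel-smoothed repeatability quantiles along the concentration axis."""

    grid: np.ndarray
    q25: np.ndarray
    q50: np.ndarray
    q75: np.ndarray
    bandwidth: float


def _weighted_quantile(y_sorted: np.ndarray, w_sorted: np.ndarray, q: float) -> float:
    # midpoint-rule weighted empirical quantile with linear interpolation
    cw = np.cumsum(w_sorted)
    total = cw[-1]
    pos = (cw - 0.5 * w_sorted) / total
    return float(np.interp(q, pos, y_sorted))


def running_quantiles(
    x, y, quantiles=QUANTILES, bandwidth: float | None = None, grid_size: int = 100
) -> SmoothedQuantiles:
    """Gaussian-kernel-weighted running quantiles of y along x.

    Default bandwidth is one tenth of the x range.  Weights are renormalized
    at each grid point, so edges are handled without boundary bias beyond
    the kernel's own smoothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 10:
        raise ParameterError("need at least 10 points to smooth")
    span = float(x.max() - x.min())
    if bandwidth is None:
        bandwidth = span / 10.0 if span > 0 else 1.0
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    grid = np.linspace(x.min(), x.max(), grid_size)
    order = np.argsort(y, kind="stable")
    ys = y[order]
    xs = x[order]
    curves = {q: np.empty(grid_size) for q in quantiles}
    for gi, g in enumerate(grid):
        w = np.exp(-0.5 * ((xs - g) / bandwidth) ** 2)
        w = np.maximum(w, 1e-300)
        for q in quantiles:
            curves[q][gi] = _weighted_quantile(ys, w, q)
    return SmoothedQuantiles(
        grid=grid,
        q25=curves[quantiles[0]],
        q50=curves[quantiles[1]],
        q75=curves[quantiles[2]],
        bandwidth=float(bandwidth),
    )


def _fd_bins(x: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 10
    width = 2 * iqr / len(x) ** (1 / 3)
    return max(int(np.ceil((x.max() - x.min()) / width)), 1)


def plot_repeatability_vs_concentration(
    profile, path, bandwidth: float | None = None
) -> Path:
    """Repeatability-vs-concentration scatter with smoothed quantile curves
    and marginal histograms (R at right, concentration at top)."""
    path = Path(path)
    x = np.asarray(profile.mean_concentration, float)
    y = np.asarray(profile.R, float)
    if x.size < 1:
        raise ParameterError("empty profile")

    fig = plt.figure(figsize=(7, 7))
    gs = fig.add_gridspec(
        2, 2, width_ratios=(5, 1), height_ratios=(1, 5), hspace=0.05, wspace=0.05
    )
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    ax.scatter(x, y, s=8, alpha=0.4, color="k", linewidths=0)
    sq = None
    if x.size >= 10:
        sq = running_quantiles(x, y, bandwidth=bandwidth)
        ax.plot(sq.grid, sq.q50, color="red", lw=1.5)
        ax.plot(sq.grid, sq.q25, color="red", lw=1.0, ls="--")
        ax.plot(sq.grid, sq.q75, color="red", lw=1.0, ls="--")
    ax.set_xlabel("mean measured log2 concentration")
    ax.set_ylabel("repeatability R")
    ax.set_ylim(-0.02, 1.02)
    ax_top.hist(x, bins=_fd_bins(x), color="grey")
    ax_top.tick_params(labelbottom=False)
    ax_right.hist(
        y, bins=np.linspace(0, 1, 31), orientation="horizontal", color="grey"
    )
    ax_right.tick_params(labelleft=False)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)

    points = pd.DataFrame(
        {"analyte_id": profile.analyte_ids, "mean_concentration": x, "R": y}
    )
    points.to_csv(path.with_suffix(path.suffix + ".points.tsv"), sep="\t", index=False)
    if sq is not None:
        pd.DataFrame(
            {"grid": sq.grid, "q25": sq.q25, "q50": sq.q50, "q75": sq.q75}
        ).to_csv(path.with_suffix(path.suffix + ".curve.tsv"), sep="\t", index=False)
    return path


def plot_powered_vs_sif(plan, path) -> Path:
    """% of analytes powered versus SIF, with a shaded bootstrap band."""
    path = Path(path)
    grid = np.asarray(plan.sif_grid, float)
    pct = np.asarray(plan.pct_powered, float)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if plan.ci_lower is not None:
        ax.fill_between(grid, plan.ci_lower, plan.ci_upper, color="0.8")
    ax.plot(grid, pct, color="k", lw=1.5, marker="o", ms=3)
    ax.set_xlim(1.0, grid.max())
    ax.set_ylim(0, 100)
    ax.set_xlabel("sample size inflation factor (SIF)")
    ax.set_ylabel("% analytes powered")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    out = {"sif": grid, "pct_powered": pct}
    if plan.ci_lower is not None:
        out["ci_lower"] = plan.ci_lower
        out["ci_upper"] = plan.ci_upper
    pd.DataFrame(out).to_csv(
        path.with_suffix(path.suffix + ".curve.tsv"), sep="\t", index=False
    )
    return path


def plot_replicate_scatter(table, sample_id, replicate_pair=(1, 2), path="scatter.svg") -> Path:
    """Replicate-vs-replicate scatter (one point per analyte) with the
    sample correlation r annotated — the plot this package argues against
    over-interpreting."""
    path = Path(path)
    pair = table.replicate_pair(sample_id, replicate_pair)
    r = replicate_correlation(table, sample_id, replicate_pair)
    x = pair["rep1"].to_numpy()
    y = pair["rep2"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 5))
    lims = (min(x.min(), y.min()), max(x.max(), y.max()))
    ax.plot(lims, lims, color="0.6", lw=1, zorder=0)
    ax.scatter(x, y, s=8, alpha=0.5, color="k", linewidths=0)
    ax.set_xlabel(f"replicate {replicate_pair[0]} (log concentration)")
    ax.set_ylabel(f"replicate {replicate_pair[1]} (log concentration)")
    ax.set_title(f"sample {sample_id}: r = {r:.3f}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    pair.reset_index().to_csv(
        path.with_suffix(path.suffix + ".points.tsv"), sep="\t", index=False
    )
    return path
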
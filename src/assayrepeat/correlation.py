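"""Inter-replicate correlation diagnostics.

The habit of scatterplotting one technical replicate against another (one
point per analyte) and quoting Pearson's r as "assay precision" is the
practice these diagnostics exist to interrogate.  Under the
variance-components model, as the number of analytes p grows, r converges in
probability to

    (v_d + v̄_b) / (v_d + v̄_b + v̄_e)

so a wide dynamic range v_d drives r toward 1 regardless of how noisy the
assay is relative to its biological signal.  r is therefore a confounded
precision measure; the tools here quantify that confound and the speed of
the convergence on finite analyte panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ReplicateTable
from .errors import DataError, DomainError, ParameterError


@dataclass(frozen=True)
class ConvergenceCurve:
    """r computed on random analyte subsets of increasing size."""

    p_grid: np.ndarray
    r_mean: np.ndarray
    r_sd: np.ndarray
    r_full: float
    n_resamples: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"p": self.p_grid, "r_mean": self.r_mean, "r_sd": self.r_sd}
        )


def replicate_correlation(table: ReplicateTable, sample_id, replicate_pair=(1, 2)) -> float:
    """Pearson correlation across analytes between two replicate vectors.

    Computed on analytes where both replicates of ``sample_id`` are present.
    Requires at least 3 complete analytes.
    """
    pair = table.replicate_pair(sample_id, replicate_pair)
    if len(pair) < 3:
        raise DataError(
            f"sample {sample_id!r} has only {len(pair)} analytes with both "
            f"replicates {replicate_pair}; need >=3"
        )
    x = pair["rep1"].to_numpy()
    y = pair["rep2"].to_numpy()
    return float(np.corrcoef(x, y)[0, 1])


def asymptotic_correlation(v_d: float, v_b_bar: float, v_e_bar: float) -> float:
    """Large-p limit of the inter-replicate correlation:
    (v_d + v̄_b) / (v_d + v̄_b + v̄_e)."""
    if v_d < 0 or v_b_bar < 0 or v_e_bar < 0:
        raise DomainError("variance components must be non-negative")
    total = v_d + v_b_bar + v_e_bar
    if total == 0:
        raise DomainError("all variance components are zero")
    return (v_d + v_b_bar) / total


def convergence_curve(
    table: ReplicateTable,
    sample_id,
    replicate_pair=(1, 2),
    p_grid=(10, 25, 50, 100, 250, 500, 1000),
    n_resamples: int = 200,
    seed: int = 0,
) -> ConvergenceCurve:
    """Resampling study of r versus analyte-panel size.

    For each subset size p in ``p_grid``, draws ``n_resamples`` random
    analyte subsets without replacement and records the mean and SD of r,
    alongside r on the full panel.
    """
    pair = table.replicate_pair(sample_id, replicate_pair)
    p_full = len(pair)
    p_grid = np.asarray(sorted(int(p) for p in p_grid))
    if p_grid.size == 0 or n_resamples < 1:
        raise ParameterError("need a non-empty p_grid and n_resamples >= 1")
    if p_grid[0] < 3:
        raise ParameterError("subset sizes below 3 cannot support a correlation")
    if p_grid[-1] > p_full:
        raise ParameterError(
            f"largest subset size {p_grid[-1]} exceeds the {p_full} complete analytes"
        )
    x = pair["rep1"].to_numpy()
    y = pair["rep2"].to_numpy()
    r_full = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    r_mean = np.empty(p_grid.size)
    r_sd = np.empty(p_grid.size)
    for gi, p in enumerate(p_grid):
        if p == p_full:
            r_mean[gi], r_sd[gi] = r_full, 0.0
            continue
        rs = np.empty(n_resamples)
        for b in range(n_resamples):
            idx = rng.choice(p_full, size=p, replace=False)
            rs[b] = np.corrcoef(x[idx], y[idx])[0, 1]
        r_mean[gi] = rs.mean()
        r_sd[gi] = rs.std(ddof=1) if n_resamples > 1 else 0.0
    return ConvergenceCurve(
        p_grid=p_grid, r_mean=r_mean, r_sd=r_sd,
        r_full=r_full, n_resamples=n_resamples, seed=seed,
    )


def subset_relative_deviation(
    table: ReplicateTable,
    sample_id,
    subset_size: int = 100,
    n_resamples: int = 200,
    replicate_pair=(1, 2),
    seed: int = 0,
) -> float:
    """Mean absolute relative deviation (%) of subset-r from full-panel r.

    The convergence summary: average over ``n_resamples`` random subsets of
    ``|r_subset - r_full| / r_full * 100``.
    """
    pair = table.replicate_pair(sample_id, replicate_pair)
    p_full = len(pair)
    if subset_size > p_full:
        raise ParameterError("subset_size exceeds the number of complete analytes")
    x = pair["rep1"].to_numpy()
    y = pair["rep2"].to_numpy()
    r_full = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    devs = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.choice(p_full, size=subset_size, replace=False)
        devs[b] = abs(np.corrcoef(x[idx], y[idx])[0, 1] - r_full)
    return float(devs.mean() / abs(r_full) * 100.0)
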
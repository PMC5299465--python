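"""Variance-components estimation for technical-replicate data.

The measurement model for analyte ``k``, sample ``i``, replicate ``j`` is

    y_ij^(k) = mu + a^(k) + b_i^(k) + e_ij^(k)

with independent zero-mean components: ``a^(k)`` carries the dynamic-range
variance ``v_d`` (spread of true mean concentration across analytes),
``b_i^(k)`` the biological signal variance ``v_b^(k)`` (spread across
individuals) and ``e_ij^(k)`` the experimental noise variance ``v_e^(k)``.

Per analyte we fit the classical unbalanced one-way random-effects ANOVA by
method of moments (closed form, hence cheap enough for a parametric
bootstrap):

    MSW  = sum_ij (y_ij - ybar_i.)^2 / (N - I)
    MSB  = sum_i n_i (ybar_i. - ybar..)^2 / (I - 1)
    n0'  = (N - sum_i n_i^2 / N) / (I - 1)
    v_e^ = MSW
    v_b^ = (MSB - MSW) / n0'

``v_b^`` may come out negative; it is truncated at zero (upward bias, lower
mean-squared error).  The repeatability (intraclass correlation) of analyte
``k`` is R^(k) = v_b / (v_b + v_e), the proportion of observed variance that
is biological rather than experimental.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data import ReplicateTable, validate_design
from .errors import DataError, DesignError, DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceDecomposition:
    """Fitted variance components: global v_d plus per-analyte v_b, v_e.

    ``v_b`` is stored post-truncation; ``v_b_raw`` keeps the signed
    method-of-moments estimate for diagnostics.
    """

    v_d: float
    analyte_ids: list
    v_b: np.ndarray
    v_e: np.ndarray
    analyte_means: np.ndarray
    mu_hat: float
    v_b_raw: np.ndarray | None = None

    @property
    def v_b_bar(self) -> float:
        return float(np.mean(self.v_b)) if len(self.v_b) else float("nan")

    @property
    def v_e_bar(self) -> float:
        return float(np.mean(self.v_e)) if len(self.v_e) else float("nan")


@dataclass(frozen=True)
class RepeatabilityProfile:
    """Per-analyte repeatability R^(k) with mean measured concentration."""

    analyte_ids: list
    R: np.ndarray
    mean_concentration: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    excluded: dict = field(default_factory=dict)  # analyte -> reason

    def __len__(self) -> int:
        return len(self.analyte_ids)


def anova_decompose(cells) -> tuple[float, float, float]:
    """Method-of-moments fit of one analyte's one-way random-effects model.

    Parameters
    ----------
    cells
        Mapping sample -> sequence of replicate values for this analyte.

    Returns
    -------
    (v_b_hat, v_e_hat, mean)
        ``v_b_hat`` is pre-truncation (may be negative); ``mean`` is the
        grand mean over all observations.
    """
    groups = [np.asarray(v, dtype=float) for v in cells.values() if len(v) > 0]
    if any(not np.isfinite(g).all() for g in groups):
        raise DataError("non-finite value in replicate data")
    I = len(groups)
    n = np.array([len(g) for g in groups])
    N = int(n.sum())
    if I < 2:
        raise DesignError(f"need >=2 samples with data, got {I}")
    if N - I < 1:
        raise DesignError("need at least one sample with >=2 replicates")
    means = np.array([g.mean() for g in groups])
    grand = sum(g.sum() for g in groups) / N
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    msw = ssw / (N - I)
    msb = (n * (means - grand) ** 2).sum() / (I - 1)
    n0p = (N - (n**2).sum() / N) / (I - 1)
    v_b_hat = (msb - msw) / n0p
    return float(v_b_hat), float(msw), float(grand)


def truncate_negative(v: float) -> float:
    """Clamp a variance estimate at zero (negative ANOVA estimates -> 0)."""
    if not math.isfinite(v):
        raise DataError(f"non-finite variance estimate: {v}")
    return max(v, 0.0)


def repeatability(v_b: float, v_e: float) -> float:
    """R = v_b / (v_b + v_e); the no-information case v_b = v_e = 0 maps to 0.

    Inputs must be non-negative (run :func:`truncate_negative` first).
    """
    if v_b < 0 or v_e < 0:
        raise DomainError("repeatability requires non-negative variances")
    total = v_b + v_e
    if total == 0:
        return 0.0
    return v_b / total


def ba_repeatability_coefficient(v_e: float) -> float:
    """Bland–Altman repeatability coefficient 1.96*sqrt(2*v_e).

    A 95% one-sided upper bound for the absolute difference between a pair
    of replicate readings, on the scale of the measurements themselves.
    """
    if v_e < 0:
        raise DomainError("v_e must be non-negative")
    return 1.96 * math.sqrt(2.0 * v_e)


def estimate_dynamic_range(analyte_means, per_analyte_mean_sampling_var) -> float:
    """Method-of-moments estimate of the dynamic-range variance v_d.

    Between-analyte sample variance (denominator p-1) of the per-analyte
    grand means, minus the average sampling variance of those means under
    each analyte's own replication design, truncated at zero.
    """
    means = np.asarray(analyte_means, dtype=float)
    if means.size < 2:
        raise DesignError("need >=2 analytes to estimate dynamic range")
    correction = float(np.mean(np.asarray(per_analyte_mean_sampling_var, float)))
    return truncate_negative(float(np.var(means, ddof=1)) - correction)


def _anova_matrix(y: np.ndarray, counts: np.ndarray):
    """Vectorized ANOVA over many analytes sharing one replication design.

    ``y`` is (p, N) with columns grouped by sample (sample 0's n_0 replicates
    first, then sample 1's, ...); ``counts`` gives n_i per sample.
    Returns (v_b_raw, v_e, grand_means) arrays of length p.
    """
    counts = np.asarray(counts)
    I = counts.size
    N = int(counts.sum())
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    sums = np.add.reduceat(y, starts, axis=1)  # (p, I)
    means_i = sums / counts
    grand = sums.sum(axis=1) / N
    # computational SS formula can go ~-1e-16 by cancellation; SSW >= 0 truly
    ssw = np.maximum((y**2).sum(axis=1) - (counts * means_i**2).sum(axis=1), 0.0)
    v_e = ssw / (N - I)
    msb = (counts * (means_i - grand[:, None]) ** 2).sum(axis=1) / (I - 1)
    n0p = (N - (counts**2).sum() / N) / (I - 1)
    v_b_raw = (msb - v_e) / n0p
    return v_b_raw, v_e, grand


def _mean_sampling_variance(v_b, v_e, counts) -> float:
    """First-order variance of one analyte's grand mean under its design:
    Var(ybar..) = v_b * sum n_i^2 / N^2 + v_e / N."""
    counts = np.asarray(counts)
    N = counts.sum()
    return float(v_b * (counts**2).sum() / N**2 + v_e / N)


def decompose_matrix(y: np.ndarray, counts, analyte_ids=None):
    """Fast-path decomposition for complete (no missing cells) pilots.

    ``y`` is (p, N) with observation columns grouped by sample in design
    order and ``counts`` the per-sample replicate counts n_i — the layout
    produced by :func:`assayrepeat.simulate.simulate_matrix`.  Applies the
    same estimators as :func:`decompose_all` without the tabular overhead.
    """
    y = np.asarray(y, dtype=float)
    counts = np.asarray(counts, dtype=int)
    if counts.size < 2:
        raise DesignError("need >=2 samples")
    if counts.sum() - counts.size < 1:
        raise DesignError("need at least one sample with >=2 replicates")
    p = y.shape[0]
    v_b_raw, v_e, means = _anova_matrix(y, counts)
    v_b = np.maximum(v_b_raw, 0.0)
    N = int(counts.sum())
    samp_var = v_b * (counts**2).sum() / N**2 + v_e / N
    v_d = estimate_dynamic_range(means, samp_var) if p >= 2 else 0.0
    ids = list(analyte_ids) if analyte_ids is not None else list(range(p))
    decomposition = VarianceDecomposition(
        v_d=v_d, analyte_ids=ids, v_b=v_b, v_e=v_e,
        analyte_means=means, mu_hat=float(y.mean()), v_b_raw=v_b_raw,
    )
    with np.errstate(invalid="ignore"):
        R = np.where(v_b + v_e > 0, v_b / np.maximum(v_b + v_e, 1e-300), 0.0)
    profile = RepeatabilityProfile(
        analyte_ids=ids, R=np.clip(R, 0.0, 1.0), mean_concentration=means,
    )
    return decomposition, profile


def decompose_all(table: ReplicateTable):
    """Fit every analyte and assemble the assay-wide decomposition.

    Per analyte: ANOVA fit, truncation of negative v_b, repeatability.
    Analytes whose own design cannot support the fit (fewer than 2 samples
    with data, or no replicated sample) are excluded with a logged reason;
    it is an error only if every analyte fails.

    Returns
    -------
    (VarianceDecomposition, RepeatabilityProfile)
    """
    validate_design(table)
    f = table.frame
    agg = f.groupby(["analyte_id", "sample_id"], sort=True)["value"].agg(
        ["count", "sum", "mean", lambda s: ((s - s.mean()) ** 2).sum()]
    )
    agg.columns = ["n", "sum", "mean", "ssw"]

    ids, v_b_raw_l, v_e_l, means_l, samp_var_l = [], [], [], [], []
    excluded: dict = {}
    for analyte, g in agg.groupby(level="analyte_id", sort=True):
        n = g["n"].to_numpy()
        I = len(n)
        N = int(n.sum())
        if I < 2:
            excluded[analyte] = "fewer than 2 samples with data"
            continue
        if N - I < 1:
            excluded[analyte] = "no sample with >=2 replicates"
            continue
        grand = g["sum"].sum() / N
        msw = g["ssw"].sum() / (N - I)
        msb = (n * (g["mean"].to_numpy() - grand) ** 2).sum() / (I - 1)
        n0p = (N - (n**2).sum() / N) / (I - 1)
        v_b_raw = (msb - msw) / n0p
        v_b = truncate_negative(v_b_raw)
        ids.append(analyte)
        v_b_raw_l.append(v_b_raw)
        v_e_l.append(msw)
        means_l.append(grand)
        samp_var_l.append(_mean_sampling_variance(v_b, msw, n))
    for analyte, reason in excluded.items():
        logger.warning("analyte %s excluded: %s", analyte, reason)
    if not ids:
        raise DesignError("no analyte supports variance estimation")

    v_b_raw = np.array(v_b_raw_l)
    v_b = np.maximum(v_b_raw, 0.0)
    v_e = np.array(v_e_l)
    means = np.array(means_l)
    n_trunc = int((v_b_raw < 0).sum())
    if n_trunc:
        logger.info("truncated %d negative v_b estimates to zero", n_trunc)

    v_d = (
        estimate_dynamic_range(means, samp_var_l) if len(ids) >= 2 else 0.0
    )
    mu_hat = float(f["value"].mean())
    decomposition = VarianceDecomposition(
        v_d=v_d, analyte_ids=ids, v_b=v_b, v_e=v_e,
        analyte_means=means, mu_hat=mu_hat, v_b_raw=v_b_raw,
    )
    R = np.array([repeatability(b, e) for b, e in zip(v_b, v_e)])
    profile = RepeatabilityProfile(
        analyte_ids=ids, R=R, mean_concentration=means, excluded=excluded,
    )
    return decomposition, profile
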
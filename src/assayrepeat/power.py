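"""Sample-size planning under measurement error.

The reference design is a balanced two-group comparison of analyte
concentration (treatment vs control), tested with the two-sided
equal-variance two-sample t-test.  The targeted standardized effect is
Δ = |μ_T − μ_C| / √v_b, in units of the biological standard deviation.

A perfect instrument (repeatability R = 1) needs a total sample size n0.
Measurement error attenuates the observable effect to Δ√R, and the variance
inflation factor 1/R = (v_b + v_e)/v_b is the factor by which sample size
must grow to restore power.  The sample size inflation factor SIF := n/n0
then gives the planning rule: analyte k is well powered iff SIF > 1/R^(k).
Given the pilot's distribution of repeatabilities, the % of analytes
powered at each SIF drives the choice of n = SIF × n0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ParameterError

DEFAULT_SIF_GRID = (1.1, 1.5, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class PowerPlan:
    """A complete design report: baseline size plus the SIF trade-off table."""

    delta: float
    alpha: float
    power_target: float
    n0: int
    sif_grid: np.ndarray
    pct_powered: np.ndarray
    n_adjusted: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "sif": self.sif_grid,
            "pct_powered": self.pct_powered,
            "n_adjusted": self.n_adjusted,
        }
        if self.ci_lower is not None:
            d["ci_lower"] = self.ci_lower
            d["ci_upper"] = self.ci_upper
        return pd.DataFrame(d)


def _two_sample_power(n_total: int, d: float, alpha: float) -> float:
    """Exact noncentral-t power of the balanced two-sided test."""
    m = n_total / 2.0
    df = n_total - 2
    nc = d * math.sqrt(m / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def base_sample_size(delta: float, alpha: float, power_target: float,
                     cap: int = 10_000_000) -> int:
    """Smallest even total n0 so the balanced two-sample t-test reaches the
    target power at standardized effect ``delta`` on a perfect instrument."""
    if delta <= 0:
        raise ParameterError("delta must be positive")
    if not (0 < alpha < 1 and 0 < power_target < 1):
        raise ParameterError("alpha and power_target must lie in (0, 1)")
    n = 4
    while n <= cap:
        if _two_sample_power(n, delta, alpha) >= power_target:
            return n
        n += 2
    raise ParameterError(f"target power unattainable below n={cap}")


def sif_threshold(R: float) -> float:
    """Variance inflation factor 1/R: the SIF above which an analyte with
    repeatability R is well powered.  R = 0 maps to +inf (never powered)."""
    if R == 0:
        return math.inf
    if not (0 < R <= 1):
        raise DomainError(f"repeatability must lie in [0, 1], got {R}")
    return 1.0 / R


def fraction_powered(R_values, sif: float) -> float:
    """Percentage of analytes with SIF strictly above their 1/R threshold."""
    R = np.asarray(R_values, dtype=float)
    if R.size == 0:
        raise ParameterError("R_values is empty")
    if np.any((R < 0) | (R > 1)):
        raise DomainError("repeatabilities must lie in [0, 1]")
    if sif < 1:
        raise ParameterError("SIF must be >= 1")
    with np.errstate(divide="ignore", over="ignore"):
        thresholds = np.divide(1.0, R, out=np.full_like(R, np.inf), where=R > 0)
    powered = sif > thresholds  # strict: boundary analytes are unpowered
    return float(100.0 * powered.sum() / R.size)


def adjusted_sample_size(n0: int, sif: float) -> int:
    """n = SIF × n0, rounded up to the nearest even integer (balanced groups)."""
    if n0 <= 0 or n0 % 2:
        raise ParameterError("n0 must be a positive even total")
    if sif < 1:
        raise ParameterError("SIF must be >= 1")
    return int(2 * math.ceil(sif * n0 / 2.0 - 1e-12))


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise-error-controlling per-test level alpha / n_tests."""
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return alpha / n_tests


def effective_effect(delta: float, R: float) -> float:
    """Attenuated standardized effect Δ√R on the measured (noisy) scale."""
    if delta < 0 or not (0 <= R <= 1):
        raise ParameterError("need delta >= 0 and R in [0, 1]")
    return delta * math.sqrt(R)


def achieved_power(n_total: int, delta: float, alpha: float, R: float = 1.0) -> float:
    """Noncentral-t power of the two-sided test at total size ``n_total``
    for an analyte with repeatability ``R`` (effect attenuated to Δ√R)."""
    if n_total < 4 or n_total % 2:
        raise ParameterError("n_total must be an even total >= 4")
    return _two_sample_power(n_total, effective_effect(delta, R), alpha)


def monte_carlo_power(
    n_total: int,
    delta: float,
    alpha: float,
    R: float = 1.0,
    n_sims: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> float:
    """Empirical power by simulation; independent of the analytic formula.

    Each replicate experiment draws balanced groups whose per-subject
    measurement is biology + noise: variance v_b + v_e with
    v_b/(v_b + v_e) = R and group means differing by delta*sqrt(v_b).
    The test applied is scipy's two-sided equal-variance t-test.
    """
    if n_total < 4 or n_total % 2:
        raise ParameterError("n_total must be an even total >= 4")
    m = n_total // 2
    sd_obs = math.sqrt(1.0 / R) if R > 0 else math.inf
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        x = rng.normal(0.0, sd_obs, size=(b, m))
        y = rng.normal(delta, sd_obs, size=(b, m))
        res = stats.ttest_ind(x, y, axis=1)
        rejections += int((res.pvalue < alpha).sum())
        done += b
    return rejections / n_sims


def power_table(profile, sif_grid=DEFAULT_SIF_GRID, bands=None) -> pd.DataFrame:
    """% of analytes powered at each SIF, with optional bootstrap bands.

    ``bands`` is a (lower, upper) pair of per-SIF percentage arrays, e.g.
    from :func:`assayrepeat.bootstrap.powered_fraction_bands`.
    """
    sif_grid = np.asarray(sif_grid, dtype=float)
    if sif_grid.size == 0:
        raise ParameterError("sif_grid is empty")
    if len(profile) == 0:
        raise ParameterError("profile is empty")
    pct = np.array([fraction_powered(profile.R, s) for s in sif_grid])
    out = pd.DataFrame({"sif": sif_grid, "pct_powered": pct})
    if bands is not None:
        lower, upper = bands
        if len(lower) != sif_grid.size or len(upper) != sif_grid.size:
            raise ParameterError("bands do not match the SIF grid")
        out["ci_lower"] = np.asarray(lower, float)
        out["ci_upper"] = np.asarray(upper, float)
    return out


def build_power_plan(
    profile,
    delta: float,
    alpha: float,
    power_target: float,
    sif_grid=DEFAULT_SIF_GRID,
    bands=None,
) -> PowerPlan:
    """Assemble the full design report for a fitted repeatability profile."""
    n0 = base_sample_size(delta, alpha, power_target)
    tab = power_table(profile, sif_grid, bands)
    n_adj = np.array([adjusted_sample_size(n0, s) for s in tab["sif"]])
    return PowerPlan(
        delta=delta, alpha=alpha, power_target=power_target, n0=n0,
        sif_grid=tab["sif"].to_numpy(),
        pct_powered=tab["pct_powered"].to_numpy(),
        n_adjusted=n_adj,
        ci_lower=tab["ci_lower"].to_numpy() if "ci_lower" in tab else None,
        ci_upper=tab["ci_upper"].to_numpy() if "ci_upper" in tab else None,
    )
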
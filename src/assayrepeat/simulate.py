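"""Generative model for technical-replicate pilot data.

Draws datasets with the exact hierarchical Gaussian structure

    y_ij^(k) = mu + a^(k) + b_i^(k) + e_ij^(k)

    a^(k)    ~ N(0, v_d)          analyte-level offset (dynamic range)
    b_i^(k)  ~ N(0, v_b^(k))      biology: sample i's deviation at analyte k
    e_ij^(k) ~ N(0, v_e^(k))      measurement noise per observation

Per-analyte variances v_b^(k), v_e^(k) are either constant across analytes
or drawn from a log-normal law (specified by its mean and SD on the
variance scale), and v_e^(k) may additionally be linked to analyte
concentration through a monotone multiplier — emulating instruments that
measure low-abundance analytes less precisely.

The default replication design mirrors the pilot layouts of real multiplex
assays: ``n_replicated`` samples measured in duplicate, the rest once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import ReplicateTable
from .errors import ParameterError

# A variance law is either a non-negative float (constant across analytes)
# or a tuple ("lognormal", mean, sd) on the variance scale.
VarianceLaw = "float | tuple[str, float, float]"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; a dataset is a pure function of (config, seed)."""

    p: int
    n_samples: int
    n_replicated: int
    v_d: float
    v_b_law: object = 0.05
    v_e_law: object = 0.05
    mu: float = 10.0
    replicate_counts: Sequence[int] | None = None  # explicit per-sample n_i
    noise_link: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.p < 1:
            raise ParameterError("need p >= 1 analytes")
        if self.n_replicated > self.n_samples:
            raise ParameterError("n_replicated cannot exceed n_samples")
        if self.v_d < 0:
            raise ParameterError("v_d must be non-negative")
        if self.replicate_counts is not None:
            if len(self.replicate_counts) != self.n_samples:
                raise ParameterError("replicate_counts must have n_samples entries")
            if any(c < 1 for c in self.replicate_counts):
                raise ParameterError("every sample needs >=1 replicate")

    def design(self) -> np.ndarray:
        """Per-sample replicate counts n_i."""
        if self.replicate_counts is not None:
            return np.asarray(self.replicate_counts, dtype=int)
        counts = np.ones(self.n_samples, dtype=int)
        counts[: self.n_replicated] = 2
        return counts


def _draw_variances(law, p: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(law, (int, float)):
        if law < 0:
            raise ParameterError("constant variance law must be non-negative")
        return np.full(p, float(law))
    if isinstance(law, (tuple, list)) and len(law) == 3 and law[0] == "lognormal":
        _, mean, sd = law
        if mean <= 0 or sd < 0:
            raise ParameterError("lognormal law needs mean > 0 and sd >= 0")
        if sd == 0:
            return np.full(p, float(mean))
        # match mean/SD on the variance scale
        sigma2 = np.log1p((sd / mean) ** 2)
        mu_log = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu_log, np.sqrt(sigma2), size=p)
    raise ParameterError(f"unrecognized variance law: {law!r}")


def simulate_matrix(config: SimulationConfig, rng: np.random.Generator):
    """Core sampler returning arrays (fast path, no DataFrame).

    Returns ``(y, counts, truth)`` where ``y`` is (p, N) with observation
    columns grouped by sample in design order, ``counts`` the per-sample
    n_i, and ``truth`` the drawn analyte offsets and per-analyte variances.
    """
    counts = config.design()
    N = int(counts.sum())
    p = config.p
    sample_of_col = np.repeat(np.arange(config.n_samples), counts)
    a = rng.normal(0.0, np.sqrt(config.v_d), size=p)
    v_b = _draw_variances(config.v_b_law, p, rng)
    v_e = _draw_variances(config.v_e_law, p, rng)
    if config.noise_link is not None:
        mult = np.asarray(config.noise_link(config.mu + a), dtype=float)
        if mult.shape != (p,) or np.any(mult < 0):
            raise ParameterError("noise_link must map p means to p non-negative multipliers")
        v_e = v_e * mult
    b = rng.normal(0.0, 1.0, size=(p, config.n_samples)) * np.sqrt(v_b)[:, None]
    e = rng.normal(0.0, 1.0, size=(p, N)) * np.sqrt(v_e)[:, None]
    y = config.mu + a[:, None] + b[:, sample_of_col] + e
    truth = {
        "mu": config.mu,
        "v_d": config.v_d,
        "a": a,
        "v_b": v_b,
        "v_e": v_e,
    }
    return y, counts, truth


def _matrix_to_table(y: np.ndarray, counts: np.ndarray) -> ReplicateTable:
    p, N = y.shape
    n_samples = counts.size
    width_a = len(str(p))
    width_s = len(str(n_samples))
    analytes = np.array([f"A{i + 1:0{width_a}d}" for i in range(p)])
    samples = np.array([f"S{i + 1:0{width_s}d}" for i in range(n_samples)])
    sample_of_col = np.repeat(np.arange(n_samples), counts)
    rep_of_col = np.concatenate([np.arange(1, c + 1) for c in counts])
    frame = pd.DataFrame(
        {
            "analyte_id": np.repeat(analytes, N),
            "sample_id": np.tile(samples[sample_of_col], p),
            "replicate_id": np.tile(rep_of_col, p),
            "value": y.ravel(),
        }
    )
    return ReplicateTable.from_frame(frame)


def simulate_dataset(config: SimulationConfig):
    """Draw one pilot dataset.

    Returns ``(table, truth)``: the :class:`ReplicateTable` plus a record of
    the drawn analyte offsets a^(k) and per-analyte variances, for use as a
    ground-truth oracle in recovery studies.
    """
    rng = np.random.default_rng(config.seed)
    y, counts, truth = simulate_matrix(config, rng)
    return _matrix_to_table(y, counts), truth


def make_fig1e_example(
    seed: int = 0,
    v_d: float = 9.0,
    v_b: float = 0.05,
    v_e: float = 0.05,
    p: int = 3,
) -> ReplicateTable:
    """Pedagogical example: a few analytes, one individual, two replicates.

    The dynamic range v_d dwarfs both the biological and noise variances, so
    a replicate-vs-replicate scatter of even three analytes tends to hug the
    diagonal — the confound that makes inter-replicate r a misleading
    precision measure.
    """
    config = SimulationConfig(
        p=p, n_samples=1, n_replicated=1, v_d=v_d,
        v_b_law=v_b, v_e_law=v_e, mu=10.0, seed=seed,
    )
    table, _ = simulate_dataset(config)
    return table


def assay_like_config(
    p: int = 1624,
    n_samples: int = 69,
    n_replicated: int = 69,
    v_d: float = 3.57,
    v_b: float = 0.05,
    v_e: float = 0.07,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Config whose defaults emulate a duplicated microRNA pilot panel
    (1624 analytes, 69 samples all run in duplicate, wide dynamic range)."""
    return SimulationConfig(
        p=p, n_samples=n_samples, n_replicated=n_replicated,
        v_d=v_d, v_b_law=v_b, v_e_law=v_e, seed=seed, **kwargs,
    )
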
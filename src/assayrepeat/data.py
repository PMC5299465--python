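"""Containers and IO for technical-replicate pilot data.

A pilot experiment measures ``p`` analytes on ``I`` biological samples, with
some samples assayed in technical replicate (split aliquots run through the
instrument separately).  Observations are measured log-concentrations
``y_ij^(k)`` indexed by analyte ``k``, sample ``i`` and replicate ``j``.

The long on-disk layout is a TSV/CSV with columns
``analyte_id, sample_id, replicate_id, value``; the wide layout is one row
per analyte with observation columns, plus a two-column map assigning each
observation column a ``(sample_id, replicate_id)`` pair.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, FormatError, ParseError

LONG_COLUMNS = ("analyte_id", "sample_id", "replicate_id", "value")


@dataclass(frozen=True)
class ReplicateTable:
    """Validated set of replicate observations in long form.

    ``frame`` has columns ``analyte_id, sample_id, replicate_id, value`` with
    one row per observation.  Replicate indices are re-labelled 1..n_i within
    each (analyte, sample) cell during validation; replicate identity carries
    no meaning beyond grouping.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReplicateTable":
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        df = frame.loc[:, list(LONG_COLUMNS)].copy()
        df["value"] = _coerce_numeric(df["value"])
        if not np.isfinite(df["value"].to_numpy()).all():
            raise ParseError("non-finite observation values")
        if df.duplicated(["analyte_id", "sample_id", "replicate_id"]).any():
            dupes = df[df.duplicated(["analyte_id", "sample_id", "replicate_id"])]
            raise FormatError(
                f"duplicate (analyte, sample, replicate) keys, e.g. "
                f"{dupes.iloc[0, :3].tolist()}"
            )
        if df["analyte_id"].nunique() < 1 or len(df) == 0:
            raise DesignError("need at least 1 analyte with observations")
        if df["sample_id"].nunique() < 1:
            raise DesignError("need at least 1 sample")
        # re-index replicates to 1..n_i within each cell (stable order)
        df = df.sort_values(["analyte_id", "sample_id", "replicate_id"], kind="stable")
        df["replicate_id"] = df.groupby(["analyte_id", "sample_id"]).cumcount() + 1
        return cls(df.reset_index(drop=True))

    @property
    def analyte_ids(self) -> list:
        return sorted(self.frame["analyte_id"].unique().tolist())

    @property
    def sample_ids(self) -> list:
        return sorted(self.frame["sample_id"].unique().tolist())

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def observations(self) -> dict:
        """Mapping (analyte, sample, replicate) -> value."""
        return {
            (r.analyte_id, r.sample_id, r.replicate_id): r.value
            for r in self.frame.itertuples(index=False)
        }

    def cells(self, analyte_id) -> dict:
        """Per-sample replicate value lists for one analyte."""
        sub = self.frame[self.frame["analyte_id"] == analyte_id]
        return {
            s: g["value"].to_numpy() for s, g in sub.groupby("sample_id", sort=True)
        }

    def replicate_pair(self, sample_id, pair=(1, 2)) -> pd.DataFrame:
        """Two replicate vectors for one sample, on analytes where both exist.

        Returns a frame indexed by analyte_id with columns ``rep1, rep2``.
        """
        sub = self.frame[
            (self.frame["sample_id"] == sample_id)
            & (self.frame["replicate_id"].isin(pair))
        ]
        wide = sub.pivot(index="analyte_id", columns="replicate_id", values="value")
        wide = wide.dropna()
        if wide.shape[1] < 2:
            return pd.DataFrame(columns=["rep1", "rep2"])
        wide.columns = ["rep1", "rep2"]
        return wide

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReplicateTable):
            return NotImplemented
        a = self.frame.sort_values(list(LONG_COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(LONG_COLUMNS)).reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class DesignSummary:
    """Counts describing the replication design of a pilot table."""

    n_samples: int
    n_replicated: int  # samples with >=2 replicates on >=1 analyte
    n_analytes: int
    replicate_counts: dict  # histogram: per-sample n_i -> number of samples
    per_sample_replicates: dict = field(default_factory=dict)  # sample -> n_i
    low_replication_warning: bool = False


def _coerce_numeric(series: pd.Series) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    if out.isna().any() and not series.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ParseError(f"non-numeric value: {bad!r}")
    return out.astype(float)


def read_replicate_table(
    path,
    layout: str = "long",
    column_map: Mapping | None = None,
    log_transform: str = "none",
) -> ReplicateTable:
    """Read a pilot dataset from a delimited text file.

    Parameters
    ----------
    path
        TSV or CSV file (delimiter sniffed from the extension; ``.csv`` means
        comma, anything else tab).
    layout
        ``"long"`` — columns analyte_id, sample_id, replicate_id, value
        (``column_map`` may rename them, ours -> theirs).
        ``"wide"`` — one row per analyte; ``column_map`` is required and maps
        each observation column name to a ``(sample_id, replicate_id)`` pair;
        the first unmapped column is taken as the analyte identifier.
    log_transform
        ``"none"`` (values already on a log scale, the default) or ``"log2"``
        (raw positive concentrations, log2 applied on ingestion).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if layout == "long":
        rename = {}
        if column_map:
            rename = {v: k for k, v in column_map.items()}
        df = raw.rename(columns=rename)
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"long layout: missing columns {missing}")
        df = df.loc[:, list(LONG_COLUMNS)]
    elif layout == "wide":
        if not column_map:
            raise FormatError("wide layout requires a column_map")
        obs_cols = [c for c in raw.columns if c in column_map]
        if not obs_cols:
            raise FormatError("column_map matches no columns in the file")
        id_cols = [c for c in raw.columns if c not in column_map]
        if not id_cols:
            raise FormatError("wide layout: no analyte identifier column")
        long = raw.melt(
            id_vars=id_cols[0], value_vars=obs_cols,
            var_name="_col", value_name="value",
        ).dropna(subset=["value"])
        long["sample_id"] = long["_col"].map(lambda c: column_map[c][0])
        long["replicate_id"] = long["_col"].map(lambda c: column_map[c][1])
        df = long.rename(columns={id_cols[0]: "analyte_id"})[list(LONG_COLUMNS)]
    else:
        raise FormatError(f"unknown layout {layout!r}")

    df = df.dropna(subset=["value"])
    df["value"] = _coerce_numeric(df["value"])
    if log_transform == "log2":
        if (df["value"] <= 0).any():
            bad = df.loc[df["value"] <= 0, "value"].iloc[0]
            raise DomainError(f"log2 transform requires positive values, got {bad}")
        df["value"] = np.log2(df["value"])
    elif log_transform != "none":
        raise FormatError(f"unknown log_transform {log_transform!r}")
    return ReplicateTable.from_frame(df)


def write_replicate_table(table: ReplicateTable, path) -> None:
    """Write a table in the canonical long TSV layout."""
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def validate_design(table: ReplicateTable) -> DesignSummary:
    """Summarize and sanity-check the replication design.

    A sample counts as replicated when it has >=2 replicates on at least one
    analyte.  Estimation of within-sample (noise) variance is impossible with
    zero replicated samples, which is an error; a single replicated sample is
    permitted but flagged (``low_replication_warning``).
    """
    f = table.frame
    per_cell = f.groupby(["sample_id", "analyte_id"], sort=False).size()
    per_sample = per_cell.groupby("sample_id").max()  # n_i = max over analytes
    n_samples = len(per_sample)
    if n_samples < 2:
        raise DesignError("ANOVA estimation requires at least 2 samples")
    n_replicated = int((per_sample >= 2).sum())
    if n_replicated == 0:
        raise DesignError(
            "no sample has >=2 technical replicates: "
            "within-sample variance is inestimable"
        )
    counts = Counter(per_sample.tolist())
    return DesignSummary(
        n_samples=n_samples,
        n_replicated=n_replicated,
        n_analytes=f["analyte_id"].nunique(),
        replicate_counts=dict(sorted(counts.items())),
        per_sample_replicates=per_sample.to_dict(),
        low_replication_warning=n_replicated < 2,
    )


def write_estimates(profile, decomposition, path) -> None:
    """Write per-analyte estimates as TSV plus a JSON companion summary.

    One row per analyte: analyte_id, mean_log2_concentration, v_b, v_e, R and
    CI bounds (empty when no bootstrap was run).  Global quantities (v_d,
    v̄_b, v̄_e) go to ``<path>.summary.json``.  Floats are printed with
    round-trip precision so a read-back reproduces the estimates exactly.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "analyte_id": profile.analyte_ids,
            "mean_log2_concentration": profile.mean_concentration,
            "v_b": decomposition.v_b,
            "v_e": decomposition.v_e,
            "R": profile.R,
            "ci_lower": profile.ci_lower if profile.ci_lower is not None else np.nan,
            "ci_upper": profile.ci_upper if profile.ci_upper is not None else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    summary = {
        "v_d": decomposition.v_d,
        "v_b_bar": decomposition.v_b_bar,
        "v_e_bar": decomposition.v_e_bar,
        "mu_hat": decomposition.mu_hat,
        "n_analytes": len(profile.analyte_ids),
        "excluded_analytes": dict(profile.excluded),
    }
    Path(str(path) + ".summary.json").write_text(json.dumps(summary, indent=2))


def read_estimates(path):
    """Read back a ``write_estimates`` TSV (inverse operation).

    Returns ``(profile, summary_dict)`` where summary may be ``None`` when
    the companion file is absent.
    """
    from .anova import RepeatabilityProfile  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"analyte_id", "mean_log2_concentration", "v_b", "v_e", "R"}
    if not need.issubset(df.columns):
        raise FormatError(f"estimates file missing columns {need - set(df.columns)}")
    has_ci = df["ci_lower"].notna().all() if "ci_lower" in df.columns else False
    profile = RepeatabilityProfile(
        analyte_ids=df["analyte_id"].tolist(),
        R=df["R"].to_numpy(float),
        mean_concentration=df["mean_log2_concentration"].to_numpy(float),
        ci_lower=df["ci_lower"].to_numpy(float) if has_ci else None,
        ci_upper=df["ci_upper"].to_numpy(float) if has_ci else None,
    )
    companion = Path(str(path) + ".summary.json")
    summary = json.loads(companion.read_text()) if companion.exists() else None
    return profile, summary
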
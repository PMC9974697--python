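"""Site-table I/O, validation, and pipeline configuration.

CSV is the sole tabular interchange format: one row per site with a unique
``site_id``, planar coordinates ``x, y`` in meters (required only for
spillover analysis), covariate columns, a binary treatment indicator ``D``
and an outcome ``Q`` (binary by default, real-valued in continuous mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PipelineConfig", "read_site_table", "validate_site_table", "write_site_table"]


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the workflow's standard defaults:
    two matched controls per treated site, a propensity caliper of 0.01, and a
    5% common-support tolerance."""

    covariates: list[str] = field(default_factory=list)
    input_path: str | None = None
    k: int = 2
    caliper: float = 0.01
    support_tolerance: float = 0.05
    buffer_distances: list[float] = field(default_factory=list)
    n_boot: int = 1000
    seed: int = 0
    output_dir: str | None = None
    outcome_mode: str = "binary"
    strict_balance: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.caliper > 0:
            raise ValueError("caliper must be positive")
        if self.outcome_mode not in ("binary", "continuous"):
            raise ValueError("outcome_mode must be 'binary' or 'continuous'")

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "input_path": self.input_path,
            "k": self.k,
            "caliper": self.caliper,
            "support_tolerance": self.support_tolerance,
            "buffer_distances": list(self.buffer_distances),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "outcome_mode": self.outcome_mode,
            "strict_balance": self.strict_balance,
        }


def _check_binary(values: pd.Series, name: str) -> None:
    bad = ~values.isin([0, 1])
    if bad.any():
        rows = values.index[bad].tolist()[:5]
        raise ValueError(
            f"column {name!r} must contain only 0/1; offending row index(es): {rows}"
        )


def validate_site_table(
    sites: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome_mode: str = "binary",
    require_coords: bool = False,
) -> pd.DataFrame:
    """Validate (and return) a site table; raises listing every problem found."""
    problems = []
    for col in ("site_id", "D", "Q"):
        if col not in sites.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise ValueError("invalid site table: " + "; ".join(problems))
    if sites["site_id"].duplicated().any():
        dupes = sites["site_id"][sites["site_id"].duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate site_id values: {dupes}")
    _check_binary(sites["D"], "D")
    if outcome_mode == "binary":
        _check_binary(sites["Q"], "Q")
    elif sites["Q"].isna().any():
        raise ValueError("outcome Q contains missing values")
    if require_coords:
        for col in ("x", "y"):
            if col not in sites.columns:
                problems.append(f"missing coordinate column {col!r}")
            elif sites[col].isna().any():
                problems.append(f"coordinate column {col!r} has missing values")
    for cov in covariates or []:
        if cov not in sites.columns:
            problems.append(f"missing covariate column {cov!r}")
        elif sites[cov].isna().any():
            problems.append(f"covariate {cov!r} has missing values")
    if problems:
        raise ValueError("invalid site table: " + "; ".join(problems))
    return sites


def read_site_table(
    path,
    covariates: list[str] | None = None,
    outcome_mode: str = "binary",
    require_coords: bool = False,
) -> pd.DataFrame:
    """Read and validate a site CSV (header row required)."""
    sites = pd.read_csv(path)
    return validate_site_table(
        sites, covariates=covariates, outcome_mode=outcome_mode, require_coords=require_coords
    )


def write_site_table(sites: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sites.to_csv(path, index=False)


def infer_covariates(sites: pd.DataFrame) -> list[str]:
    """All numeric columns that are not structural (site_id, x, y, D, Q)."""
    reserved = {"site_id", "x", "y", "D", "Q"}
    return [
        c
        for c in sites.columns
        if c not in reserved and np.issubdtype(sites[c].dtype, np.number)
    ]
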
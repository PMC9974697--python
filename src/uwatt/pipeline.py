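"""End-to-end estimation pipeline: trim -> fit -> match -> balance -> weights
-> ATT_Q + ATT_W -> bounds -> comparison (-> optional spillover ladder).

Each stage failure is re-raised with the stage named, and every run produces a
structured log (stage, parameters, counts, seed) so that re-running from the
logged configuration reproduces all outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import (
    ATTResult,
    BoundsResult,
    ComparisonResult,
    att_bounds,
    compare_atts,
    compute_weights,
    estimate_att,
)
from .io import PipelineConfig, read_site_table, validate_site_table
from .matching import MatchSet, balance_diagnostics, match_nearest, trim_common_support
from .selection import SelectionModel, fit_selection, marginal_effects, predict_propensity
from .spillover import SpilloverReport, spillover_analysis

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("uwatt")


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: PipelineConfig
    sites: pd.DataFrame
    trimmed: pd.DataFrame
    trim_report: pd.DataFrame
    model: SelectionModel
    margeff: pd.DataFrame
    matches: MatchSet
    balance: pd.DataFrame
    att_q: ATTResult
    att_w: ATTResult
    bounds: BoundsResult
    comparison: ComparisonResult
    weight_cv: float
    spillover: SpilloverReport | None = None
    log: list[dict] = field(default_factory=list)

    @property
    def balance_failures(self) -> int:
        ok = self.balance["pass_smd"] & self.balance["pass_variance_ratio"]
        return int((~ok).sum())

    def summary_dict(self) -> dict:
        out = {
            "config": self.config.to_dict(),
            "selection": self.model.summary_dict(),
            "att_q": self.att_q.summary_dict(),
            "att_w": self.att_w.summary_dict(),
            "bounds": {
                "tau_max": self.bounds.tau_max,
                "tau_min": self.bounds.tau_min,
                "tau_min_constrained": self.bounds.tau_min_constrained,
                "effects_weights_correlation": self.bounds.correlation,
            },
            "comparison": {
                "difference_q_minus_w": self.comparison.difference,
                "se": self.comparison.se,
                "p_value": self.comparison.p_value,
            },
            "weight_cv": self.weight_cv,
            "balance_failures": self.balance_failures,
            "n1": self.matches.n1,
            "n0": self.matches.n0,
            "dropped_by_caliper": int(self.matches.dropped_treated.size),
            "log": self.log,
        }
        if self.spillover is not None:
            out["spillover"] = {
                "table": self.spillover.table.to_dict(orient="records"),
                "all_cis_overlap_baseline": self.spillover.all_cis_overlap_baseline,
            }
        return out

    def write(self, output_dir) -> None:
        """Write all reports: CSVs per stage plus one JSON summary."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trim_report.to_csv(out / "trim_report.csv", index=False)
        self.margeff.to_csv(out / "marginal_effects.csv", index=False)
        self.matches.to_frame().to_csv(out / "matches.csv", index=False)
        self.balance.to_csv(out / "balance.csv", index=False)
        if self.spillover is not None:
            self.spillover.table.to_csv(out / "spillover.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=float)


def _stage(name: str, log: list[dict], fn, **params):
    logger.info("stage %s: %s", name, params)
    try:
        result = fn()
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(name, exc) from exc
    log.append({"stage": name, "params": {k: v for k, v in params.items()}})
    return result


def run_pipeline(config: PipelineConfig, sites: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full estimation workflow on a site table.

    ``sites`` may be passed directly; otherwise it is read from
    ``config.input_path``.  Returns a :class:`PipelineResult`; if
    ``config.output_dir`` is set, all reports are also written there.
    Raises :class:`PipelineError` naming the failing stage on any error, and —
    only when ``config.strict_balance`` is set — when a covariate fails the
    matched balance criteria.
    """
    log: list[dict] = []
    need_coords = bool(config.buffer_distances)
    if sites is None:
        if config.input_path is None:
            raise ValueError("either sites or config.input_path must be given")
        sites = _stage(
            "read",
            log,
            lambda: read_site_table(
                config.input_path,
                covariates=config.covariates,
                outcome_mode=config.outcome_mode,
                require_coords=need_coords,
            ),
            path=str(config.input_path),
        )
    else:
        sites = _stage(
            "validate",
            log,
            lambda: validate_site_table(
                sites,
                covariates=config.covariates,
                outcome_mode=config.outcome_mode,
                require_coords=need_coords,
            ),
            n_sites=len(sites),
        )
    cov = list(config.covariates)

    trimmed, trim_report = _stage(
        "trim_common_support",
        log,
        lambda: trim_common_support(sites, cov, config.support_tolerance),
        tolerance=config.support_tolerance,
    )
    log[-1]["n_dropped"] = int(len(sites) - len(trimmed))

    model = _stage("fit_selection", log, lambda: fit_selection(trimmed, cov), covariates=cov)
    margeff = _stage("marginal_effects", log, lambda: marginal_effects(model, trimmed))
    p = predict_propensity(model, trimmed)

    matches = _stage(
        "match_nearest",
        log,
        lambda: match_nearest(
            p,
            trimmed["D"].to_numpy(),
            k=config.k,
            caliper=config.caliper,
            site_id=trimmed["site_id"].to_numpy(),
            outcome=trimmed["Q"].to_numpy(dtype=float),
        ),
        k=config.k,
        caliper=config.caliper,
    )
    log[-1].update({"n1": matches.n1, "n0": matches.n0, "dropped": int(matches.dropped_treated.size)})
    if matches.n1 == 0:
        raise PipelineError("match_nearest", ValueError("no treated site survived the caliper"))

    balance = _stage(
        "balance_diagnostics",
        log,
        lambda: balance_diagnostics(trimmed, matches, cov, propensity=p),
    )
    n_fail = int((~(balance["pass_smd"] & balance["pass_variance_ratio"])).sum())
    log[-1]["balance_failures"] = n_fail
    if config.strict_balance and n_fail > 0:
        raise PipelineError(
            "balance_diagnostics",
            ValueError(f"{n_fail} covariate(s) fail the matched balance criteria"),
        )

    # Utility weights from the retained treated sites' propensities.
    idx = pd.Index(trimmed["site_id"])
    t_pos = idx.get_indexer(matches.treated_ids)
    weights = _stage("utility_weights", log, lambda: compute_weights(p[t_pos]))

    effects = matches.effects
    att_q = _stage(
        "estimate_att_q",
        log,
        lambda: estimate_att(effects, "uniform", n_boot=config.n_boot, seed=config.seed, n0=matches.n0),
        n_boot=config.n_boot,
        seed=config.seed,
    )
    att_w = _stage(
        "estimate_att_w",
        log,
        lambda: estimate_att(effects, weights.W, n_boot=config.n_boot, seed=config.seed, n0=matches.n0),
        n_boot=config.n_boot,
        seed=config.seed,
    )
    bounds = _stage("att_bounds", log, lambda: att_bounds(effects, weights.W))
    comparison = _stage(
        "compare_atts",
        log,
        lambda: compare_atts(effects, weights.W, n_boot=config.n_boot, seed=config.seed),
        n_boot=config.n_boot,
        seed=config.seed,
    )

    spill = None
    if config.buffer_distances:
        spill = _stage(
            "spillover",
            log,
            lambda: spillover_analysis(
                sites,
                config.buffer_distances,
                cov,
                k=config.k,
                caliper=config.caliper,
                support_tolerance=config.support_tolerance,
                n_boot=config.n_boot,
                seed=config.seed,
            ),
            distances=list(config.buffer_distances),
            seed=config.seed,
        )

    result = PipelineResult(
        config=config,
        sites=sites,
        trimmed=trimmed,
        trim_report=trim_report,
        model=model,
        margeff=margeff,
        matches=matches,
        balance=balance,
        att_q=att_q,
        att_w=att_w,
        bounds=bounds,
        comparison=comparison,
        weight_cv=weights.cv,
        spillover=spill,
        log=log,
    )
    if config.output_dir:
        result.write(config.output_dir)
    return result
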
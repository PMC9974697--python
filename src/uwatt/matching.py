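"""Common-support trimming, caliper nearest-neighbor matching, and balance
diagnostics.

Matching is on the propensity score, with replacement: each untreated site can
serve as the nearest neighbor of several treated sites.  A treated site keeps
its ``k`` closest controls within the caliper (inclusive comparison, ties
broken by lower ``site_id`` for platform-independent output) or is dropped and
recorded.  Balance is assessed with the two standard diagnostics: the
standardized mean difference (pass when |SMD| < 0.1) and the
treated/control variance ratio, judged against the central 95% band of an
F(N1-1, N1-1) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchSet",
    "trim_common_support",
    "match_nearest",
    "balance_diagnostics",
    "variance_ratio_bounds",
    "SMD_THRESHOLD",
]

SMD_THRESHOLD = 0.1


@dataclass
class MatchSet:
    """Treated-to-control assignments from caliper nearest-neighbor matching.

    Arrays are aligned over the ``n1`` retained treated sites;
    ``control_ids``/``distances`` have shape ``(n1, k)``.  ``q_counterfactual``
    is the unweighted mean outcome of each treated site's matched controls.
    """

    treated_ids: np.ndarray
    control_ids: np.ndarray
    distances: np.ndarray
    p_treated: np.ndarray
    q_treated: np.ndarray | None
    q_counterfactual: np.ndarray | None
    dropped_treated: np.ndarray
    k: int
    caliper: float

    @property
    def n1(self) -> int:
        return int(self.treated_ids.size)

    @property
    def n0(self) -> int:
        """Distinct untreated sites used as controls."""
        return int(np.unique(self.control_ids).size)

    @property
    def effects(self) -> np.ndarray:
        """Per-treated matched differences Q_i - Q_j."""
        if self.q_treated is None or self.q_counterfactual is None:
            raise ValueError("match set was built without outcomes")
        return self.q_treated - self.q_counterfactual

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per (treated, control, rank)."""
        n1, k = self.control_ids.shape
        return pd.DataFrame(
            {
                "treated_id": np.repeat(self.treated_ids, k),
                "control_id": self.control_ids.ravel(),
                "rank": np.tile(np.arange(1, k + 1), n1),
                "distance": self.distances.ravel(),
            }
        )


def trim_common_support(
    sites: pd.DataFrame, covariates: list[str], tolerance: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop untreated sites outside the (tolerance-expanded) treated range.

    For each covariate with treated range [lo, hi] and span s = hi - lo, an
    untreated site is dropped when its value falls outside
    [lo - tolerance*s, hi + tolerance*s].  Treated sites are never dropped.
    Returns the trimmed table and a per-covariate drop report.
    """
    D = sites["D"].to_numpy()
    if (D == 1).sum() == 0:
        raise ValueError("common-support trimming requires at least one treated site")
    keep = np.ones(len(sites), dtype=bool)
    untreated = D == 0
    rows = []
    for name in covariates:
        v = sites[name].to_numpy(dtype=float)
        lo, hi = v[D == 1].min(), v[D == 1].max()
        span = hi - lo
        bad = untreated & ((v < lo - tolerance * span) | (v > hi + tolerance * span))
        rows.append(
            {
                "covariate": name,
                "treated_lo": lo,
                "treated_hi": hi,
                "n_dropped": int(bad.sum()),
            }
        )
        keep &= ~bad
    report = pd.DataFrame(rows)
    report.attrs["n_dropped_total"] = int((~keep).sum())
    return sites.loc[keep].reset_index(drop=True), report


def match_nearest(
    propensity: np.ndarray,
    D: np.ndarray,
    k: int = 2,
    caliper: float = 0.01,
    site_id: np.ndarray | None = None,
    outcome: np.ndarray | None = None,
) -> MatchSet:
    """k-nearest-neighbor propensity matching with replacement and a caliper.

    Each treated site is matched to the ``k`` untreated sites with the smallest
    |p_i - p_j|, admitting distances up to and including the caliper; treated
    sites with fewer than ``k`` admissible controls are dropped and listed in
    ``dropped_treated``.  Distance ties are broken by lower site id.  The
    boundary comparison carries a 1e-9 relative tolerance so that decimal
    calipers behave inclusively despite binary floating point (0.30 - 0.29
    must count as within a 0.01 caliper).
    """
    p = np.asarray(propensity, dtype=float)
    D = np.asarray(D)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not caliper > 0:
        raise ValueError("caliper must be positive")
    if site_id is None:
        site_id = np.arange(len(p))
    site_id = np.asarray(site_id)
    t_rows = np.flatnonzero(D == 1)
    c_rows = np.flatnonzero(D == 0)
    if c_rows.size < k:
        raise ValueError(f"need at least k={k} untreated sites, have {c_rows.size}")

    order = np.lexsort((site_id[c_rows], p[c_rows]))
    c_rows = c_rows[order]
    cp = p[c_rows]
    cid = site_id[c_rows]

    cal = caliper * (1.0 + 1e-9)  # inclusive boundary, robust to float noise
    kept, dropped, ctl_ids, dists, ctl_rows = [], [], [], [], []
    for i in t_rows:
        pi = p[i]
        lo = np.searchsorted(cp, pi - cal, side="left")
        hi = np.searchsorted(cp, pi + cal, side="right")
        cand = np.arange(lo, hi)
        d = np.abs(cp[cand] - pi)
        cand = cand[d <= cal]
        if cand.size < k:
            dropped.append(i)
            continue
        d = np.abs(cp[cand] - pi)
        sel = cand[np.lexsort((cid[cand], d))[:k]]
        kept.append(i)
        ctl_ids.append(cid[sel])
        dists.append(np.abs(cp[sel] - pi))
        ctl_rows.append(c_rows[sel])

    kept = np.asarray(kept, dtype=int)
    dropped = np.asarray(dropped, dtype=int)
    ctl_ids = np.asarray(ctl_ids, dtype=site_id.dtype).reshape(len(kept), k)
    dists = np.asarray(dists, dtype=float).reshape(len(kept), k)
    q_t = q_cf = None
    if outcome is not None:
        outcome = np.asarray(outcome, dtype=float)
        q_t = outcome[kept]
        q_cf = (
            outcome[np.asarray(ctl_rows, dtype=int).reshape(len(kept), k)].mean(axis=1)
            if len(kept)
            else np.empty(0)
        )
    return MatchSet(
        treated_ids=site_id[kept],
        control_ids=ctl_ids,
        distances=dists,
        p_treated=p[kept],
        q_treated=q_t,
        q_counterfactual=q_cf,
        dropped_treated=site_id[dropped],
        k=k,
        caliper=caliper,
    )


def variance_ratio_bounds(n1: int) -> tuple[float, float]:
    """Central 95% band of the F(n1-1, n1-1) distribution.

    This is the acceptance band for a treated/control variance ratio when n1
    matched pairs contribute to each group's variance.
    """
    if n1 < 2:
        raise ValueError("variance-ratio band requires n1 >= 2")
    lo, hi = stats.f.ppf([0.025, 0.975], n1 - 1, n1 - 1)
    return float(lo), float(hi)


def _smd_and_vr(
    t: np.ndarray, c: np.ndarray, denom_sd: float
) -> tuple[float, float]:
    smd = (t.mean() - c.mean()) / denom_sd if denom_sd > 0 else np.nan
    var_c = c.var(ddof=1)
    vr = t.var(ddof=1) / var_c if var_c > 0 else np.nan
    return float(smd), float(vr)


def balance_diagnostics(
    sites: pd.DataFrame,
    matches: MatchSet,
    covariates: list[str],
    propensity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw and matched SMD / variance-ratio diagnostics per covariate.

    Raw columns compare all treated with all untreated sites; matched columns
    compare retained treated sites with their matched controls counted with
    multiplicity.  The SMD denominator pools the *raw* group variances in both
    cases, so matched and raw SMDs are on the same scale.  When ``propensity``
    is given, a final row reports the same diagnostics for the score itself.
    """
    if matches.n1 == 0:
        raise ValueError("empty match set")
    D = sites["D"].to_numpy()
    idx = pd.Index(sites["site_id"])
    t_pos = idx.get_indexer(matches.treated_ids)
    c_pos = idx.get_indexer(matches.control_ids.ravel())
    if (t_pos < 0).any() or (c_pos < 0).any():
        raise ValueError("match set refers to site ids absent from the table")
    f_lo, f_hi = variance_ratio_bounds(matches.n1)

    work = sites.copy()
    names = list(covariates)
    if propensity is not None:
        work = work.assign(_propensity=np.asarray(propensity, dtype=float))
        names = names + ["_propensity"]

    rows = []
    for name in names:
        v = work[name].to_numpy(dtype=float)
        vt, vc = v[D == 1], v[D == 0]
        denom = np.sqrt((vt.var(ddof=1) + vc.var(ddof=1)) / 2.0)
        applicable = denom > 0
        smd_raw, vr_raw = _smd_and_vr(vt, vc, denom)
        smd_m, vr_m = _smd_and_vr(v[t_pos], v[c_pos], denom)
        pass_smd = bool(applicable and abs(smd_m) < SMD_THRESHOLD)
        pass_vr = bool(applicable and np.isfinite(vr_m) and f_lo <= vr_m <= f_hi)
        rows.append(
            {
                "covariate": "propensity_score" if name == "_propensity" else name,
                "smd_raw": smd_raw,
                "smd_matched": smd_m,
                "variance_ratio_raw": vr_raw,
                "variance_ratio_matched": vr_m,
                "pass_smd": pass_smd,
                "pass_variance_ratio": pass_vr,
                "applicable": applicable,
                "f_lower": f_lo,
                "f_upper": f_hi,
                "n1": matches.n1,
            }
        )
    return pd.DataFrame(rows)
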
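"""Structural Roy-model simulator with known ground-truth treatment effects.

The data-generating process mirrors the two-agent random-utility story that
motivates the utility-weighted ATT:

* A **land user** decides whether to deforest each site.  The net private gain
  from retaining forest is ``mu_L(X) = alpha0 + alpha @ X`` plus a standard
  logistic shock ``U_L``; an (unobserved) compliance cost ``C`` is added when
  the site is protected.  Potential outcomes are

  - ``Q0 = 1(mu_L(X) > U_L)``       (forest retained without protection)
  - ``Q1 = 1(mu_L(X) > U_L - C)``   (forest retained under protection)

* A **regulator** protects the site when the perceived social benefit exceeds
  the converted opportunity cost: ``D = 1(theta0 + theta @ X > U_R)`` with
  ``theta = beta - k_R * alpha`` and ``U_R`` standard logistic, independent of
  ``U_L`` (so selection is on observables only and matching on the propensity
  score is valid).  The regulator's private signal about the social benefit is
  ``U_S = -U_R``.

Because ``C >= 0`` the potential outcomes are monotone (``Q1 >= Q0``) and the
treated sites partition into three groups: S1 (never deforested), S2 (always
deforested) and S3 (saved only by protection).  The simulator records these
labels plus the realized regulator gain per site, from which the true physical
ATT (the S3 share among treated sites), the true welfare sum and the true
utility-weighted ATT are computed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "SimConfig",
    "SimTruth",
    "default_config",
    "simulate_sites",
    "classify_groups",
    "true_treatment_effects",
    "write_simulation",
]


@dataclass(frozen=True)
class Covariate:
    """Specification of one simulated site characteristic.

    ``kind`` is ``"continuous"`` (normal with ``mean``/``sd``) or ``"dummy"``
    (Bernoulli with success probability ``p``).
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "dummy"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "dummy" and not 0.0 < self.p < 1.0:
            raise ValueError("dummy probability must be in (0, 1)")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError("continuous sd must be positive")


#: Default covariate mix: two continuous site characteristics and two 0/1
#: dummies, echoing the distance-variable / indicator mix typical of
#: protected-area selection models.
DEFAULT_COVARIATES: tuple[Covariate, ...] = (
    Covariate("dist_coast", "continuous"),
    Covariate("species_index", "continuous"),
    Covariate("gulf_coast", "dummy", p=0.3),
    Covariate("edge_far", "dummy", p=0.3),
)


@dataclass
class SimConfig:
    """Parameters of the Roy-model data-generating process.

    alpha/beta are slope vectors over ``covariates`` for the land user's net
    gain from retaining forest and the regulator's social benefit; ``alpha0``
    and ``beta0`` are the corresponding intercepts.  ``k_R`` converts private
    gains into social-benefit units and ``C`` is the land user's expected
    compliance cost (``numpy.inf`` is accepted as a flag for a prohibitive
    penalty).  Coordinates are drawn uniformly on ``spatial_extent`` (meters);
    if ``cluster_radius`` is set, treated sites are instead re-placed inside
    discs of that radius around ``n_clusters`` random centers, inducing the
    spatial clustering needed to exercise spillover diagnostics.
    """

    n_sites: int = 10_000
    covariates: tuple[Covariate, ...] = DEFAULT_COVARIATES
    alpha: tuple[float, ...] = (0.8, -0.5, -0.6, 0.4)
    alpha0: float = 0.3
    beta: tuple[float, ...] = (-0.4, 0.7, -0.9, 0.8)
    beta0: float = -0.9
    k_R: float = 0.5
    C: float = 1.5
    spatial_extent: tuple[float, float] = (100_000.0, 100_000.0)
    cluster_radius: float | None = None
    n_clusters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be a positive integer")
        k = len(self.covariates)
        if len(self.alpha) != k or len(self.beta) != k:
            raise ValueError(
                f"alpha (len {len(self.alpha)}) and beta (len {len(self.beta)}) "
                f"must match the {k} covariates"
            )
        if self.C < 0:
            raise ValueError("compliance cost C must be nonnegative")
        if self.k_R < 0:
            raise ValueError("conversion factor k_R must be nonnegative")
        if self.spatial_extent[0] <= 0 or self.spatial_extent[1] <= 0:
            raise ValueError("spatial extent must be positive")

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def theta_true(self) -> np.ndarray:
        """Selection-equation coefficients (intercept first): beta - k_R*alpha."""
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        return np.concatenate([[self.beta0 - self.k_R * self.alpha0], b - self.k_R * a])

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "covariates": [vars(c) for c in self.covariates],
            "alpha": list(self.alpha),
            "alpha0": self.alpha0,
            "beta": list(self.beta),
            "beta0": self.beta0,
            "k_R": self.k_R,
            "C": self.C,
            "spatial_extent": list(self.spatial_extent),
            "cluster_radius": self.cluster_radius,
            "n_clusters": self.n_clusters,
            "seed": self.seed,
        }


@dataclass
class SimTruth:
    """Ground truth attached to a simulated site table.

    ``table`` holds per-site potential outcomes, group labels and the realized
    regulator gain ``theta0 + theta@X - U_R`` (equal, site by site, to the
    welfare change from effective protection).  Scalar fields are the true
    estimands the downstream estimators target.
    """

    table: pd.DataFrame
    theta_true: np.ndarray
    k_R: float
    C: float
    tau_att_q_true: float = field(default=np.nan)
    tau_att_w_true: float = field(default=np.nan)
    tau_delta_y_true: float = field(default=np.nan)
    tau_delta_y_with_penalty: float = field(default=np.nan)

    def scalars(self) -> dict:
        return {
            "tau_att_q_true": self.tau_att_q_true,
            "tau_att_w_true": self.tau_att_w_true,
            "tau_delta_y_true": self.tau_delta_y_true,
            "tau_delta_y_with_penalty": self.tau_delta_y_with_penalty,
        }


def classify_groups(Q0: np.ndarray, Q1: np.ndarray) -> np.ndarray:
    """Label sites S1/S2/S3 from their potential outcomes.

    (Q0, Q1) = (1, 1) -> S1 (never deforested), (0, 0) -> S2 (always
    deforested), (0, 1) -> S3 (saved only by protection).  The pair (1, 0)
    would mean protection *causes* deforestation, which a nonnegative
    compliance cost rules out; it raises ``ValueError``.
    """
    Q0 = np.asarray(Q0)
    Q1 = np.asarray(Q1)
    if not (np.isin(Q0, (0, 1)).all() and np.isin(Q1, (0, 1)).all()):
        raise ValueError("potential outcomes must be binary 0/1")
    bad = (Q0 == 1) & (Q1 == 0)
    if bad.any():
        raise ValueError(
            f"invalid potential-outcome pair (Q0=1, Q1=0) at {int(bad.sum())} site(s): "
            "protection causing deforestation is ruled out"
        )
    labels = np.where(Q1 == 0, "S2", np.where(Q0 == 1, "S1", "S3"))
    return labels.astype(object)


def true_treatment_effects(
    truth: SimTruth, D: np.ndarray
) -> tuple[float, float, float]:
    """True (tau_att_q, tau_att_w, tau_delta_y) from simulated potential outcomes.

    * ``tau_att_q``: share of group S3 among treated sites — the physical ATT.
    * ``tau_delta_y``: sum of the realized regulator gain over treated S3
      sites — the program's welfare effect (upper-bound version that omits the
      unobservable compliance-cost penalty for S2 sites).
    * ``tau_att_w``: the same sum divided by the total realized gain over all
      treated sites — the utility-weighted ATT.
    """
    D = np.asarray(D)
    treated = D == 1
    if not treated.any():
        raise ValueError("no treated sites: ATT estimands are undefined")
    group = truth.table["group"].to_numpy()
    gain = truth.table["regulator_gain"].to_numpy()
    s3_treated = treated & (group == "S3")
    tau_q = float(s3_treated.sum() / treated.sum())
    num = float(gain[s3_treated].sum())
    den = float(gain[treated].sum())
    tau_w = num / den
    return tau_q, tau_w, num


def simulate_sites(config: SimConfig | None = None) -> tuple[pd.DataFrame, SimTruth]:
    """Draw one site table plus its ground truth from the Roy model.

    Returns ``(sites, truth)`` where ``sites`` has columns
    ``site_id, x, y, <covariates...>, D, Q`` and ``truth`` carries per-site
    potential outcomes, S1/S2/S3 labels, the realized regulator gain and the
    true ATT estimands.  Identical configs (including seed) give identical
    output.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    cols = {}
    for cov in config.covariates:
        if cov.kind == "continuous":
            cols[cov.name] = rng.normal(cov.mean, cov.sd, size=n)
        else:
            cols[cov.name] = rng.binomial(1, cov.p, size=n).astype(float)
    X = np.column_stack([cols[name] for name in config.covariate_names])

    alpha = np.asarray(config.alpha, dtype=float)
    mu_L = config.alpha0 + X @ alpha
    theta = config.theta_true
    index_R = theta[0] + X @ theta[1:]

    U_R = rng.logistic(size=n)
    D = (index_R > U_R).astype(np.int64)
    U_L = rng.logistic(size=n)
    Q0 = (mu_L > U_L).astype(np.int64)
    Q1 = (mu_L > U_L - config.C).astype(np.int64)
    Q = D * Q1 + (1 - D) * Q0

    width, height = config.spatial_extent
    x = rng.uniform(0.0, width, size=n)
    y = rng.uniform(0.0, height, size=n)
    if config.cluster_radius is not None:
        # Re-place treated sites near random cluster centers so that treatment
        # has spatial structure (used to exercise buffer-exclusion checks).
        centers = np.column_stack(
            [rng.uniform(0, width, config.n_clusters), rng.uniform(0, height, config.n_clusters)]
        )
        t_idx = np.flatnonzero(D == 1)
        which = rng.integers(0, config.n_clusters, size=t_idx.size)
        ang = rng.uniform(0, 2 * np.pi, size=t_idx.size)
        rad = config.cluster_radius * np.sqrt(rng.uniform(size=t_idx.size))
        x[t_idx] = np.clip(centers[which, 0] + rad * np.cos(ang), 0, width)
        y[t_idx] = np.clip(centers[which, 1] + rad * np.sin(ang), 0, height)

    site_id = np.arange(1, n + 1, dtype=np.int64)
    sites = pd.DataFrame({"site_id": site_id, "x": x, "y": y})
    for name in config.covariate_names:
        sites[name] = cols[name]
    sites["D"] = D
    sites["Q"] = Q

    group = classify_groups(Q0, Q1)
    gain = index_R - U_R
    truth_table = pd.DataFrame(
        {
            "site_id": site_id,
            "Q0": Q0,
            "Q1": Q1,
            "group": group,
            "regulator_gain": gain,
        }
    )
    truth = SimTruth(table=truth_table, theta_true=theta, k_R=config.k_R, C=config.C)
    tau_q, tau_w, delta_y = true_treatment_effects(truth, D)
    truth.tau_att_q_true = tau_q
    truth.tau_att_w_true = tau_w
    truth.tau_delta_y_true = delta_y
    n_s2_treated = int(((group == "S2") & (D == 1)).sum())
    truth.tau_delta_y_with_penalty = delta_y - config.k_R * config.C * n_s2_treated
    return sites, truth


def default_config(seed: int = 0, n_sites: int = 10_000, **overrides) -> SimConfig:
    """The package's reference simulation scenario with a chosen seed."""
    return SimConfig(n_sites=n_sites, seed=seed, **overrides)


def write_simulation(
    sites: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    sites_path,
    truth_path=None,
    summary_path=None,
) -> None:
    """Write the site table (CSV), the per-site truth sidecar (CSV) and a JSON
    summary of the true scalar estimands plus the generating config."""
    sites.to_csv(sites_path, index=False)
    if truth_path is not None:
        truth.table.to_csv(truth_path, index=False)
    if summary_path is not None:
        summary = {"config": config.to_dict(), "truth": truth.scalars()}
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
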
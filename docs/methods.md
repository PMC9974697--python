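# Methods

## The structural model behind the simulator

The simulator generates the exact data-generating process the estimators
assume, with two agents acting on each forest site *i* with covariates `Xᵢ`.

**Land user.** The net private gain from *retaining* forest is
`μ_L(Xᵢ) = α₀ + α·Xᵢ` plus a standard-logistic shock `U_L` known only to the
land user. Protection adds an expected compliance cost `C ≥ 0` (subjective
probability of being caught times the penalty) to the deforestation option.
Potential outcomes are therefore

    Q₀ᵢ = 1( μ_L(Xᵢ) > U_Lᵢ )          without protection
    Q₁ᵢ = 1( μ_L(Xᵢ) > U_Lᵢ − C )      under protection

and the observed outcome is `Q = D·Q₁ + (1−D)·Q₀`. Because `C ≥ 0`,
`Q₁ ≥ Q₀` site by site, and treated sites partition into S1 (retained either
way), S2 (deforested either way) and S3 (saved only by protection). The pair
`(Q₀, Q₁) = (1, 0)` — protection *causing* deforestation — is impossible
under the model and `classify_groups` rejects it.

**Regulator.** Protection is chosen when perceived social benefit
`β₀ + β·Xᵢ + U_S` exceeds the converted private opportunity cost
`k_R·μ_L(Xᵢ)`. Writing `θ = β − k_R·α` (intercept `θ₀ = β₀ − k_R·α₀`) and
`U_R = −U_S` with `U_R` standard logistic:

    Dᵢ = 1( θ₀ + θ·Xᵢ > U_Rᵢ )

One logistic draw per site generates both `U_R` and `U_S`. `U_R ⟂ U_L`, so
potential outcomes are independent of treatment given X (the conditional
independence assumption) and propensity-score matching is valid by
construction. The standard-logistic law of `U_R` is required, not
conventional: the closed-form weight below is derived under it.

**Ground truth.** The realized regulator gain `θ₀ + θ·Xᵢ − U_Rᵢ` equals,
site by site, the welfare change from effective protection, so the simulator
reports exactly:

- `tau_att_q_true` — the S3 share among treated sites;
- `tau_delta_y_true` — the sum of realized gains over treated S3 sites
  (the estimable welfare effect, which omits the unobservable `−k_R·C`
  penalty for treated S2 sites and is therefore an upper bound; the
  penalized version is reported alongside as `tau_delta_y_with_penalty`);
- `tau_att_w_true` — that sum divided by the total realized gain over all
  treated sites (a number in [0, 1]: achieved share of the achievable gain).

## Default scenario

Chosen once as a realistic mid-size evaluation problem and used by tests and
the acceptance script alike:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 10,000 | sampled forest sites |
| covariates | 2 standard-normal + 2 Bernoulli(0.3) | continuous indices and 0/1 indicators, the mix typical of protected-area selection models |
| `α` (slopes), `α₀` | (0.8, −0.5, −0.6, 0.4), 0.3 | land-user net gain from retention |
| `β` (slopes), `β₀` | (−0.4, 0.7, −0.9, 0.8), −0.9 | regulator's social benefit |
| `k_R` | 0.5 | private-to-social conversion factor |
| `C` | 1.5 | compliance cost, logistic-scale units (`∞` accepted as a flag) |
| `spatial_extent` | 100 km × 100 km | uniform coordinate placement, meters |

These give a ~30% treated share, true physical ATT ≈ 0.29, selection
pseudo-R² ≈ 0.20 and raw covariate imbalance up to |SMD| ≈ 0.77 — strong
enough selection that matching is genuinely needed, weak enough that common
support holds. Workflow defaults follow the standard matched-evaluation
practice the package is built around: `k = 2` matched controls, caliper 0.01
on the propensity score, 5% common-support tolerance, |SMD| < 0.1 and the
central 95% F(N₁−1, N₁−1) band as balance criteria.

The spillover exercises use a sparse-treatment variant (`β₀ = −2.6`, ~10%
treated). At the default 30% treated share the point density is such that a
2 km exclusion buffer would remove ~98% of the untreated pool; the buffer
diagnostic presumes a control pool that stays ample after exclusion, which is
also the regime of its motivating applications.

## Estimation pipeline

1. **Common-support trim** — untreated sites with any covariate more than 5%
   of the treated span outside the treated range are dropped; treated sites
   never are.
2. **Selection fit** — maximum-likelihood logistic regression of D on the
   covariates plus intercept (Newton, score driven below 1e−6 in absolute
   terms or the fit is refused). Perfect and quasi-separation raise an error
   naming the covariate(s) when a single one is responsible: downstream
   weights diverge as p → 1, so a separated fit is never usable. Marginal
   effects are evaluated at covariate means, with 0/1 covariates handled as
   discrete changes; SEs are delta-method. McFadden's pseudo-R² is reported.
3. **Matching** — k-nearest-neighbor on the propensity score, with
   replacement, inclusive caliper (with 1e−9 relative tolerance so decimal
   calipers behave inclusively in binary floating point), distance ties
   broken by lower site id for platform-independent reproducibility.
4. **Balance** — SMD and variance ratio, raw (all treated vs all untreated)
   and matched (retained treated vs controls counted with multiplicity). The
   SMD denominator pools the *raw* group variances in both versions so the
   two columns share a scale. Note the F band tightens like 1/√N₁: at
   N₁ ≈ 3,000 it is ±7%, far stricter than at the few hundred matched pairs
   typical of field applications, so borderline variance-ratio failures at
   large N₁ should be read with that in mind.
5. **Estimation** — `τ̂_Q` (uniform weights) and `τ̂_W` (weights
   `W = p·ln(1/(1−p))`, computed as `−p·log1p(−p)`, the numerically stable
   equivalent of `p·softplus(logit p)`), with rearrangement bounds, the
   effects–weights correlation, the weight coefficient of variation, and a
   paired bootstrap test of `τ̂_Q − τ̂_W`.

Continuous outcomes use the identical estimator formulas; only the 0/1
validation of Q is relaxed.

## Inference choices and a known limitation

Two standard errors are computed. The plug-in form
`SE² = Σωᵢ²(dᵢ − τ̂)² · n/(n−1)` reduces to the classical SE of a mean under
uniform weights. The default is a bootstrap that resamples treated sites with
their matched counterfactuals and weights, because control reuse correlates
matched differences across treated sites.

Both are *conditional* standard errors: they hold the fitted selection model
and the matched counterfactual values fixed, so they exclude control-outcome
noise and weight-estimation noise, and the unconditional sampling variability
of `τ̂_W` across full re-draws of the data can substantially exceed them.
Reported CIs for `τ̂_W` should therefore be read as conditional-on-design; an
unconditional interval would require re-fitting and re-matching inside each
bootstrap replicate. The test suite checks the
bootstrap against the quantity it targets (i.i.d. resampling of
effect–weight pairs from a fixed population).

The p-value conventions are two-sided normal approximations on bootstrap SEs
throughout, stated so users can substitute other inference choices.

## Bounds

"Perfectly positively (negatively) correlated" is operationalized as the
comonotone (anti-comonotone) pairing of the observed weight and effect
multisets, which attains the exact extremum of the weighted mean over all
pairings (rearrangement inequality; verified exhaustively in tests up to
n = 6). The constrained minimum zeroes negative effects before pairing —
ruling out treatment causing the adverse outcome — and is reported as the
exact value, which is typically small but need not be exactly zero.

A companion Monte-Carlo diagnostic, `conditional_gain_oracle`, reports the
simulated conditional gain `E[θX − U | θX − U > 0]` next to the closed-form
weight for the same index. A direct truncated-logistic-mean calculation gives
`ln(1 + e^{θX})/p(θX)`, which differs from the closed form
`p·ln(1 + e^{θX})` by a factor of `p²`; the package treats the closed form as
canonical (it is what the weighted estimand's derivation uses) and surfaces
the oracle for transparency. Both are monotone in `θX`, so the *ordering* of
sites — all the weighted ATT's qualitative conclusions — is identical under
either convention; only the dispersion of the weights differs.

## Spillover diagnostic

Untreated sites within a Euclidean distance (inclusive) of the nearest
treated site are excluded, and the full pipeline — selection re-fit, re-trim,
re-match, re-balance, re-estimate with uniform weights — is repeated per
distance in a ladder including a distance-0 baseline. Overlapping confidence
intervals across the ladder indicate negligible local spillover. Distances
are point-to-point; real protection polygons with buffered boundaries reduce
to this when sites are represented by sample points. The diagnostic flags
spillover; it does not estimate leakage or blockage magnitudes.

## What the simulator does and does not emulate

It reproduces the statistical structure the estimators assume: logistic
selection on observables, independent land-user noise, compliance-cost
monotonicity, spatial coordinates (optionally clustered treatment via
`cluster_radius`). It does **not** emulate spatially correlated outcomes or
covariates, polygon geometry, time series of forest loss, measurement error
in satellite-derived outcomes, or violations of conditional independence.
Passing tests therefore demonstrate correctness of the estimators *under the
model's assumptions*; they cannot certify performance on real data where
selection on unobservables or spatial interference may be present.

## Numerical and degenerate-input conventions

- Propensities are clipped to the open unit interval at machine precision;
  weights require p strictly inside (0, 1).
- Matching with caliper `∞` and k = 1 reproduces classical nearest-neighbor
  matching (no treated site dropped).
- A covariate with zero variance in both groups yields not-applicable balance
  diagnostics, flagged rather than silently passed.
- Constant effects make the effects–weights correlation undefined (NaN), and
  degenerate zero-SE comparisons report p = 1 when the difference is exactly
  zero.
- All randomness (simulation, bootstrap, oracle) flows through explicit
  integer seeds; equal seeds give byte-identical outputs.

## Test-scale choices

The suite runs the recovery experiment at n = 50,000 sites × 20 seeds and
the spillover null at n = 2,500 × 20 seeds; property tests use reduced sizes
(hypothesis-driven instances up to n = 6 for exhaustive pairing enumeration,
2,000-site tables for balance properties). These sizes were chosen to give
the Monte-Carlo assertions comfortable margins at interactive runtimes.
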
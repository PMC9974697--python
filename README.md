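# uwatt — utility-weighted treatment effects from physical outcomes

Impact evaluations of conservation programs usually measure outcomes in
physical terms: a protected forest site either kept its forest (`Q = 1`) or
lost it (`Q = 0`). The standard estimand, the average treatment effect on the
treated (ATT), counts how many protected sites were *effectively* protected —
but it says nothing about whether those were the sites worth protecting.
`uwatt` implements a weighted ATT that recovers this economic dimension from
the same data, for analysts evaluating programs where a regulator chose which
units to treat.

## The method

Treatment assignment is modeled as a rational regulator's discrete choice
(a Roy / random-utility model): site *i* is protected when the perceived net
gain `θXᵢ` exceeds a standard-logistic shock, so the propensity score is
`p(Xᵢ) = e^{θXᵢ}/(1 + e^{θXᵢ})`. Under this selection model the regulator's
expected utility gain from protecting a site, conditional on having chosen to
protect it, has the closed form

    Wᵢ = p(Xᵢ) · ln( 1 / (1 − p(Xᵢ)) )

With matched differences `dᵢ = Qᵢ − Q_j` (treated outcome minus its matched
counterfactual), the two estimators are

    τ̂_ATT^Q = (1/N₁) Σ dᵢ                   (physical ATT)
    τ̂_ATT^W = Σ (Wᵢ / Σ W_j) · dᵢ           (utility-weighted ATT)

They differ only in the weights, so `τ̂_W > τ̂_Q` exactly when effects and
weights are positively correlated — i.e. when the program worked best where
the regulator valued protection most. Sorting the weight and effect multisets
against each other (rearrangement pairing) gives the exact range `τ̂_W` could
have taken, a built-in diagnostic of how informative the weighting is.

The toolkit covers the full workflow:

- **`uwatt.simulate`** — a structural Roy-model simulator (land-user and
  regulator utilities, compliance cost, logistic shocks) that generates site
  tables with *known* true effects, so every stage is testable without
  external data;
- **`uwatt.selection`** — logistic selection fit, propensities, at-means
  marginal effects with delta-method SEs;
- **`uwatt.matching`** — common-support trimming, k-nearest-neighbor caliper
  matching with replacement, SMD and variance-ratio balance diagnostics with
  the F-distribution band;
- **`uwatt.estimators`** — utility weights, both ATT estimators, plug-in and
  bootstrap SEs, rearrangement bounds, and a paired test of `τ̂_Q − τ̂_W`;
- **`uwatt.spillover`** — buffer-exclusion robustness ladder for local
  spillovers (leakage/blockage);
- **`uwatt.pipeline` / CLI `uwatt`** — the end-to-end run.

## Worked example

```python
from uwatt import PipelineConfig, default_config, run_pipeline, simulate_sites

config = default_config(seed=1)            # 10,000 sites, 4 covariates
sites, truth = simulate_sites(config)
print(truth.tau_att_q_true, truth.tau_att_w_true)   # 0.2864 0.2971

res = run_pipeline(PipelineConfig(covariates=config.covariate_names,
                                  seed=1, n_boot=500), sites=sites)
print(f"ATT_Q = {res.att_q.estimate:.4f} (SE {res.att_q.se:.4f})")
print(f"ATT_W = {res.att_w.estimate:.4f} (SE {res.att_w.se:.4f})")
print(f"bounds on ATT_W: [{res.bounds.tau_min:.3f}, {res.bounds.tau_max:.3f}]")
```

prints

```
ATT_Q = 0.2961 (SE 0.0102)
ATT_W = 0.3448 (SE 0.0147)
bounds on ATT_W: [-0.252, 0.762]
```

Reading: of 3,010 protected sites, 2,975 found two controls within the 0.01
caliper; an estimated 29.6% of them were effectively protected, against a true
S3 share (sites saved only by protection) of 28.6%. The utility-weighted
estimate, 34.5%, exceeds the physical one because in this draw the matched
effects correlate positively (r = 0.08) with the weights — protection worked
slightly better where the simulated regulator expected more gain. The bounds
show `τ̂_W` could have landed anywhere in [−0.25, 0.76] had the correlation
been perfect in either direction, which is why the weighted and unweighted
numbers must be interpreted as answers to different questions.

The same workflow from the shell:

```sh
uwatt simulate --n 10000 --seed 1 --out sites.csv
uwatt run --input sites.csv --seed 1 --out-dir report/
```

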
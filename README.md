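# bayescox

Bayesian semiparametric Cox proportional-hazards modelling with
spike-and-slab variable selection for high-dimensional survival data
(p ≫ n), written for biostatisticians who want posterior inclusion
probabilities — not just a point estimate — and a principled way to fold a
secondary genomic data source (e.g. per-gene copy-number variability) into
the selection prior.

## The model

The hazard for a subject with covariates x is λ(t|x) = h₀(t)·exp(x'β).
Time is partitioned at the observed event times and the baseline hazard
enters through per-interval increments h_j with a gamma-process prior
centred on a Weibull fit H*(t) = η₀t^κ₀ to the Nelson–Aalen estimate
(confidence weight c₀ = 2).  The data enter through the grouped likelihood

    L(D | β, h) ∝ ∏_j exp{−h_j Σ_{ι∈R_j∖D_j} e^{x_ι'β}} ∏_{ξ∈D_j} (1 − e^{−h_j e^{x_ξ'β}}).

Each coefficient carries a spike-and-slab mixture indexed by an inclusion
indicator γ_i ~ Bernoulli(π_i):

    β_i | γ_i ~ (1 − γ_i)·N(0, τ²) + γ_i·N(0, c_b²τ²),   τ = 0.0375, c_b = 20,

and a Gibbs sampler (adaptive random-walk Metropolis for β, exact Bernoulli
draws for γ, gamma draws for h) yields posterior inclusion probabilities
P(γ_i = 1 | D).  The π_i are where prior knowledge enters: uniform k/p,
informative values on designated features, or proportional to a secondary
data source's per-feature dispersion.  Optional parallel tempering runs
prior-broadened replicas with state swaps.  Predictions from the selected
top model are scored by the IPCW (Graf) Brier score against a Kaplan–Meier
reference.  `docs/methods.md` has the full write-up.

## Worked example

```python
import bayescox as bc

# a sparse-truth Cox-Weibull study: n=200 subjects, p=500 block-correlated
# features, beta = (0.75, -0.75, 0.5, -0.5, 0.25, -0.25, 0, ..., 0)
scenario = bc.make_scenario("sparse", seed=2)
X, t, d = bc.simulate_dataset(scenario)

model = bc.BayesCoxSSVS(t, d, X, k=20)          # uniform prior pi = 20/500
res = model.fit(n_iter=20_000, burn_in=5_000, seed=2)
print(res.summary().head(6).to_string(index=False))
print("mean model size:", res.mean_model_size)

X_new, t_new, d_new = bc.simulate_dataset(scenario, seed=5002)
pred = res.evaluate(X_new, t_new, d_new, t_max=80.0)
print(f"IBS {pred.ibs:.3f} vs Kaplan-Meier reference {pred.ibs_reference:.3f}")
```

prints

```
feature  beta_mean  beta_sd  inclusion_prob  selected
     x1   0.815786 0.148650        1.000000      True
     x2  -0.947111 0.176329        1.000000      True
     x3   0.738660 0.162954        1.000000      True
     x4  -0.706323 0.137063        1.000000      True
   x296   0.133754 0.177157        0.294200      True
   x176  -0.117543 0.166887        0.260133      True
mean model size: 11
IBS 0.153 vs Kaplan-Meier reference 0.179
```

The four top rows are the four strongest simulated effects — their
posterior inclusion probabilities are ≈1 and the posterior means carry the
right signs — and the selected model beats the covariate-free Kaplan–Meier
reference on an independent test set.

The same pipeline is scriptable from the shell:

```bash
bayescox simulate --scenario sparse --seed 2 --out-prefix data/train
bayescox fit --covariates data/train_covariates.tsv \
             --survival data/train_survival.tsv --out-prefix runs/fit
bayescox evaluate --fit-prefix runs/fit --covariates data/test_covariates.tsv \
                  --survival data/test_survival.tsv --out-prefix runs/eval
bayescox diagnose --fit-prefix runs/fit --out-prefix runs/diag
```

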
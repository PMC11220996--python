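# stcar — Bayesian spatio-temporal CAR models for areal count panels

`stcar` is for analysts modelling counts observed on a set of neighbouring
regions over consecutive years — severe-food-insecurity totals across the
54 countries of a continent, disease counts across districts, and similar
areal panels. It answers three questions at once: which covariates drive
the rate, how strongly outcomes cluster in space and persist in time, and
which space-time structure the data actually support.

## The model

Counts follow a Poisson rate model with a population offset and a
space-time random effect:

    Y_it ~ Poisson(mu_it),      log mu_it = x_it' beta + log n_it + psi_it.

Spatial dependence uses the Leroux conditional-autoregressive (CAR) prior
with precision

    Q(W, rho) = rho (W_d - W) + (1 - rho) I,

where `W` is the binary adjacency matrix (`w_ij = 1` for neighbouring
areas), `W_d` its diagonal degree matrix, and `rho` in [0, 1] the
dependence strength. Four decompositions of `psi_it` are provided —
area-specific linear trends (`linear`), the Knorr-Held ANOVA split into
spatial main effect + temporal main effect + independent interaction
(`anova`), a separable model with one spatial field per year (`separable`),
and a first-order autoregressive space-time field (`ar`). Models are
fitted by Metropolis-within-Gibbs MCMC (default: 120,000 iterations,
20,000 burn-in, thinning 10 → 10,000 retained draws), compared by WAIC,
and validated by 70/30 hold-out predictive-interval coverage. Moran's I,
a correlation-matrix PCA stage for wide indicator tables, and a synthetic
panel generator with known ground truth round out the pipeline. See
`docs/methods.md` for the full specification.

## Worked example

```python
import numpy as np
from stcar import (SimulationConfig, ModelSpec, ChainConfig,
                   simulate_panel, run_chain, rate_ratio_percent)
from stcar.assess import samples_waic

# a 54-country x 20-year panel at the default operating point
panel, truth = simulate_panel(SimulationConfig(seed=1))
spec = ModelSpec(variant="anova", n_covariates=5)
cfg = ChainConfig(n_iter=30_000, burn_in=5_000, thin=5, seed=11)
samples = run_chain(panel, spec, cfg)

print(samples.summary(panel.covariate_names).to_string(index=False))
print("WAIC", round(samples_waic(samples).waic, 1))
b = samples.draws["beta"][:, 1].mean()   # avg_food_supply coefficient
print("rate ratio %.1f%%" % rate_ratio_percent(b, "ratio"))
```

Output (abridged):

```
              parameter    mean     sd    q2.5     q50   q97.5
              intercept -2.3902 0.0601 -2.5088 -2.3901 -2.2731
        avg_food_supply -0.1588 0.0322 -0.2242 -0.1575 -0.0973
     consumption_status  0.1310 0.0312  0.0693  0.1316  0.1914
            environment -0.1214 0.0301 -0.1808 -0.1210 -0.0637
         food_stability  0.1585 0.0319  0.0975  0.1573  0.2227
dietary_supply_adequacy  0.2220 0.0344  0.1532  0.2228  0.2868
           tau2_spatial  0.4423 0.1533  0.2275  0.4133  0.8143
          tau2_temporal  0.0833 0.0370  0.0326  0.0763  0.1768
       tau2_interaction  0.2095 0.0285  0.1557  0.2081  0.2685
            rho_spatial  0.2742 0.1956  0.0123  0.2399  0.7330
           rho_temporal  0.5075 0.2430  0.0532  0.5164  0.9185
WAIC 2520.9
rate ratio 85.3%
```

Reading it: each one-unit rise of the (standardised) average-food-supply
component multiplies the severe-food-insecurity rate by ~0.85 — a rate
ratio of 85.3% — and its 95% credible interval (-0.224, -0.097) excludes
zero. The panel was generated with that coefficient at -0.218, and every
true coefficient lies inside its interval here. The variance split
attributes most structured variation to the spatial main effect
(tau2_spatial ≈ 0.44 vs temporal 0.08, interaction 0.21), and the
positive rho estimates say neighbouring areas move together and years
carry over.

The same pipeline is scriptable from a shell:

```sh
stcar simulate --areas 54 --years 20 --seed 1 --out sim
stcar fit      --panel sim/panel.csv --graph sim/graph.json \
               --model anova --iters 30000 --burn-in 5000 --thin 5 --out fit
stcar compare  --panel sim/panel.csv --graph sim/graph.json --out cmp
stcar validate --panel sim/panel.csv --graph sim/graph.json --out val
stcar map      --fit-dir fit --out map
```

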
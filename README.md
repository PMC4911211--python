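# modincidence

Modular-network modelling of age-specific incidence for complex genetic
disorders (Crohn's disease being the motivating case), for
epidemiologists and modellers who want a mechanistic, four-parameter
alternative to purely descriptive age-incidence fits.

## The model

The disease network consists of N functional modules (e.g. barrier
function, autophagy, bacterial sensing), each in a disease-*permissive*
or *protective* state; disease onset requires all N modules permissive
at once. Each module is a three-state continuous-time Markov chain:
naive at birth, stabilizing into its mature state after an exponential
time with mean τ (years), adopting the permissive state with probability
Φ (the *module disease propensity*, MDP) and the protective state
otherwise; mature protective modules fail to the permissive state at the
slow rate 1/T (T ≫ τ). With exchangeable (mean-field) modules the onset
CDF is

    Pr(onset ≤ x) = { (1 − w)(1 − e^(−x/τ)) + w(1 − e^(−x/T)) }^N,
    w = (1 − Φ)/(1 − τ/T),

and the age-specific incidence I(x) is its derivative — an exponential
rise to a young-adult peak followed by a slow decline, the shape seen in
population registries. The package provides:

- closed forms for the general (heterogeneous) and homogenized models
  (`core.py`), with Monte-Carlo cohort simulation as an oracle
  (`simulate.py`);
- statsmodels-style least-squares fitting of (τ, T, Φ) with the integer
  module count N profiled over a grid (`IncidenceModel` /
  `IncidenceFitResult` in `fit.py`);
- a secular-trend simulator for an environmental risk factor spreading
  through the population around a half-exposure year t₅₀, with a
  transient destabilization of mature modules (`transition.py`);
- the mapping between GWAS odds ratios, risk-allele frequencies and
  carrier MDPs, OR ≈ (1−p)²F / (Φ − (1−(1−p)²)F), its inversion, a
  detection-power correction for OR histograms, and the implied MDP
  density by change of variables (`genetics.py`);
- synthetic registries and locus catalogues so the whole pipeline is
  testable without external data (`simulate.py`), plus CSV/YAML I/O and
  a `modincidence` command-line interface.

## Worked example

Generate a synthetic registry (5-year bins to age 90, 5×10⁶
person-years per bin, Poisson case counts) and fit it:

```python
from modincidence import (HomogenizedParams, RegistryConfig, FitConfig,
                          IncidenceModel, generate_registry)

truth = HomogenizedParams(N=12, tau=8.0, T=1240.0, Phi=0.63)
table = generate_registry(RegistryConfig(params=truth, noise="poisson", seed=42))
res = IncidenceModel(table).fit(FitConfig(N_grid=(12,), n_starts=16, seed=0))
print(res.summary())
```

```
Homogenized modular-network incidence fit
=============================================
bins:    18    loss: unweighted_ls
N    = 12   (profiled over [12])
tau  =     8.0065 y
T    =     1281.1 y
Phi  =     0.6315
SSE  =      2.819   R^2 = 0.99599
converged: True
```

The fit recovers the generating maturation time (8.01 vs 8 y) and
propensity (0.6315 vs 0.63) to a fraction of a percent and the weakly
identified failure time T to ~3% here (its profile is a long ridge —
expect ~25% in general), explaining 99.6% of the bin-to-bin variance;
the fitted curve peaks at age 22.5. The same objects drive the CLI:

```bash
modincidence generate --what registry --config registry.yaml --seed 1 --out reg.csv
modincidence fit --table reg.csv --out fit.json
modincidence transition --scenario scenario.yaml --out curves.csv
```

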
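# nestfate

Known-fate daily nest survival analysis for field studies of ground-nesting
birds, built around the two-region Northern Lapwing (*Vanellus vanellus*)
monitoring design: weekly nest visits (or nest cameras) that censor each
nesting attempt into three day-of-season dates — the day the nest was found
with eggs (*i*), the last day it was known active (*j*), and the day its
fate was confirmed (*k*).

The package provides, as a single tested pipeline:

- **`nestfate.dsr`** — the core model.  Daily survival rate (DSR) on the
  logit scale, `S_t = logit⁻¹(xₜ'β)`, with an interval-censored known-fate
  likelihood per nest:

  ```
  log L = Σ_{t=i}^{j-1} log S_t  +  [failed] · log(1 − Π_{t=j}^{k-1} S_t)
  ```

  `DSRModel(day_table, spec).fit()` returns a `DSRResults` with the MLE
  `β̂`, covariance from the inverse observed information, Wald CIs,
  AICc, prediction and a `summary()` table — statsmodels-style.
- **`nestfate.selection`** — constrained all-subsets model selection:
  enumeration of every hierarchical submodel of a global model, a
  collinearity screen (|r| > 0.65), a factor-balance filter (chi-square +
  minimum group size), an uninformative-parameter screen (every covariate
  CI overlapping 0), and AICc ranking with Akaike weights.
- **`nestfate.period`** — the probability of surviving a full 27-day
  incubation, estimated by a weather bootstrap: resample the season's
  observed days, average the 27-day window survival over all start days,
  and re-centre the replicate distribution on `(mean DSR)²⁷`.
- **`nestfate.fates`** — fate contingency analysis: exact r×c Fisher tests
  (exhaustive enumeration, Monte Carlo beyond ~5×10⁶ tables),
  conditional-MLE odds ratios of the noncentral hypergeometric model, and
  Holm–Bonferroni-adjusted fate-by-fate comparisons.
- **`nestfate.simulate`** — a generator for the whole study: AR(1) regional
  weather with seasonal trends, a logit-linear true DSR, and the discovery
  / weekly-visit observation process that produces the censored *i/j/k*
  records, returning the latent truth for estimator validation.
- **`nestfate.pipeline` / `nestfate` CLI** — configuration, the end-to-end
  run, and a checksummed, seed-reproducible report bundle.

## Worked example

Simulate ~200 nests under the default two-region scenario and run the full
analysis:

```sh
nestfate run --seed 1 --out demo
```

prints (abridged):

```
Known-fate daily nest survival (logit link)
  terms: region + method + wind_mean + wind_mean_lag1 + region:method + wind_mean:wind_mean_lag1
  K = 7   exposure days = 3915
  logLik = -155.036   AICc = 324.101   converged = True
  term                                    coef       SE    lower    upper
  intercept                             -3.612    1.095   -5.757   -1.466*
  region                                 1.728    0.790    0.181    3.276*
  method                                 3.309    0.591    2.151    4.466*
  ...
Cumulative incubation survival (corrected bootstrap):
  region=Alsace, method=camera: 0.338 (SE 0.047, 95% CI 0.250-0.430)
  region=HautsDeFrance, method=camera: 0.743 (SE 0.017, 95% CI 0.708-0.772)
Fate composition by region: Fisher exact p = 9.17e-16
```

Reading this: the AICc-best candidate keeps region, monitoring method,
their interaction, and the current- and previous-day wind speeds with their
interaction; coefficients are on the logit scale, so `region = 1.73` means
the daily odds of nest survival are `e^1.73 ≈ 5.6×` higher in
Hauts-de-France than in Alsace at reference levels.  The bootstrap rows
convert daily survival into the probability of bringing a clutch through
all 27 incubation days, and the Fisher test confirms the regional fate
compositions differ.

The same stages are available programmatically:

```python
from nestfate import (DSRModel, ModelSpec, join_covariates,
                      read_nest_table, read_covariate_table)

nests = read_nest_table("nests.csv")
weather = read_covariate_table("covariates.csv")
day_table = join_covariates(nests, weather)
res = DSRModel(day_table, ModelSpec(("region", "wind_mean_lag1"))).fit()
print(res.summary())
```

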
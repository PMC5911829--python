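# lctax

Latent class analysis with bias-corrected covariate modeling, and taxometric
analysis with bootstrapped comparison data — one reproducible pipeline for the
two questions that arise together in typology research (developmental and
educational psychology, psychopathology, epidemiology):

1. **Given a categorical latent structure, what predicts class membership?**
   `lctax` fits the latent class measurement model by multi-start EM, selects
   the number of classes (BIC, L², entropy pseudo-R², parametric bootstrap
   LRT), and relates membership to covariates via the one-step model and the
   three-step workflow. The naive third step — regressing the assigned class
   on covariates — is systematically *downward-biased* because classification
   error attenuates the association; the package implements the two standard
   corrections, **BCH** (inverse-classification-error reweighting with a
   sandwich variance) and **ML** (treating the assigned class as a single
   fallible indicator with known error rates).
2. **Is the latent structure categorical (a taxon) or dimensional at all?**
   The coherent-cut-kinetics procedures — **MAMBAC**, **MAXCOV**, **MAXEIG**,
   **L-Mode** — are compared against bootstrapped comparison populations that
   reproduce the data's marginals and correlations under idealized categorical
   and dimensional structures, and summarized by the **Comparison Curve Fit
   Index**.

## The models in brief

The measurement model is an unrestricted finite mixture for K categorical
items under local independence:

    p(Y = y) = Σ_c p(X = c) Π_k p(Y_k = y_k | X = c)

with posteriors by Bayes' rule, modal or proportional assignment W, and the
classification-error matrix D[c,s] = p(W = s | X = c). The structural model is
a multinomial logit p(X = c | ψ) on the covariates; the BCH third step
maximizes the weighted pseudo-likelihood with weights w*_ic = Σ_s w_is (D⁻¹)_sc,
and the ML third step maximizes Σ_i Σ_s w_is log Σ_c p(X = c | ψ_i) D[c,s].

The taxometric verdict compares the empirical curve of each procedure with
the mean curve of samples from each comparison population via the
root-mean-square residual, and

    CCFI = RMSR_dim / (RMSR_dim + RMSR_cat)  ∈ [0, 1],

with CCFI > 0.5 favoring a taxon, < 0.5 a dimension, and 0.4–0.6 treated as
ambiguous under the conservative rule.

## Worked example

```python
import numpy as np
from lctax import (LCAGenSpec, binary_item_probs, make_lca_data,
                   compare_methods, TaxonicSpec, make_taxonic,
                   run_taxometric_suite)

# covariate effect on class membership, with moderate class separation
theta = binary_item_probs(0.76, 0.24, 6)
spec = LCAGenSpec(n_cases=2000, n_classes=2, item_probs=theta,
                  n_categories=np.full(6, 2),
                  logit_intercepts=[0.0], logit_slopes=[[0.25]], seed=21)
data, _ = make_lca_data(spec)
print(compare_methods(data, 2, seed=5).round(3))

# taxometric verdict on prototypical taxonic data
tax, _ = make_taxonic(TaxonicSpec(n_cases=600, seed=41))
suite = run_taxometric_suite(tax, ("mambac", "maxeig", "lmode"), seed=42)
for r in suite["results"]:
    print(f"{r.procedure}: CCFI={r.ccfi:.3f} ({r.verdict})")
```

The seven-method table prints one row per estimator (true |effect| 0.25 here):
the naive `proportional` and `modal` rows are attenuated (≈0.13), while the
`one_step`, `*_bch` and `*_ml` rows sit near the truth (≈0.18 at this single
seed; unbiased on average). The suite prints, for this seed,

```
mambac: CCFI=0.822 (taxonic)
maxeig: CCFI=0.705 (taxonic)
lmode:  CCFI=0.810 (taxonic)
```

— the empirical curves fit the categorical comparison data far better than the
dimensional ones. The `examples/` directory holds one short narrative script
per capability; each prints its numbers with a line on what they mean.

## Command line

A thin CLI mirrors the library: `lctax simulate`, `lctax fit`,
`lctax stepwise`, `lctax taxometrics`, and `lctax pipeline` (YAML config, one
master JSON report, CSV curve exports). Every stochastic command requires
`--seed`, and every report embeds the seed and settings that produced it.

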
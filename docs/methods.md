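# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `lctax`, in the order the pipeline uses them.

## Latent class measurement model

The model is a finite mixture for N cases on K categorical items: class
proportions π_c (c = 1..C) and, per class and item, an unrestricted
probability vector over that item's M_k categories. Items are conditionally
independent given the class (local independence). Ordinal items are modeled
as unordered multinomial — no order restriction is imposed on the conditional
probabilities; ordinal-restricted variants are out of scope.

**Estimation.** Maximum likelihood by EM on the table of unique response
patterns. Defaults: 20 random starts (all probability vectors drawn
Dirichlet(1)), convergence at relative log-likelihood change < 1e-8, at most
5000 iterations. All starts are advanced simultaneously as one batched numpy
computation; the same batching refits models on hundreds of bootstrap
replicates at once, which is what makes the 200×99-replicate calibration runs
in the test suite affordable. M-step probabilities are floored at 1e-10 and
renormalized so sparse patterns can never produce log(0). A fit in which no
start converged is returned flagged, not discarded.

**Label order.** Classes are relabeled after fitting: descending class
proportion, ties broken by the first item's first-category probability. With
near-equal classes (e.g. a 50/50 mixture) the size order is effectively
random across replicates, so simulation harnesses align labels to the truth
by comparing item profiles before averaging coefficients.

**Fit statistics.** Log-likelihood; BIC = −2·LL + Npar·ln(N) with N the
number of cases; L² = 2 Σ_y n_y ln(n_y / (N p̂_y)) against the saturated
multinomial over observed patterns; entropy pseudo-R² = 1 − (mean posterior
entropy)/(entropy of the class proportions), natural logs, 0·log 0 := 0, and
1.0 by convention for a one-class model. The classification-error matrix is
D[c,s] = (1/N) Σ_i p(X=c|y_i) w_is / π_c; the overall classification error is
1 − Σ_c π_c D[c,c].

**Class enumeration.** `select_model` fits a range of C under one protocol
(one master seed, per-C substreams). `bootstrap_lrt` implements the
parametric (conditional) bootstrap of C vs C+1: simulate from the fitted null,
refit both models per replicate, p = (1 + #{boot ≥ observed})/(n_kept + 1).
Non-convergent replicates are dropped and counted; a >20% drop rate logs a
warning. The reported p-value is the bootstrap p-value of the L² difference.

## Covariates: one-step and three-step estimation

The structural model is a multinomial logit p(X = c | ψ) with the last class
(smallest, after relabeling) as the reference; coefficients are reported on
the log-odds scale, as are the tables the seven-method comparison produces.

* **One-step**: joint EM over measurement and structural parameters (the
  E-step posterior combines the covariate-dependent prior with the item
  likelihood; the M-step updates item probabilities in closed form and the
  logit by damped Newton). Structural standard errors come from the observed
  information of the marginal likelihood in the logit coefficients with the
  measurement parameters held at their estimates — a profile approximation
  that slightly understates the uncertainty from estimating the measurement
  part.
* **Naive third step**: weighted multinomial logit of the assignment weights
  (modal one-hot or proportional posteriors) on the covariates; model-based
  standard errors. Downward-biased whenever classification is imperfect.
* **BCH**: the assignment weights are multiplied by D⁻¹ (w*_ic = Σ_s w_is
  (D⁻¹)_sc); rows still sum to 1 but entries may be negative. The same
  weighted logit is maximized — because each case's weights sum to one, the
  expected information is the standard multinomial one and stays positive
  definite, so Newton remains stable despite negative weights. Standard
  errors use a sandwich estimator whose meat aggregates scores per case (one
  score per case, not per expanded record). BCH requires D to be invertible;
  a condition number above 1e8 is refused.
* **ML**: the assigned class W is treated as a single fallible indicator of X
  with fixed error probabilities D[c,s]; the marginal likelihood
  Σ_i Σ_s w_is log Σ_c p(X=c|ψ_i) D[c,s] is maximized by EM (each M-step is a
  weighted logit fit), with standard errors from the observed information of
  this marginal likelihood (central finite differences of the analytic
  gradient, step 1e-5). A D row with a zero diagonal (a class never correctly
  assigned) is refused.

The Newton solver caps coefficients at |40| and flags separation; negative
BCH weights are kept, never truncated. Covariates enter jointly in one model;
`compare_methods` reports the seven estimators (one-step; naive/ML/BCH under
proportional and modal assignment) in a fixed-schema table.

## Taxometric procedures

All procedures sort cases on an *input* indicator — ties broken by the sum of
the remaining indicators, then case index, so coarse ordinal data yield
deterministic cuts — and track a statistic of the *output* indicators.

* **MAMBAC** (k(k−1) curves): 50 cuts at evenly spaced ranks between 25 cases
  from each extreme; curve value = mean(output above cut) − mean(output
  below).
* **MAXCOV** (k(k−1)(k−2)/2 curves): 50 overlapping windows at 0.90 overlap
  (window width w solves N = w + 49·0.1·w); value = within-window covariance
  of an output pair; x = window mean of the input.
* **MAXEIG** (k curves): as MAXCOV but the largest eigenvalue of the
  covariance matrix of all k−1 outputs with the diagonal zeroed, so the
  statistic reflects covariation only; for k = 3 this equals |cov| of the two
  outputs, which the tests exploit as a closed form.
* **L-Mode** (1 curve): first factor by principal-axis factoring of the
  correlation matrix (squared multiple correlations as initial communalities,
  ≤25 iterations), Bartlett weighted-least-squares scores standardized to
  mean 0, variance 1; Gaussian KDE with Silverman bandwidth on a 512-point
  grid over [−3, 3].

Cut/window counts follow the dominant conventions in the taxometric
literature; they are exposed as parameters. Curves carry a construction grid
(cut ranks, window indices, or the density grid) shared by any two datasets
analyzed under the same settings, so comparison curves align with empirical
curves without interpolation.

**Modes and base rate.** The L-Mode mode locations M_L < 0 < M_R are the
highest interior local maxima of the density on each side of zero (falling
back to the side argmax when a side has no local peak — otherwise a decaying
tail would masquerade as a mode). With standardized scores a two-point
mixture satisfies P·M_R + (1−P)·M_L ≈ 0, so the base-rate estimate is
P̂ = M_L/(M_L − M_R), clipped to [0.05, 0.95] because extreme mode locations
otherwise leave too few cases to model a comparison group. The *clear
bimodality* flag requires both mode heights within a factor 2 of each other
**and** a genuine dip between them (minimum density between the modes below
0.75 of the lower mode height). The dip condition matters on discretized
data, where KDE ripples would otherwise certify unimodal densities as
bimodal; without clear bimodality the base rate falls back to 0.5 with a
provenance flag.

**Suitability screen.** Sample size ≥ 300, k ≥ 2 indicators, ≥ 4 ordered
categories, between-group validity d ≥ 1.25 and within-group correlations
≤ 0.30, the group-based quantities computed from a provisional split of the
cases at the assumed base rate on the total score. The screen warns and never
blocks: a few violations or borderline values are tolerated.

## Comparison data and the CCFI

Two comparison populations (default size 10·N, capped at 100 000) are
bootstrapped from the data being analyzed:

* **Dimensional**: multivariate-normal deviates are transformed to carry the
  target correlation matrix exactly in-sample, then each variable's values
  are replaced rank-wise by a stratified resample of the empirical marginal
  (the marginal replicated in full, only the remainder drawn at random). The
  realized correlations of the replaced data are measured, the residual
  (target − realized) is fed back into the intermediate target matrix, and
  the best of 10 iterations by RMS discrepancy is kept; non-positive-definite
  intermediates are eigenvalue-clipped. The achieved RMS discrepancy is
  recorded on the population (typically < 0.01, warned above 0.05).
* **Categorical**: cases are split into a putative taxon (the ⌈P·N⌉ highest
  total scores, P from the L-Mode estimate unless supplied) and its
  complement; each group's marginals and within-group correlations are
  reproduced separately and the groups concatenated in base-rate proportion.
  Groups of fewer than 20 source cases are refused.

The five-step procedure: (1) empirical curves per procedure, panel-averaged;
(2) both comparison populations; (3) 10 random samples of size N per
population, curves computed per sample and averaged, with ±1 SD bands
retained for export; (4) RMSR between the empirical mean curve and each
structure's mean curve; (5) CCFI = RMSR_dim/(RMSR_dim + RMSR_cat) per
procedure, the mean of the per-procedure CCFIs, and a pooled CCFI over the
concatenated curve points. Verdicts: taxonic ≥ 0.6, dimensional ≤ 0.4,
ambiguous between (the plain 0.5 split is available behind a flag). The
reported CCFI spread is the standard deviation of replicate-wise CCFIs across
paired comparison samples — a pragmatic stand-in for a standard error,
labeled as such in the report.

Procedures that cannot run (e.g. L-Mode with two indicators) are dropped from
the suite with a logged note rather than failing it.

## Synthetic data

The generators define the study conditions the tests and the acceptance
script run under.

* **Taxonic**: Bernoulli(P) group membership; within each group multivariate
  normal with equicorrelation `within_r` and a mean offset of d standard
  deviations on every indicator; discretized to C_ord equal-frequency
  categories using pooled thresholds. Prototypical defaults: N=600, k=4,
  P=0.50, d=2.0, within_r=0, C_ord=4 — the common prototypical settings in
  the taxometric literature; the generation parameters behind published
  artificial-data tables are typically unstated, so these documented defaults
  stand in, and deviations of reproduced index values from printed ones
  should be read with that in mind.
* **Dimensional**: one-factor model x_j = λf + √(1−λ²)e_j, same
  discretization. `match_dimensional_to_taxonic` picks λ so the *realized*
  mean inter-indicator correlation matches the taxonic dataset's: λ² equals
  the observed mean r divided by the discretization attenuation factor
  ([Σφ(thresholds)]²/var(code) ≈ 0.86 for four equal-frequency categories).
  Matching on λ² alone would undershoot the realized correlation by that
  factor and break the "all else held constant" logic of the comparison.
* **Latent-class**: items drawn from specified class profiles; membership
  either from fixed proportions or from a multinomial logit on
  standard-normal covariates. For the bias-correction studies the binary-item
  profile 0.76/0.24 across six items was chosen because it yields entropy
  R² ≈ 0.70 — the moderate-separation regime where the three-step bias is
  visible but correctable.

Every generator is deterministic given its seed. What the generators do *not*
emulate: skewed or zero-inflated marginals, unequal item validities,
correlated covariates, missing data, and within-group correlation structure
beyond equicorrelation. Passing tests therefore demonstrate correctness of
the algorithms under clean prototypical conditions, not robustness of the
taxometric verdict on messy real data.

## Numerical and reproducibility choices

Probability floors 1e-10 (EM) and 1e-300 (log guards); modal-assignment ties
to the lowest class index; Newton ridge 1e-10·tr(H)/dim with step-halving;
finite-difference Hessians use step 1e-5 on the analytic gradient. The
pipeline derives one substream per stage from the master seed (stage-name
keyed), so adding a stage never perturbs another stage's draws; identical
config and seed reproduce every number bit-for-bit. Problem sizes in the test
suite (e.g. 20 paired suite runs for direction checks, 10 seeds for level
checks, 100 replications of the bias study, 200×99 for bootstrap
calibration) were chosen as the smallest at which the checked statistics are
stable across reruns.

## Known limitations

* Standard errors for the one-step structural part are profile-based (see
  above); full-information standard errors would require the joint observed
  information over measurement and structural parameters.
* The BCH sandwich can be anti-conservative when classes are poorly separated
  and D is near-singular; the condition-number guard refuses the worst cases
  but values near the threshold deserve skepticism.
* MAXCOV/MAXEIG window statistics are noisy on coarse ordinal indicators at
  moderate N; CCFIs computed from them carry visibly more Monte-Carlo spread
  than MAMBAC or L-Mode, and with the default 10 comparison samples that
  noise pulls CCFIs toward 0.5 relative to analyses with many more samples.
* The multinomial treatment of ordinal indicators discards order information;
  a well-fitting ordinal-restricted model would be more parsimonious.
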
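# Methods

## The model

The analysis object is a recursive path model over observed variables grouped
into six blocks — patient characteristics (PC), comorbidities (CM), index
treatment regimen (ITR), complications (CP), healthcare resource utilization
(HCRU) and a single total-cost outcome (THCC). Only these block-level arrows
are permitted, each expanded to all variable-level edges between the connected
blocks:

```
PC → THCC   CM → THCC   ITR → THCC   CP → THCC   HCRU → THCC
PC → ITR    CM → ITR    ITR → CP     CM → CP     ITR → HCRU   CP → HCRU
```

The graph is acyclic and the equation errors are assumed uncorrelated, so the
system is estimated equation-by-equation with ordinary least squares — for
recursive systems this coincides with the maximum-likelihood solution, and no
joint optimization is needed. There are no latent variables: every node is an
observed column of the analysis table.

**Binary endogenous variables.** Regimen dummies and complication flags are
fitted with linear equations (linear-probability paths). This is a modelling
approximation, standard in observed-variable path analysis of mixed data; the
synthetic generator draws binaries from exactly this linear-probability
mechanism, so on synthetic data the approximation is exact in the mean. A
logistic draw is available in the generator (`EndogBinary(logistic=True)`)
for misspecification experiments.

**Standardization.** Standardized coefficients use sample standard deviations
of all variables, binary indicators included (the `std.all` convention),
because the reported effect tables standardize dummy predictors as well:
`beta = B * sd(parent) / sd(child)`.

**Robust standard errors.** Costs are strongly right-skewed, so per-equation
sandwich (heteroskedasticity-consistent) standard errors are used. The exact
flavor is configurable (`HC0`/`HC1`/`HC3` via `fit(cov_type=...)`); the
default is HC1, the degrees-of-freedom-corrected estimator, a reasonable
default at a few thousand observations.

**Effect decomposition.** For each predictor the direct effect is its edge
into THCC; the indirect effect sums the products of standardized coefficients
over every directed path of length ≥ 2 into THCC; the total effect is their
sum, exactly. Indirect effects are computed from powers of the (nilpotent)
standardized coefficient matrix — entry `[thcc, pred]` of `beta^k` sums all
length-k path products — and the test suite cross-checks this against both
the closed-form single-node formulas and an exhaustive DFS enumeration. With
several regimen dummies, the dummies act as simultaneous mediators and the
indirect effect sums over all of them; the reference regimen (other
chemotherapy without rituximab) carries no path. HCRU variables have no
outgoing edges except into cost, hence structurally no indirect effect.

Note one discrepancy in the published closed-form decomposition this package
follows the graph on: the comorbidity indirect effect must include the
CM→ITR→CP→THCC term (`b·d·v`), by symmetry with the patient-characteristics
formula (`a·d·v`); texts sometimes omit it. Exhaustive path enumeration is
the arbiter here.

**Confidence intervals.** Default inference for indirect and total effects is
a nonparametric bootstrap (resampling rows, 2000 replicates by default,
percentile intervals, p-values from sign counts with +1 continuity
correction), because sampling distributions of coefficient products are
skewed. A delta-method alternative propagates the per-equation sandwich
covariances through the path-product polynomial (gradients by central
differences); it treats the standardizing SDs as fixed, which is the usual
first-order approximation, and is used for quick summaries and cross-checks.
Degenerate bootstrap resamples (a constant column or rank-deficient design)
are redrawn and counted on the results object. P-values are two-sided with no
multiplicity correction, matching the 5% convention of the effect tables this
reproduces.

**Model fit.** SRMR is the root mean square over the p(p+1)/2 unique elements
of the residual between observed and model-implied correlation matrices,
standardized by observed SDs, including the standardized variance residuals
on the diagonal. The implied covariance is `(I−B)⁻¹ Ψ (I−B)⁻ᵀ` with a
saturated (freely estimated) exogenous block and diagonal residual variances
computed with the n−1 denominator, so that implied moments reproduce sample
moments exactly wherever the DAG saturates them. Exogenous covariances are
treated as free — whether the original analysis fixed them is not stated, and
the saturated choice is the lavaan default. One consequence worth knowing:
mutually exclusive regimen dummies have negative residual covariances
(−μᵢμⱼ) that a recursive model with uncorrelated errors cannot reproduce, so
even a perfectly specified fit on such data has SRMR around 0.02–0.03 rather
than 0; this is a property of the data structure, not an estimation error,
and it stays well below the 0.08 good-fit bound.

## The synthetic generator

The generator works top-down: structural equations first produce each
patient's analysis variables, then claims are emitted so every pipeline stage
re-derives them exactly. That design guarantees the data-generating process
of the path model is known in closed form, which is what the recovery and
coverage tests rely on.

**Planting standardized coefficients exactly.** Coefficients are specified on
the standardized scale and converted to raw scale analytically. The
conversion needs population means and covariances of all upstream variables,
which are computed recursively:

- exogenous Bernoulli: var = p(1−p); exclusive exogenous groups (age bands,
  CCI bands): cov(Dᵢ,Dⱼ) = −pᵢpⱼ;
- linear-probability binaries, drawn by uniform thresholding of the linear
  predictor: conditional mean is exactly linear, var = μ(1−μ), and
  cov(Y, Z) = cov(lp, Z) for any earlier variable Z;
- exclusive endogenous categories (the regimen): category probabilities are
  linear in the predictors with the reference absorbing the remainder, so
  every dummy again has an exactly linear conditional mean;
- counts: 1 + Poisson with linear mean (hospitalization counts are then
  equidispersed rather than the overdispersed counts of real claims);
- continuous (length of stay): linear mean plus centered-gamma noise
  (right-skewed), rounded to whole days — the rounding perturbs the implied
  moments by ~1e−5 on the standardized scale, far below test tolerances;
- cost: linear mean times a mean-one log-normal error; its sigma is solved so
  the cost variance hits the target SD exactly, making the planted
  standardized coefficients exact at population level and the error
  heteroskedastic, which is precisely why the sandwich SEs exist.

The resolver also validates feasibility on the support hull of the bounded
parents: linear probabilities must stay inside [0,1], category probabilities
inside the simplex, the Poisson mean at least 1, length of stay nonnegative,
and the cost's linear predictor strictly positive (a multiplicative error
cannot rescue a negative mean). Infeasible plantings fail loudly at
configuration time.

**Default study conditions.** Base rates (44.3% female, age and CCI-band
frequencies, complication rates 15%/16%/5.5%, regimen mix), the mean cost
(73,296 USD), the mean LOS (123 days) and the direct standardized effects
into cost mirror the published second-line cohort, including the dominant
LOS effect of 0.750. Mediator-path coefficients (a, b, c, d, k, m) are set
to moderate plausible values — the source reports only the resulting indirect
effects, not the path coefficients themselves. Two spreads are deliberately
smaller than the heavy-tailed real data: cost SD 40,000 USD (printed: 58,410)
and LOS SD 60 days (printed: 100.5), because the positivity validation above
must hold on the whole support; with the real spreads a linear model with
planted effects of this size would generate negative costs. Consequently the
synthetic data are a well-behaved version of the real thing: passing recovery
tests shows the estimator and decomposition are correct under the stated
model, not that real claims are this clean.

**Claims emission.** Each patient gets: a first-line R-CHOP course (21-day
cycles), a transition to the index line by either trigger (new drugs after
7–60 days, or a 91–150-day gap), an index line matching the planted regimen
category, optionally a later line (including MEAM conditioning followed by
auto-SCT when the transplant flag is planted), lookback and comorbidity
diagnosis claims that reproduce the planted modified-CCI band exactly,
complication events after the index (and, for a fraction of patients without
the complication, a pre-treatment history plus a post-index code — exercising
the history-suppression rule), hospital stays partitioning the planted LOS,
monthly outpatient visits and supportive-pharmacy claims satisfying the
claim-frequency rule, and imaging/ER/radiation encounters for descriptive
flags. Diagnosis codes are chosen so planted quantities never interfere: the
complication codes (I20.0, N17.9, K75.9) lie outside the Quan CCI map, the
CCI kit avoids the complication sets, and C18.9 doubles as the prior-cancer
flag and the malignancy weight when both are planted.

**Cost allocation.** The planted adjusted-USD total is split over the
patient's in-window claims by configurable category proportions (renormalized
over the categories the patient actually has), then converted *backwards*
into nominal JPY using each claim's service-year FX and CPI — so the cost
engine's forward conversion recovers the planted total to floating-point
precision. Claims dated before the index carry zero cost: all cost mass lives
inside the follow-up window, making "sum of claim costs" and "total cost
during follow-up" the same planted number. Real data violate this (the
negative pharmacy minimum in published cost tables is one symptom); the cost
engine therefore tolerates negative claim amounts on input even though the
generator never emits them.

**Corruption scenarios.** `corrupt_bundle` flags an exact fraction of
patients and makes each violate exactly one selection rule: truncating
records at day 300 (follow-up rule), deleting all claims in the second
6-month window (claim-frequency rule), deleting the lookback claims, or
adding rituximab plus another immunotherapy on the index date (exclusion
rule). The selection ledger must then attribute exactly the flagged patients
to exactly the named rule.

## Pipeline conventions and edge choices

- Selection rules are anchored at the first DLBCL treatment (study entry);
  the cohort index is the start of the requested line. The CCI lookback is
  the 6 months before the *cohort index*; the selection lookback is the 6
  months before *first treatment*.
- Follow-up ends at min(death/censor date, last record). The
  claims-per-6-month check walks consecutive windows from first treatment;
  a partial final window is satisfied by any claim up to the end of
  follow-up.
- The ±30-day initiation window applies to every line, not only the first —
  otherwise 2L/3L index regimens could not be classified consistently. It
  restarts at each line.
- An SCT claim never starts a line: it merges into the line that started on
  or before it (the treatment-gap rule wins over any hypothetical
  SCT-triggered line).
- A conditioning course (MINE/LEED/MCEC/MEAM) classifies as
  conditioning-before-auto-SCT only when an autologous transplant occurs in
  the line; otherwise it counts as other chemotherapy without rituximab.
  Both conditioning checks run before the named-category cascade.
- Unmapped drug codes are excluded from line assignment (strict mode raises
  instead); they are priced as other-pharmacy costs. Lines whose components
  match no category and contain no classifiable chemotherapy component are
  "not otherwise specified".
- Age is computed in whole years at the index date from birth year. Age-band
  dummies follow the effect-table bands (<66 reference, 66–70, 71–75, 76–80,
  81–85, ≥86). Index year enters the model as a single numeric covariate
  centered at 2008.
- Cost quantiles use linear interpolation and SD the n−1 denominator; a
  single-observation SD is reported as 0 with a warning. Per-category n
  counts patients with any non-zero cost in the category. Whether SCT costs
  are also embedded in inpatient costs is ambiguous in real fee schedules;
  the aggregator asserts no component-sum identity (the synthetic allocation
  is disjoint, where the identity holds exactly).
- Conversion uses the claim's service-year rates (admission year for stays).

## Problem sizes and tolerances

The test suite fits at n = 4,000 (the scale of the published 2L cohort);
parameter-recovery and coverage checks run 200 replicates with 200 bootstrap
resamples each, asserting mean absolute bias < 0.01 per planted standardized
coefficient and mean 95%-CI coverage within [0.92, 0.98]. The acceptance
script simulates 4,208 patients and 500 bootstrap replicates. Exact
identities (effect decomposition, currency round trip, path-enumeration
equivalence) are asserted at 1e−12…1e−9; exact-recovery claims (lines,
covariates, costs vs. planted truth) at equality or 1e−6 USD.

## Known limitations

- Linear-probability paths can in principle predict outside [0,1] on real
  data; the model reports no warning for that (the generator, by contrast,
  validates its own feasibility).
- The recursive-uncorrelated-errors structure cannot represent the negative
  residual covariance among exclusive regimen dummies (see SRMR note above).
- Hospitalization counts are equidispersed in the generator; real claims are
  overdispersed.
- The delta-method CIs ignore the sampling variability of the standardizing
  SDs; prefer the bootstrap for reported intervals.
- The shipped complication ICD-10 sets are configuration defaults, not a
  validated phenotype; studies should substitute their own code lists.
- Costs accrued outside the capturing facilities, survival modelling, and
  per-cycle toxicity attribution are out of scope.
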
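# Methods

## The trajectory mixture

`trajmap` models repeated trait measurements with a finite mixture of
polynomial mean trajectories. Conditional on latent subgroup `j`, visits
are independent Gaussians around `μ_ijt = Σ_d β_jd t^d + γ_j' x_it` with
a residual SD `σ` shared across subgroups (subgroup-specific SDs are
available behind `sigma_shared=False`, but the shared form is the
convention in group-based trajectory modelling and is the default).
Individuals with missing visits contribute likelihood only over observed
visits; nothing is imputed. The likelihood is a plain (uncensored)
Gaussian mixture: trait values such as SBP are treated as fully observed
rather than censored at instrument limits.

Estimation is EM:

* E-step: posterior membership `BPP_ij ∝ π_j Π_t N(y_it; μ_ijt, σ)`.
* M-step: weighted least squares for `(β, γ)` (one solve per subgroup
  when covariate coefficients are subgroup-specific, one joint
  block system when they are shared), closed-form updates for `σ` and
  `π`. A ridge of 1e-10 on the normal equations guards rank-deficient
  designs, and `σ` is floored at `1e-6 · sd(y)` to rule out degenerate
  spikes.
* Convergence when the log-likelihood changes by less than 1e-8, cap of
  500 iterations. Initialization is a quantile split of the individual
  mean values into `k` groups; restarts (default 10 in the functional
  API, fewer in the batch pipeline) randomly reassign 30% of individuals,
  all driven by one seeded generator. The best converged restart wins;
  if none converges the best fit is returned flagged `converged=False`.

The log-likelihood is monotone over EM iterations (asserted in tests),
and the mixture is identified only up to label permutation — downstream
code therefore never relies on label order, and the clinically relevant
subgroup is located by its fitted value, not its index.

Standard errors come from the numerical observed information: the
analytic score (the responsibility-weighted complete-data score) is
differentiated by central differences in the packed free parameters
(`β`, `γ`, mixing logits, `log σ`), and the negative Hessian is inverted.
Wald p-values use the standard normal. The mixing proportions are
parameterized by a multinomial logit so the simplex constraint holds
throughout.

## Model selection

For each candidate `k` (1..6 by default) the fit is run twice. The first
run gives every subgroup the same initial polynomial order; each
subgroup's order is then cut to the highest order whose Wald p-value is
below 5%, or to 0 (intercept only — the intercept is never removed) when
none qualifies. The second run refits with the pruned orders, and
covariates, when requested, enter only at this second stage. The initial
order is min(3, T−1): a degree-3 polynomial is unidentified on fewer
than four distinct time points, and fitting it anyway inflates every
coefficient SE and prunes real slopes away. With the common three-visit
design the first run is therefore quadratic.

`k` is chosen by `BIC = loglik − (p/2)·ln(N)` with `N` the number of
individuals (an observation-count variant is available via
`bic_sample_size="observations"`), maximized; ties break toward smaller
`k`. `p` counts `Σ_j (order_j+1)` polynomial coefficients, `k−1` mixing
parameters, one `σ`, and the covariate coefficients (per-subgroup by
default, shared optionally — the time coding likewise defaults to visit
index 0,1,2 with age-as-time available by supplying different `times`).

## Derived phenotype

The clinically relevant subgroup maximizes (or, for declining-trait
diseases, minimizes) the fitted polynomial at the last time point,
evaluated at covariate reference level zero so that the ranking reflects
the trajectory itself rather than covariate composition. An exact tie is
an error, since no rule can order the tied subgroups. The BPP column of
that subgroup is the quantitative trait; the binary version thresholds at
0.5 with the boundary mapped to "affected" (the boundary case has
probability ~0 in practice; the rule is documented and configurable). A
Box-Cox transform (`scipy` MLE for λ) is available but off by default —
on well-separated mixtures the BPP distribution is strongly bimodal and
thresholded membership is invariant to any monotone transform.

## Association tests

* `wald_qt_test`: simple linear regression of trait on dosage, t-test
  with n−2 df; monomorphic SNPs return `p = NaN` with a reason code.
  FDR across SNPs is Benjamini–Hochberg (via statsmodels).
* `qfam_perm_test` / `qfam_perm_scan`: the same statistic, with an
  empirical p `(1 + #{|t*| ≥ |t|})/(n_perm + 1)` from permutations that
  shuffle trait values only within families, preserving family structure
  (and hence robust to family-level confounding, which the tests verify).
  The `+1` estimator keeps empirical p-values strictly positive.
* `tdt_test` / `tdt_scan`: transmissions from heterozygous parents to
  affected offspring; for a trio with `h` heterozygous parents and `f`
  homozygous-coded parents, the coded-allele transmissions from the
  heterozygous parents equal `g_child − f`, which doubles as the
  Mendelian-consistency check (inconsistent trios are skipped and
  tallied). `χ² = (b−c)²/(b+c)` with a 1-df upper tail. All trios
  extractable from the extended pedigrees are used; residual dependence
  among relatives is absorbed by the permutation null.
* `perm_correct_family`: max-statistic correction. For the TDT each
  informative transmission is a fair coin under the null, so permutations
  redraw `b* ~ Binomial(b+c, ½)` per SNP and track the maximum statistic;
  the regression scan shares its within-family shuffles across SNPs the
  same way.

The locus-heterogeneity extension of the family test is out of scope;
the standard TDT with permutation correction stands in for the
dichotomous-trait family analysis.

## Replicate-set power

`build_replicate_sets` draws sets of three distinct replicate ids
(discovery + two confirmatory) without replacement within a set,
independently across sets — with 100 sets over a 200-replicate pool,
reuse across sets is unavoidable and intended. A gene is YES for a set
only when every one of the three replicates has a qualifying SNP inside
the gene: ranked in the top `ceil(x% · m)` of the `m` SNPs tested in that
replicate's scan (population criterion), or `p ≤ α` (family criterion).
Gene intervals are 1-based inclusive in memory; BED input is 0-based
half-open and converted on read. Condition comparisons (covariates vs.
none) use a paired two-sided t-test over genes by default; vectors whose
differences have zero variance return a reason code, and an unpaired
variant is available.

## Synthetic cohorts

The generator emulates the study shape this method was designed around:
20 three-generation pedigrees of 42 members (~840 relatives), 157
unrelated individuals, 3 visits, 200 phenotype replicates over one fixed
genotype set. Founders draw genotypes at linkage equilibrium from
per-SNP MAFs uniform on (0.1, 0.5); descendants are gene-dropped (each
parent transmits the coded allele with probability dosage/2), which makes
the data Mendelian-error-free by construction. No LD model is included:
the test surface is power and calibration, not fine mapping.

Phenotypes follow the same trajectory-mixture form the analysis assumes,
with an SBP-like truth: three subgroups at intercepts 112/128/150 mmHg
with slopes 2/3/5 per visit, `π = (0.56, 0.35, 0.09)` (a high "fast"
subgroup of ~9%), `σ = 8` mmHg, and covariates — age (0.25 mmHg/yr,
baseline 50 ± 8, 5-year visit spacing), antihypertensive medication
(−8 mmHg, more likely in the high subgroup and at later visits), smoking
(+4), sex (+4). Age, smoking and sex are fixed across replicates;
subgroup, medication and noise are re-drawn per replicate.

Genetic effects come in two modes. `level-shift` (default) adds a
per-allele mean shift at every visit, scaled against the base phenotype
variance so the gene explains a target fraction of total trait variance;
the headline causal gene defaults to 6%, with 14 smaller genes
(0.6–3%) and three null regions of 5/10/20 SNPs completing the default
region map. `group-logit` instead adds to the log-odds of high-subgroup
membership, serving as a misspecification stressor since it moves
membership rather than level. A monomorphic causal SNP makes the
variance target unattainable and raises an error.

Because the generator shares the analysis model's functional form,
passing tests demonstrate internal consistency (correct estimation,
calibration and power accounting under the stated model), not robustness
to real-data features such as censored measurements, LD, assortative
mating, non-Gaussian residuals or informative missingness.

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at desk scale: model-selection recovery uses
50 datasets of 600 individuals (25 in the acceptance script), calibration
uses 2000 null SNPs for the Wald test, 4000–5000 null SNPs over 1000
trios for the TDT (the χ²₁ reference is asymptotic in the number of
informative transmissions, so small trio panels are compared against it
only qualitatively), and 300–400 SNPs at 999 permutations for the
within-family test. The end-to-end power study uses 300 unrelated
individuals, 16 phenotype replicates and 40 replicate sets per
effect-size point — enough draws for the all-three-replicates YES rule to
yield a stable estimate — rather than the full 200/100 design.

## Known limitations

* The censored-normal likelihood used by some trajectory software is not
  implemented; traits are assumed uncensored.
* Wald SEs from the observed information can be unreliable when a fitted
  mixing proportion sits near 0 (the information matrix is then nearly
  singular); such components are usually pruned away by BIC first.
* The top-x% ranking universe is the SNP panel of one replicate's scan;
  genome-wide ranking semantics would need the full panel in one table.
* X-chromosome transmission rules, binary PLINK files and mixed-model
  (kinship) association are not supported.
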
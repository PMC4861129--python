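# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that fix otherwise ambiguous
behaviour.

## Normalization model

Raw targeted-MS peak areas are assumed multiplicative:
`raw = scale(method, sample) × abundance × noise`, where the per-sample,
per-method scale term captures injection and ionization variation. Each
method's spiked internal standards follow the same scale, so the estimator
of `scale(m, s)` is the **median of that method's internal-standard raw
values in sample s**; dividing by it cancels the scale exactly, after which
values are log2-transformed and median-centered per metabolite. The median
(not mean) of standards is robust to a single aberrant standard and reduces
to the geometric midpoint for the two-standard design used here.

Conventions: zero raw values are replaced by half the smallest positive
value of that metabolite before log2 (preserves within-metabolite
ordering; a metabolite that is entirely zero becomes missing); missing
values propagate as missing with no imputation; metabolites with fewer
than 3 non-missing values in either group are excluded from testing (the
t-test needs ≥ 2, and 3 guards the variance estimate). A method without an
internal-standard row, or a sample whose standards are all zero, is an
error naming the method/sample — silent fallbacks would corrupt every
downstream stage.

## Differential testing

Per feature, a two-sided two-sample t-test; the default is the classical
pooled-variance statistic, with Welch's form selectable (`variant=
"welch"`). Degenerate inputs are defined rather than fatal: identical
constant groups give t = 0, p = 1; zero pooled variance with unequal means
gives p = 0 with a runtime warning. Multiple testing uses
Benjamini–Hochberg step-up: q_(i) = min_{j ≥ i} p_(j)·m/j, capped at 1,
returned in input order.

Two significance rules serve the two feature classes:

* metabolites: q ≤ 0.15 (inclusive boundary);
* transcripts: p < 0.05 (strict) **and** |log2 mean difference| ≥ 1
  ("exceeding twofold"; the gate is on the mean of log2 values — the
  alternative reading, log2 of mean intensities, is not implemented
  because the pipeline works in log2 space throughout).

The transcript comparison is unpaired by default even when matched pairs
exist; the fold-change/p rule does not require pairing and the unpaired
form applies uniformly across cohorts.

## Pathway overrepresentation

Mapped genes are the union over differential metabolites of their mapped
symbols (upper-cased; unmapped metabolites contribute nothing and are
logged). Enrichment of a gene set of size K in a query of size n within a
universe of size N with overlap k is the inclusive upper hypergeometric
tail P(X ≥ k), computed with scipy's hypergeometric distribution and
validated against exhaustive enumeration for N ≤ 30. The universe defaults
to the union of all collection members plus the query (user-overridable) —
with no stated universe this is the least arbitrary choice and makes
results invariant to adding sets disjoint from the query. q-values are BH
across the collection; the significance flag uses raw p < 0.05, matching
the exploratory convention of pathway screens; ties in the p-sorted report
break by set name.

## Signature scoring

z_{g,s} = (x_{g,s} − mean_g)/sd_g with the sample (n−1) standard
deviation (population sd by flag); zero-variance genes are excluded with a
warning. The activity score is S_s = Σ_induced z − Σ_repressed z, with
direction taken from the sign of the integrated log2 fold-change.
Signature genes absent from a cohort's matrix are dropped and the score
runs over the available genes — the intended cross-platform behaviour when
one signature is applied to arrays that measure different gene subsets.
With complete data each z row sums to zero, so cohort score sums vanish;
this is asserted to 1e-9·n in the tests.

## Survival analysis

Specimens are stably sorted ascending by (score, specimen id); the low
stratum is the first ⌈f_low·n⌉ and the high stratum the last ⌈f_high·n⌉,
taken as the exact complement when f_low + f_high = 1 so the split is a
partition (377 specimens at 25/75 give 95 and 282 — the ceiling rule is
the only rounding consistent with that split). Ties in score break by
specimen id for determinism.

The log-rank statistic accumulates, at each distinct event time, observed
minus expected events in one group under the conditional hypergeometric
model, with variance d(n−d)n₁n₀/(n²(n−1)); all events at a tied time enter
together. χ² = (O−E)²/V against χ²(1). The Cox model is a univariate
partial likelihood maximized by Newton–Raphson (tolerance 1e-10, 100
iterations, convergence failure is an error) with Breslow tie handling;
both the Wald test at the MLE and the score test at β = 0 are reported —
the latter equals the log-rank χ² for a binary covariate without ties,
which the tests use as a cross-check. The exploratory threshold scan runs
the log-rank over a grid of breakdowns — default {(0.25, 0.75),
(0.33, 0.67), (0.33, 0.33), (0.5, 0.5)} — deliberately without
multiplicity correction; failed grid points (e.g. constant scores) are
flagged, not fatal.

## Refinement

Stage 1 keeps genes whose one-gene signature (with its integrated
direction) is significant at ≥ 1 grid point in **every** cohort with one
common survival direction across all significant grid points
(`require_all_grid_points=True` gives the strictest reading). Using the
same sum z-score machinery for single genes keeps one statistical pathway
through the code; a per-gene Cox filter would be a reasonable alternative
and is deliberately not the default. Stage 2 enumerates subsets
size-descending, then lexicographically, and returns the first subset
significant (p < α, default 0.05, uncorrected — the search is labelled
exploratory) with concordant direction in all cohorts at the target
breakdown; larger subsets are preferred because they retain more of the
validated signature. Enumeration is guarded at 20 candidates (2²⁰−1
subsets) unless `max_size` bounds the strata. An audit helper re-scores
the chosen subset from scratch, so a reported subset is never trusted to
the search loop alone.

## Synthetic-study generator

The generator exists to give every stage inputs with known ground truth.

* **Metabolomics**: log2 abundance = per-(method, sample) scale (uniform
  on [−1, 1] in log2, i.e. raw scale log-uniform on [0.5, 2] — non-trivial
  so normalization is actually exercised) + metabolite baseline (uniform
  [3, 10]) + δ for planted metabolites in tumor samples + N(0, noise_sd²).
  Two internal-standard rows per method share the scale term. Defaults
  mirror the real design: 145 metabolites, 31 planted, 46 tumor vs 14
  benign, 4 methods, δ = 2 log2 units, noise sd 0.5. An optional uniform
  missingness rate masks analyte cells (standards are never masked).
* **Expression/survival**: log2 expression with planted ± gene_effect
  shifts (default 1.5, above the twofold gate) in tumor specimens; the
  latent score is the sum z-score of the planted up/down signature genes
  over tumor specimens, standardized; survival times are exponential with
  hazard = baseline_hazard·exp(β·score) — the simplest proportional-hazards
  generator, sufficient to exercise log-rank and Cox. Censoring times are
  Uniform(0, u) with u solved by bisection so the expected censoring
  fraction matches the requested rate (no censoring model is implied by
  the application; independence and a single tunable rate are the neutral
  choice). Default cohort: 377 specimens, β = 1.5, 30% censoring.
* **Mapping/gene sets**: planted metabolites map round-robin onto the
  planted differential genes (covering all of them), other metabolites map
  to 0..k non-differential genes; the collection chunks the universe into
  fixed-size sets plus one set holding the planted genes, so enrichment
  has a true positive.

All randomness derives from `seed` through independent named streams, so
identical configs are bit-identical and the three generators do not
perturb each other.

What the generator does **not** emulate: chromatographic drift with
injection order, missing-not-at-random dropout, correlated gene modules,
batch effects in expression, non-proportional hazards, and informative
censoring. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to these
real-data pathologies.

## Problem sizes used in validation

The calibration suite uses 1,000 null matrices of 20 features (10+10
samples) for the t-test and 1,500 null cohorts of 60 specimens for the
25/75 log-rank, each checked to within 3 binomial standard errors of the
5% nominal level; recovery uses 20 seeds of the 50-metabolite/10-planted
design (δ = 2, noise 0.5, 10+10) and 50 replicates of three 300-specimen
cohorts (β = 2) for the subset search. These sizes give standard errors
well below the margins being asserted while keeping the full suite around
a minute on one core.

## Known limitations

* The hypergeometric universe is a modelling choice; enrichment p-values
  shift with it, which is why the default is explicit and overridable.
* The combinatorial search's first-hit, size-descending order is one of
  several defensible orders; all passing subsets can be collected
  (`collect_all=True`) when the choice matters.
* The Cox implementation is univariate by design; multivariable
  adjustment for clinical covariates is out of scope.
* Survival time is treated as unitless throughout.
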
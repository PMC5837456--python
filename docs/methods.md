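# Methods

`phenoscan` automates a phenome scan: testing one trait of interest — an
SNP dosage, a weighted allele score, or an ordinary phenotype — against
every field of a biobank-style phenotype table. The hard part is not the
regressions but the heterogeneity of the fields: continuous measurements,
integer counts, single-choice and multiple-choice questionnaire items,
each with their own missingness conventions. This note records the rules
the engine applies, the parameters that matter, what the synthetic cohorts
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Data model

A phenotype column is named `x<field>_<instance>_<array>`: `field` is the
measured variable, `instance` the time point, `array` the repeat within a
time point. The engine uses the **first occurrence only** — the lowest
instance present, normally 0 (no longitudinal aggregation is attempted;
see Limitations). For continuous and integer fields with several array
columns at that instance (repeat measurements taken moments apart, e.g.
spirometry), the per-participant **mean of the non-missing repeats** is
used; a participant with every repeat missing stays missing.

Two metadata files drive the scan. The *variable-information* TSV gives
each field's declared type (continuous / integer / categorical-single /
categorical-multiple), its data-coding id, an a-priori exclusion flag, a
trait-equivalent flag, and — for categorical-multiple fields — which
participants count as FALSE in the expanded binary children. The
*data-coding* TSV describes each reusable coding: whether its categories
are ordered, the value ordering, value reassignments (`old=new`, with `NA`
meaning "recode to missing"), and an optional default substituted for
missing values. The exact column schemas are this package's own dialect
(documented in `phenoscan.metadata_io`); delimiters are `|` inside
orderings and `,` between `old=new` pairs, chosen for TSV safety.

## The variable-processing flow

Every non-excluded field is routed to one of four statistical data types.

**Continuous fields.** After collapsing and recoding, the vector is
normally transformed by the inverse rank-normal transform (IRNT):
value → Φ⁻¹((r − 0.5)/n), with r the 1-based rank among the n non-missing
values. The (r − 0.5)/n offset is symmetric and never produces the 0 or 1
quantile. Tied values receive distinct ranks uniformly at random, seeded
per field (run seed + field id, mod 2³¹), so partitioned and whole scans
agree bit for bit. Rank-normalising a vector dominated by a single value
(e.g. zero alcohol intake for most of a cohort) would only inject noise
through those random tie ranks, so when the modal value's share of
non-missing observations **strictly exceeds 0.2** the vector is instead
cut into **3 ordered categories** of roughly equal mass (binary if only
two distinct values exist). The 0.2 dominance threshold is a configurable
package choice (`ProcessingConfig.dominance_threshold`); the criterion in
the field is stated only qualitatively, and 0.2 keeps plainly continuous
vectors (max share 1/n) far from the boundary while catching genuinely
zero-inflated ones.

Split points fall strictly between distinct observed values and are chosen
to minimise the maximum absolute deviation of any category count from n/k,
ties broken toward the lowest split values. Small numbers of distinct
values are solved by exhaustive enumeration; larger ones by a dynamic
program over suffixes with the same objective and tie-break. With more
than 2 but fewer than k distinct values, each value becomes its own
category.

**Integer fields.** 2 distinct values → binary; 3–20 → ordered categorical
in natural numeric order; more than 20 → the continuous path above
(IRNT or binning). The 20-distinct boundary is exposed as
`ProcessingConfig.integer_distinct_max`.

**Categorical (single).** Values are recoded through the field's data
coding; negative values denote answer categories like "prefer not to
answer" and become missing (this applies to both categorical types, never
to continuous/integer measurements, where negatives are legitimate). Two
remaining distinct values → binary; otherwise ordered (ranks taken from
the coding's declared ordering) or unordered per the coding's ordinal
flag. A categorical-single field without a resolvable coding is a
configuration error, not a silent skip.

**Categorical (multiple).** Each participant holds a set of values across
the array columns. One binary child `field#value` is created per distinct
non-negative observed value; a participant is TRUE for a child iff the
value is in their set. Who counts as FALSE is field-specific: holders of
some other value, responders to the question, or everyone. Regardless of
that option, a participant whose set contains a negative missingness code
and lacks the child's value is set to **missing, never FALSE** — the
unknown answer could have been that value. (A participant who *does* hold
the value is TRUE even if they also hold a missingness code.)

Fields with at most one distinct non-missing value are removed and
counted, not errored. `FlowCounters` tallies every field entering the
flow against emissions and per-reason removals; conservation
(entered = emitted + removed) is asserted in tests on every run.

## Association testing

The derived phenotype is the dependent variable, the trait the independent
variable. All models adjust for the configured confounders — by default
age at recruitment and sex, plus a genotype-chip indicator when the trait
is genetic (a helper derives it from measurement-batch labels; it is never
inferred automatically), or exactly the columns of a user-supplied
confounder file. Analysis is complete-case per variable; no imputation.
Confounders constant on the complete cases (sex, for a sex-specific field)
are dropped with a log notice.

| data type | model | estimate | p-value |
|---|---|---|---|
| continuous | linear regression | beta (per unit trait) | Wald |
| binary | binomial (logistic) | odds ratio | Wald |
| ordered | proportional-odds ordinal logistic | odds ratio | LRT of trait (Wald optional) |
| unordered | multinomial logistic | — | LRT, χ²(K−1) |

The unordered model has no single overall effect, so only the
likelihood-ratio model p-value is reported and those results never enter
forest plots. For the ordered model the reference p-value is the
likelihood-ratio test of adding the trait to the confounder-only fit
(with no confounders the null log-likelihood has the closed form
Σ nₖ log(nₖ/n), since the intercepts-only cumulative-logit model saturates
the marginal category probabilities); a Wald option is provided because
either convention is defensible, and the choice is recorded in the model
spec.

Scan-level filters: variables with **fewer than 500** complete cases are
not tested (500 itself is tested), and unordered variables with **more
than 1000** categories are not tested (1000 itself passes); both removals
are counted. Non-convergence (perfect separation, failed optimiser) keeps
a flagged result with the p-value absent rather than dropping the variable
silently. The scan never aborts on a single variable.

## Ranking and output

Results are ranked by ascending p (ties by field id). The Bonferroni
threshold is α/m where m counts non-validation results that produced a
p-value; trait-equivalent ("validation-only") phenotypes are reported but
excluded from m. Significance is strict: `p < α/m`. QQ points pair the
sorted observed −log10 p against −log10((i − 0.5)/m). Forest-plot data
tables (continuous betas; ordered and binary odds ratios, each with 95%
CIs) are computed separately from rendering so tests assert on numbers,
not images. The hierarchical JSON export arranges results on a category
tree (validated to be a single-rooted acyclic hierarchy; unmapped fields
attach to the root with a warning) and is checked against the schema
shipped at `phenoscan/data/viz_schema.json`.

Partitioned runs (`--num-parts`, `--part-index`) slice the sorted field
ids into contiguous, near-equal parts. Per-part outputs are unranked; the
merge step recomputes ranking and the threshold over the union, because a
per-part m would make the threshold too lenient. Because tie-breaking
randomness is seeded per field, a merged multi-part scan is byte-identical
to a single-part scan.

## Synthetic cohorts

`phenoscan.simulate` generates complete, self-consistent inputs with known
ground truth. The trait emulates a weighted allele score: 96 biallelic
variant dosages (frequencies 0.05–0.5), weighted by effect sizes, plus
Gaussian noise, standardised. Phenotypes are drawn conditionally on the
trait, age and sex through the link matching their family — identity +
Gaussian noise for continuous, cumulative logit for ordinal, logit for
binary, softmax for unordered — so an injected effect size lives on the
scale the regression estimates. Field kinds cover every routing branch:
multi-array continuous (shared true value + small device noise),
zero-inflated continuous (~60% structural zeros), integer fields at the
2/20/21-distinct boundaries, ordinal and unordered single-choice fields
(with a ~1% slice of negative "prefer not to answer" codes), and
multi-choice fields with 5 selectable values, ~5% non-responders and ~2%
negative "not known" codes.

Each field draws from a child generator keyed on (seed, field id), so
cohorts are reproducible bit for bit and adding or reordering fields does
not perturb the others. The default fixture plan covers all nine kinds
plus an a-priori excluded and a trait-equivalent field; the default
cohort size is 5,000 participants, large enough that derived variables
survive the n ≥ 500 filter at realistic missingness. The suite's heavier
checks use 1,500 participants and 500 null fields (type-I error,
uniformity) and 200 replicates at n = 1,000 (sign recovery) — sizes
chosen so the whole suite runs comfortably on one CPU.

What the simulator does **not** emulate: real marginal distributions of
biobank fields, linkage disequilibrium among variants, informative
(non-random) missingness, longitudinal structure, or correlated phenotype
blocks. Passing tests therefore demonstrate the engine's rules and
statistics are implemented correctly, not that any particular real-data
finding would replicate.

## Numerical choices

- Ordered and multinomial fits use BFGS (gtol 1e-8, up to 500/300
  iterations); optimiser non-convergence is surfaced in the result, never
  hidden.
- Linear-model rank deficiency (collinear confounders) flags
  `converged=False` while still reporting the pseudo-inverse fit.
- Results TSVs store floats at full `repr` precision and are read back
  with round-trip float parsing, which is what makes merge outputs
  byte-identical to single runs.
- p-values can underflow to exactly 0 for trait-equivalent sanity checks;
  QQ computation clips at the smallest positive double.
- The binning tie-break (lowest split values) and the strict inequalities
  at the dominance threshold and the Bonferroni threshold are fixed
  conventions, asserted in tests.

## Known limitations

- Only the first time point is analysed; multi-instance aggregation is out
  of scope.
- Huge unordered codings (e.g. thousand-category job codes) are removed by
  the category limit rather than merged via their hierarchy.
- No zero-inflated or other bespoke error models; the scan is a screening
  tool, and flagged associations deserve a dedicated follow-up model.
- No instrumental-variable estimation: when the trait is a genetic score,
  causal interpretation happens outside the engine.
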
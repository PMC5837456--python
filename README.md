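# phenoscan

Automated, rule-based phenome scans for biobank-style phenotype tables.

A phenome scan tests one *trait of interest* — an SNP dosage, a weighted
allele score for Mendelian-randomization screening (MR-pheWAS), or an
ordinary exposure (EnWAS) — against thousands of heterogeneous phenotype
fields at once. Doing that by hand means deciding, field by field, how a
variable should be coded and which regression applies. `phenoscan`
automates the decision with a fixed rule flow and is aimed at
epidemiologists and statistical geneticists running hypothesis-generating
screens over biobank extracts.

## The engine in brief

Each field, named `x<field>_<instance>_<array>` (variable / time point /
repeat), is reduced to its first time point, repeat measurements are
averaged, and the field is routed to one of four data types:

- **continuous** — inverse rank-normal transformed,
  x → Φ⁻¹((r − ½)/n), ties broken at random under the run seed; tested by
  linear regression (estimate: β per unit trait, Wald p);
- **ordered categorical** — either a declared ordinal coding, an integer
  field with 3–20 distinct values, or a dominated continuous field cut
  into 3 equal-mass categories; tested by proportional-odds ordinal
  logistic regression (estimate: OR; p from the likelihood-ratio test of
  the trait);
- **binary** — any route ending with two distinct values, plus the binary
  children of multiple-choice fields; tested by logistic regression
  (estimate: OR, Wald p);
- **unordered categorical** — multinomial logistic regression, model
  p-value from the likelihood-ratio test 2(ℓ₁ − ℓ₀) ~ χ²(K−1); no overall
  estimate exists.

Negative categorical codes ("prefer not to answer", "not known") become
missing. Multiple-choice fields expand to one binary child per observed
value, with configurable FALSE semantics and the guarantee that a
participant holding a missingness code is never counted as FALSE for a
value they might have held. All regressions adjust for age and sex (plus
genotype chip for genetic traits) or for the columns of a user-supplied
confounder file. Variables with fewer than 500 complete cases, and
unordered variables with more than 1000 categories, are filtered and
counted. Results are ranked by p against the Bonferroni threshold α/m,
where m excludes phenotypes flagged a priori as equivalent to the trait.

## Worked example

The package ships a cohort simulator, so the full pipeline runs with no
real data. Generate a synthetic cohort of 2,000 participants with effects
injected on one continuous field (β = 0.25) and one binary field
(log-OR = 0.4):

```python
from phenoscan.simulate import (SimulationConfig, default_field_plan,
                                generate_cohort, inject_associations, write_cohort)

config = SimulationConfig(n_participants=2000, seed=7,
                          field_plan=default_field_plan(n_null_per_kind=1))
config = inject_associations(config, [1000, 1003], [0.25, 0.4])
paths = write_cohort(generate_cohort(config), "example")
```

then scan it from the shell:

```bash
phenoscan run \
  --phenofile example/phenotypes.csv \
  --traitofinterestfile example/trait.csv \
  --confounderfile example/confounders.csv \
  --variablelistfile example/variable_info.tsv \
  --datacodingfile example/data_coding.tsv \
  --categoryfile example/categories.tsv \
  --fieldcategoryfile example/field_categories.tsv \
  --resdir example/results --trait-col score --seed 7
```

which prints

```
13 tests; Bonferroni threshold 0.00385; 3 below threshold
results written to example/results
```

and writes `results.tsv`, a QQ plot, per-data-type forest plots and the
hierarchical `results_viz.json`. The top of `results.tsv`:

```
name  data_type   n     estimate  p_value        below_threshold  validation_only
1010  CONTINUOUS  1971  0.697     4.77e-292      True             True
1000  CONTINUOUS  1960  0.228     9.29e-25       True             False
1003  BINARY      1973  1.420     1.23e-13       True             False
```

Field 1010 is the simulated trait-equivalent phenotype: it tops the
ranking (a sanity check that the scan works) but is flagged
validation-only and excluded from the 13 tests that set the threshold
0.05/13 ≈ 0.00385. The two injected effects are recovered — β̂ = 0.228
for the continuous field (true 0.25 before rank transformation) and
OR = 1.42 ≈ exp(0.4) for the binary field — and the remaining null fields
sit above the threshold.

Large scans parallelise with `--num-parts`/`--part-index`; run
`phenoscan merge --resdir <dir>` afterwards. The merged output is
byte-identical to a single-part run, with the multiple-testing burden
computed over the merged set.

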
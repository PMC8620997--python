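# Methods

## Scope and model

The package implements a cohort pharmacogenetic analysis: do CYP2D6 /
CYP2C19 metabolizer phenotypes shift HbA1c (mmol/mol) in people taking
antidepressant or antipsychotic drugs whose primary clearance route runs
through those enzymes, and does the shift differ by diabetes status?

For each drug cohort the model is ordinary least squares:

```
HbA1c_i = b0 + b_D * diabetes_i
        + sum_k b_k * phenotype_ik            (indicators, NM reference)
        + sum_k g_k * diabetes_i * phenotype_ik
        + covariates (antidiabetic treatment, enzyme-inhibitor exposure,
                      BMI, age, sex[male], ancestry indicators) + e_i
```

Inference is classical OLS with Wald 95 % intervals and two-sided
p-values (a heteroscedasticity-robust HC1 option exists but is off by
default, since the reference tables show symmetric CIs consistent with
classical standard errors). When any phenotype×diabetes interaction has
p < 0.05 (strict), the cohort is re-fitted separately within the diabetic
and non-diabetic strata, dropping the diabetes main effect and
interactions but keeping all other terms.

Multiple testing uses nested per-family thresholds rather than a global
Bonferroni: the two grouped analyses (tricyclics, antipsychotics) use
significant p < 0.05/2 = 0.025 and suggestive p < 0.1/2 = 0.05; the six
single-drug analyses use p < 0.05/6 and p < 0.1/6. Exact fractions are
compared; additionally a p-value equal to the threshold's conventional
two-significant-figure rounding (0.0083, 0.017) is accepted, because
quoted p-values carry the same rounding. Raw p-values are always reported
next to the verdict labels.

## Star-allele model and phenotype translation

A star allele is a named haplotype defined by a fixed variant set with an
assigned function class (none / decreased / normal / increased). Matching
is subset-containment: an allele matches a haplotype when all of its
defining variants carry the alternate allele there. Haplotypes matching no
allele default to \*1 (wild-type) — the behavior of any panel-limited
assay, and the reason panel gaps inflate NM calls (missing defining sites
are therefore counted per call for auditing). When several alleles match,
the one with the most defining variants wins (most specific); residual
ties resolve to the least functional allele (conservative toward detecting
impaired metabolism) and are logged. The bundled CYP2D6 table encodes \*4
as {rs1065852, rs3892097} and \*10 as {rs1065852}, so the nested-allele
tie-break is exercised by real nomenclature, not just toy tables.

CYP2D6 diplotypes are scored by the Gaedigk additive activity scheme
(none 0, decreased 0.5, normal 1; diplotype score = sum) and binned
0 → PM, 0.5–1 → IM, 1.5–2 → NM. The bin map is configurable (a named
`cpic2019` variant is provided; at the 0.5-step granularity of this panel
it coincides with the default). Without copy-number input no ultra-rapid
or whole-gene-deletion CYP2D6 call is possible; increased-function CYP2D6
input is refused rather than silently binned. CYP2C19 phenotypes come from
function-class pairs: none/none → PM, none/normal → IM, normal/normal →
NM, normal/increased → RM, increased/increased → UM; the none/increased
combination defaults to IM (the usual convention) and is configurable.

## Variant and sample QC

Variants pass the common rule at MAF ≥ 1 % and imputation information
≥ 0.3, computed within ancestry stratum when labels are supplied. Star
allele-defining variants failing the common rule are not discarded:
imputed ones are rescued at information ≥ 0.6; directly genotyped ones are
kept iff their intensity-cluster review passed (the review is upstream and
arrives as a boolean). Every exclusion carries exactly one reason, applied
in a fixed order (variant: maf before info; sample: missingness → sex
mismatch → excess relatedness → kinship), so exclusion counts partition
the removals. Kinship pruning removes one member of each pair above 0.083
(≈ third degree) greedily by degree in the over-threshold kinship graph,
ties to the smaller sample id; this retains the maximum number of samples
on chains and stars of relatives and leaves no retained pair above the
threshold (asserted by property test). Pruning runs on the full input
sample set by default, before any cohort restriction.

## Cohort construction

Medication strings are case-folded and mapped through a proprietary→generic
synonym table; unmatched names pass through and are logged. Participants
reporting antidiabetic medication while denying diabetes are excluded
(uncertain diagnosis), as are records without HbA1c when the outcome is
required. The single-drug threshold is ≥ 1800 users by default (comparator
configurable, and a pinned-drug list can reproduce a fixed published
grouping at any synthetic scale). Tricyclics other than amitriptyline form
a grouped cohort — amitriptyline is excluded there because its frequency
would dominate the group — modelled with both genes' phenotype terms since
tertiary-amine tricyclics are substrates of both enzymes. CYP2D6-substrate
antipsychotics form one grouped cohort. Participants taking several study
drugs join every matching cohort. Substrate/inhibitor tables ship as
editable TSVs; the CYP2D6 inhibitor list deliberately excludes the index
SSRIs themselves (otherwise the inhibitor covariate would be collinear
with cohort membership), matching the low inhibitor prevalence reported
in biobank extracts of this design.

## Synthetic cohort generator

The simulator emulates a biobank extract. Star-allele pairs are drawn
independently per gene per participant (Hardy–Weinberg) from European-like
frequencies (CYP2D6: \*1 .635, \*4 .19, \*41 .08, \*9 .03, \*10 .02,
\*17 .02, \*6 .015, \*3 .01; CYP2C19: \*1 .61, \*2 .18, \*17 .205,
\*3 .005), chosen once so that implied phenotype shares resemble a large
European-ancestry cohort (CYP2D6 PM ≈ 4.6 %, CYP2C19 PM ≈ 3.4 %,
RM ≈ 25 %, UM ≈ 4.2 %). Haplotypes are rendered as a phased VCF carrying
exactly each allele's defining variants, plus decoy sites with random low
frequencies to exercise QC. Medications are independent Bernoulli draws
(participants drawing nothing are assigned one drug, keeping everyone a
psychotropic user); 10 % of mentions appear under proprietary synonyms; a
configurable number of rows violate the antidiabetic/diabetes consistency
rule on purpose. Covariates: age uniform 40–70, BMI normal(28.8, 5.66),
68.9 % female, ancestry shares from the demographic profile of the design.
HbA1c is `X beta + eps` with i.i.d. Gaussian noise, clipped to the assay
analytical range 15–184 mmol/mol (clip events are counted, since clipping
slightly biases extreme simulations). Everything derives from one seed and
regenerates byte-identically.

Deliberately not emulated: linkage-disequilibrium-realistic background
variation (only star-defining plus decoy sites are emitted), copy-number
variants, genotyping error, imputation uncertainty in the genotypes
themselves (the information scores are metadata for QC, not noise in the
GT fields), drug dose/duration, and phenoconversion (inhibitor exposure
enters as a covariate, never as a phenotype reassignment). Passing tests
therefore demonstrate the pipeline's correctness on clean phased input,
not robustness to assay artefacts.

## Parameter-recovery experiments

The reference estimates were computed on restricted data, so the
validation target is recovery, not reproduction: each experiment rebuilds
a published design exactly — phenotype-level counts, diabetic counts
(allocated per level where the stratified tables give them), covariate
distributions as above — generates HbA1c using the published coefficient
estimates as generative truth, refits with the package's own models, and
averages each coefficient over replicates. The residual SD is tuned per
replicate from the published adjusted R²:
`sd = std(X beta) * sqrt((1 - R2) / R2)`. OLS is unbiased under correct
specification, so replicate means must land within 3 Monte-Carlo standard
errors of truth; that is the acceptance criterion, not a tolerance fitted
to anything. Replicate counts are 500 for the pooled designs (n = 1930
paroxetine, n = 1887 venlafaxine with interactions) and 1000 for the
diabetic strata (n = 182 venlafaxine, n = 426 fluoxetine) — sizes at which
the Monte-Carlo error is a few hundredths of a mmol/mol and a full run
takes well under a minute on one CPU.

## Numerical and degenerate-input choices

* Phenotype levels with zero members are dropped from the design with a
  warning; interaction cells that coincide exactly with another column
  (e.g. every poor metabolizer diabetic) are structurally inestimable and
  dropped likewise. Any *other* exact collinearity raises an error naming
  the redundant columns (via pivoted QR), as does n ≤ p.
* Constant non-intercept columns (a flag nobody carries, a stratum where
  everyone shares a status) are collinear with the intercept by
  construction and dropped with a warning.
* Missing covariates: complete-case within cohort; dropped counts are
  attached to the result.
* Ancestry enters as indicators against the largest observed group.
* Unphased heterozygous genotypes are an input error naming sample and
  site; homozygous genotypes carry no phase information and are accepted
  either way. Genotypes missing at defining sites are treated as reference
  (cannot support a match) and counted as misclassification risk.
* Genome build is carried on the definition table and checked against the
  VCF header (`##genome_build`), warning on mismatch.

## Known limitations

No CYP2D6 copy-number handling (hence no UM calls and no \*5); no
suballele resolution; no dose–response or longitudinal modelling; the
synthetic generator's medication co-occurrence is independent per drug,
which understates real co-prescription correlation; and the recovery
experiments validate the estimator under the published designs, not the
field validity of the published estimates themselves.
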
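# cypmeta

Pharmacogenetic analysis of glycaemic control in people taking
antidepressants and antipsychotics: **star-allele metabolizer phenotyping of
CYP2D6 and CYP2C19 from phased genotypes, and HbA1c association modelling
with diabetes-status interactions** — plus a synthetic biobank-cohort
simulator so the whole pipeline can be developed and validated without
access to restricted cohort data.

## What it does

CYP2D6 and CYP2C19 metabolize most antidepressants and many antipsychotics.
Loss-of-function *star alleles* (e.g. CYP2D6\*4, CYP2C19\*2) reduce or
abolish enzyme activity; carriers reach higher drug levels and may be more
prone to adverse metabolic effects such as impaired glycaemic control,
measured by glycated hemoglobin (HbA1c, mmol/mol).

The pipeline:

1. **Variant QC** — post-imputation filters (MAF ≥ 1 %, imputation
   information score ≥ 0.3) with a rescue path for rare star-allele-defining
   variants (imputed: info ≥ 0.6; genotyped: manual intensity-cluster
   review flag), plus sample exclusions (missingness > 10 %, sex mismatch,
   excess relatedness, kinship > 0.083 pair pruning).
2. **Phenotyping** — phased haplotypes are matched against star-allele
   definition tables; diplotypes are translated to metabolizer phenotypes.
   CYP2D6 uses the Gaedigk activity score
   (`score = v(allele_1) + v(allele_2)` with v ∈ {0, 0.5, 1}; 0 → PM,
   0.5–1 → IM, 1.5–2 → NM). CYP2C19 uses function-class pairs
   (PM/IM/NM/RM/UM).
3. **Cohorts** — free-text drug names are normalized to generics; every
   antidepressant with ≥ 1800 users gets its own cohort; remaining
   tricyclics form a grouped cohort excluding amitriptyline; all
   CYP2D6-substrate antipsychotics form one cohort.
4. **Association** — per cohort, OLS of HbA1c on phenotype indicators (NM
   reference), diabetes, phenotype×diabetes interactions and covariates
   (antidiabetic treatment, enzyme-inhibitor exposure, BMI, sex, age,
   ancestry). A significant interaction (p < 0.05) triggers
   diabetes-stratified re-fitting. Verdicts use nested thresholds:
   grouped analyses 0.05/2 = 0.025 (suggestive 0.1/2), single-drug
   analyses 0.05/6 (suggestive 0.1/6).

## Worked example: parameter recovery

The published effect estimates for this design come from restricted biobank
data, so the package validates itself by *parameter recovery*: rebuild a
published cohort design exactly (level counts, diabetic counts), generate
HbA1c from the published coefficients as truth, refit, and check the
replicate-mean estimate.

```python
from cypmeta.recovery import PAROXETINE_POOLED, run_recovery

rec = run_recovery(PAROXETINE_POOLED, 100, seed=7,
                   terms=["CYP2D6 PM", "CYP2D6 IM", "diabetes"])
for term in ("CYP2D6 PM", "CYP2D6 IM", "diabetes"):
    print(f"{term:12s} mean={rec.mean(term):6.3f}  MC-SE={rec.mc_se(term):.3f}")
```

```
CYP2D6 PM    mean= 2.453  MC-SE=0.045
CYP2D6 IM    mean= 0.221  MC-SE=0.020
diabetes     mean= 6.878  MC-SE=0.055
```

The generative truth for this design is PM +2.43, IM +0.23 and diabetes
+6.85 mmol/mol; the replicate means land within Monte-Carlo error of each,
confirming the fitting machinery is unbiased under the published design.

## Worked example: full synthetic pipeline

```bash
cat > run.yaml <<EOF
output_dir: out
seed: 1
simulate: {n_participants: 2000, n_antidiabetic_without_diabetes: 5}
cohorts: {single_drug_min: 100}
EOF
cypmeta run-all --config run.yaml
```

This simulates a 2000-person cohort (phased VCF over both gene regions,
participant table with free-text medications), runs QC, phenotyping,
cohort construction and association, and writes per-stage outputs under
`out/`. The phenotype frequency report for that seed:

```
   gene label  count  pct    formatted
CYP2C19    NM    734 36.7  734 (36.7%)
CYP2C19    IM    633 31.6  633 (31.6%)
CYP2C19    PM     69  3.5    69 (3.5%)
CYP2C19    RM    478 23.9  478 (23.9%)
CYP2C19    UM     86  4.3    86 (4.3%)
 CYP2D6    NM   1241 62.0 1241 (62.0%)
 CYP2D6    IM    672 33.6  672 (33.6%)
 CYP2D6    PM     87  4.3    87 (4.3%)
```

Poor metabolizers are rare (≈4 % for both genes), as expected under
European-like star-allele frequencies. Association tables
(`out/association/*_pooled.tsv`) mirror the publication layout: term,
level n, estimate, 95 % CI, p, with observations and R²/adjusted R²
attached.

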
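# pgxcns

A pharmacogenetic (PGx) panel interpretation engine for drugs of the central
nervous system. Psychiatric and neurological prescribing is notoriously
trial-and-error: response, dosing and adverse drug events (ADEs) for
antipsychotics, antidepressants and anti-epileptics depend strongly on
polymorphisms in drug-metabolising cytochromes (CYP2C9, CYP2C19, CYP2D6),
phase-II enzymes (UGT2B7) and signalling genes (DRD2/3, HTR2C, MC4R, FKBP5,
EPHX1, GRIK1, SCN1A). `pgxcns` turns raw genotype calls for a 24-SNP /
13-gene panel into clinical decision support for 28 CNS drugs, and provides
the cohort statistics needed to validate such a panel against reference
populations.

The package is written for clinical bioinformaticians and biostatisticians:
everything is a library function first, with a thin `pgxcns` command-line
tool on top.

## What it computes

**Star-allele diplotypes.** CYP star alleles are defined by the alt alleles
of specific SNPs (e.g. rs4244285 → CYP2C19\*2, rs1799853 → CYP2C9\*2;
CYP2D6\*4 requires rs3892097, with the rs1065852 alt riding along in cis,
while rs1065852 alone defines \*10). From unphased dosages the caller
enumerates every haplotype pair consistent with the observed alt-allele
counts and resolves phase by rule: double heterozygotes resolve in trans
except declared cis pairs (rs3892097 + rs1065852 → \*4/\*1). A brute-force
enumeration oracle is part of the public API and the test contract.

**Metabolizer phenotypes.** Diplotypes map to
poor / intermediate / extensive / ultra-rapid metabolizer classes through an
explicit rule table (CYP2C19 \*17 carriers with a normal allele count as
ultra-rapid; \*1/\*4 for CYP2D6 is extensive, exactly as the reference table
the panel ships with states) with an allele-function fallback for pairs the
table does not list.

**Gene-drug interaction categories.** Each drug is assigned to the
category c ∈ {L, M, H} (low / medium / high interaction) maximising

```
score(c) = Σ_{i ∈ D_c} EL_i + Σ_{j ∈ G_c} PG_j
```

where D_c is the set of triggered association rules of category c, EL their
evidence-level scores (1A=5 … 3=1, PharmGKB-style levels; level-4
annotations are rejected at load), G_c the *set* of distinct genes among
those rules and PG the gene prioritisation score (group A=3, B=2, C=1).
Ties break toward the higher category. Medium/high drugs carry clinical
advice texts drawn from the panel's nine advice templates.

**Cohort statistics.** Genotype-class frequencies (2×3 tables, df = 2) are
compared to reference populations with Pearson's χ² and Cramér's V
(√(χ²/n) for 2×3), with a Freeman–Halton exact test whenever fewer than 80%
of expected counts reach 5 or any expected count is 0, and Holm–Bonferroni
adjustment across the whole comparison family. Nonlinear PCA on binarized
variant carriage is computed as multiple correspondence analysis of the
complete disjunctive indicator matrix, with scree-based component selection
and MAD-based outlier flagging.

**Synthetic cohorts.** A seeded generator draws genotypes under
Hardy–Weinberg equilibrium at configurable allele frequencies (optionally
with copula-correlated variant pairs) plus age/sex metadata, and the four
worked clinical cases ship as fixtures — so the whole pipeline is testable
without patient data.

## Worked example

Interpret the bundled clinical case fixtures against the bundled demo panel
(24 variants, 13 genes, 28 drugs):

```sh
pgxcns interpret \
    --genotypes src/pgxcns/data/cases_abcd.tsv \
    --out reports --format md
```

The report for `case_d` (rs4244285 AG; rs3892097 CT + rs1065852 AG;
rs4713916 AA) begins:

```
# PGx report — sample case_d

Panel: pgx-cns-demo/1.0  |  Engine: 0.1.0

## Metabolizer status

| Gene | Diplotype | Phenotype |
|---|---|---|
| CYP2C19 | *1/*2 | intermediate |
| CYP2C9 | *1/*1 | extensive |
| CYP2D6 | *1/*4 | extensive |

## Drug interaction categories

| Drug | Category | Triggered associations |
|---|---|---|
| fluoxetine | H | FKBP5 (2B, Efficacy) |
| amitriptyline | M | CYP2C19 (1A, Metabolism) |
| citalopram | M | CYP2C19 (1A, Metabolism) |
| ...
```

Reading the numbers: the single rs4244285 alt allele gives the CYP2C19
\*1/\*2 diplotype, an intermediate metabolizer, which triggers the
medium-interaction metabolism rules for the CYP2C19-cleared antidepressants
(slower clearance — consider reduced dose and slow titration). The
rs3892097/rs1065852 double heterozygote resolves in cis to CYP2D6 \*1/\*4,
an extensive metabolizer, so CYP2D6 substrates stay at low interaction. The
rs4713916 AA homozygote fires the high-interaction response rule for
fluoxetine.

Other subcommands: `simulate` (seeded HWE cohorts), `popstats`
(cohort-vs-reference comparison suite), `mca` (nonlinear PCA / MCA),
`summary` (metadata + metabolizer distributions). `--panel` defaults to the
bundled demo panel; any panel can be supplied as a YAML file following the
documented schema in `src/pgxcns/data/panel_pgx_cns_demo.yaml`.

## Scope notes

CYP2D6 copy-number variation and HLA-A/HLA-B typing (carbamazepine
hypersensitivity) are outside the panel's scope, and the bundled demo
panel's association matrix beyond the literature-stated examples consists of
clearly marked placeholder assignments — see `docs/methods.md` for the full
model description, parameter defaults and limitations.
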
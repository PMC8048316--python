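# Methods

This note documents the models and procedures implemented in `pgxcns`, the
defaults they use, and what the bundled synthetic data can and cannot show.

## Panel model

A panel is a static, versioned YAML file declaring variants (rsid, gene,
ref/alt on the forward orientation of the genotype input), genes with
prioritisation groups, drugs, star-allele definitions, diplotype→phenotype
rules, and genotype-drug association rules. The loader enforces referential
closure (every rsid/gene/drug referenced by any rule must exist), uniqueness
of rsids, drug names and per-gene star names, strictly decreasing
evidence-level scores, and rejects evidence level 4 (case-report grade)
outright. Serialisation expands association families into explicit per-state
rules, so load → save → load is the identity.

Evidence-level scores are not dictated by the literature the panel encodes;
the default monotone map 1A=5, 1B=4, 2A=3, 2B=2, 3=1 preserves the argmax
semantics of the scoring formula and is overridable per panel file
(`el_scores`). Gene prioritisation is fixed at A=3 (metabolising enzymes),
B=2 (signalling proteins), C=1 (additional signalling proteins).

The demo panel's association matrix encodes the literature-stated
associations (CYP2C19 → citalopram/escitalopram/sertraline/amitriptyline,
CYP2C9 → valproic acid/phenytoin, CYP2D6 → paroxetine/mirtazapine and
antipsychotics, MC4R rs17782313 → quetiapine weight gain, FKBP5 rs4713916 →
antidepressant response, HTR2C rs1414334 → metabolic syndrome, ANKK1/DRD2
rs1800497 → tardive dyskinesia/hyperprolactinemia, EPHX1 and SCN1A →
carbamazepine, UGT2B7 → valproic acid/lamotrigine, DRD2 rs1799978 →
risperidone response, GRIK1 → topiramate). Category assignments follow the
minimum/intermediate/enhanced convention (homozygous wild-type → L,
heterozygous → M, homozygous variant → H) for single-SNP markers, and
extensive → L / intermediate → M / poor, ultra-rapid → H for CYP phenotype
triggers. Assignments beyond the stated examples are placeholders; real
deployments supply their own curated panel file.

## Genotype input

Two routes: a wide TSV (one column per rsid, two-letter genotypes, `--` or
`NA` missing) and VCF v4.x with GT fields, matched by ID. Dosage is the
count of the panel alt allele (0/1/2); missing stays missing and is never
coerced to reference. When observed alleles match neither panel allele,
reverse-complement reconciliation is attempted — except at strand-ambiguous
A/T and C/G SNPs, where a silent flip would corrupt dosage undetectably, so
the mismatch is a hard error. VCF records whose REF/ALT are swapped relative
to the panel are reconciled by inverting the dosage. The three CYP2D6
deletion variants use the one-letter token `D` for the deleted allele.

## Diplotype calling

Star alleles are defined by defining SNPs, optional absorbed SNPs
(containment: the rs1065852 alt is expected on CYP2D6\*4 haplotypes; the
rs12248560 alt on a CYP2C19\*4 haplotype does not create a separate \*17)
and optional excluded SNPs. Calling proceeds by exhaustive phase
enumeration: every split of the observed dosages into two haplotypes is
generated (≤ 2^h for h heterozygous sites, h ≤ 6), each haplotype is mapped
to a star, and splits in which a haplotype matches no single star cleanly
are discarded. An empty candidate set is an inconsistency error (e.g.
homozygous \*2 plus heterozygous \*3 at CYP2C9 would force a two-star
haplotype).

Preference among candidates: (1) declared cis pairs — rs3892097+rs1065852
double heterozygotes resolve in cis to \*4/\*1; (2) otherwise maximise the
number of variant haplotypes, which is exactly the trans assumption for
double heterozygotes (\*2/\*3 for CYP2C9, \*2/\*17 and \*4/\*17 for
CYP2C19). Remaining ties are flagged `ambiguous`. The phase rule for
unphased double heterozygotes is this package's documented choice; no
statistical phasing or population LD is used.

Missing defining SNPs are handled by completion: if every possible value of
the missing dosages yields the same diplotype, the call stands (with the
sites listed as unresolved); otherwise the reference-completion call is
returned flagged ambiguous, and downstream consumers treat the gene as
unresolved rather than assuming reference.

## Phenotype classification

Explicit diplotype→phenotype rules always win. The fallback classifies by
allele function (normal / decreased / none / increased): two no-function →
poor; one no-function, or two decreased, or increased with
decreased/no-function → intermediate; increased with normal → ultra-rapid;
else extensive. Two deliberate fidelity choices of the bundled table:
CYP2C19 \*1/\*17 is ultra-rapid (carrier counting, not just \*17
homozygotes), and CYP2D6 \*1/\*4 is extensive — external guidelines grade
\*1/\*4 as intermediate, but the bundled table reproduces its source
reference table verbatim; override via the panel file if other guidance is
preferred. CYP2C19 \*2/\*17 is intermediate (config-overridable). Without
CNV data, CYP2D6 ultra-rapid calls are unreachable by construction.

## Drug scoring and reports

For each drug, per category c: el_sum = Σ EL over triggered rules of
category c; pg_sum = Σ PG over the *set* of distinct genes of those rules
(a gene never double-counts within a category); the drug takes the category
with the largest total, ties broken toward the higher-interaction category
(clinically conservative) and flagged. Rules with zero evidence weight are
fully inert — they contribute neither EL nor their gene's PG — so adding
them can never change an assignment. With no triggered rules a drug is L
with all totals zero.

Reports are deterministic: drugs sorted by category (H > M > L) then name,
canonical JSON plus Markdown. Advice keys (at most the nine defined by the
panel) attach only to drugs assigned M or H. A drug whose rules depend on a
missing call or an unresolved diplotype is reported `indeterminate` rather
than silently L — low interaction must never be an artefact of missing data.

## Population comparisons

Comparisons use genotype-class counts (2×3), not allele counts; the design
df is 2 throughout. Pearson's χ² is the textbook Σ(O−E)²/E with expected
counts from the margins; Cramér's V = √(χ²/(n·(min(r,c)−1))) = √(χ²/n) for
2×3; strength labels: weak ≤ 0.20, moderate 0.21–0.34, strong ≥ 0.35. The
adequacy rule (≥80% of expected cells ≥5 and no zero expected cell) routes
failing tables to the Freeman–Halton exact test: full enumeration of the
fixed-margin state space when it has ≤ 10^7 tables (always true for the 2×3
tables this panel produces), otherwise seeded Patefield Monte Carlo with
10^5 tables. A fully monomorphic table (both populations entirely in one
genotype class) is returned as the trivial independence result (χ²=0, V=0,
p=1) rather than an error, since rare variants routinely produce empty
genotype classes; only a zero row margin is degenerate.

Holm–Bonferroni is applied across the family of all comparisons actually
performed in a run (24 variants × available references). Reference
populations enter either as explicit genotype counts or as allele
frequencies expanded under HWE at the stated sample sizes (defaults CEU 180,
YRI 180, CHB 90), rounded to nearest with a largest-remainder correction so
each row sums exactly to its sample size. The bundled frequency profiles
are plausible continental values written for testing and are labelled
non-authoritative in the file itself.

## Nonlinear PCA / MCA

Binarization codes carrier status (dosage ≥ 1) in complete disjunctive form
(two indicator columns per variant); monomorphic variants are dropped with
a warning, samples with no calls are excluded, and an isolated missing call
codes as non-carrier. The decomposition is classical correspondence
analysis of the indicator matrix: SVD of (P − rcᵀ)/√(rcᵀ); principal
inertias are squared singular values; the trivial axis vanishes by
centering. Total inertia equals J/q − 1 exactly and inertia proportions are
reported raw (no Benzécri/Greenacre correction). Axes are oriented so the
largest-magnitude loading is positive. Component selection uses the scree
elbow (largest k before the maximal drop in successive eigenvalue
differences), with a user override. Outlier flagging marks samples beyond
median ± k·MAD (default k = 6) on the selected components; the threshold is
this package's own convention. Trailing near-tied eigenvalues span
rotation-degenerate subspaces in which individual coordinates are not
unique — only leading, well-separated components should be interpreted.

## Synthetic cohorts

Genotypes are i.i.d. across variants under HWE: each haplotype carries the
alt allele with probability q, via a latent-Gaussian threshold per
haplotype. The optional co-occurrence knob imposes a correlation on chosen
variant pairs through the Gaussian copula at the haplotype level, which
lets tests plant detectable carrier co-occurrence structure for MCA. Age
bands (0–20, 21–40, 41–60, 61–80, 81–100) default to probabilities
20/164/183/112/22 out of 501 and sex to 226 male / 275 female — the
composition of the CNS patient cohort the pipeline is designed around. All
draws flow through one `numpy` generator seeded from the mandatory config
seed; identical configs produce byte-identical cohort TSVs.

What the generator does *not* emulate: linkage disequilibrium between star
alleles (so biologically implausible combinations such as a \*2 homozygote
who also carries \*17 occur at low rates and surface as inconsistency/
unresolved calls — on real data these essentially do not arise), population
substructure, genotyping error and missingness patterns. Passing tests on
synthetic cohorts therefore validate the computational contracts, not
concordance with any particular patient population; the published
metabolizer counts and MCA variance shares of a real 501-patient cohort are
not reproducible from synthetic data, and the acceptance script reports the
synthetic analogues under their own names.

## Problem sizes and numerical choices

The test suite and acceptance script use: exhaustive 3^k dosage grids per
gene (k ≤ 6), 501-sample cohorts for distribution-level checks, 10 000
samples for HWE recovery (3-standard-error bands), 5 000 for goodness-of-fit
sweeps, and 10^5 Monte Carlo tables when exercising the exact-test
fallback. Exact-test tie handling uses a 1e-9 log-probability tolerance;
MCA discards singular values below 1e-12; Holm uses a stable sort so equal
p-values adjust identically regardless of input order.
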
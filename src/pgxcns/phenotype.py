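"""Metabolizer phenotype classification and cohort distributions.

Explicit diplotype->phenotype rules from the panel config always win; pairs
without an explicit rule fall back to per-allele function classes
(normal / decreased / none / increased):

* two no-function alleles -> poor
* exactly one no-function allele, or two decreased-function alleles,
  or increased paired with decreased/no-function -> intermediate
* an increased-function allele with a normal (or increased) partner
  -> ultra_rapid
* everything else -> extensive
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import pandas as pd

from .diplotype import Diplotype, call_diplotype
from .errors import ClassificationError, InconsistentGenotypeError
from .genotypes import CohortGenotypes
from .panel import PHENOTYPES, PanelDefinition


@dataclasses.dataclass(frozen=True)
class MetabolizerPhenotype:
    gene: str
    phenotype: str  # poor / intermediate / extensive / ultra_rapid
    rule_id: str


def _fallback(fa: str, fb: str) -> str:
    classes = sorted((fa, fb))
    n_none = classes.count("none")
    if n_none == 2:
        return "poor"
    if n_none == 1:
        return "intermediate"
    if classes == ["decreased", "decreased"]:
        return "intermediate"
    if "increased" in classes:
        return "intermediate" if "decreased" in classes else "ultra_rapid"
    return "extensive"


def classify_metabolizer(d: Diplotype, panel: PanelDefinition) -> MetabolizerPhenotype:
    """Map a diplotype to its metabolizer phenotype."""
    rule = panel.phenotype_rule(d.gene, d.pattern)
    if rule is not None:
        return MetabolizerPhenotype(gene=d.gene, phenotype=rule.phenotype, rule_id=rule.rule_id)
    funcs = panel.allele_function.get(d.gene)
    if funcs is None or d.allele_a not in funcs or d.allele_b not in funcs:
        raise ClassificationError(
            f"no phenotype rule or allele-function fallback for {d.gene} {d.pattern}"
        )
    pheno = _fallback(funcs[d.allele_a], funcs[d.allele_b])
    return MetabolizerPhenotype(
        gene=d.gene,
        phenotype=pheno,
        rule_id=f"fallback:{funcs[d.allele_a]}/{funcs[d.allele_b]}",
    )


@dataclasses.dataclass
class PhenotypeDistribution:
    gene: str
    counts: dict[str, int]  # phenotype -> count
    n: int
    unresolved: int = 0

    def percent(self, phenotype: str) -> float:
        if self.n == 0:
            return 0.0
        return round(100.0 * self.counts.get(phenotype, 0) / self.n, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": self.gene,
                "phenotype": p,
                "count": self.counts.get(p, 0),
                "percent": self.percent(p),
            }
            for p in PHENOTYPES
        ]
        return pd.DataFrame(rows)


def cohort_phenotype_distribution(
    cohort: CohortGenotypes, gene: str, panel: PanelDefinition
) -> PhenotypeDistribution:
    """Per-phenotype counts over a cohort for one CYP gene.

    Samples whose diplotype is unresolvable (inconsistent dosages, or missing
    defining SNPs that change the call) are excluded from the counts and
    tallied under ``unresolved``.
    """
    counts = {p: 0 for p in PHENOTYPES}
    unresolved = 0
    for sample in cohort:
        try:
            dip = call_diplotype(sample, gene, panel)
        except InconsistentGenotypeError:
            unresolved += 1
            continue
        if dip.ambiguous:
            unresolved += 1
            continue
        counts[classify_metabolizer(dip, panel).phenotype] += 1
    return PhenotypeDistribution(gene=gene, counts=counts, n=len(cohort), unresolved=unresolved)


def phenotypes_for_sample(
    sample, panel: PanelDefinition
) -> dict[str, Optional[MetabolizerPhenotype]]:
    """Metabolizer phenotypes for every star-allele gene of the panel; None
    where the diplotype is unresolved."""
    out: dict[str, Optional[MetabolizerPhenotype]] = {}
    for gene in panel.star_genes:
        try:
            dip = call_diplotype(sample, gene, panel)
        except InconsistentGenotypeError:
            out[gene] = None
            continue
        out[gene] = None if dip.ambiguous else classify_metabolizer(dip, panel)
    return out
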
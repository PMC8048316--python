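"""Gene-drug interaction categorisation and per-sample clinical reports.

Every drug is assigned to the interaction category c in {L, M, H} maximising

    sum_{i in D_c} EL_i  +  sum_{j in G_c} PG_j

where D_c is the set of triggered genotype-drug association rules of category
c, EL_i the numeric evidence-level score of rule i, G_c the SET of distinct
genes among those rules and PG_j the gene prioritisation score.  Ties are
broken toward the higher-interaction category (clinically conservative).
Rules with a zero evidence weight are inert: they contribute neither EL nor
their gene's PG.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

from . import __version__ as ENGINE_VERSION
from .diplotype import Diplotype, call_diplotype
from .errors import InconsistentGenotypeError
from .genotypes import SampleGenotypes
from .panel import AssociationRule, PanelDefinition
from .phenotype import MetabolizerPhenotype, classify_metabolizer

_CATEGORY_RANK = {"H": 0, "M": 1, "L": 2}


@dataclasses.dataclass(frozen=True)
class TriggeredAssociation:
    rule: AssociationRule
    evidence_value: str
    gene: str


@dataclasses.dataclass(frozen=True)
class SkippedAssociation:
    rule: AssociationRule
    reason: str


@dataclasses.dataclass
class CategoryScore:
    el_sum: int = 0
    pg_sum: int = 0

    @property
    def total(self) -> int:
        return self.el_sum + self.pg_sum


@dataclasses.dataclass
class DrugScore:
    drug: str
    per_category: dict[str, CategoryScore]
    assigned_category: str  # "L"/"M"/"H" or "indeterminate"
    tie_broken: bool
    triggered: list[TriggeredAssociation]
    advice_keys: tuple[str, ...] = ()
    caveats: tuple[str, ...] = ()


def _resolve_gene_state(
    sample: SampleGenotypes, panel: PanelDefinition
) -> tuple[dict[str, Optional[Diplotype]], dict[str, Optional[MetabolizerPhenotype]]]:
    diplotypes: dict[str, Optional[Diplotype]] = {}
    phenotypes: dict[str, Optional[MetabolizerPhenotype]] = {}
    for gene in panel.star_genes:
        try:
            dip = call_diplotype(sample, gene, panel)
        except InconsistentGenotypeError:
            diplotypes[gene] = None
            phenotypes[gene] = None
            continue
        diplotypes[gene] = dip
        phenotypes[gene] = None if dip.ambiguous else classify_metabolizer(dip, panel)
    return diplotypes, phenotypes


def triggered_associations(
    sample: SampleGenotypes,
    panel: PanelDefinition,
    diplotypes: Optional[dict[str, Optional[Diplotype]]] = None,
    phenotypes: Optional[dict[str, Optional[MetabolizerPhenotype]]] = None,
) -> tuple[list[TriggeredAssociation], list[SkippedAssociation]]:
    """Evaluate every panel association rule against one sample.

    Returns the triggered rules and the rules that could not be evaluated
    (missing genotype call, or an unresolved diplotype upstream).
    """
    if diplotypes is None or phenotypes is None:
        diplotypes, phenotypes = _resolve_gene_state(sample, panel)
    triggered: list[TriggeredAssociation] = []
    skipped: list[SkippedAssociation] = []
    for rule in panel.associations:
        t = rule.trigger
        if t.kind == "genotype":
            d = sample.dosage(t.rsid)
            if d is None:
                skipped.append(SkippedAssociation(rule, f"missing call at {t.rsid}"))
            elif d in t.dosages:
                triggered.append(
                    TriggeredAssociation(rule, f"{t.rsid} dosage {d}", rule.gene)
                )
        elif t.kind == "phenotype":
            ph = phenotypes.get(rule.gene)
            if ph is None:
                skipped.append(
                    SkippedAssociation(rule, f"unresolved {rule.gene} diplotype")
                )
            elif ph.phenotype == t.phenotype:
                triggered.append(
                    TriggeredAssociation(rule, f"{rule.gene} {ph.phenotype}", rule.gene)
                )
        elif t.kind == "diplotype":
            dip = diplotypes.get(rule.gene)
            if dip is None or dip.ambiguous:
                skipped.append(
                    SkippedAssociation(rule, f"unresolved {rule.gene} diplotype")
                )
            elif dip.pattern == t.diplotype:
                triggered.append(
                    TriggeredAssociation(rule, f"{rule.gene} {dip.pattern}", rule.gene)
                )
    return triggered, skipped


def score_drug(
    drug: str, triggered: list[TriggeredAssociation], panel: PanelDefinition
) -> DrugScore:
    """Apply the category-score argmax for one drug."""
    relevant = [t for t in triggered if t.rule.drug == drug]
    # zero-weight rules are inert: no EL contribution and no gene PG
    active = [t for t in relevant if t.rule.el_score > 0]
    per_category = {c: CategoryScore() for c in ("L", "M", "H")}
    genes: dict[str, set[str]] = {c: set() for c in ("L", "M", "H")}
    for t in active:
        c = t.rule.category
        per_category[c].el_sum += t.rule.el_score
        genes[c].add(t.gene)
    for c, gset in genes.items():
        per_category[c].pg_sum = sum(panel.gene(g).pg_score for g in gset)

    if not active:
        return DrugScore(
            drug=drug,
            per_category=per_category,
            assigned_category="L",
            tie_broken=False,
            triggered=relevant,
        )
    max_total = max(s.total for s in per_category.values())
    attaining = [c for c, s in per_category.items() if s.total == max_total]
    assigned = min(attaining, key=lambda c: _CATEGORY_RANK[c])
    return DrugScore(
        drug=drug,
        per_category=per_category,
        assigned_category=assigned,
        tie_broken=len(attaining) > 1,
        triggered=relevant,
    )


@dataclasses.dataclass
class SampleReport:
    sample_id: str
    diplotypes: dict[str, Optional[Diplotype]]
    phenotypes: dict[str, Optional[MetabolizerPhenotype]]
    drug_results: list[DrugScore]
    panel_version: str
    engine_version: str
    caveats: tuple[str, ...] = ()

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "panel_version": self.panel_version,
            "engine_version": self.engine_version,
            "diplotypes": {
                g: (
                    {
                        "diplotype": d.pattern,
                        "ambiguous": d.ambiguous,
                        "unresolved_sites": list(d.unresolved_sites),
                    }
                    if d is not None
                    else {"diplotype": None, "ambiguous": True, "unresolved_sites": []}
                )
                for g, d in sorted(self.diplotypes.items())
            },
            "phenotypes": {
                g: (p.phenotype if p is not None else None)
                for g, p in sorted(self.phenotypes.items())
            },
            "drugs": [
                {
                    "drug": r.drug,
                    "category": r.assigned_category,
                    "tie_broken": r.tie_broken,
                    "scores": {
                        c: {"el_sum": s.el_sum, "pg_sum": s.pg_sum, "total": s.total}
                        for c, s in sorted(r.per_category.items())
                    },
                    "triggered": [
                        {
                            "rule_id": t.rule.rule_id,
                            "gene": t.gene,
                            "evidence_level": t.rule.evidence_level,
                            "category": t.rule.category,
                            "advisory": t.rule.advisory,
                            "fda": t.rule.fda_annotation,
                            "evidence_value": t.evidence_value,
                        }
                        for t in r.triggered
                    ],
                    "advice_keys": list(r.advice_keys),
                    "caveats": list(r.caveats),
                }
                for r in self.drug_results
            ],
            "caveats": list(self.caveats),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n"

    def to_markdown(self, panel: PanelDefinition) -> str:
        lines = [
            f"# PGx report — sample {self.sample_id}",
            "",
            f"Panel: {self.panel_version}  |  Engine: {self.engine_version}",
            "",
            "## Metabolizer status",
            "",
            "| Gene | Diplotype | Phenotype |",
            "|---|---|---|",
        ]
        for g in sorted(self.diplotypes):
            d = self.diplotypes[g]
            p = self.phenotypes.get(g)
            dip = d.pattern if d is not None else "unresolved"
            if d is not None and d.ambiguous:
                dip += " (ambiguous)"
            lines.append(f"| {g} | {dip} | {p.phenotype if p else 'unresolved'} |")
        lines += ["", "## Drug interaction categories", ""]
        lines += ["| Drug | Category | Triggered associations |", "|---|---|---|"]
        for r in self.drug_results:
            trig = "; ".join(
                f"{t.gene} ({t.rule.evidence_level}, {t.rule.advisory})" for t in r.triggered
            )
            lines.append(f"| {r.drug} | {r.assigned_category} | {trig or '—'} |")
        advised = [r for r in self.drug_results if r.advice_keys]
        if advised:
            lines += ["", "## Clinical advices", ""]
            for r in advised:
                for key in r.advice_keys:
                    lines.append(f"- **{r.drug}**: {panel.advice_templates[key]}")
        if self.caveats:
            lines += ["", "## Caveats", ""]
            lines += [f"- {c}" for c in self.caveats]
        return "\n".join(lines) + "\n"


def build_report(sample: SampleGenotypes, panel: PanelDefinition) -> SampleReport:
    """Deterministic per-sample clinical report covering all panel drugs.

    Drugs whose association rules depend on a missing genotype call or an
    unresolved diplotype are reported ``indeterminate`` rather than being
    silently scored from partial evidence alone.
    """
    diplotypes, phenotypes = _resolve_gene_state(sample, panel)
    triggered, skipped = triggered_associations(sample, panel, diplotypes, phenotypes)
    skipped_by_drug: dict[str, list[SkippedAssociation]] = {}
    for s in skipped:
        skipped_by_drug.setdefault(s.rule.drug, []).append(s)

    results = []
    for drug_def in panel.drugs:
        drug = drug_def.name
        score = score_drug(drug, triggered, panel)
        drug_skips = skipped_by_drug.get(drug, [])
        if drug_skips:
            reasons = sorted({s.reason for s in drug_skips})
            score.assigned_category = "indeterminate"
            score.caveats = tuple(reasons)
        if score.assigned_category in ("M", "H"):
            keys = sorted(
                {
                    t.rule.advice_key
                    for t in score.triggered
                    if t.rule.advice_key is not None and t.rule.category in ("M", "H")
                }
            )
            score.advice_keys = tuple(keys[:9])
        results.append(score)

    order = {"H": 0, "M": 1, "L": 2, "indeterminate": 3}
    results.sort(key=lambda r: (order[r.assigned_category], r.drug))
    caveats = tuple(
        sorted({f"{s.rule.drug}: {s.reason}" for s in skipped})
    )
    return SampleReport(
        sample_id=sample.sample_id,
        diplotypes=diplotypes,
        phenotypes=phenotypes,
        drug_results=results,
        panel_version=f"{panel.name}/{panel.version}",
        engine_version=ENGINE_VERSION,
        caveats=caveats,
    )
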
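"""Panel data model: variants, genes, drugs, star-allele definitions,
diplotype->phenotype rules and genotype-drug association rules.

A panel is a static, versioned YAML configuration (see
``data/panel_pgx_cns_demo.yaml`` for the documented schema).  The loader
enforces referential integrity across every rule list and rejects evidence
level 4 annotations, which are excluded from the panel by design.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import PanelLoadError

PG_SCORES = {"A": 3, "B": 2, "C": 1}

EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B", "3")
DEFAULT_EL_SCORES = {"1A": 5, "1B": 4, "2A": 3, "2B": 2, "3": 1}

CATEGORIES = ("L", "M", "H")
PHENOTYPES = ("poor", "intermediate", "extensive", "ultra_rapid")

ADVISORIES = (
    "Efficacy",
    "Metabolism",
    "PK",
    "Toxicity",
    "ADE (miscellaneous)",
    "ADE (weight gain)",
    "ADE (metabolic syndrome)",
    "ADE (tardive dyskinesia)",
    "ADE (hypertriglyceridemia)",
    "ADE (hyperprolactinemia)",
    "ADE (gastroenteric)",
    "ADE (stroke)",
)

FDA_ANNOTATIONS = ("Actionable", "InformativePGx", "NoRecommendation")


class VariantDef(BaseModel):
    """One biallelic panel SNP.  ``alt_allele`` may be the one-letter
    deletion token ``"D"``."""

    model_config = ConfigDict(frozen=True)

    rsid: str
    gene: str
    ref_allele: str
    alt_allele: str
    assay_id: Optional[str] = None

    @field_validator("ref_allele", "alt_allele")
    @classmethod
    def _single_token(cls, v: str) -> str:
        if len(v) != 1 or v not in "ACGTD":
            raise ValueError(f"allele token must be one of A/C/G/T/D, got {v!r}")
        return v


class GeneDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    symbol: str
    priority_group: Literal["A", "B", "C"]
    functional_class: str = ""

    @property
    def pg_score(self) -> int:
        return PG_SCORES[self.priority_group]


class DrugDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    atc_or_class: Optional[str] = None


class StarAlleleRule(BaseModel):
    """A star allele is assigned to a haplotype when the alt alleles of all
    ``defining_rsids`` are present, none of ``excluded_rsids`` is present, and
    every other alt on the haplotype is in ``absorbed_rsids`` (containment:
    e.g. the rs1065852 alt rides along on CYP2D6*4 haplotypes without
    creating a separate *10)."""

    model_config = ConfigDict(frozen=True)

    gene: str
    star: str
    defining_rsids: tuple[str, ...]
    excluded_rsids: tuple[str, ...] = ()
    absorbed_rsids: tuple[str, ...] = ()


class PhenotypeRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    gene: str
    diplotype_pattern: str  # e.g. "*4/*10", unordered
    phenotype: Literal["poor", "intermediate", "extensive", "ultra_rapid"]

    @property
    def rule_id(self) -> str:
        return f"{self.gene}:{self.diplotype_pattern}"

    def stars(self) -> tuple[str, str]:
        a, b = self.diplotype_pattern.split("/")
        return a, b


class Trigger(BaseModel):
    """Genotype predicate of an association rule.

    kind="genotype": matches when the sample's dosage at ``rsid`` is in
    ``dosages``.  kind="phenotype": matches the gene's metabolizer phenotype.
    kind="diplotype": matches a specific unordered star pair.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["genotype", "phenotype", "diplotype"]
    rsid: Optional[str] = None
    dosages: tuple[int, ...] = ()
    phenotype: Optional[str] = None
    diplotype: Optional[str] = None


class AssociationRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    drug: str
    gene: str
    trigger: Trigger
    evidence_level: Literal["1A", "1B", "2A", "2B", "3"]
    el_score: int
    category: Literal["L", "M", "H"]
    advisory: str
    fda_annotation: Literal["Actionable", "InformativePGx", "NoRecommendation"]
    advice_key: Optional[str] = None


class PanelDefinition(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    version: str
    variants: tuple[VariantDef, ...]
    genes: tuple[GeneDef, ...]
    drugs: tuple[DrugDef, ...]
    star_rules: tuple[StarAlleleRule, ...]
    phenotype_rules: tuple[PhenotypeRule, ...]
    associations: tuple[AssociationRule, ...]
    advice_templates: dict[str, str]
    el_scores: dict[str, int]
    allele_function: dict[str, dict[str, str]]
    cis_pairs: tuple[tuple[str, str], ...] = ()

    # -- lookups -----------------------------------------------------------
    def variant(self, rsid: str) -> VariantDef:
        try:
            return self._variant_index[rsid]
        except KeyError:
            raise KeyError(f"rsid {rsid} not in panel {self.name}") from None

    def gene(self, symbol: str) -> GeneDef:
        return self._gene_index[symbol]

    @property
    def _variant_index(self) -> dict[str, VariantDef]:
        idx = self.__dict__.get("_vidx")
        if idx is None:
            idx = {v.rsid: v for v in self.variants}
            object.__setattr__(self, "_vidx", idx)
        return idx

    @property
    def _gene_index(self) -> dict[str, GeneDef]:
        idx = self.__dict__.get("_gidx")
        if idx is None:
            idx = {g.symbol: g for g in self.genes}
            object.__setattr__(self, "_gidx", idx)
        return idx

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    @property
    def star_genes(self) -> tuple[str, ...]:
        """Genes with a star-allele system, in panel gene order."""
        with_stars = {r.gene for r in self.star_rules}
        return tuple(g.symbol for g in self.genes if g.symbol in with_stars)

    def star_rules_for(self, gene: str) -> tuple[StarAlleleRule, ...]:
        return tuple(r for r in self.star_rules if r.gene == gene)

    def defining_rsids(self, gene: str) -> tuple[str, ...]:
        """All rsids that participate in the gene's star definitions, in
        panel variant order."""
        involved: set[str] = set()
        for r in self.star_rules_for(gene):
            involved.update(r.defining_rsids)
            involved.update(r.absorbed_rsids)
            involved.update(r.excluded_rsids)
        return tuple(rs for rs in self.rsids if rs in involved)

    def phenotype_rule(self, gene: str, pattern: str) -> Optional[PhenotypeRule]:
        for r in self.phenotype_rules:
            if r.gene == gene and r.diplotype_pattern == pattern:
                return r
        return None

    def cis_pairs_for(self, gene: str) -> tuple[tuple[str, str], ...]:
        gene_rs = set(self.defining_rsids(gene))
        return tuple(p for p in self.cis_pairs if set(p) <= gene_rs)

    # -- serialization -----------------------------------------------------
    def to_config_dict(self) -> dict:
        """Fully expanded config (each association rule explicit); loading
        this dict reproduces the panel field-by-field."""
        return {
            "panel": {"name": self.name, "version": self.version},
            "el_scores": dict(self.el_scores),
            "genes": [
                {
                    "symbol": g.symbol,
                    "priority_group": g.priority_group,
                    "functional_class": g.functional_class,
                }
                for g in self.genes
            ],
            "variants": [
                {
                    "rsid": v.rsid,
                    "gene": v.gene,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    **({"assay_id": v.assay_id} if v.assay_id else {}),
                }
                for v in self.variants
            ],
            "drugs": [
                {"name": d.name, **({"atc_or_class": d.atc_or_class} if d.atc_or_class else {})}
                for d in self.drugs
            ],
            "star_alleles": [
                {
                    "gene": r.gene,
                    "star": r.star,
                    "defining": list(r.defining_rsids),
                    **({"absorbs": list(r.absorbed_rsids)} if r.absorbed_rsids else {}),
                    **({"excludes": list(r.excluded_rsids)} if r.excluded_rsids else {}),
                }
                for r in self.star_rules
            ],
            "cis_pairs": [list(p) for p in self.cis_pairs],
            "allele_function": {g: dict(m) for g, m in self.allele_function.items()},
            "phenotype_rules": [
                {"gene": r.gene, "pattern": r.diplotype_pattern, "phenotype": r.phenotype}
                for r in self.phenotype_rules
            ],
            "associations": [
                {
                    "rule_id": a.rule_id,
                    "drug": a.drug,
                    "gene": a.gene,
                    "trigger": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in a.trigger.model_dump().items()
                        if v not in (None, ())
                    },
                    "evidence_level": a.evidence_level,
                    "category": a.category,
                    "advisory": a.advisory,
                    "fda": a.fda_annotation,
                    **({"advice_key": a.advice_key} if a.advice_key else {}),
                }
                for a in self.associations
            ],
            "advice_templates": dict(self.advice_templates),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_config_dict(), sort_keys=False, allow_unicode=True)
        )


# ---------------------------------------------------------------------------
# loading


def _expand_association_family(entry: dict, el_scores: dict[str, int]) -> list[AssociationRule]:
    """Expand the compact family form (one entry per variant/phenotype-drug
    family) into explicit per-state AssociationRules."""
    drugs = entry.get("drugs") or [entry["drug"]]
    gene = entry["gene"]
    level = str(entry["evidence_level"])
    if level == "4":
        raise PanelLoadError(
            "evidence level 4 associations (case reports / non-significant "
            "studies) are excluded from the panel"
        )
    advisory = entry["advisory"]
    fda = entry["fda"]
    advice = entry.get("advice")
    overrides = entry.get("advice_overrides", {})
    rules: list[AssociationRule] = []
    for drug in sorted(drugs):
        if "genotype_categories" in entry:
            rsid = entry["rsid"]
            for dosage, cat in sorted(entry["genotype_categories"].items()):
                dosage = int(dosage)
                key = overrides.get(dosage, advice) if cat in ("M", "H") else None
                rules.append(
                    AssociationRule(
                        rule_id=f"{drug}|{gene}|{rsid}|d{dosage}|{advisory}",
                        drug=drug,
                        gene=gene,
                        trigger=Trigger(kind="genotype", rsid=rsid, dosages=(dosage,)),
                        evidence_level=level,
                        el_score=el_scores[level],
                        category=cat,
                        advisory=advisory,
                        fda_annotation=fda,
                        advice_key=key,
                    )
                )
        elif "phenotype_categories" in entry:
            for pheno, cat in sorted(entry["phenotype_categories"].items()):
                key = overrides.get(pheno, advice) if cat in ("M", "H") else None
                rules.append(
                    AssociationRule(
                        rule_id=f"{drug}|{gene}|{pheno}|{advisory}",
                        drug=drug,
                        gene=gene,
                        trigger=Trigger(kind="phenotype", phenotype=pheno),
                        evidence_level=level,
                        el_score=el_scores[level],
                        category=cat,
                        advisory=advisory,
                        fda_annotation=fda,
                        advice_key=key,
                    )
                )
        else:
            raise PanelLoadError(
                f"association family for {drugs} has neither genotype_categories "
                "nor phenotype_categories"
            )
    return rules


def _explicit_association(entry: dict, el_scores: dict[str, int]) -> AssociationRule:
    level = str(entry["evidence_level"])
    if level == "4":
        raise PanelLoadError(
            "evidence level 4 associations (case reports / non-significant "
            "studies) are excluded from the panel"
        )
    trig = dict(entry["trigger"])
    if "dosages" in trig:
        trig["dosages"] = tuple(int(d) for d in trig["dosages"])
    return AssociationRule(
        rule_id=entry["rule_id"],
        drug=entry["drug"],
        gene=entry["gene"],
        trigger=Trigger(**trig),
        evidence_level=level,
        el_score=el_scores[level],
        category=entry["category"],
        advisory=entry["advisory"],
        fda_annotation=entry["fda"],
        advice_key=entry.get("advice_key"),
    )


def panel_from_dict(cfg: dict) -> PanelDefinition:
    """Build and validate a PanelDefinition from a parsed config mapping."""
    try:
        meta = cfg["panel"]
        genes = tuple(
            GeneDef(
                symbol=g["symbol"],
                priority_group=g["priority_group"],
                functional_class=g.get("functional_class", ""),
            )
            for g in cfg["genes"]
        )
        gene_set = {g.symbol for g in genes}
        if len(gene_set) != len(genes):
            raise PanelLoadError("duplicate gene symbol in panel config")

        seen: set[str] = set()
        variants = []
        for v in cfg["variants"]:
            if v["rsid"] in seen:
                raise PanelLoadError(f"duplicate rsid in panel config: {v['rsid']}")
            seen.add(v["rsid"])
            if v["gene"] not in gene_set:
                raise PanelLoadError(f"variant {v['rsid']} references unknown gene {v['gene']}")
            if v["ref"] == v["alt"]:
                raise PanelLoadError(f"variant {v['rsid']} has identical ref and alt alleles")
            variants.append(
                VariantDef(
                    rsid=v["rsid"],
                    gene=v["gene"],
                    ref_allele=v["ref"],
                    alt_allele=v["alt"],
                    assay_id=v.get("assay_id"),
                )
            )
        variants = tuple(sorted(variants, key=lambda v: v.rsid))
        rsid_set = {v.rsid for v in variants}

        drug_names = [d["name"] for d in cfg["drugs"]]
        if len(set(drug_names)) != len(drug_names):
            raise PanelLoadError("duplicate drug name in panel config")
        drugs = tuple(
            sorted(
                (DrugDef(name=d["name"], atc_or_class=d.get("atc_or_class")) for d in cfg["drugs"]),
                key=lambda d: d.name,
            )
        )
        drug_set = {d.name for d in drugs}

        el_scores = {str(k): int(v) for k, v in cfg.get("el_scores", DEFAULT_EL_SCORES).items()}
        ordered = [el_scores.get(lv) for lv in EVIDENCE_LEVELS]
        if any(s is None for s in ordered):
            raise PanelLoadError("el_scores must cover all of 1A, 1B, 2A, 2B, 3")
        if not all(a > b for a, b in zip(ordered, ordered[1:])) or ordered[-1] <= 0:
            raise PanelLoadError(
                "el_scores must be strictly decreasing across 1A>1B>2A>2B>3 and positive"
            )

        star_seen: set[tuple[str, str]] = set()
        star_rules = []
        for r in cfg.get("star_alleles", []):
            key = (r["gene"], r["star"])
            if key in star_seen:
                raise PanelLoadError(f"star allele {r['star']} defined twice for {r['gene']}")
            star_seen.add(key)
            if not r["defining"]:
                raise PanelLoadError(f"star allele {r['star']} ({r['gene']}) has no defining rsids")
            for rs in (*r["defining"], *r.get("absorbs", []), *r.get("excludes", [])):
                if rs not in rsid_set:
                    raise PanelLoadError(f"star allele {r['star']} references unknown rsid {rs}")
            star_rules.append(
                StarAlleleRule(
                    gene=r["gene"],
                    star=r["star"],
                    defining_rsids=tuple(r["defining"]),
                    absorbed_rsids=tuple(r.get("absorbs", [])),
                    excluded_rsids=tuple(r.get("excludes", [])),
                )
            )
        star_rules = tuple(star_rules)

        phen_rules = []
        for r in cfg.get("phenotype_rules", []):
            if r["gene"] not in gene_set:
                raise PanelLoadError(f"phenotype rule references unknown gene {r['gene']}")
            phen_rules.append(
                PhenotypeRule(
                    gene=r["gene"], diplotype_pattern=r["pattern"], phenotype=r["phenotype"]
                )
            )
        phen_rules = tuple(phen_rules)

        advice_templates = dict(cfg.get("advice_templates", {}))

        associations: list[AssociationRule] = []
        for entry in cfg.get("associations", []):
            if "trigger" in entry:
                associations.append(_explicit_association(entry, el_scores))
            else:
                associations.extend(_expand_association_family(entry, el_scores))
        for a in associations:
            if a.drug not in drug_set:
                raise PanelLoadError(f"association {a.rule_id} references unknown drug {a.drug}")
            if a.gene not in gene_set:
                raise PanelLoadError(f"association {a.rule_id} references unknown gene {a.gene}")
            if a.trigger.kind == "genotype" and a.trigger.rsid not in rsid_set:
                raise PanelLoadError(
                    f"association {a.rule_id} references unknown rsid {a.trigger.rsid}"
                )
            if a.advisory not in ADVISORIES:
                raise PanelLoadError(f"association {a.rule_id}: unknown advisory {a.advisory!r}")
            if a.advice_key is not None and a.advice_key not in advice_templates:
                raise PanelLoadError(
                    f"association {a.rule_id}: advice key {a.advice_key!r} has no template"
                )
        associations.sort(key=lambda a: (a.drug, a.rule_id))

        allele_function = {g: dict(m) for g, m in cfg.get("allele_function", {}).items()}
        cis_pairs = tuple(tuple(p) for p in cfg.get("cis_pairs", []))
        for p in cis_pairs:
            if len(p) != 2 or any(rs not in rsid_set for rs in p):
                raise PanelLoadError(f"bad cis pair {p}")

        return PanelDefinition(
            name=meta["name"],
            version=str(meta["version"]),
            variants=variants,
            genes=genes,
            drugs=drugs,
            star_rules=star_rules,
            phenotype_rules=phen_rules,
            associations=tuple(associations),
            advice_templates=advice_templates,
            el_scores=el_scores,
            allele_function=allele_function,
            cis_pairs=cis_pairs,
        )
    except PanelLoadError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelLoadError(f"malformed panel config: {exc}") from exc


def load_panel(path: str | Path) -> PanelDefinition:
    """Load and validate a panel configuration file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PanelLoadError(f"panel config {path} did not parse to a mapping")
    return panel_from_dict(cfg)


def builtin_demo_panel() -> PanelDefinition:
    """The bundled demo PGx-CNS panel: 24 SNPs / 13 genes / 28 drugs."""
    ref = importlib.resources.files("pgxcns.data") / "panel_pgx_cns_demo.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return panel_from_dict(cfg)
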
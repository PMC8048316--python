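"""Cohort genotype containers and readers.

Two input routes are supported: a wide TSV genotype table (one row per
sample, one column per panel rsid holding two-letter genotypes such as
``AG``) and standard VCF with GT fields.  Both are normalized to alt-allele
dosages (0/1/2) against the panel's ref/alt definitions; missingness is kept
explicit and never silently coerced to the reference genotype.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import AlleleMismatchError, GenotypeParseError
from .panel import PanelDefinition, VariantDef

MISSING_TOKENS = {"--", "NA", "", ".", "./.", "nan"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "D": "D"}

#: dosage value used for an explicit missing call
MISSING: Optional[int] = None


def _is_strand_ambiguous(variant: VariantDef) -> bool:
    """A/T and C/G SNPs read identically on both strands; flips there are
    undetectable, so they are never attempted."""
    pair = {variant.ref_allele, variant.alt_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


def normalize_call(raw: str, variant: VariantDef) -> Optional[int]:
    """Convert a two-letter genotype string to an alt-allele dosage.

    Returns None for a missing token.  When neither observed allele matches
    the panel ref/alt pair, reverse-complement reconciliation is attempted,
    except at strand-ambiguous (A/T, C/G) sites where a mismatch is a hard
    error.
    """
    raw = str(raw).strip()
    if raw in MISSING_TOKENS:
        return None
    if len(raw) != 2:
        raise GenotypeParseError(
            f"{variant.rsid}: genotype string {raw!r} is not two allele tokens"
        )
    alleles = [raw[0].upper(), raw[1].upper()]
    valid = {variant.ref_allele, variant.alt_allele}
    if not set(alleles) <= valid:
        if _is_strand_ambiguous(variant) or not all(a in _COMPLEMENT for a in alleles):
            raise AlleleMismatchError(
                f"{variant.rsid}: observed alleles {raw!r} do not match "
                f"panel alleles {variant.ref_allele}/{variant.alt_allele}"
            )
        flipped = [_COMPLEMENT[a] for a in alleles]
        if not set(flipped) <= valid:
            raise AlleleMismatchError(
                f"{variant.rsid}: observed alleles {raw!r} cannot be reconciled "
                f"with panel alleles {variant.ref_allele}/{variant.alt_allele} "
                "(tried reverse complement)"
            )
        alleles = flipped
    return sum(a == variant.alt_allele for a in alleles)


@dataclasses.dataclass(frozen=True)
class GenotypeCall:
    rsid: str
    dosage: Optional[int]  # 0/1/2 or None for missing

    def __post_init__(self) -> None:
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0/1/2 or None, got {self.dosage}")


@dataclasses.dataclass
class SampleGenotypes:
    sample_id: str
    calls: dict[str, Optional[int]]  # rsid -> dosage (None = missing)
    age_years: Optional[int] = None
    sex: Optional[str] = None  # "male" / "female"

    def __post_init__(self) -> None:
        if self.age_years is not None and not 0 <= self.age_years <= 120:
            raise ValueError(f"age {self.age_years} outside [0, 120]")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")

    def dosage(self, rsid: str) -> Optional[int]:
        return self.calls.get(rsid)


@dataclasses.dataclass
class CohortGenotypes:
    samples: list[SampleGenotypes]
    panel_version: str = ""

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def sample(self, sample_id: str) -> SampleGenotypes:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def dosages(self, rsid: str) -> list[Optional[int]]:
        return [s.dosage(rsid) for s in self.samples]


# ---------------------------------------------------------------------------
# wide genotype table

_META_COLUMNS = {"sample_id", "age", "sex"}


def read_genotype_table(path: str | Path, panel: PanelDefinition) -> CohortGenotypes:
    """Read a wide TSV genotype table.

    Header contract: a ``sample_id`` column, optional ``age`` and ``sex``
    metadata columns, and one column per panel rsid with two-letter genotypes
    (``--``/``NA`` for missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise GenotypeParseError(f"{path}: missing required sample_id column")
    unknown = [c for c in df.columns if c not in _META_COLUMNS and c not in set(panel.rsids)]
    if unknown:
        raise GenotypeParseError(f"{path}: columns not in panel: {', '.join(unknown)}")
    rsid_cols = [c for c in df.columns if c not in _META_COLUMNS]

    samples = []
    for _, row in df.iterrows():
        calls: dict[str, Optional[int]] = {}
        for rsid in rsid_cols:
            try:
                calls[rsid] = normalize_call(row[rsid], panel.variant(rsid))
            except GenotypeParseError as exc:
                raise GenotypeParseError(f"sample {row['sample_id']}: {exc}") from exc
        age = row.get("age")
        sex = row.get("sex")
        samples.append(
            SampleGenotypes(
                sample_id=row["sample_id"],
                calls=calls,
                age_years=int(age) if age not in (None, "", "NA") else None,
                sex=sex if sex not in (None, "", "NA") else None,
            )
        )
    return CohortGenotypes(samples=samples, panel_version=f"{panel.name}/{panel.version}")


def write_genotype_table(
    cohort: CohortGenotypes, path: str | Path, panel: PanelDefinition
) -> None:
    """Canonical wide-TSV writer (inverse of :func:`read_genotype_table`)."""
    rows = []
    for s in cohort:
        row: dict[str, str] = {"sample_id": s.sample_id}
        row["age"] = "" if s.age_years is None else str(s.age_years)
        row["sex"] = "" if s.sex is None else s.sex
        for v in panel.variants:
            d = s.dosage(v.rsid)
            if d is None:
                row[v.rsid] = "--"
            else:
                alleles = [v.ref_allele] * (2 - d) + [v.alt_allele] * d
                row[v.rsid] = "".join(alleles)
        rows.append(row)
    cols = ["sample_id", "age", "sex", *[v.rsid for v in panel.variants]]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, panel: PanelDefinition) -> CohortGenotypes:
    """Read panel genotypes from a VCF (v4.x) with GT fields.

    Records are matched to panel sites by ID primarily, falling back to
    position is not attempted (the panel is rsid-keyed).  Ref/alt swapped
    records are reconciled by inverting the dosage; unreconcilable or
    multiallelic sites are per-site errors.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    calls: dict[str, dict[str, Optional[int]]] = {sid: {} for sid in sample_ids}
    panel_rsids = set(panel.rsids)

    for rec in vcf:
        rsid = rec.ID
        if rsid is None or rsid not in panel_rsids:
            continue
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"{rsid}: multiallelic records are not supported by the panel"
            )
        variant = panel.variant(rsid)
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if (ref, alt) == (variant.ref_allele, variant.alt_allele):
            flip = False
        elif (ref, alt) == (variant.alt_allele, variant.ref_allele):
            flip = True  # swapped report: dosage = 2 - raw
        else:
            raise AlleleMismatchError(
                f"{rsid}: VCF alleles {ref}/{alt} do not match panel "
                f"{variant.ref_allele}/{variant.alt_allele}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sid, gt in zip(sample_ids, rec.gt_types):
            if gt == 2:
                calls[sid][rsid] = None
            else:
                raw = {0: 0, 1: 1, 3: 2}[gt]
                calls[sid][rsid] = 2 - raw if flip else raw

    samples = [SampleGenotypes(sample_id=sid, calls=calls[sid]) for sid in sample_ids]
    return CohortGenotypes(samples=samples, panel_version=f"{panel.name}/{panel.version}")


def cohort_from_dosages(
    dosage_rows: Iterable[tuple[str, dict[str, Optional[int]]]],
    panel: PanelDefinition,
) -> CohortGenotypes:
    """Build a cohort directly from (sample_id, rsid->dosage) pairs."""
    samples = [SampleGenotypes(sample_id=sid, calls=dict(d)) for sid, d in dosage_rows]
    return CohortGenotypes(samples=samples, panel_version=f"{panel.name}/{panel.version}")
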
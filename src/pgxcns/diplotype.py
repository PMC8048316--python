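"""Star-allele diplotype calling from unphased panel-SNP dosages.

Each CYP gene's star alleles are defined by the alt alleles of one or two
panel SNPs.  A diplotype call enumerates every haplotype pair whose per-SNP
alt-allele sums equal the observed dosages, maps each haplotype to a star
allele, and selects a preferred candidate:

* unphased double heterozygotes at two different star-defining SNPs resolve
  in trans (two single-variant haplotypes) — the only decompositions in which
  every haplotype maps cleanly to one star;
* declared cis pairs (rs3892097 + rs1065852 for CYP2D6*4) resolve in cis:
  both alt alleles are placed on one haplotype, which the containment rule
  maps to *4, leaving the other haplotype *1.

Missing calls at defining SNPs are handled conservatively: if every possible
completion of the missing dosages yields the same diplotype the call stands;
otherwise the reference-completion call is returned flagged ``ambiguous``
with the missing sites listed in ``unresolved_sites``.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional

from .errors import InconsistentGenotypeError
from .genotypes import SampleGenotypes
from .panel import PanelDefinition, StarAlleleRule


def star_number(star: str) -> int:
    return int(star.lstrip("*"))


@dataclasses.dataclass(frozen=True, order=True)
class Diplotype:
    gene: str
    allele_a: str
    allele_b: str
    ambiguous: bool = False
    unresolved_sites: tuple[str, ...] = ()

    @property
    def pair(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def pattern(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.gene} {self.pattern}"


def _ordered_pair(star_x: str, star_y: str) -> tuple[str, str]:
    return tuple(sorted((star_x, star_y), key=star_number))  # type: ignore[return-value]


def _assign_star(alt_set: frozenset[str], rules: tuple[StarAlleleRule, ...]) -> Optional[str]:
    """Map one haplotype's alt-allele set to a star name, or None when the
    set matches no single star cleanly (multi-star haplotype)."""
    if not alt_set:
        return "*1"
    matches = []
    for r in rules:
        if not set(r.defining_rsids) <= alt_set:
            continue
        if set(r.excluded_rsids) & alt_set:
            continue
        leftover = alt_set - set(r.defining_rsids) - set(r.absorbed_rsids)
        if leftover:
            continue
        matches.append(r.star)
    if len(matches) == 1:
        return matches[0]
    return None


def _phase_candidates(
    dosages: dict[str, int], rules: tuple[StarAlleleRule, ...]
) -> list[tuple[frozenset[str], frozenset[str], str, str]]:
    """All phase decompositions whose haplotypes map cleanly to stars."""
    hom = {rs for rs, d in dosages.items() if d == 2}
    het = sorted(rs for rs, d in dosages.items() if d == 1)
    out = []
    seen: set[tuple[frozenset, frozenset]] = set()
    for assignment in itertools.product((0, 1), repeat=len(het)):
        hap_a = frozenset(hom | {rs for rs, side in zip(het, assignment) if side == 0})
        hap_b = frozenset(hom | {rs for rs, side in zip(het, assignment) if side == 1})
        key = (hap_a, hap_b) if sorted(hap_a) <= sorted(hap_b) else (hap_b, hap_a)
        if key in seen:
            continue
        seen.add(key)
        star_a = _assign_star(key[0], rules)
        star_b = _assign_star(key[1], rules)
        if star_a is None or star_b is None:
            continue
        out.append((key[0], key[1], star_a, star_b))
    return out


def enumerate_consistent_diplotypes(
    dosages: dict[str, int], rules: tuple[StarAlleleRule, ...], gene: str
) -> set[Diplotype]:
    """Brute-force oracle: every diplotype consistent with the observed
    dosages under the star rules.  Raises when no haplotype pair exists in
    which each haplotype maps to a single star."""
    cands = _phase_candidates(dosages, rules)
    if not cands:
        raise InconsistentGenotypeError(
            f"{gene}: dosages {dict(sorted(dosages.items()))} admit no "
            "haplotype pair mapping cleanly onto the panel star alleles"
        )
    out = set()
    for _, _, star_a, star_b in cands:
        a, b = _ordered_pair(star_a, star_b)
        out.add(Diplotype(gene=gene, allele_a=a, allele_b=b))
    return out


def _call_concrete(
    dosages: dict[str, int], panel: PanelDefinition, gene: str
) -> tuple[Diplotype, bool]:
    """Diplotype for fully observed dosages; returns (call, ambiguous)."""
    rules = panel.star_rules_for(gene)
    cands = _phase_candidates(dosages, rules)
    if not cands:
        raise InconsistentGenotypeError(
            f"{gene}: dosages {dict(sorted(dosages.items()))} admit no "
            "haplotype pair mapping cleanly onto the panel star alleles"
        )
    cis = panel.cis_pairs_for(gene)

    def pref_key(c):
        hap_a, hap_b, star_a, star_b = c
        cis_hits = sum(
            1
            for x, y in cis
            if dosages.get(x, 0) >= 1
            and dosages.get(y, 0) >= 1
            and (({x, y} <= hap_a) or ({x, y} <= hap_b))
        )
        n_variant_haps = (len(hap_a) > 0) + (len(hap_b) > 0)
        # deterministic final tie-break on the star pair itself
        return (-cis_hits, -n_variant_haps, _ordered_pair(star_a, star_b))

    ranked = sorted(cands, key=pref_key)
    best = ranked[0]
    best_key = pref_key(best)[:2]
    best_pair = _ordered_pair(best[2], best[3])
    ambiguous = any(
        pref_key(c)[:2] == best_key and _ordered_pair(c[2], c[3]) != best_pair
        for c in ranked[1:]
    )
    return Diplotype(gene=gene, allele_a=best_pair[0], allele_b=best_pair[1]), ambiguous


def call_diplotype(
    sample: SampleGenotypes, gene: str, panel: PanelDefinition
) -> Diplotype:
    """Infer the star-allele diplotype of ``gene`` for one sample."""
    rsids = panel.defining_rsids(gene)
    if not rsids:
        raise ValueError(f"{gene} has no star-allele system in panel {panel.name}")
    dosages = {rs: sample.dosage(rs) for rs in rsids}
    missing = sorted(rs for rs, d in dosages.items() if d is None)
    if not missing:
        dip, ambiguous = _call_concrete({rs: d for rs, d in dosages.items()}, panel, gene)
        return dataclasses.replace(dip, ambiguous=ambiguous)

    observed = {rs: d for rs, d in dosages.items() if d is not None}
    results: list[tuple[tuple[int, ...], Diplotype]] = []
    for completion in itertools.product((0, 1, 2), repeat=len(missing)):
        full = dict(observed)
        full.update(dict(zip(missing, completion)))
        try:
            dip, amb = _call_concrete(full, panel, gene)
        except InconsistentGenotypeError:
            continue
        if not amb:
            results.append((completion, dip))
        else:
            results.append((completion, dataclasses.replace(dip, ambiguous=True)))
    if not results:
        raise InconsistentGenotypeError(
            f"{gene}: no completion of missing sites {missing} is consistent"
        )
    pairs = {d.pair for _, d in results}
    if len(pairs) == 1 and not any(d.ambiguous for _, d in results):
        # the missing sites cannot change the call
        d = results[0][1]
        return dataclasses.replace(d, unresolved_sites=tuple(missing))
    # prefer the reference (all-zero) completion when available
    zero = tuple(0 for _ in missing)
    chosen = next((d for c, d in results if c == zero), results[0][1])
    return dataclasses.replace(chosen, ambiguous=True, unresolved_sites=tuple(missing))
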
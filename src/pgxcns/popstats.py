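"""Cohort-vs-reference genotype frequency comparisons.

For every panel variant the cohort's genotype-class counts (ref-hom, het,
alt-hom) are compared to a reference population's counts in a 2x3 table with
Pearson's chi-square (df = 2) and Cramer's V.  When the chi-square sampling
adequacy rule is violated (fewer than 80% of expected cells >= 5, or any
expected cell exactly 0) the Freeman-Halton exact test of independence is
computed instead.  P-values across the whole family of comparisons are
adjusted with the Holm-Bonferroni procedure.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateTableError
from .genotypes import CohortGenotypes
from .panel import PanelDefinition

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


@dataclasses.dataclass(frozen=True)
class GenotypeCountTable:
    variant: str
    row_labels: tuple[str, str]
    counts: tuple[tuple[int, int, int], tuple[int, int, int]]

    @property
    def n(self) -> int:
        return int(sum(sum(r) for r in self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclasses.dataclass(frozen=True)
class FrequencyComparison:
    variant: str
    populations: tuple[str, str]
    chi2: float
    df: int
    p_raw: float
    cramers_v: float
    strength: str  # weak / moderate / strong
    test_used: str  # chi_square / fisher_exact
    adequacy_violated: bool
    p_adjusted: Optional[float] = None


def genotype_counts(cohort: CohortGenotypes, variant: str) -> tuple[tuple[int, int, int], int]:
    """Counts of dosage 0/1/2 at a variant; missing calls are excluded from
    the tally and returned separately."""
    c = [0, 0, 0]
    missing = 0
    for d in cohort.dosages(variant):
        if d is None:
            missing += 1
        else:
            c[d] += 1
    return (c[0], c[1], c[2]), missing


def _strength(v: float) -> str:
    if v >= 0.35:
        return "strong"
    if v > 0.20:
        return "moderate"
    return "weak"


def freeman_halton_p(
    table: np.ndarray, max_states: int = 10_000_000, n_mc: int = 100_000, seed: int = 0
) -> float:
    """Exact (Freeman-Halton) test of independence for a 2xC table.

    P-value = total probability, under fixed margins, of tables whose
    hypergeometric probability does not exceed the observed one.  Enumerates
    the margin-bounded state space when it is small enough, otherwise falls
    back to seeded Patefield Monte Carlo sampling.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ValueError("freeman_halton_p implements 2xC tables")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())

    def log_prob(first_row: np.ndarray) -> float:
        second = col - first_row
        return (
            gammaln(row + 1).sum()
            + gammaln(col + 1).sum()
            - gammaln(n + 1)
            - gammaln(first_row + 1).sum()
            - gammaln(second + 1).sum()
        )

    obs_lp = log_prob(t[0])
    bounds = np.minimum(row[0], col)
    n_states = int(np.prod(bounds + 1))
    if n_states <= max_states:
        total = 0.0
        tol = 1e-9

        def recurse(idx: int, remaining: int, prefix: list[int]) -> None:
            nonlocal total
            if idx == len(col) - 1:
                if remaining <= col[idx]:
                    fr = np.array(prefix + [remaining])
                    lp = log_prob(fr)
                    if lp <= obs_lp + tol:
                        total += math.exp(lp)
                return
            for v in range(min(remaining, col[idx]) + 1):
                recurse(idx + 1, remaining - v, prefix + [v])

        recurse(0, int(row[0]), [])
        return min(1.0, total)

    rng = np.random.default_rng(seed)
    dist = stats.random_table(row, col, seed=rng)
    samples = dist.rvs(n_mc, method="patefield").astype(int)
    lps = np.array([log_prob(s[0]) for s in samples])
    return float((np.sum(lps <= obs_lp + 1e-9) + 1) / (n_mc + 1))


def compare_populations(table: GenotypeCountTable, seed: int = 0) -> FrequencyComparison:
    """Pearson chi-square / Freeman-Halton comparison of one 2x3 table."""
    arr = table.as_array()
    if (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"{table.variant}: zero row margin")
    n = arr.sum()
    df = 2  # 2x3 genotype-class design
    if (arr.sum(axis=0) > 0).sum() < 2:
        # both populations monomorphic in the same genotype class: the rows
        # are proportionally identical and independence holds trivially
        return FrequencyComparison(
            variant=table.variant,
            populations=table.row_labels,
            chi2=0.0,
            df=df,
            p_raw=1.0,
            cramers_v=0.0,
            strength="weak",
            test_used="fisher_exact",
            adequacy_violated=True,
        )

    # textbook Pearson statistic; cells in an empty genotype column have
    # expected count 0 and contribute nothing (the adequacy rule routes such
    # tables to the exact test regardless)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (arr - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    cramers_v = math.sqrt(chi2 / (n * (min(arr.shape) - 1)))

    adequacy_violated = bool((expected >= 5).mean() < 0.8 or (expected == 0).any())
    if adequacy_violated:
        keep = arr.sum(axis=0) > 0
        p = freeman_halton_p(arr[:, keep], seed=seed)
        test_used = "fisher_exact"
    else:
        p = float(stats.chi2.sf(chi2, df))
        test_used = "chi_square"
    return FrequencyComparison(
        variant=table.variant,
        populations=table.row_labels,
        chi2=float(chi2),
        df=df,
        p_raw=p,
        cramers_v=float(cramers_v),
        strength=_strength(cramers_v),
        test_used=test_used,
        adequacy_violated=adequacy_violated,
    )


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = min(1.0, (m - i) * p[idx])
        running = max(running, val)
        adjusted[idx] = running
    return adjusted.tolist()


# ---------------------------------------------------------------------------
# reference populations


@dataclasses.dataclass(frozen=True)
class ReferencePopulation:
    name: str
    counts: dict[str, tuple[int, int, int]]  # rsid -> (hom_ref, het, hom_alt)


def hwe_counts(alt_freq: float, n: int) -> tuple[int, int, int]:
    """Integer genotype counts for allele frequency q under Hardy-Weinberg,
    rounded to nearest with a largest-remainder fix so they sum to n."""
    q = float(alt_freq)
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    raw = probs * n
    base = np.floor(raw + 0.5).astype(int)
    diff = n - base.sum()
    if diff != 0:
        # push the correction onto the cell(s) with the largest rounding error
        err = raw - base
        order = np.argsort(-err if diff > 0 else err)
        for k in range(abs(int(diff))):
            base[order[k % 3]] += 1 if diff > 0 else -1
    return int(base[0]), int(base[1]), int(base[2])


def load_reference_populations(path: str | Path) -> list[ReferencePopulation]:
    """Read reference genotype tables from TSV.

    Two input modes per row, labelled by the available columns: explicit
    genotype counts (``hom_ref``, ``het``, ``hom_alt``) or an allele
    frequency expanded under HWE (``alt_freq`` x ``sample_size``).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    pops = []
    for name, grp in df.groupby("population", sort=True):
        counts: dict[str, tuple[int, int, int]] = {}
        for _, row in grp.iterrows():
            if {"hom_ref", "het", "hom_alt"} <= set(grp.columns) and not pd.isna(
                row.get("hom_ref")
            ):
                counts[row["rsid"]] = (int(row["hom_ref"]), int(row["het"]), int(row["hom_alt"]))
            else:
                counts[row["rsid"]] = hwe_counts(float(row["alt_freq"]), int(row["sample_size"]))
        pops.append(ReferencePopulation(name=str(name), counts=counts))
    return pops


def run_comparison_suite(
    cohort: CohortGenotypes,
    references: list[ReferencePopulation],
    panel: PanelDefinition,
    cohort_label: str = "cohort",
    alpha: float = 0.05,
    seed: int = 0,
) -> list[FrequencyComparison]:
    """All variant x reference comparisons with family-wide Holm adjustment.

    References missing a variant reduce the family size accordingly; output
    is ordered by rsid then population name.
    """
    comparisons: list[FrequencyComparison] = []
    for rsid in panel.rsids:
        cohort_counts, _ = genotype_counts(cohort, rsid)
        for ref in sorted(references, key=lambda r: r.name):
            if rsid not in ref.counts:
                continue
            table = GenotypeCountTable(
                variant=rsid,
                row_labels=(cohort_label, ref.name),
                counts=(cohort_counts, ref.counts[rsid]),
            )
            comparisons.append(compare_populations(table, seed=seed))
    adjusted = holm_bonferroni([c.p_raw for c in comparisons])
    comparisons = [
        dataclasses.replace(c, p_adjusted=adj) for c, adj in zip(comparisons, adjusted)
    ]
    comparisons.sort(key=lambda c: (c.variant, c.populations[1]))
    return comparisons


def comparisons_to_frame(comparisons: list[FrequencyComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rsid": c.variant,
                "population": c.populations[1],
                "chi2": c.chi2,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "cramers_v": c.cramers_v,
                "strength": c.strength,
                "test_used": c.test_used,
                "adequacy_violated": c.adequacy_violated,
            }
            for c in comparisons
        ]
    )
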
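"""Synthetic cohort generation and the bundled clinical case fixtures.

Genotypes are drawn per variant under Hardy-Weinberg equilibrium at
configurable alt-allele frequencies: each of a sample's two haplotypes
carries the alt allele independently with probability q, giving genotype
probabilities (1-q)^2, 2q(1-q), q^2.  An optional co-occurrence knob
correlates chosen variant pairs through a Gaussian-copula threshold scheme
on the haplotype level (to plant the kind of carrier co-occurrence structure
the MCA module is meant to detect).  Age and sex metadata follow a
configurable band distribution; defaults mirror a CNS-patient cohort
(bands 0-20 / 21-40 / 41-60 / 61-80 / 81-100 at 4.0 / 32.7 / 36.5 / 22.4 /
4.4%, 45.1% male).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import CohortGenotypes, SampleGenotypes
from .panel import PanelDefinition

AGE_BANDS = ((0, 20), (21, 40), (41, 60), (61, 80), (81, 100))
DEFAULT_AGE_BAND_PROBS = (20 / 501, 164 / 501, 183 / 501, 112 / 501, 22 / 501)
DEFAULT_SEX_PROBS = (226 / 501, 275 / 501)  # male, female


@dataclasses.dataclass(frozen=True)
class FrequencyProfile:
    name: str
    alt_freqs: dict[str, float]

    def __post_init__(self) -> None:
        bad = {rs: q for rs, q in self.alt_freqs.items() if not 0.0 <= q <= 1.0}
        if bad:
            raise ValueError(f"allele frequencies outside [0,1]: {bad}")


@dataclasses.dataclass
class SimulationConfig:
    n_samples: int
    profile: FrequencyProfile
    seed: int
    age_band_probs: Sequence[float] = DEFAULT_AGE_BAND_PROBS
    sex_probs: Sequence[float] = DEFAULT_SEX_PROBS
    #: optional (rsid, rsid, rho) triples correlating haplotype alt carriage
    correlated_pairs: Sequence[tuple[str, str, float]] = ()

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for probs, label in ((self.age_band_probs, "age"), (self.sex_probs, "sex")):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities must sum to 1")


def load_frequency_profile(path: str | Path, name: Optional[str] = None) -> FrequencyProfile:
    """Read a frequency profile TSV with columns rsid, alt_freq (optionally
    population to select among several)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if name is not None and "population" in df.columns:
        df = df[df["population"] == name]
        if df.empty:
            raise ValueError(f"population {name!r} not found in {path}")
    return FrequencyProfile(
        name=name or "profile",
        alt_freqs=dict(zip(df["rsid"], df["alt_freq"].astype(float))),
    )


def demo_frequency_profiles() -> dict[str, FrequencyProfile]:
    """The bundled demo continental profiles (plausible but non-authoritative
    values written for testing)."""
    ref = importlib.resources.files("pgxcns.data") / "demo_population_frequencies.tsv"
    import io

    df = pd.read_csv(io.StringIO(ref.read_text()), sep="\t", comment="#")
    out = {}
    for pop, grp in df.groupby("population"):
        out[str(pop)] = FrequencyProfile(
            name=str(pop), alt_freqs=dict(zip(grp["rsid"], grp["alt_freq"].astype(float)))
        )
    return out


def simulate_cohort(cfg: SimulationConfig, panel: PanelDefinition) -> CohortGenotypes:
    """Draw a fully reproducible HWE cohort with age/sex metadata."""
    rng = np.random.default_rng(cfg.seed)
    rsids = [v.rsid for v in panel.variants]
    missing_freqs = [rs for rs in rsids if rs not in cfg.profile.alt_freqs]
    if missing_freqs:
        raise ValueError(f"profile {cfg.profile.name} lacks frequencies for: {missing_freqs}")
    q = np.array([cfg.profile.alt_freqs[rs] for rs in rsids])
    n, v = cfg.n_samples, len(rsids)

    # haplotype-level Gaussian copula: latent z per haplotype, alt allele when
    # z < Phi^-1(q); identity correlation except for configured pairs
    corr = np.eye(v)
    idx = {rs: i for i, rs in enumerate(rsids)}
    for a, b, rho in cfg.correlated_pairs:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    thresholds = norm.ppf(q)
    if np.allclose(corr, np.eye(v)):
        z = rng.standard_normal((2, n, v))
    else:
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((2, n, v)) @ chol.T
    dosage = (z < thresholds).sum(axis=0).astype(int)  # (n, v)

    band_idx = rng.choice(len(AGE_BANDS), size=n, p=np.asarray(cfg.age_band_probs))
    ages = np.array(
        [rng.integers(AGE_BANDS[b][0], AGE_BANDS[b][1] + 1) for b in band_idx]
    )
    sexes = rng.choice(["male", "female"], size=n, p=np.asarray(cfg.sex_probs))

    width = len(str(n))
    samples = [
        SampleGenotypes(
            sample_id=f"sim{str(i + 1).zfill(width)}",
            calls={rs: int(dosage[i, j]) for j, rs in enumerate(rsids)},
            age_years=int(ages[i]),
            sex=str(sexes[i]),
        )
        for i in range(n)
    ]
    return CohortGenotypes(samples=samples, panel_version=f"{panel.name}/{panel.version}")


# ---------------------------------------------------------------------------
# clinical case fixtures

# Genotypes exactly as printed for the four worked clinical cases; panel
# sites not stated in the text are set to the reference genotype.
_CASE_GENOTYPES = {
    "case_a": {"rs1799978": "TT", "rs1800497": "GG", "rs4244285": "AA"},
    "case_b": {"rs1414334": "CG", "rs17782313": "CT"},
    "case_c": {
        "rs4244285": "AG",
        "rs28399504": "AA",
        "rs12248560": "CT",
        "rs4713916": "GG",
    },
    "case_d": {
        "rs4244285": "AG",
        "rs4986893": "GG",
        "rs28399504": "AA",
        "rs12248560": "CC",
        "rs3892097": "CT",
        "rs1065852": "AG",
        "rs4713916": "AA",
    },
}
_CASE_META = {
    "case_a": (19, "male"),
    "case_b": (30, "female"),
    "case_c": (56, "female"),
    "case_d": (49, "male"),
}


def clinical_case_fixtures(panel: PanelDefinition) -> CohortGenotypes:
    """The four worked clinical cases as a 4-sample cohort."""
    from .genotypes import normalize_call

    samples = []
    for case_id in sorted(_CASE_GENOTYPES):
        stated = _CASE_GENOTYPES[case_id]
        calls = {}
        for variant in panel.variants:
            if variant.rsid in stated:
                calls[variant.rsid] = normalize_call(stated[variant.rsid], variant)
            else:
                calls[variant.rsid] = 0
        age, sex = _CASE_META[case_id]
        samples.append(
            SampleGenotypes(sample_id=case_id, calls=calls, age_years=age, sex=sex)
        )
    return CohortGenotypes(samples=samples, panel_version=f"{panel.name}/{panel.version}")


# ---------------------------------------------------------------------------
# metadata summaries


def cohort_metadata_summary(cohort: CohortGenotypes) -> pd.DataFrame:
    """Counts and percentages per age band and sex (one decimal)."""
    n = len(cohort)
    rows = []
    for lo, hi in AGE_BANDS:
        count = sum(
            1 for s in cohort if s.age_years is not None and lo <= s.age_years <= hi
        )
        rows.append(("age", f"{lo}-{hi}", count))
    rows.append(("age", "unknown", sum(1 for s in cohort if s.age_years is None)))
    for sex in ("male", "female"):
        rows.append(("sex", sex, sum(1 for s in cohort if s.sex == sex)))
    rows.append(("sex", "unknown", sum(1 for s in cohort if s.sex is None)))
    df = pd.DataFrame(rows, columns=["factor", "band", "count"])
    df = df[(df["band"] != "unknown") | (df["count"] > 0)].reset_index(drop=True)
    df["percent"] = (
        (100.0 * df["count"] / n).round(1) if n else 0.0
    )
    return df if n else df.iloc[0:0]


def metadata_summary_from_counts(
    age_band_counts: Sequence[int], male_count: int, n: int
) -> pd.DataFrame:
    """Summary table directly from printed band counts (no cohort needed)."""
    rows = [
        ("age", f"{lo}-{hi}", c) for (lo, hi), c in zip(AGE_BANDS, age_band_counts)
    ]
    rows.append(("sex", "male", male_count))
    rows.append(("sex", "female", n - male_count))
    df = pd.DataFrame(rows, columns=["factor", "band", "count"])
    df["percent"] = (100.0 * df["count"] / n).round(1)
    return df
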
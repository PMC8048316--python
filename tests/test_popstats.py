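"""Contingency statistics: chi-square, Cramer's V, exact test, Holm."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pgxcns.errors import DegenerateTableError
from pgxcns.genotypes import CohortGenotypes, SampleGenotypes
from pgxcns.popstats import (
    GenotypeCountTable,
    ReferencePopulation,
    compare_populations,
    freeman_halton_p,
    genotype_counts,
    holm_bonferroni,
    hwe_counts,
    run_comparison_suite,
)
from pgxcns.simulate import SimulationConfig, simulate_cohort


def _table(counts, variant="rsX"):
    return GenotypeCountTable(
        variant=variant, row_labels=("cohort", "ref"), counts=tuple(map(tuple, counts))
    )


def _random_tables(n, rng, low=0, high=60):
    for _ in range(n):
        t = rng.integers(low, high, size=(2, 3))
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) > 0).sum() < 2:
            continue
        yield t


def test_genotype_counts_tally(panel):
    zeros = {rs: 0 for rs in panel.rsids}
    dosages = [0, 0, 1, 2, None]
    cohort = CohortGenotypes(
        samples=[
            SampleGenotypes(sample_id=f"s{i}", calls={**zeros, "rs4244285": d})
            for i, d in enumerate(dosages)
        ]
    )
    counts, missing = genotype_counts(cohort, "rs4244285")
    assert counts == (2, 1, 1)
    assert missing == 1


def test_proportional_rows_give_null_result():
    c = compare_populations(_table([[10, 20, 30], [20, 40, 60]]))
    assert c.chi2 == pytest.approx(0.0, abs=1e-12)
    assert c.cramers_v == pytest.approx(0.0, abs=1e-12)
    assert c.p_raw == pytest.approx(1.0)


def test_textbook_chi_square_hand_computation():
    # independent evaluation of sum (O-E)^2 / E over the 2x3 table
    obs = [[10, 20, 70], [30, 30, 40]]
    n = 200
    row = [100, 100]
    col = [40, 50, 110]
    chi2 = 0.0
    for i in range(2):
        for j in range(3):
            e = row[i] * col[j] / n
            chi2 += (obs[i][j] - e) ** 2 / e
    c = compare_populations(_table(obs))
    assert c.chi2 == pytest.approx(chi2, rel=1e-12)
    assert c.cramers_v == pytest.approx((chi2 / n) ** 0.5, rel=1e-12)
    assert c.df == 2


def test_df_is_two_for_all_tables():
    rng = np.random.default_rng(0)
    for t in _random_tables(200, rng):
        assert compare_populations(_table(t)).df == 2


def test_cramers_v_identity_and_scaling():
    rng = np.random.default_rng(1)
    for t in _random_tables(50, rng, low=1):
        c = compare_populations(_table(t))
        assert c.cramers_v == pytest.approx((c.chi2 / t.sum()) ** 0.5, rel=1e-12)
        scaled = compare_populations(_table(t * 7))
        assert scaled.chi2 == pytest.approx(7 * c.chi2, rel=1e-9)
        assert scaled.cramers_v == pytest.approx(c.cramers_v, rel=1e-9)


def test_adequacy_rule_selects_the_test():
    rng = np.random.default_rng(2)
    for t in _random_tables(100, rng):
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        violated = (expected >= 5).mean() < 0.8 or (expected == 0).any()
        c = compare_populations(_table(t))
        assert c.adequacy_violated == violated
        assert c.test_used == ("fisher_exact" if violated else "chi_square")


def test_strength_labels():
    assert compare_populations(_table([[50, 30, 20], [50, 30, 20]])).strength == "weak"
    strong = compare_populations(_table([[90, 5, 5], [20, 40, 40]]))
    assert strong.cramers_v >= 0.35
    assert strong.strength == "strong"


def test_degenerate_margins_rejected():
    with pytest.raises(DegenerateTableError):
        compare_populations(_table([[0, 0, 0], [1, 2, 3]]))


def test_fully_monomorphic_table_is_trivially_independent():
    c = compare_populations(_table([[5, 0, 0], [7, 0, 0]]))
    assert (c.chi2, c.p_raw, c.cramers_v) == (0.0, 1.0, 0.0)
    assert c.df == 2


# ---------------------------------------------------------------------------
# Freeman-Halton exact test


def test_freeman_halton_matches_r_fisher_test():
    # reference p-values computed independently with R's fisher.test
    assert freeman_halton_p(np.array([[8, 2, 5], [3, 7, 6]])) == pytest.approx(
        0.0911888907, abs=1e-9
    )
    assert freeman_halton_p(np.array([[12, 5, 3], [14, 2, 6]])) == pytest.approx(
        0.3765489460, abs=1e-9
    )


def test_freeman_halton_reduces_to_fisher_on_2x2():
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = rng.integers(0, 12, size=(2, 2))
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            continue
        _, p = stats.fisher_exact(t)
        assert freeman_halton_p(t) == pytest.approx(p, abs=1e-10)


def test_monte_carlo_fallback_agrees_with_enumeration():
    t = np.array([[8, 2, 5], [3, 7, 6]])
    exact = freeman_halton_p(t)
    mc = freeman_halton_p(t, max_states=1, n_mc=200_000, seed=5)
    assert mc == pytest.approx(exact, abs=0.01)


def test_exact_and_chi2_agree_on_large_balanced_tables():
    t = np.array([[120, 230, 150], [130, 220, 160]])
    c = compare_populations(_table(t))
    p_exact = freeman_halton_p(t)
    assert abs(c.p_raw - p_exact) < 0.01


# ---------------------------------------------------------------------------
# Holm-Bonferroni


def test_holm_textbook_examples():
    assert holm_bonferroni([0.04]) == [0.04]
    assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_bonferroni([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]


def test_holm_properties_on_random_vectors():
    rng = np.random.default_rng(4)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 12))
        adj = np.array(holm_bonferroni(p))
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        # never exceeds plain Bonferroni
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-12).all()
        # permutation equivariance
        perm = rng.permutation(len(p))
        assert np.allclose(np.array(holm_bonferroni(p[perm])), adj[perm])
        # independent stepwise computation
        order = np.argsort(p, kind="stable")
        expect = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (len(p) - rank) * p[idx]))
            expect[idx] = running
        assert np.allclose(adj, expect)


def test_holm_rejects_bad_input():
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.5])


# ---------------------------------------------------------------------------
# comparison suite


def test_hwe_counts_sum_and_shape():
    for q, n in itertools.product([0.0, 0.1, 0.37, 0.5, 1.0], [90, 180, 501]):
        c = hwe_counts(q, n)
        assert sum(c) == n
        assert all(x >= 0 for x in c)
    assert hwe_counts(0.0, 100) == (100, 0, 0)
    assert hwe_counts(1.0, 100) == (0, 0, 100)


def _null_references(profile, panel):
    return [
        ReferencePopulation(
            name=name,
            counts={rs: hwe_counts(q, n) for rs, q in profile.alt_freqs.items()},
        )
        for name, n in (("CEU", 180), ("YRI", 180), ("CHB", 90))
    ]


def test_suite_runs_72_comparisons_with_family_holm(panel, ceu_profile):
    cohort = simulate_cohort(
        SimulationConfig(n_samples=501, profile=ceu_profile, seed=13), panel
    )
    refs = _null_references(ceu_profile, panel)
    comps = run_comparison_suite(cohort, refs, panel, seed=13)
    assert len(comps) == 72
    assert all(c.p_adjusted >= c.p_raw - 1e-15 for c in comps)
    # ordered by rsid then population
    assert [(c.variant, c.populations[1]) for c in comps] == sorted(
        (c.variant, c.populations[1]) for c in comps
    )


def test_reference_missing_a_variant_shrinks_the_family(panel, ceu_profile):
    cohort = simulate_cohort(
        SimulationConfig(n_samples=120, profile=ceu_profile, seed=14), panel
    )
    refs = _null_references(ceu_profile, panel)
    partial = ReferencePopulation(
        name="CEU",
        counts={rs: c for rs, c in refs[0].counts.items() if rs != "rs4244285"},
    )
    comps = run_comparison_suite(cohort, [partial, refs[1], refs[2]], panel, seed=14)
    assert len(comps) == 71


def test_null_cohort_mostly_nonsignificant_after_adjustment(panel, ceu_profile):
    """Type-I error control: a cohort drawn from the reference's own
    frequencies should almost never reject after Holm."""
    cohort = simulate_cohort(
        SimulationConfig(n_samples=501, profile=ceu_profile, seed=21), panel
    )
    comps = run_comparison_suite(cohort, _null_references(ceu_profile, panel), panel, seed=21)
    assert len(comps) == 72
    nonsig = sum(1 for c in comps if c.p_adjusted >= 0.05)
    assert nonsig / len(comps) >= 0.95
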
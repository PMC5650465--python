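"""Cohort association: count tables, chi-squared models, BH/Bonferroni, gradient."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from caninedsd.association import (
    AssociationResult,
    CohortCounts,
    af_gradient_check,
    bh_adjust,
    bonferroni_threshold,
    contingency_chisq,
    genetic_model_collapse,
    genotype_count_table,
    gwas_snp_prefilter,
)
from caninedsd.core_io import HET, HOM_ALT, HOM_REF, MISSING
from caninedsd.simulate import SimConfig, simulate_cohorts, substream
from conftest import random_matrix


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def test_genotype_count_table_basic(tiny_matrix):
    cohort_of = {"S1": "a", "S2": "a", "S3": "a"}
    counts, flagged = genotype_count_table(tiny_matrix, "chr1", 200, cohort_of)
    cc = counts["a"]
    # calls at site 200 are (het, missing, hom_alt)
    assert (cc.het, cc.hom_alt, cc.hom_ref, cc.n) == (1, 1, 0, 2)
    assert flagged == []


def test_genotype_count_table_flags_empty_cohort(tiny_matrix):
    cohort_of = {"S1": "a", "S2": "a", "S3": "a", "ghost": "b"}
    counts, flagged = genotype_count_table(tiny_matrix, "chr1", 100, cohort_of)
    assert flagged == ["b"]
    assert counts["b"].n == 0


def test_genotype_count_table_matches_recount(rng):
    m = random_matrix(rng, 40, 5, missing_rate=0.1)
    cohort_of = {s: ("x" if i % 2 else "y") for i, s in enumerate(m.samples)}
    counts, _ = genotype_count_table(m, "chr1", 30, cohort_of)
    j = m.site_index("chr1", 30)
    for name in ("x", "y"):
        members = [i for i, s in enumerate(m.samples) if cohort_of[s] == name]
        col = m.calls[members, j]
        assert counts[name].hom_alt == (col == HOM_ALT).sum()
        assert counts[name].het == (col == HET).sum()
        assert counts[name].hom_ref == (col == HOM_REF).sum()


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def test_chisq_null_table():
    res = contingency_chisq([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p == pytest.approx(1.0)


def test_chisq_matches_textbook_formula(rng):
    for _ in range(20):
        tab = rng.integers(1, 60, size=(2, 2)).astype(float)
        res = contingency_chisq(tab)
        row, col, tot = tab.sum(1), tab.sum(0), tab.sum()
        expect = sum(
            (tab[i, j] - row[i] * col[j] / tot) ** 2 / (row[i] * col[j] / tot)
            for i in range(2)
            for j in range(2)
        )
        assert res.statistic == pytest.approx(expect, abs=1e-10)


def test_chisq_matches_scipy_with_and_without_yates(rng):
    for _ in range(10):
        tab = rng.integers(2, 40, size=(2, 3)).astype(float)
        res = contingency_chisq(tab)
        chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)
        assert res.df == df
        tab22 = rng.integers(2, 40, size=(2, 2)).astype(float)
        res_y = contingency_chisq(tab22, yates=True)
        chi2_y, p_y, _, _ = stats.chi2_contingency(tab22, correction=True)
        assert res_y.statistic == pytest.approx(chi2_y, rel=1e-12)


def test_chisq_pvalue_reference_point():
    res = contingency_chisq([[15, 5], [5, 15]])
    assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)
    assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 1))


def test_chisq_yates_never_exceeds_uncorrected(rng):
    for _ in range(25):
        tab = rng.integers(0, 30, size=(2, 2)).astype(float) + 1
        plain = contingency_chisq(tab).statistic
        yates = contingency_chisq(tab, yates=True).statistic
        assert yates <= plain + 1e-12


def test_chisq_degenerate_margin():
    with pytest.raises(ValueError, match="col 1"):
        contingency_chisq([[5, 0], [7, 0]])


# ---------------------------------------------------------------------------
# model collapse
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "model,expect",
    [
        ("dominant", [78, 21]),
        ("recessive", [3, 96]),
        ("genotypic", [3, 75, 21]),
        ("allelic", [81, 117]),
    ],
)
def test_model_collapse_published_counts(model, expect):
    # affected-pets style tallies (3 hom, 75 het, 21 ref as percentages)
    case = CohortCounts(hom_alt=3, het=75, hom_ref=21)
    ctrl = CohortCounts(hom_alt=9, het=42, hom_ref=48)
    tab = genetic_model_collapse(case, ctrl, model)
    assert tab[0].tolist() == expect


def test_model_collapse_conserves_totals():
    case = CohortCounts(hom_alt=5, het=20, hom_ref=30)
    ctrl = CohortCounts(hom_alt=2, het=10, hom_ref=40)
    for model in ("dominant", "recessive", "genotypic"):
        tab = genetic_model_collapse(case, ctrl, model)
        assert tab.sum() == case.n + ctrl.n  # no third-allele carriers here


def test_allelic_collapse_matches_enumeration():
    case = CohortCounts(hom_alt=4, het=6, hom_ref=10)
    alleles = [1, 1] * 4 + [0, 1] * 6 + [0, 0] * 10
    tab = genetic_model_collapse(case, case, "allelic")
    assert tab[0, 0] == sum(alleles)
    assert tab[0, 1] == len(alleles) - sum(alleles)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def test_bonferroni_published_threshold():
    assert bonferroni_threshold(0.05, 76) == pytest.approx(6.58e-4, rel=1e-2)
    assert float(f"{bonferroni_threshold(0.05, 76):.1e}") == 6.6e-4
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 2000) == 2.5e-5


def _bh_brute_force(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def test_bh_hand_examples():
    assert bh_adjust([0.02]).tolist() == [0.02]
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_matches_brute_force_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(10):
        p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, _bh_brute_force(p), atol=1e-12)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, sm_adj, atol=1e-12)


@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
def test_bh_permutation_invariant_and_monotone(p):
    p = np.asarray(p)
    adj = bh_adjust(p)
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-12).all()
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 0.0])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


# ---------------------------------------------------------------------------
# allele-frequency gradient
# ---------------------------------------------------------------------------

def test_gradient_published_fractions():
    # cohort tallies reconstructed from the printed genotype percentages
    # (N=63, 3/75/21/2% -> 2/47/13/1; N=65, 9/42/48/2% -> 6/27/31/1;
    #  N=60, 5/25/65/5% -> 3/15/39/3)
    affected = CohortCounts(hom_alt=2, het=47, hom_ref=13, other=1)
    control1 = CohortCounts(hom_alt=6, het=27, hom_ref=31, other=1)
    control2 = CohortCounts(hom_alt=3, het=15, hom_ref=39, other=3)
    res = af_gradient_check(affected, control1, control2)
    assert res.gradient
    assert res.afs[0] == pytest.approx(0.405, abs=1e-3)
    assert res.afs[2] == pytest.approx(0.175, abs=1e-3)
    assert set(res.pairwise) == {
        "affected_vs_control1", "affected_vs_control2", "control1_vs_control2"
    }


def test_gradient_equal_cohorts_false():
    cc = CohortCounts(hom_alt=5, het=20, hom_ref=40)
    res = af_gradient_check(cc, cc, cc)
    assert not res.gradient


def test_gradient_detected_in_simulation():
    detected = 0
    n_seeds = 200
    for seed in range(n_seeds):
        counts = simulate_cohorts(SimConfig(seed=seed))
        res = af_gradient_check(
            counts["affected_pets"], counts["control_pets_1"], counts["control_pets_2"]
        )
        detected += res.gradient
    assert detected / n_seeds >= 0.95


# ---------------------------------------------------------------------------
# GWAS prefilter
# ---------------------------------------------------------------------------

def test_prefilter_drops_missing_and_low_maf(rng):
    m = random_matrix(rng, 20, 50, missing_rate=0.0)
    m.calls[0, 0] = MISSING
    out, info = gwas_snp_prefilter(m, maf_min=0.3, thin_every=1)
    assert info["after_missing"] == 49
    for j in range(out.n_sites):
        af = out.calls[:, j].mean() / 2
        assert min(af, 1 - af) >= 0.3


def test_prefilter_maf_boundary():
    # MAF 0.29 dropped, 0.30 kept ("< 0.3" is removed)
    n = 50
    calls_29 = np.zeros((n, 1), dtype=np.int8)
    calls_29[:29, 0] = HET  # AF 0.29
    calls_30 = np.zeros((n, 1), dtype=np.int8)
    calls_30[:30, 0] = HET  # AF 0.30
    from caninedsd.core_io import GenotypeMatrix, VariantSite

    m = GenotypeMatrix(
        [VariantSite("chr1", 1, "A", "C"), VariantSite("chr1", 2, "A", "C")],
        [f"S{i}" for i in range(n)],
        np.hstack([calls_29, calls_30]),
    )
    out, _ = gwas_snp_prefilter(m, maf_min=0.3, thin_every=1)
    assert [s.pos for s in out.sites] == [2]


def test_prefilter_thinning_modes(rng):
    m = random_matrix(rng, 30, 100)
    kept, info = gwas_snp_prefilter(m, maf_min=0.0, thin_every=10, thin_keep=True)
    assert info["after_thin"] == 10  # every 10th kept: 1st, 11th, ...
    dropped, info2 = gwas_snp_prefilter(m, maf_min=0.0, thin_every=10, thin_keep=False)
    assert info2["after_thin"] == 90


def test_prefilter_matches_sequential_brute_force(rng):
    m = random_matrix(rng, 25, 1000, missing_rate=0.02)
    out, info = gwas_snp_prefilter(m, maf_min=0.3, thin_every=10)
    survivors = []
    for j in range(m.n_sites):
        col = m.calls[:, j]
        if (col == MISSING).any():
            continue
        af = col.mean() / 2
        if min(af, 1 - af) < 0.3:
            continue
        survivors.append(j)
    survivors = survivors[::10]
    assert [s.key for s in out.sites] == [m.sites[j].key for j in survivors]


def test_null_dominant_test_type_one_error():
    # no AF difference, n=60 per cohort, 2000 replicates at nominal 0.05
    rng = substream(5, "null_assoc")
    n, af = 60, 0.3
    probs = [(1 - af) ** 2, 2 * af * (1 - af), af**2]
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        a = rng.multinomial(n, probs)
        b = rng.multinomial(n, probs)
        tab = genetic_model_collapse(
            CohortCounts(hom_alt=int(a[2]), het=int(a[1]), hom_ref=int(a[0])),
            CohortCounts(hom_alt=int(b[2]), het=int(b[1]), hom_ref=int(b[0])),
            "dominant",
        )
        rejections += contingency_chisq(tab).p < 0.05
    assert 0.035 <= rejections / n_rep <= 0.065
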
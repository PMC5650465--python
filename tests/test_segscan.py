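"""Segregation filter, enrichment scan, homozygosity blocks, breed sharing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from caninedsd.core_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
)
from caninedsd.segscan import (
    SegregationPattern,
    breed_sharing_table,
    enrichment_scan,
    fold_enrichment,
    homozygosity_blocks,
    segregation_pattern_filter,
)
from conftest import random_matrix


def _matrix(calls, positions=None, chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    positions = positions or [10 * (j + 1) for j in range(n_sites)]
    sites = [VariantSite(chrom, p, "A", "C") for p in positions]
    return GenotypeMatrix(sites, [f"S{i}" for i in range(n_samples)], calls)


RECESSIVE = SegregationPattern(
    {"S0": HOM_ALT, "S1": HOM_ALT, "S2": HET, "S3": HOM_REF}
)


# ---------------------------------------------------------------------------
# segregation filter
# ---------------------------------------------------------------------------

def test_pattern_filter_basic():
    # two sites: the first matches the pattern, the second has a hom-ref carrier
    m = _matrix(np.array([[2, 2], [2, 2], [1, 0], [0, 0]]))
    kept, idx = segregation_pattern_filter(m, RECESSIVE)
    assert [s.pos for s in kept] == [10]
    assert idx.tolist() == [0]


def test_pattern_filter_missing_policies():
    m = _matrix(np.array([[2], [2], [MISSING], [0]]))
    kept, _ = segregation_pattern_filter(m, RECESSIVE)
    assert kept == []  # fail_match: missing cannot confirm
    lenient = SegregationPattern(RECESSIVE.required, "ignore_sample")
    kept, _ = segregation_pattern_filter(m, lenient)
    assert len(kept) == 1


def test_pattern_filter_unknown_sample():
    m = _matrix(np.zeros((2, 1)))
    with pytest.raises(KeyError, match="S9"):
        segregation_pattern_filter(m, SegregationPattern({"S9": HOM_ALT}))


def test_pattern_filter_matches_brute_force(rng):
    m = random_matrix(rng, 6, 500, missing_rate=0.05)
    pattern = SegregationPattern({"S0": HOM_ALT, "S1": HOM_ALT, "S2": HET, "S3": HOM_REF})
    kept, idx = segregation_pattern_filter(m, pattern)
    expect = []
    for j in range(m.n_sites):
        ok = all(
            m.calls[m.sample_index(sid), j] == req
            for sid, req in pattern.required.items()
        )
        if ok:
            expect.append(j)
    assert idx.tolist() == expect


def test_pattern_filter_monotone(rng):
    # adding a required sample never grows the retained set
    m = random_matrix(rng, 6, 400, missing_rate=0.02)
    base = SegregationPattern({"S0": HOM_ALT, "S1": HET})
    bigger = SegregationPattern({"S0": HOM_ALT, "S1": HET, "S2": HOM_REF})
    kept_base, _ = segregation_pattern_filter(m, base)
    kept_big, _ = segregation_pattern_filter(m, bigger)
    assert set(s.key for s in kept_big) <= set(s.key for s in kept_base)


def test_pattern_tsv_round_trip(tmp_path):
    RECESSIVE.to_tsv(tmp_path / "p.tsv")
    back = SegregationPattern.from_tsv(tmp_path / "p.tsv")
    assert back.required == RECESSIVE.required


# ---------------------------------------------------------------------------
# fold enrichment
# ---------------------------------------------------------------------------

def test_fold_enrichment_published_bound():
    fold = fold_enrichment(244, 1.9e6, 18_600, 2.392e9)
    assert fold == pytest.approx((244 / 1.9e6) / (18_600 / 2.392e9))
    assert fold > 16


def test_fold_enrichment_trivial_cases():
    assert fold_enrichment(10, 1e6, 100, 1e7) == 1.0  # k/K == w/G
    assert fold_enrichment(100, 1e7, 100, 1e7) == 1.0  # whole genome
    with pytest.raises(ValueError):
        fold_enrichment(1, 1e6, 0, 1e9)
    with pytest.raises(ValueError):
        fold_enrichment(1, 1e9, 10, 1e6)


@given(
    k=st.integers(1, 100),
    w=st.integers(1, 10**6),
    scale=st.floats(0.01, 1000),
)
def test_fold_enrichment_scale_invariant(k, w, scale):
    K, G = 200, 10**9
    base = fold_enrichment(k, w, K, G)
    scaled = fold_enrichment(k, w * scale, K, G * scale)
    assert scaled == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# enrichment scan
# ---------------------------------------------------------------------------

def test_scan_single_cluster_ranked_first():
    sites = [VariantSite("chr1", 1000 + 10 * i, "A", "C") for i in range(20)]
    sites += [VariantSite("chr2", 5_000_000, "A", "C")]
    result = enrichment_scan(sites, genome_bp=1e8)
    assert result.windows[0].interval.chrom == "chr1"
    top = result.top_segment
    assert top.interval.chrom == "chr1"
    assert top.interval.start == 1000 and top.interval.end == 1190


def test_scan_tie_broken_by_position():
    # two identical clusters: tie resolved by (chrom, start)
    sites = [VariantSite("chr2", 1_000 + i, "A", "C") for i in range(5)]
    sites += [VariantSite("chr1", 9_000_000 + i, "A", "C") for i in range(5)]
    result = enrichment_scan(sites, genome_bp=1e8)
    segs = result.segments
    assert len(segs) == 2
    assert segs[0].fold == pytest.approx(segs[1].fold)
    assert (segs[0].interval.chrom, segs[0].interval.start) < (
        segs[1].interval.chrom, segs[1].interval.start
    )


def test_scan_window_fold_consistency():
    sites = [VariantSite("chr1", 100 + i * 50, "A", "C") for i in range(30)]
    result = enrichment_scan(sites, window_bp=1000, step_bp=100, genome_bp=1e6)
    for w in result.windows:
        assert w.fold == pytest.approx(fold_enrichment(w.k, w.w, w.K, w.G))
        assert 0 <= w.k <= w.K


def test_scan_requires_sites():
    with pytest.raises(ValueError):
        enrichment_scan([])


def test_uniform_scatter_max_fold_calibration():
    """Null calibration: on uniformly scattered retained sites at survey
    scale (18,600 sites, 2.392 Gb), the median over simulated genomes of the
    maximum 1 Mb window fold stays below 3.

    The window statistic is evaluated on the same grid the scanner uses;
    one genome is cross-checked against the full scanner output.
    """
    rng = np.random.default_rng(424242)
    G, K, W, S = 2.392e9, 18_600, 1_000_000, 100_000
    maxima = []
    n_genomes = 300
    for rep in range(n_genomes):
        pos = np.sort(rng.integers(1, int(G) + 1, size=K))
        starts = np.arange(1, int(G) + 1, S)
        k = np.searchsorted(pos, starts + W - 1, side="right") - np.searchsorted(
            pos, starts, side="left"
        )
        maxima.append(fold_enrichment(int(k.max()), W, K, G))
    assert np.median(maxima) < 3

    # grid equivalence with the scanner on one genome (fold threshold high
    # enough that no merge happens; compare the max window fold)
    pos = np.sort(rng.integers(1, 10_000_000, size=500))
    sites = [VariantSite("chr1", int(p), "A", "C") for p in np.unique(pos)]
    result = enrichment_scan(sites, window_bp=W, step_bp=S, genome_bp=G)
    starts = np.arange(1, max(s.pos for s in sites) + 1, S)
    upos = np.unique(pos)
    k = np.searchsorted(upos, starts + W - 1, side="right") - np.searchsorted(
        upos, starts, side="left"
    )
    expect = fold_enrichment(int(k.max()), W, len(upos), G)
    assert result.windows[0].fold == pytest.approx(expect)


# ---------------------------------------------------------------------------
# homozygosity blocks
# ---------------------------------------------------------------------------

def _case_control_matrix(qual_mask, chrom="chr1"):
    """Two cases, two controls; qualifying sites per mask, others scrambled."""
    n = len(qual_mask)
    calls = np.zeros((4, n), dtype=np.int8)
    for j, q in enumerate(qual_mask):
        if q:
            calls[:2, j] = HOM_ALT
            calls[2:, j] = HOM_REF
        else:
            calls[:, j] = [HOM_ALT, HET, HOM_REF, HOM_REF]
    return _matrix(calls, chrom=chrom)


def test_blocks_basic_run():
    m = _case_control_matrix([True] * 5)
    blocks = homozygosity_blocks(m, ["S0", "S1"], ["S2", "S3"], min_sites=3)
    assert len(blocks) == 1
    assert len(blocks[0].site_indices) == 5
    assert blocks[0].interval.start == 10 and blocks[0].interval.end == 50


def test_blocks_split_by_violation():
    m = _case_control_matrix([True, True, True, False, True, True, True])
    blocks = homozygosity_blocks(m, ["S0", "S1"], ["S2", "S3"], min_sites=2)
    assert len(blocks) == 2
    # a violation budget of one bridges the gap
    merged = homozygosity_blocks(m, ["S0", "S1"], ["S2", "S3"], min_sites=2, max_violations=1)
    assert len(merged) == 1 and len(merged[0].site_indices) == 6


def test_blocks_input_validation():
    m = _case_control_matrix([True])
    with pytest.raises(ValueError, match="non-empty"):
        homozygosity_blocks(m, [], ["S2"], 1)
    with pytest.raises(ValueError, match="overlap"):
        homozygosity_blocks(m, ["S0"], ["S0"], 1)


def _brute_force_blocks(m, cases, controls, min_sites):
    """Quadratic oracle: test every (start, end) run of sites."""
    qual = []
    for j in range(m.n_sites):
        col = m.calls[:, j]
        ci = [m.sample_index(s) for s in cases]
        ki = [m.sample_index(s) for s in controls]
        qual.append(all(col[i] == HOM_ALT for i in ci) and all(col[i] == HOM_REF for i in ki))
    out = []
    j = 0
    while j < m.n_sites:
        if qual[j]:
            k = j
            while k + 1 < m.n_sites and qual[k + 1]:
                k += 1
            if k - j + 1 >= min_sites:
                out.append((j, k))
            j = k + 1
        else:
            j += 1
    return out


def test_blocks_match_quadratic_oracle(rng):
    m = random_matrix(rng, 6, 300)
    cases, controls = ["S0", "S1"], ["S2", "S3"]
    blocks = homozygosity_blocks(m, cases, controls, min_sites=2)
    expect = _brute_force_blocks(m, cases, controls, 2)
    assert [(b.site_indices[0], b.site_indices[-1]) for b in blocks] == expect


# ---------------------------------------------------------------------------
# breed sharing
# ---------------------------------------------------------------------------

def test_breed_sharing_counts():
    m = _case_control_matrix([True, True])
    blocks = homozygosity_blocks(m, ["S0", "S1"], ["S2", "S3"], min_sites=2)
    breed_of = {"S0": "ACS", "S1": "ECS", "S2": "ACS", "S3": "BGL"}
    table, n_seg = breed_sharing_table(m, blocks[0], breed_of, affected={"S0", "S1"})
    assert n_seg == 2
    assert table["ACS"]["n_affected_hom_alt"] == 1
    # no affected hom-alt anywhere -> zero segregating breeds
    table, n_seg = breed_sharing_table(m, blocks[0], breed_of, affected=set())
    assert n_seg == 0


def test_breed_sharing_planted_cohort(rng):
    # 21 breeds, sharing planted in 20: one affected per breed, one hom_ref
    n_breeds = 21
    calls = np.full((n_breeds, 4), HOM_ALT, dtype=np.int8)
    calls[-1, :] = HOM_REF
    m = _matrix(calls)
    block_calls = np.vstack([calls, np.zeros((1, 4), dtype=np.int8)])
    m = _matrix(block_calls)
    samples = m.samples
    breed_of = {s: f"breed{i}" for i, s in enumerate(samples)}
    affected = set(samples[:-1])
    from caninedsd.segscan import HaplotypeBlock
    from caninedsd.core_io import GenomicInterval

    block = HaplotypeBlock(GenomicInterval("chr1", 10, 40), [0, 1, 2, 3])
    table, n_seg = breed_sharing_table(m, block, breed_of, affected)
    assert n_seg == 20
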
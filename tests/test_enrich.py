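import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from skyscan.enrich import (
    enrichment_test,
    fisher_enrichment,
    genes_in_regions,
    permutation_null,
    run_enrichment_suite,
)
from skyscan.io import GeneAnnotation


def genes_on(contig, intervals):
    return [GeneAnnotation(f"g{i}", contig, s, e)
            for i, (s, e) in enumerate(intervals)]


def test_overlap_half_open_semantics():
    genes = genes_on("chr1", [(0, 100), (100, 200), (150, 260)])
    hits = genes_in_regions([("chr1", 100, 150)], genes)
    # gene ending exactly at region start and gene starting at region end
    assert hits == {"g1"}
    assert genes_in_regions([("chr2", 0, 1000)], genes) == set()


def test_overlap_matches_quadratic_oracle(rng):
    for _ in range(40):
        genes = [GeneAnnotation(f"g{i}", "chr1", int(s), int(s) + int(l))
                 for i, (s, l) in enumerate(zip(
                     rng.integers(0, 10_000, 30),
                     rng.integers(1, 400, 30)))]
        regions = [("chr1", int(s), int(s) + int(l)) for s, l in zip(
            rng.integers(0, 10_000, 8), rng.integers(1, 600, 8))]
        brute = {g.gene_id for g in genes for (c, s, e) in regions
                 if g.contig == c and g.start < e and s < g.end}
        assert genes_in_regions(regions, genes) == brute


def test_fisher_hand_hypergeometric():
    # 4 genes, 2 in category, draw 2, both in category -> p = 1/6
    odds, p = fisher_enrichment(2, 2, 2, 4)
    assert p == pytest.approx(1 / 6)
    # flat table: no enrichment
    odds2, p2 = fisher_enrichment(1, 2, 2, 4)
    assert p2 > 0.5
    with pytest.raises(ValueError):
        fisher_enrichment(3, 2, 5, 10)
    with pytest.raises(ValueError):
        fisher_enrichment(2, 3, 1, 10)  # more category hits than exist


def test_fisher_matches_full_enumeration_small_universes(rng):
    """Hypergeometric tail vs explicit enumeration for n_genome <= 12."""
    for _ in range(120):
        M = int(rng.integers(2, 13))
        K = int(rng.integers(0, M + 1))
        n = int(rng.integers(1, M + 1))
        k_min = max(0, n - (M - K))
        k = int(rng.integers(k_min, min(K, n) + 1))
        _, p = fisher_enrichment(k, n, K, M)
        brute = sum(comb(K, j, exact=True) * comb(M - K, n - j, exact=True)
                    for j in range(k, min(K, n) + 1)) / comb(M, n, exact=True)
        assert p == pytest.approx(brute, rel=1e-12)


def test_permutation_null_mean_and_determinism():
    is_cat = np.zeros(500, bool)
    is_cat[:100] = True  # 20% category
    null = permutation_null(is_cat, 50, B=4000, seed=11)
    again = permutation_null(is_cat, 50, B=4000, seed=11)
    assert np.array_equal(null, again)
    se = np.sqrt(0.2 * 0.8 / 50)
    assert abs(null.mean() - 0.2) < 3 * se / np.sqrt(4000)
    with pytest.raises(ValueError):
        permutation_null(is_cat, 0, B=10)
    with pytest.raises(ValueError):
        permutation_null(is_cat, 501, B=10)


def test_degenerate_universe_never_significant():
    genes = [GeneAnnotation(f"g{i}", "chr1", i * 10, i * 10 + 5,
                            frozenset({"development"})) for i in range(20)]
    res = enrichment_test([("chr1", 0, 1000)], genes, B=200, seed=1)
    assert res.prop_observed == 1.0
    # strict inequality: observed equals the degenerate null percentile
    assert not res.significant


def test_enrichment_test_counts_and_error(gene_set, small_genome):
    regions = [(b.contig, b.start, b.end) for b in small_genome[:5]]
    res = enrichment_test(regions, gene_set, B=300, seed=3)
    assert 0 < res.n_selected <= res.n_genome == len(gene_set)
    assert res.n_selected_cat <= res.n_selected
    assert res.perm_null.shape == (300,)
    assert 0 < res.perm_p <= 1
    with pytest.raises(ValueError):
        enrichment_test([("chrZ", 0, 10)], gene_set, B=10, seed=1)
    with pytest.raises(ValueError):
        enrichment_test(regions, [], B=10, seed=1)


def test_run_enrichment_suite_reproducible(gene_set, small_genome):
    region_sets = {
        "fst": [(b.contig, b.start, b.end) for b in small_genome[:4]],
        "dxy": [(b.contig, b.start, b.end) for b in small_genome[2:8]],
    }
    r1 = run_enrichment_suite(region_sets, gene_set, B=200, seed=5)
    r2 = run_enrichment_suite(region_sets, gene_set, B=200, seed=5)
    assert set(r1) == {"fst", "dxy"}
    for name in r1:
        assert np.array_equal(r1[name].perm_null, r2[name].perm_null)
        assert r1[name].to_dict() == r2[name].to_dict()


def test_observed_31_percent_beats_binomial_null_bound():
    """A 31% observed proportion clears a 20% background at n = 493."""
    rng = np.random.default_rng(17)
    is_cat = np.zeros(17_770, bool)
    is_cat[rng.choice(17_770, 3568, replace=False)] = True
    null = permutation_null(is_cat, 493, B=3000, seed=23)
    q95 = np.percentile(null, 95)
    approx = 3568 / 17_770 + 1.645 * np.sqrt(0.2008 * 0.7992 / 493)
    assert q95 == pytest.approx(approx, abs=0.01)
    assert 153 / 493 > q95
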
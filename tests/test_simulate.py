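import numpy as np
import pytest

from skyscan import (
    ParameterError,
    branch_length_sfs,
    constant_size_model,
    m1_default,
    m4_paper,
    plant_divergent_region,
    simulate_genome,
    simulate_window,
)
from skyscan.simulate import simulate_genealogy
from skyscan.windows import block_stats


def test_no_mutation_rate_means_no_variation(m4):
    import dataclasses

    silent = dataclasses.replace(m4, mu=0.0)
    b = simulate_window(silent, 8, 8, 50_000, seed=3)
    assert b.n_sites == 0
    assert all(blk.n_sites == 0 for blk in
               simulate_genome(silent, 8, 8, 3, 50_000, seed=4))


def test_window_block_invariants(small_genome):
    for b in small_genome:
        assert b.start <= b.positions.min() if b.n_sites else True
        if b.n_sites:
            assert b.positions.max() < b.end
            assert np.all(np.diff(b.positions) > 0)
            counts = b.haplotypes.sum(axis=0)
            # every retained column is segregating
            assert counts.min() >= 1
            assert counts.max() <= b.n_haplotypes - 1 or b.n_haplotypes == 1
        assert set(np.unique(b.haplotypes)).issubset({0, 1})


def test_fixed_seed_reproduces_genome(m4):
    g1 = simulate_genome(m4, 8, 8, 3, 50_000, seed=77)
    g2 = simulate_genome(m4, 8, 8, 3, 50_000, seed=77)
    for a, b in zip(g1, g2):
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.haplotypes, b.haplotypes)


def test_windows_are_individually_reproducible(m4):
    # per-window seeds come from a counter-based split of the master seed
    seeds = np.random.SeedSequence(77).generate_state(3)
    genome = simulate_genome(m4, 8, 8, 3, 50_000, seed=77)
    lone = simulate_window(m4, 8, 8, 50_000, int(seeds[1]),
                           start=50_000)
    assert np.array_equal(genome[1].positions, lone.positions)
    assert np.array_equal(genome[1].haplotypes, lone.haplotypes)


def test_parameter_errors():
    m = m4_paper()
    with pytest.raises(ParameterError):
        simulate_window(m, 1, 0, 1000, seed=1)
    with pytest.raises(ParameterError):
        simulate_window(m, 8, 8, 0, seed=1)
    with pytest.raises(ParameterError):
        simulate_window(m, 40, 40, 1000, seed=1)  # > 64 haplotypes
    with pytest.raises(ParameterError):
        branch_length_sfs(m, 8, 8, 0, seed=1)


def test_single_population_diversity_matches_coalescent_theory():
    """Mean pi ~= 4 N mu and mean S ~= Watterson at modest replication."""
    N, n_hap, L, reps = 1000.0, 8, 50_000, 3000
    model = constant_size_model(N)
    seeds = np.random.SeedSequence(5150).generate_state(reps)
    pis = np.empty(reps)
    Ss = np.empty(reps)
    for r in range(reps):
        b = simulate_window(model, n_hap, 0, L, int(seeds[r]))
        p = b.derived_counts("west") / n_hap
        pis[r] = np.sum(2 * p * (1 - p) * n_hap / (n_hap - 1)) / L
        Ss[r] = b.n_sites
    exp_pi = 4 * N * model.mu
    exp_S = 4 * N * model.mu * L * sum(1 / i for i in range(1, n_hap))
    assert abs(pis.mean() - exp_pi) < 3 * pis.std(ddof=1) / np.sqrt(reps)
    assert abs(Ss.mean() - exp_S) < 3 * Ss.std(ddof=1) / np.sqrt(reps)


def test_genealogy_masks_partition_samples(m4):
    masks, lens = simulate_genealogy(m4, 8, 8, seed=11)
    assert lens.min() >= 0
    assert len(masks) == 2 * (16 - 1)
    full = (1 << 16) - 1
    # leaf masks all appear; no branch subtends everybody
    assert all(0 < int(m) < full for m in masks)
    leaf_masks = {int(m) for m in masks if bin(int(m)).count("1") == 1}
    assert len(leaf_masks) == 16


def test_migration_homogenizes_populations():
    """Strong gene flow (>= 5 migrants/gen) erases deep-split differentiation.

    At 5 migrants/generation Fst is pinned near the two-deme island-model
    equilibrium 1/(1 + 8M) ~ 0.024 regardless of split depth, so against a
    deep isolation split it falls below 5% of the no-migration value.
    """
    from skyscan.models import DemographicModel

    T = 60_000.0
    iso = m1_default(T_split=T)
    mig = DemographicModel("M2", N_w0=15_000, N_e0=15_000, N_w1=15_000,
                           N_e1=15_000, T_split=T, m_we=5.0, m_ew=5.0)

    def mean_fst(model, seed):
        blocks = simulate_genome(model, 8, 8, 200, 50_000, seed)
        return np.nanmean([block_stats(b)["fst"] for b in blocks])

    f_mig = mean_fst(mig, 31)
    assert f_mig == pytest.approx(1 / (1 + 8 * 5.0), abs=0.02)
    assert f_mig < 0.05 * mean_fst(iso, 32)


def test_planted_region_reduces_focal_diversity_and_raises_fst(m4):
    reps = 120
    seeds = np.random.SeedSequence(8080).generate_state(reps)
    neutral = [simulate_window(m4, 8, 8, 50_000, int(s)) for s in seeds]
    planted = [plant_divergent_region(m4, b, "east", 0.05, int(s) + 1)
               for b, s in zip(neutral, seeds)]
    ns = [block_stats(b) for b in neutral]
    ps = [block_stats(b) for b in planted]
    assert np.mean([s["pi_e"] for s in ps]) < np.mean([s["pi_e"] for s in ns])
    assert np.nanmean([s["fst"] for s in ps]) > np.nanmean([s["fst"] for s in ns])
    with pytest.raises(ParameterError):
        plant_divergent_region(m4, neutral[0], "east", 1.5, seed=1)


def test_branch_length_sfs_matches_msprime_oracle():
    """Independent coalescent implementation agrees on the expected SFS."""
    msprime = pytest.importorskip("msprime")

    N = 2000.0
    model = constant_size_model(N)
    bl = branch_length_sfs(model, 6, 0, 30_000, seed=13)
    marginal = bl[:, 0][1:6]  # classes 1..5 of 6 haplotypes
    reps = msprime.sim_ancestry(samples=3, population_size=N,
                                ploidy=2, num_replicates=3000,
                                random_seed=97)
    acc = np.zeros(6)
    for ts in reps:
        for tree in ts.trees():
            for node in tree.nodes():
                k = tree.num_samples(node)
                if 0 < k < 6:
                    acc[k] += tree.branch_length(node)
    acc /= 3000
    # theory: E[T_i] = 4N/i per frequency class
    theory = 4 * N / np.arange(1, 6)
    assert np.allclose(marginal, theory, rtol=0.1)
    assert np.allclose(acc[1:6], theory, rtol=0.1)
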
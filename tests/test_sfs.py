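import dataclasses

import numpy as np
import pytest

from skyscan import constant_size_model, m1_default, m4_paper, simulate_genome
from skyscan.models import ParameterError
from skyscan.sfs import (
    FitResult,
    Sfs2D,
    build_sfs,
    build_sfs_from_vcf,
    composite_loglik,
    expected_sfs,
    expected_total_branch_length,
    fit_model,
    param_ci,
    select_model,
    sfs_moments,
)


def test_build_sfs_matches_direct_enumeration(small_genome):
    obs = build_sfs(small_genome)
    # independent tally straight off the haplotype matrices
    want = np.zeros((9, 9))
    total = 0
    for b in small_genome:
        total += b.length
        for s in range(b.n_sites):
            col = b.haplotypes[:, s]
            want[col[:8].sum(), col[8:].sum()] += 1
    want[0, 0] += total - want.sum()
    assert np.array_equal(obs.counts, want)
    assert obs.total_sites == total


def test_build_sfs_single_site_classes():
    from skyscan.simulate import HaplotypeBlock

    h = np.zeros((8, 1), np.uint8)
    h[:4, 0] = 1  # derived in all west haplotypes only
    block = HaplotypeBlock("c", 0, 100, np.array([5]), h,
                           np.array(["west"] * 4 + ["east"] * 4))
    obs = build_sfs([block])
    assert obs.counts[4, 0] == 1
    assert obs.counts[0, 0] == 99
    assert obs.total_sites == 100


def test_build_sfs_from_vcf_round_trip(tmp_path, small_genome):
    from skyscan.io import write_vcf

    pops = {f"w{i}": "west" for i in range(4)} | {f"e{i}": "east"
                                                  for i in range(4)}
    path = tmp_path / "g.vcf"
    write_vcf(small_genome, list(pops), path)
    total = sum(b.length for b in small_genome)
    obs = build_sfs_from_vcf(path, pops, {"chr1": total})
    assert np.array_equal(obs.counts, build_sfs(small_genome).counts)


def test_sfs_tsv_round_trip(tmp_path):
    counts = np.arange(20, dtype=float).reshape(4, 5)
    sfs = Sfs2D(counts)
    sfs.to_tsv(tmp_path / "x.tsv")
    back = Sfs2D.from_tsv(tmp_path / "x.tsv")
    assert np.array_equal(back.counts, counts)
    assert back.n_w == 3 and back.n_e == 4


def test_expected_sfs_is_normalized_and_deterministic(m4):
    p1 = expected_sfs(m4, 8, 8, 2000, seed=9)
    p2 = expected_sfs(m4, 8, 8, 2000, seed=9)
    assert np.array_equal(p1, p2)
    assert p1.sum() == pytest.approx(1.0)
    assert p1.min() > 0  # zero cells floored
    assert p1[0, 0] > 0.99  # monomorphic mass dominates


def test_expected_total_branch_length_single_pop_theory():
    N = 1000.0
    model = constant_size_model(N)
    for n in (4, 8):
        got = expected_total_branch_length(model, n, 0)
        theory = 4 * N * sum(1 / i for i in range(1, n))
        assert got == pytest.approx(theory, rel=1e-9)


def test_expected_total_branch_length_matches_monte_carlo(m4):
    from skyscan import branch_length_sfs

    exact = expected_total_branch_length(m4, 8, 8)
    mc = branch_length_sfs(m4, 8, 8, 100_000, seed=2).sum()
    assert mc == pytest.approx(exact, rel=0.01)


def test_composite_loglik_hand_example():
    obs = Sfs2D(np.array([[3.0, 1.0]]))
    p = np.array([[0.75, 0.25]])
    assert composite_loglik(obs, p) == pytest.approx(
        3 * np.log(0.75) + np.log(0.25))
    assert composite_loglik(obs, p) == pytest.approx(-2.2493, abs=1e-4)


def test_composite_loglik_maximal_at_observed_proportions(rng):
    obs = Sfs2D(rng.integers(1, 50, size=(3, 3)).astype(float))
    p_match = obs.counts / obs.counts.sum()
    best = composite_loglik(obs, p_match)
    for _ in range(25):
        q = rng.dirichlet(np.ones(9)).reshape(3, 3)
        assert composite_loglik(obs, q) <= best + 1e-9


def test_composite_loglik_floors_zero_cells(caplog):
    obs = Sfs2D(np.array([[1.0, 1.0]]))
    p = np.array([[1.0, 0.0]])
    with caplog.at_level("WARNING"):
        ll = composite_loglik(obs, p)
    assert np.isfinite(ll)
    assert "flooring" in caplog.text


def test_sfs_moments_recover_observed_statistics(small_genome):
    from skyscan.windows import window_table

    obs = build_sfs(small_genome)
    pi_w, pi_e, d = sfs_moments(obs)
    df = window_table(small_genome, min_snps=0, z=False)
    L = sum(b.length for b in small_genome)
    w = df["end"] - df["start"]
    assert pi_w == pytest.approx(np.average(df["pi_w"], weights=w), rel=1e-9)
    assert d == pytest.approx(np.average(df["dxy"], weights=w), rel=1e-9)


def test_select_model_prefers_low_aic_then_parsimony():
    m1 = FitResult(m1_default(), loglik=-100.0)
    m4 = FitResult(m4_paper(), loglik=-100.0)
    best, table = select_model([m4, m1])
    assert best == "M1"  # equal loglik: fewer parameters wins
    assert table.loc[0, "aic"] == pytest.approx(2 * 3 + 200)
    best2, _ = select_model([FitResult(m4_paper(), loglik=-10.0), m1])
    assert best2 == "M4"
    single, _ = select_model([m1])
    assert single == "M1"
    with pytest.raises(ValueError):
        select_model([])


def test_param_ci_top_fraction_counting():
    fits = [FitResult(m1_default(N_w0=1000.0 * (i + 1), N_e0=1000.0,
                               N_w1=1000.0 * (i + 1), N_e1=1000.0),
                      loglik=-float(i)) for i in range(100)]
    ci = param_ci(fits, top_frac=0.05)
    assert ci.loc[0, "n_kept"] == 5
    # identical replicates -> zero-width interval
    same = [FitResult(m1_default(), loglik=-1.0) for _ in range(10)]
    ci2 = param_ci(same)
    assert (ci2["min"] == ci2["max"]).all()
    with pytest.raises(ValueError):
        param_ci([])
    with pytest.raises(ValueError):
        param_ci(fits, top_frac=0.0)


def test_fit_model_deterministic_and_structured():
    truth = m1_default()
    blocks = simulate_genome(truth, 8, 8, 150, 50_000, seed=60)
    obs = build_sfs(blocks)
    kw = dict(n_loops=1, n_sims_per_loop=4000, n_sims_per_eval=1500,
              n_starts=4, n_polish=2, final_sims=8000, seed=3)
    f1 = fit_model(obs, "M1", **kw)
    f2 = fit_model(obs, "M1", **kw)
    assert f1.model == f2.model and f1.loglik == f2.loglik
    assert f1.k == 3
    assert f1.aic == pytest.approx(2 * 3 - 2 * f1.loglik)
    with pytest.raises(ParameterError):
        fit_model(obs, "M7")
    with pytest.raises(ParameterError):
        fit_model(obs, "M1", n_loops=0)
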
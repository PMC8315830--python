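import numpy as np
import pytest

from skyscan.sweep import (
    SweepModel,
    _sweep_transition,
    background_sfs,
    clr_at,
    compare_populations,
    scan,
)


def test_background_sfs_matches_enumeration(small_genome):
    bg = background_sfs(small_genome, "west")
    assert bg.sum() == pytest.approx(1.0)
    counts = np.zeros(9)
    total = 0
    for b in small_genome:
        total += b.length
        for s in range(b.n_sites):
            counts[b.haplotypes[:8, s].sum()] += 1
    counts[0] += total - counts.sum()
    assert np.allclose(bg, counts / counts.sum())
    with pytest.raises(ValueError):
        background_sfs([], "west")


def test_sweep_transition_conserves_probability():
    rng = np.random.default_rng(5)
    b = rng.dirichlet(np.ones(9))
    for K in range(9):
        out = _sweep_transition(b, K)
        assert out.sum() == pytest.approx(1.0)
        assert out.min() >= 0
    # K = n leaves the background untouched
    assert np.allclose(_sweep_transition(b, 8), b)


def test_full_hitchhiking_concentrates_extreme_classes():
    """p_esc = 0: all mass moves to the invariant/fixed classes.

    With a 2-class interior-free background (0.6 at class 0, 0.4 at class
    2 of n=2), the swept spectrum is (0.6, 0, 0.4); with interior mass at
    class 1 of n=2 (0.6, 0.4, 0), the derived-allele mean 0.2 ends fixed:
    (0.8, 0, 0.2).
    """
    model = SweepModel.from_background(np.array([0.6, 0.0, 0.4]))
    p0 = np.exp(model.log_ratio[0] + np.log(np.maximum(model.background,
                                                       1e-300)))
    assert p0[0] == pytest.approx(0.6, abs=1e-12)
    assert p0[2] == pytest.approx(0.4, abs=1e-12)

    model2 = SweepModel.from_background(np.array([0.6, 0.4, 0.0]))
    row = model2.log_ratio[0]
    p_swept = np.exp(row) * np.maximum(model2.background, 1e-300)
    # hand arithmetic: q_1 = (0.8, 0.2); ancestor derived w.p. 0.2
    assert p_swept[0] == pytest.approx(0.8, abs=1e-12)
    assert p_swept[2] == pytest.approx(0.2, abs=1e-12)


def test_neutral_limit_gives_zero_clr():
    rng = np.random.default_rng(6)
    b = rng.dirichlet(np.ones(9))
    model = SweepModel.from_background(b)
    # alpha so large that p_esc = 1 at every site: distortion vanishes
    positions = np.arange(10) * 1000 + 500
    classes = rng.integers(0, 9, size=10)
    clr, alpha = clr_at(5000, positions, classes, model,
                        alpha_grid=np.array([1e6]))
    assert clr == 0.0
    assert np.isnan(alpha)


def test_clr_nonnegative_everywhere(small_genome):
    track, _ = scan(small_genome, "east")
    assert (track["clr"] >= 0).all()
    assert len(track) == 20 * 5  # 10 kb grid over 50 kb windows
    t2, _ = scan(small_genome, "east")
    assert np.array_equal(track["clr"], t2["clr"])  # deterministic


def test_scan_threshold_and_regions(small_genome):
    track, regions = scan(small_genome, "west", threshold=np.inf)
    assert len(regions) == 0
    thr = float(np.percentile(track["clr"], 50))
    _, regions2 = scan(small_genome, "west", threshold=thr)
    assert len(regions2) >= 1
    assert (regions2["end"] > regions2["start"]).all()


def test_compare_populations_identical_tracks():
    clr = np.linspace(0, 5, 50)
    out = compare_populations(clr, clr, 10, 10)
    assert out["wilcoxon_p"] > 0.99
    assert out["chi2_stat"] == pytest.approx(0.0)
    assert out["chi2_p"] == pytest.approx(1.0)


def test_compare_populations_region_count_chi2():
    """Goodness of fit of counts 4104 vs 2184 against an equal split."""
    out = compare_populations(np.ones(5), np.ones(5), 4104, 2184)
    expected = (4104 + 2184) / 2
    hand = (4104 - expected) ** 2 / expected + (2184 - expected) ** 2 / expected
    assert hand == pytest.approx(586.26, abs=0.01)
    assert out["chi2_stat"] == pytest.approx(hand)
    assert out["chi2_p"] < 1e-100
    # custom expectation vector is honoured
    out2 = compare_populations(np.ones(5), np.ones(5), 4104, 2184,
                               expected=[4104, 2184])
    assert out2["chi2_stat"] == pytest.approx(0.0)


def test_planted_sweep_windows_separate_from_neutral(m4):
    from skyscan.experiments import sweep_separation_experiment

    out = sweep_separation_experiment(m4, n_windows=150, n_planted=20,
                                      shrink=0.05, seed=17)
    assert out["mean_clr_planted"] > out["mean_clr_neutral"]
    assert out["wilcoxon_p"] < 0.01
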
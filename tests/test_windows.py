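"""Window statistics against brute-force pairwise oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skyscan.windows import (
    dxy,
    hudson_fst,
    ld_decay,
    pi,
    smlh,
    window_table,
    z_transform,
)

# ---------------------------------------------------------------- oracles


def brute_fst(h1, h2):
    """Hudson Fst by explicit per-site summation over haplotype matrices."""
    num = den = 0.0
    n1, n2 = h1.shape[0], h2.shape[0]
    for s in range(h1.shape[1]):
        p1, p2 = h1[:, s].mean(), h2[:, s].mean()
        num += ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                - p2 * (1 - p2) / (n2 - 1))
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den else float("nan")


def brute_dxy(h1, h2, L):
    """Mean mismatch over every between-population haplotype pair."""
    tot = 0.0
    for a in h1:
        for b in h2:
            tot += np.sum(a != b)
    return tot / (h1.shape[0] * h2.shape[0]) / L


def brute_pi(h, L):
    """Mean mismatch over all within-population pairs."""
    n = h.shape[0]
    tot = 0.0
    pairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            tot += np.sum(h[a] != h[b])
            pairs += 1
    return tot / pairs / L


def random_matrix(rng, n, S):
    """Random segregating 0/1 matrix (every column polymorphic pooled)."""
    h = rng.integers(0, 2, size=(n, S))
    for s in range(S):
        col = h[:, s]
        if col.sum() == 0:
            col[rng.integers(n)] = 1
        elif col.sum() == n:
            col[rng.integers(n)] = 0
    return h


# ----------------------------------------------------------------- tests


def test_statistics_match_brute_force_on_many_fixtures():
    rng = np.random.default_rng(420)
    for _ in range(120):
        n1 = int(rng.integers(2, 9))
        n2 = int(rng.integers(2, 9))
        S = int(rng.integers(1, 25))
        L = int(rng.integers(S, 2000))
        h1 = random_matrix(rng, n1, S)
        h2 = random_matrix(rng, n2, S)
        d1, d2 = h1.sum(axis=0), h2.sum(axis=0)
        got = hudson_fst(d1, n1, d2, n2)
        want = brute_fst(h1, h2)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-12, abs=1e-15)
        assert dxy(d1, n1, d2, n2, L) == pytest.approx(
            brute_dxy(h1, h2, L), rel=1e-12, abs=1e-15)
        assert pi(d1, n1, L) == pytest.approx(
            brute_pi(h1, L), rel=1e-12, abs=1e-15)


def test_fst_extremes():
    # fixed difference -> 1
    assert hudson_fst([4], 4, [0], 4) == pytest.approx(1.0)
    # identical frequencies -> <= 0 (negative bias correction)
    assert hudson_fst([2, 1], 4, [2, 1], 4) <= 0.0
    with pytest.raises(ValueError):
        hudson_fst([1], 1, [0], 4)


def test_dxy_simple_cases():
    assert dxy([4], 4, [0], 4, 100) == pytest.approx(0.01)
    assert dxy([0], 4, [0], 4, 100) == 0.0
    assert dxy([2], 4, [2], 4, 50) >= 0.0


def test_pi_simple_cases():
    assert pi([0, 0], 4, 1000) == 0.0
    # two haplotypes differing at 3 of 1000 sites
    assert pi([1, 1, 1], 2, 1000) == pytest.approx(0.003)


def test_smlh_normalizes_to_unit_mean():
    g = np.array([[1, 1, 0, 2], [1, 0, 0, 2]])  # het props 0.5 and 0.25
    out = smlh(g, ["a", "b"])
    assert out["smlh"].mean() == pytest.approx(1.0)
    assert out["smlh"].tolist() == pytest.approx([4 / 3, 2 / 3])
    # two samples with het 0.02 and 0.04
    g2 = np.zeros((2, 100), dtype=int)
    g2[0, :2] = 1
    g2[1, :4] = 1
    out2 = smlh(g2)
    assert out2["smlh"].tolist() == pytest.approx([2 / 3, 4 / 3])


def test_z_transform_two_points_and_degenerate():
    z = z_transform([0.0, 1.0])
    assert z == pytest.approx([-0.7071067811865475, 0.7071067811865475])
    with pytest.raises(ValueError):
        z_transform([0.5, 0.5, 0.5])
    z2 = z_transform([1.0, np.nan, 3.0])
    assert np.isnan(z2[1]) and z2[0] == pytest.approx(-0.7071067811865475)


@given(st.lists(st.integers(-10_000, 10_000), min_size=3, max_size=40,
                unique=True))
@settings(max_examples=60, deadline=None)
def test_z_transform_standardizes(values):
    z = z_transform(np.asarray(values, dtype=float) / 1000.0)
    assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
    assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-9)


def test_z_quantile_of_normal_sample():
    rng = np.random.default_rng(7)
    z = z_transform(rng.normal(0.05, 0.01, size=200_000))
    assert np.percentile(z, 95) == pytest.approx(1.645, abs=0.02)


def test_ld_decay_duplicated_column_and_independence():
    rng = np.random.default_rng(11)
    n = 400
    a = rng.integers(0, 2, size=n)
    h = np.column_stack([a, a, rng.integers(0, 2, size=(n, 8))])
    pos = np.concatenate([[0, 50], 200 + np.arange(8) * 100])
    out = ld_decay(h, pos, max_dist=1000, n_bins=10)
    assert out.loc[0, "mean_r2"] == pytest.approx(1.0)  # duplicate at d=50
    far = out["mean_r2"].to_numpy()[2:]
    far = far[np.isfinite(far)]
    assert far.mean() == pytest.approx(1 / n, abs=5 / n)
    with pytest.raises(ValueError):
        ld_decay(np.zeros((4, 3)), [1, 2, 3], max_dist=10)


def test_window_table_flags_sparse_windows(small_genome):
    df = window_table(small_genome, min_snps=3)
    assert {"contig", "start", "end", "n_snps", "fst", "dxy", "pi_w",
            "pi_e", "z_fst", "z_dxy"} <= set(df.columns)
    sparse = df["n_snps"] < 3
    assert df.loc[sparse, "fst"].isna().all()
    zs = df["z_fst"].dropna()
    assert zs.mean() == pytest.approx(0.0, abs=1e-9)
    assert zs.std(ddof=1) == pytest.approx(1.0, rel=1e-9)
    assert (df["dxy"] >= 0).all()
    assert (df["fst"].dropna() <= 1).all()
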
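"""Composite-likelihood-ratio scan for selective sweeps within a population.

The scan follows the SweepFinder/SweeD model family: the genome-wide
unfolded frequency-class distribution (including the invariant and
fixed-derived classes) serves as the neutral background, and at each grid
point the background is distorted by a hard-sweep escape process.  A
lineage at distance ``d`` from the sweep site escapes the sweep with
probability ``p_esc = 1 - exp(-alpha * d)``; the ``K`` escaped lineages
plus the single sweeping ancestor represent a pre-sweep sample of size
``K + 1`` drawn from the background (by hypergeometric downsampling), and
the ancestor's allele is copied into the ``n - K`` hitchhiking lineages.
As ``p_esc -> 0`` this pushes all probability mass into the extreme
classes (0 and n); as ``p_esc -> 1`` it reduces to the background.

The CLR at a grid point is the composite log-likelihood ratio summed over
sites, maximized over a log-spaced ``alpha`` grid and floored at zero (the
neutral limit is always admissible).  Escape probabilities are evaluated
through a fine lookup table in ``p_esc`` for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom, chisquare, ranksums

from .simulate import HaplotypeBlock

__all__ = [
    "background_sfs",
    "SweepModel",
    "clr_at",
    "scan",
    "compare_populations",
    "DEFAULT_ALPHA_GRID",
]

#: per-bp sweep-decay rates over which the CLR is maximized
DEFAULT_ALPHA_GRID = np.logspace(-6, -1, 20)

_TINY = 1e-300


def background_sfs(blocks: list[HaplotypeBlock], pop: str) -> np.ndarray:
    """Genome-wide unfolded frequency-class probabilities for one population.

    Class ``c`` (0..n) is the fraction of *all* sites - including the
    monomorphic remainder of each window, which lands in class 0 - at which
    ``c`` haplotypes of ``pop`` carry the derived allele.
    """
    if not blocks:
        raise ValueError("no blocks supplied")
    n = int((blocks[0].pop_labels == pop).sum())
    if n < 2:
        raise ValueError(f"population {pop!r} needs >= 2 haplotypes")
    counts = np.zeros(n + 1, np.float64)
    total = 0
    for b in blocks:
        total += b.length
        if b.n_sites:
            counts += np.bincount(b.derived_counts(pop), minlength=n + 1)
    counts[0] += total - counts.sum()
    if counts.sum() <= 0:
        raise ValueError("empty background")
    return counts / counts.sum()


def _downsample_matrix(n: int, m: int) -> np.ndarray:
    """D[f, i] = P(i derived in a subsample of m | f derived in n)."""
    f = np.arange(n + 1)[:, None]
    i = np.arange(m + 1)[None, :]

    def logc(a, b):
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return out

    valid = (i <= f) & (m - i <= n - f)
    lp = logc(f, i) + logc(n - f, m - i) - logc(np.float64(n), np.float64(m))
    D = np.where(valid, np.exp(lp), 0.0)
    return D


def _sweep_transition(b: np.ndarray, K: int) -> np.ndarray:
    """Post-sweep class distribution given exactly K escaped lineages."""
    n = b.size - 1
    if K >= n:
        return b.copy()
    m = K + 1
    q = b @ _downsample_matrix(n, m)  # pre-sweep sample of the K+1 ancestors
    out = np.zeros(n + 1)
    i = np.arange(m + 1)
    w_derived = i / m            # sweeping ancestor carries the derived allele
    # ancestor derived: its allele fills the n-K hitchhikers -> class i-1+n-K
    for ii in range(1, m + 1):
        out[ii - 1 + n - K] += q[ii] * w_derived[ii]
    # ancestor ancestral: class stays at the escaped derived count i
    for ii in range(0, m + 1):
        j = min(ii, n)
        out[j] += q[ii] * (1.0 - w_derived[ii])
    return out


@dataclass
class SweepModel:
    """Precomputed sweep-distortion lookup over a ``p_esc`` grid.

    ``log_ratio[g, c]`` is log P_sweep(class c | p_esc_grid[g]) minus
    log P_background(class c).
    """

    background: np.ndarray
    p_esc_grid: np.ndarray
    log_ratio: np.ndarray

    @classmethod
    def from_background(cls, background: np.ndarray,
                        n_pesc: int = 201) -> "SweepModel":
        b = np.asarray(background, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("background must be a 1-D class distribution")
        if not np.isclose(b.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        n = b.size - 1
        transitions = np.stack([_sweep_transition(b, K) for K in range(n + 1)])
        grid = np.linspace(0.0, 1.0, n_pesc)
        K = np.arange(n + 1)
        weights = binom.pmf(K[None, :], n, grid[:, None])  # (n_pesc, n+1)
        p_sweep = weights @ transitions                     # (n_pesc, n+1)
        log_ratio = (np.log(np.maximum(p_sweep, _TINY))
                     - np.log(np.maximum(b, _TINY))[None, :])
        return cls(b, grid, log_ratio)

    def ratio_at(self, p_esc: np.ndarray, classes: np.ndarray) -> np.ndarray:
        idx = np.rint(p_esc * (self.p_esc_grid.size - 1)).astype(np.intp)
        return self.log_ratio[idx, classes]


def clr_at(grid_pos: int, positions: np.ndarray, classes: np.ndarray,
           model: SweepModel, alpha_grid=None, *,
           n_invariant: int = 0, window: tuple[int, int] | None = None,
           n_quad: int = 16) -> tuple[float, float]:
    """CLR and best alpha for a sweep centred at ``grid_pos``.

    ``positions``/``classes`` are the segregating sites (derived-allele
    class per site in the focal population).  ``n_invariant`` monomorphic
    sites spread uniformly over ``window`` enter through ``n_quad``
    quadrature points - near a sweep the invariant class itself becomes
    more probable, so these sites carry signal too.  Returns ``(clr,
    alpha_hat)`` with the CLR floored at the neutral limit 0 (``alpha_hat``
    is NaN there).
    """
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    positions = np.asarray(positions)
    classes = np.asarray(classes, dtype=np.intp)
    d = np.abs(positions - grid_pos)[None, :]                 # (1, S)
    pe = 1.0 - np.exp(-alpha_grid[:, None] * d)               # (A, S)
    scores = model.ratio_at(pe, classes[None, :]).sum(axis=1)  # (A,)
    if n_invariant and window is not None:
        lo, hi = window
        mids = lo + (np.arange(n_quad) + 0.5) * (hi - lo) / n_quad
        d_inv = np.abs(mids - grid_pos)[None, :]
        pe_inv = 1.0 - np.exp(-alpha_grid[:, None] * d_inv)
        zeros = np.zeros((1, n_quad), np.intp)
        scores = scores + model.ratio_at(pe_inv, zeros).sum(axis=1) * (
            n_invariant / n_quad)
    best = int(np.argmax(scores))
    clr = float(scores[best])
    if clr <= 0.0:
        return 0.0, float("nan")
    return clr, float(alpha_grid[best])


def scan(blocks: list[HaplotypeBlock], pop: str, *, grid_spacing: int = 10_000,
         alpha_grid=None, background: np.ndarray | None = None,
         threshold: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CLR sweep scan over a set of windows for one population.

    Grid points are placed every ``grid_spacing`` bp within each window;
    each point is evaluated against the sites of its window (windows are
    modelled as unlinked).  Returns the per-point track and, when a
    ``threshold`` is given, contiguous supra-threshold grid runs merged
    into regions.
    """
    if not blocks:
        raise ValueError("no blocks supplied")
    if background is None:
        background = background_sfs(blocks, pop)
    model = SweepModel.from_background(background)
    rows = []
    for b in blocks:
        classes = b.derived_counts(pop)
        n_inv = b.length - b.n_sites
        for gp in range(b.start + grid_spacing // 2, b.end, grid_spacing):
            clr, a_hat = clr_at(gp, b.positions, classes, model, alpha_grid,
                                n_invariant=n_inv, window=(b.start, b.end))
            rows.append((b.contig, gp, clr, a_hat))
    track = pd.DataFrame(rows, columns=["contig", "pos", "clr", "alpha_hat"])
    regions = pd.DataFrame(columns=["contig", "start", "end"])
    if threshold is not None and len(track):
        hits = track[track["clr"] > threshold]
        spans = []
        for contig, grp in hits.groupby("contig", sort=False):
            ps = np.sort(grp["pos"].to_numpy())
            run_start = prev = None
            for p in ps:
                if prev is not None and p - prev <= grid_spacing:
                    prev = p
                    continue
                if prev is not None:
                    spans.append((contig, run_start - grid_spacing // 2,
                                  prev + grid_spacing // 2))
                run_start = prev = p
            if prev is not None:
                spans.append((contig, run_start - grid_spacing // 2,
                              prev + grid_spacing // 2))
        regions = pd.DataFrame(spans, columns=["contig", "start", "end"])
    return track, regions


def compare_populations(clr_w, clr_e, n_regions_w: int, n_regions_e: int,
                        expected=None) -> dict:
    """Between-population CLR comparison.

    Two-sided Wilcoxon rank-sum on the per-grid-point CLR tracks, and a
    chi-square goodness-of-fit of the two supra-threshold region counts
    against ``expected`` (defaults to an equal split of the total).
    """
    clr_w = np.asarray(clr_w, dtype=float)
    clr_e = np.asarray(clr_e, dtype=float)
    w_stat, w_p = ranksums(clr_w, clr_e)
    obs = np.array([n_regions_w, n_regions_e], dtype=float)
    if expected is None:
        expected = np.full(2, obs.sum() / 2.0)
    chi_stat, chi_p = chisquare(obs, f_exp=np.asarray(expected, dtype=float))
    return {
        "mean_clr_w": float(clr_w.mean()) if clr_w.size else float("nan"),
        "mean_clr_e": float(clr_e.mean()) if clr_e.size else float("nan"),
        "wilcoxon_stat": float(w_stat),
        "wilcoxon_p": float(w_p),
        "n_regions_w": int(n_regions_w),
        "n_regions_e": int(n_regions_e),
        "chi2_stat": float(chi_stat),
        "chi2_p": float(chi_p),
    }
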
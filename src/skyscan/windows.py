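"""Per-window population-genetic statistics.

Implements the scan statistics used to map the landscape of divergence
between the two populations: Hudson's Fst (ratio-of-averages form, robust
to unequal and small sample sizes), absolute divergence Dxy, within-
population nucleotide diversity pi, per-individual standardized multilocus
heterozygosity (sMLH), the genome-wide Z-transformation of Fst and a
pairwise-r^2 linkage-disequilibrium decay profile (the check that justifies
the 50 kb window size).

All site-level inputs are derived-allele counts and sample sizes per site;
window-level functions operate on :class:`~skyscan.simulate.HaplotypeBlock`
objects or tidy tables thereof.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import HaplotypeBlock

__all__ = [
    "hudson_fst",
    "dxy",
    "pi",
    "smlh",
    "z_transform",
    "ld_decay",
    "block_stats",
    "window_table",
    "WINDOW_SIZE",
]

#: default scan window width in bp
WINDOW_SIZE = 50_000


def _freqs(d, n):
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    if d.shape != n.shape and n.ndim > 0:
        raise ValueError("derived counts and sample sizes differ in shape")
    n = np.broadcast_to(n, d.shape)
    if np.any(d < 0) or np.any(d > n):
        raise ValueError("derived counts must lie in [0, n]")
    return d, n


def hudson_fst(d1, n1, d2, n2) -> float:
    """Hudson's Fst as a ratio of averages over sites.

    Per site, the numerator is (p1 - p2)^2 minus the sampling-variance
    corrections p(1-p)/(n-1) for each population, and the denominator is
    the between-population heterozygosity p1(1-p2) + p2(1-p1); sums are
    taken over sites before the ratio.  Requires n >= 2 per population.
    Returns NaN when no site is informative (zero denominator sum).
    """
    d1, n1 = _freqs(d1, n1)
    d2, n2 = _freqs(d2, n2)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("hudson_fst requires >= 2 haplotypes per population")
    p1, p2 = d1 / n1, d2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    den_sum = float(den.sum())
    if den_sum == 0.0:
        return float("nan")
    return float(num.sum() / den_sum)


def dxy(d1, n1, d2, n2, L: float) -> float:
    """Mean between-population pairwise difference per site.

    Averages allele mismatch over all between-population haplotype pairs at
    each site and divides by the callable length ``L``.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    d1, n1 = _freqs(d1, n1)
    d2, n2 = _freqs(d2, n2)
    p1, p2 = d1 / n1, d2 / n2
    return float(np.sum(p1 * (1 - p2) + p2 * (1 - p1)) / L)


def pi(d, n, L: float) -> float:
    """Within-population nucleotide diversity per site.

    Sample-size-corrected mean pairwise difference:
    sum over sites of 2 p (1-p) n/(n-1), divided by ``L``.
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    d, n = _freqs(d, n)
    if np.any(n < 2):
        raise ValueError("pi requires >= 2 haplotypes")
    p = d / n
    return float(np.sum(2.0 * p * (1 - p) * n / (n - 1)) / L)


def smlh(genotypes: np.ndarray, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Standardized multilocus heterozygosity per individual.

    ``genotypes`` is a (n_samples, n_sites) diploid matrix coded 0/1/2
    (derived-allele dosage); negative entries mark missing calls and are
    excluded per sample.  Each individual's heterozygous fraction is
    divided by the mean fraction over individuals, so the output column
    ``smlh`` averages to 1 by construction.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotypes must be (n_samples, n_sites)")
    called = g >= 0
    n_called = called.sum(axis=1)
    if np.any(n_called == 0):
        raise ValueError("a sample has no called genotypes")
    het = ((g == 1) & called).sum(axis=1) / n_called
    mean_het = het.mean()
    if mean_het == 0:
        raise ValueError("no heterozygous calls in any sample")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(g.shape[0])]
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "het_prop": het,
        "smlh": het / mean_het,
    })


def z_transform(values) -> np.ndarray:
    """Genome-wide Z-transformation, (x - mean) / sd with sample sd (ddof=1).

    NaN entries (windows without a defined statistic) are ignored for the
    mean/sd and propagated in the output.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("need >= 2 defined values to Z-transform")
    sd = np.std(x[ok], ddof=1)
    if sd == 0:
        raise ValueError("zero variance: Z-transform undefined")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - np.mean(x[ok])) / sd
    return out


def ld_decay(haplotypes: np.ndarray, positions, max_dist: int,
             n_bins: int = 20) -> pd.DataFrame:
    """Mean pairwise r^2 between segregating sites, binned by distance.

    Monomorphic columns are excluded; raises if fewer than two polymorphic
    sites remain.  Returns a table with bin edges, mean r^2 and pair counts;
    the distance at which mean r^2 halves relative to the shortest-distance
    bin is the usual window-size diagnostic.
    """
    h = np.asarray(haplotypes, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    if h.ndim != 2 or h.shape[1] != pos.size:
        raise ValueError("haplotypes must be (n_hap, n_sites) matching positions")
    p = h.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic sites for LD")
    h = h[:, poly]
    pos = pos[poly]
    # r between 0/1 columns = standard Pearson correlation
    hc = (h - h.mean(axis=0)) / h.std(axis=0)
    r = hc.T @ hc / h.shape[0]
    iu, ju = np.triu_indices(h.shape[1], k=1)
    dist = np.abs(pos[ju] - pos[iu])
    keep = dist <= max_dist
    dist = dist[keep]
    r2 = r[iu, ju][keep] ** 2
    if dist.size == 0:
        raise ValueError("no site pairs within max_dist")
    edges = np.linspace(0, max_dist, n_bins + 1)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    mean_r2 = np.full(n_bins, np.nan)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    nz = counts > 0
    mean_r2[nz] = sums[nz] / counts[nz]
    return pd.DataFrame({
        "dist_low": edges[:-1].astype(int),
        "dist_high": edges[1:].astype(int),
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })


def block_stats(block: HaplotypeBlock) -> dict:
    """Fst, Dxy and within-population pi for one window block."""
    n_w = int((block.pop_labels == "west").sum())
    n_e = int((block.pop_labels == "east").sum())
    d_w = block.derived_counts("west")
    d_e = block.derived_counts("east")
    L = block.length
    out = {
        "contig": block.contig,
        "start": block.start,
        "end": block.end,
        "n_snps": block.n_sites,
        "fst": float("nan"),
        "dxy": dxy(d_w, n_w, d_e, n_e, L) if block.n_sites else 0.0,
        "pi_w": pi(d_w, n_w, L) if (block.n_sites and n_w >= 2) else 0.0,
        "pi_e": pi(d_e, n_e, L) if (block.n_sites and n_e >= 2) else 0.0,
    }
    if block.n_sites and n_w >= 2 and n_e >= 2:
        out["fst"] = hudson_fst(d_w, n_w, d_e, n_e)
    return out


def window_table(blocks: Iterable[HaplotypeBlock], *, min_snps: int = 3,
                 z: bool = True) -> pd.DataFrame:
    """Per-window statistic table for a collection of window blocks.

    Windows with fewer than ``min_snps`` SNPs keep their diversity values
    but get a missing Fst, excluding them from the Z-transformation and any
    downstream outlier calling (sparse windows otherwise dominate the Fst
    tails through sampling noise alone).
    """
    rows = [block_stats(b) for b in blocks]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no windows supplied")
    df.loc[df["n_snps"] < min_snps, "fst"] = np.nan
    if z:
        df["z_fst"] = z_transform(df["fst"].to_numpy())
        df["z_dxy"] = z_transform(df["dxy"].to_numpy())
    return df
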
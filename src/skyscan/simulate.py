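"""Backward-in-time coalescent simulation for the two-deme divergence models.

Windows are simulated independently; within a window, sequence is composed
of fully linked chunks (5 kb by default) drawn as independent genealogies -
the free-recombination-between / no-recombination-within idealization of
the empirical observation that linkage disequilibrium decays inside the
50 kb scan window.  Each chunk genealogy follows the structured coalescent:

* from the present back to ``T_split/2`` each deme has its current size;
* from there back to ``T_split`` its founding size;
* at ``T_split`` the demes merge into an ancestral pool of size
  ``N_anc = N_w0 + N_e0``.

Backward migration moves a lineage in the recipient deme into the source
deme at per-generation rate ``m / N_recipient`` (with ``m`` in expected
migrant individuals per generation, forward direction).  Pairs of lineages
in a deme of diploid size ``N`` coalesce at rate ``1 / (2N)``.

Mutations follow the infinite-sites model: a Poisson number with mean
``total branch length * mu * L`` is placed on branches proportionally to
branch length, at distinct integer positions drawn uniformly in the window.
Derived alleles are the descendants of the mutated branch.

Lineages are tracked as 64-bit descendant bitmasks, capping the total
haplotype count at 64 (the study samples 16).  The genealogy kernels are
numba-compiled; the first call in a session pays a one-off compile cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, uint64

from .models import DemographicModel, ParameterError

__all__ = [
    "HaplotypeBlock",
    "simulate_window",
    "simulate_genome",
    "plant_divergent_region",
    "branch_length_sfs",
    "simulate_genealogy",
]

_MAX_HAPLOTYPES = 64

_B1 = uint64(0x5555555555555555)
_B2 = uint64(0x3333333333333333)
_B4 = uint64(0x0F0F0F0F0F0F0F0F)
_H01 = uint64(0x0101010101010101)


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> uint64(1)) & _B1)
    x = (x & _B2) + ((x >> uint64(2)) & _B2)
    x = (x + (x >> uint64(4))) & _B4
    return (x * _H01) >> uint64(56)


@njit(cache=True)
def _sim_segments(n_w, n_e, nw1, ne1, nw0, ne0, nanc,
                  t_change, t_split, m_we, m_ew, masks, lens,
                  lin_mask, lin_deme, lin_birth):
    """One structured-coalescent genealogy.

    Fills ``masks``/``lens`` with the descendant bitmask and branch length
    of every edge segment and returns the segment count (2 * (n - 1)).
    ``lin_*`` are scratch buffers of length n.  Uses numba's module-level
    RNG; seed before calling.
    """
    n = n_w + n_e
    for i in range(n):
        lin_birth[i] = 0.0
        lin_mask[i] = uint64(1) << uint64(i)
        lin_deme[i] = 0 if i < n_w else 1
    k = n
    t = 0.0
    nseg = 0
    merged = t_split <= 0.0
    while k > 1:
        if merged:
            Nw = nanc
            Ne = nanc
            mw = 0.0
            me = 0.0
            boundary = 1.0e300
        elif t < t_change:
            Nw = nw1
            Ne = ne1
            mw = m_we
            me = m_ew
            boundary = t_change
        else:
            Nw = nw0
            Ne = ne0
            mw = m_we
            me = m_ew
            boundary = t_split

        kw = 0
        for i in range(k):
            if lin_deme[i] == 0:
                kw += 1
        ke = k - kw
        r_cw = kw * (kw - 1) / (4.0 * Nw)
        r_ce = ke * (ke - 1) / (4.0 * Ne)
        # backward migration: a lineage now in east traces to west at m_we/Ne
        r_me = ke * mw / Ne if not merged else 0.0
        r_mw = kw * me / Nw if not merged else 0.0
        total = r_cw + r_ce + r_me + r_mw

        advance_to_boundary = False
        if total <= 0.0:
            advance_to_boundary = True
        else:
            dt = np.random.exponential(1.0 / total)
            if t + dt >= boundary:
                advance_to_boundary = True
        if advance_to_boundary:
            t = boundary
            if t >= t_split and not merged:
                merged = True
                for i in range(k):
                    lin_deme[i] = 0
            continue
        t += dt

        u = np.random.random() * total
        if u < r_cw + r_ce:
            deme = 0 if u < r_cw else 1
            kd = kw if deme == 0 else ke
            # pick two distinct lineages (ordinals a < b) within the deme
            a = int(np.random.random() * kd)
            b = int(np.random.random() * (kd - 1))
            if b >= a:
                b += 1
            if a > b:
                a, b = b, a
            ia = -1
            ib = -1
            seen = 0
            for i in range(k):
                if lin_deme[i] == deme:
                    if seen == a:
                        ia = i
                    elif seen == b:
                        ib = i
                    seen += 1
            # record the two child edges
            masks[nseg] = lin_mask[ia]
            lens[nseg] = t - lin_birth[ia]
            masks[nseg + 1] = lin_mask[ib]
            lens[nseg + 1] = t - lin_birth[ib]
            nseg += 2
            lin_mask[ia] = lin_mask[ia] | lin_mask[ib]
            lin_birth[ia] = t
            # remove ib by swapping in the last lineage
            lin_mask[ib] = lin_mask[k - 1]
            lin_deme[ib] = lin_deme[k - 1]
            lin_birth[ib] = lin_birth[k - 1]
            k -= 1
        elif u < r_cw + r_ce + r_me:
            # migration: an east lineage jumps to west (backward)
            a = int(np.random.random() * ke)
            seen = 0
            for i in range(k):
                if lin_deme[i] == 1:
                    if seen == a:
                        lin_deme[i] = 0
                        break
                    seen += 1
        else:
            a = int(np.random.random() * kw)
            seen = 0
            for i in range(k):
                if lin_deme[i] == 0:
                    if seen == a:
                        lin_deme[i] = 1
                        break
                    seen += 1
    return nseg


@njit(cache=True)
def _sim_one(n_w, n_e, nw1, ne1, nw0, ne0, nanc, t_change, t_split,
             m_we, m_ew, seed, masks, lens):
    np.random.seed(seed)
    n = n_w + n_e
    lin_mask = np.empty(n, np.uint64)
    lin_deme = np.empty(n, np.int8)
    lin_birth = np.zeros(n, np.float64)
    return _sim_segments(n_w, n_e, nw1, ne1, nw0, ne0, nanc,
                         t_change, t_split, m_we, m_ew, masks, lens,
                         lin_mask, lin_deme, lin_birth)


@njit(cache=True)
def _sfs_branch_lengths(n_w, n_e, nw1, ne1, nw0, ne0, nanc, t_change,
                        t_split, m_we, m_ew, n_sims, seed, out):
    """Accumulate, over ``n_sims`` genealogies, the total branch length
    subtending exactly (i west, j east) sampled haplotypes into ``out``."""
    np.random.seed(seed)
    n = n_w + n_e
    masks = np.empty(2 * n, np.uint64)
    lens = np.empty(2 * n, np.float64)
    lin_mask = np.empty(n, np.uint64)
    lin_deme = np.empty(n, np.int8)
    lin_birth = np.zeros(n, np.float64)
    wmask = (uint64(1) << uint64(n_w)) - uint64(1)
    for _ in range(n_sims):
        nseg = _sim_segments(n_w, n_e, nw1, ne1, nw0, ne0, nanc,
                             t_change, t_split, m_we, m_ew, masks, lens,
                             lin_mask, lin_deme, lin_birth)
        for g in range(nseg):
            i = int(_popcount(masks[g] & wmask))
            j = int(_popcount(masks[g] >> uint64(n_w)))
            out[i, j] += lens[g]


def _check_sample(model: DemographicModel, n_w: int, n_e: int) -> None:
    if not isinstance(model, DemographicModel):
        raise TypeError("model must be a DemographicModel")
    if n_w < 0 or n_e < 0 or n_w + n_e < 2:
        raise ParameterError("need at least two sampled haplotypes in total")
    if n_w + n_e > _MAX_HAPLOTYPES:
        raise ParameterError(f"at most {_MAX_HAPLOTYPES} haplotypes supported")


def _kernel_args(model: DemographicModel) -> tuple:
    return (model.N_w1, model.N_e1, model.N_w0, model.N_e0, model.N_anc,
            model.T_change, model.T_split, model.m_we, model.m_ew)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class HaplotypeBlock:
    """Phased 0/1 haplotypes over a genomic interval.

    ``haplotypes`` is a (n_haplotypes, n_sites) uint8 matrix with 0 =
    ancestral and 1 = derived; ``positions`` are strictly increasing 0-based
    coordinates within ``[start, end)``; ``pop_labels`` assigns each
    haplotype row to a population ("west"/"east").
    """

    contig: str
    start: int
    end: int
    positions: np.ndarray
    haplotypes: np.ndarray
    pop_labels: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape != (len(self.pop_labels), len(self.positions)):
            raise ValueError("haplotype matrix shape inconsistent with labels/positions")
        if self.positions.size:
            if self.positions[0] < self.start or self.positions[-1] >= self.end:
                raise ValueError("positions outside [start, end)")
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def length(self) -> int:
        return self.end - self.start

    def pop_matrix(self, pop: str) -> np.ndarray:
        return self.haplotypes[self.pop_labels == pop]

    def derived_counts(self, pop: str) -> np.ndarray:
        """Per-site derived-allele counts within a population."""
        return self.pop_matrix(pop).sum(axis=0).astype(np.int64)


def simulate_genealogy(model: DemographicModel, n_w: int, n_e: int, seed):
    """Simulate one genealogy; return (descendant bitmasks, branch lengths).

    The bitmask of a branch has bit ``i`` set when sampled haplotype ``i``
    (west haplotypes first) descends from it.
    """
    _check_sample(model, n_w, n_e)
    ss = _seedseq(seed)
    n = n_w + n_e
    masks = np.empty(2 * n, np.uint64)
    lens = np.empty(2 * n, np.float64)
    nseg = _sim_one(n_w, n_e, *_kernel_args(model), _kernel_seed(ss), masks, lens)
    return masks[:nseg].copy(), lens[:nseg].copy()


def _simulate_chunk(model, n_w, n_e, L, kernel_seed, rng, masks, lens):
    """One fully linked chunk: genealogy + infinite-sites mutations.

    Returns (positions within [0, L), site bitmasks).
    """
    nseg = _sim_one(n_w, n_e, *_kernel_args(model), kernel_seed,
                    masks, lens)
    mk, ln = masks[:nseg], lens[:nseg]
    tbl = float(ln.sum())
    n_mut = rng.poisson(tbl * model.mu * L) if model.mu > 0 else 0
    n_mut = min(n_mut, L)  # infinite-sites cap: one mutation per site
    if n_mut == 0:
        return np.empty(0, np.int64), np.empty(0, np.uint64)
    seg_idx = rng.choice(nseg, size=n_mut, p=ln / tbl)
    # distinct positions by collision re-draw (cheap: n_mut << L)
    pos = rng.integers(0, L, size=n_mut)
    uniq, first = np.unique(pos, return_index=True)
    while uniq.size < n_mut:
        taken = set(uniq.tolist())
        dup_mask = np.ones(n_mut, bool)
        dup_mask[first] = False
        for i in np.nonzero(dup_mask)[0]:
            p = int(rng.integers(0, L))
            while p in taken:
                p = int(rng.integers(0, L))
            taken.add(p)
            pos[i] = p
        uniq, first = np.unique(pos, return_index=True)
    order = np.argsort(pos)
    return pos[order].astype(np.int64), mk[seg_idx[order]].copy()


#: default length of a fully linked sub-window chunk (bp); linkage
#: disequilibrium decays within the 50 kb scan window, so a window is
#: modelled as independent chunks of this size rather than one genealogy
DEFAULT_CHUNK = 5_000


def simulate_window(model: DemographicModel, n_w: int, n_e: int, L: int,
                    seed, *, contig: str = "chr1", start: int = 0,
                    chunk_size: int = DEFAULT_CHUNK) -> HaplotypeBlock:
    """Simulate one window of ``L`` sites.

    The window is composed of independent fully linked chunks of
    ``chunk_size`` bp (free recombination between chunks, none within),
    mirroring the empirical premise that linkage disequilibrium decays
    within the scan window.  ``chunk_size >= L`` gives a single genealogy
    for the whole window.  Returns a :class:`HaplotypeBlock` whose columns
    are the segregating sites; with ``mu = 0`` the block is empty.
    """
    _check_sample(model, n_w, n_e)
    L = int(L)
    if L <= 0:
        raise ParameterError("window length L must be > 0")
    chunk_size = int(chunk_size)
    if chunk_size <= 0:
        raise ParameterError("chunk_size must be > 0")
    n = n_w + n_e
    labels = np.array(["west"] * n_w + ["east"] * n_e)
    n_chunks = max(1, L // chunk_size)
    bounds = np.linspace(0, L, n_chunks + 1).astype(np.int64)
    masks = np.empty(2 * n, np.uint64)
    lens = np.empty(2 * n, np.float64)
    ss = _seedseq(seed)
    kernel_seeds = ss.generate_state(n_chunks + 1)
    rng = np.random.default_rng(int(kernel_seeds[-1]))
    all_pos = []
    all_masks = []
    for c, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        pos, mk = _simulate_chunk(model, n_w, n_e, int(hi - lo),
                                  int(kernel_seeds[c] & 0x7FFFFFFF), rng,
                                  masks, lens)
        all_pos.append(pos + lo)
        all_masks.append(mk)
    pos = np.concatenate(all_pos) + start
    site_masks = np.concatenate(all_masks)
    if pos.size == 0:
        return HaplotypeBlock(contig, start, start + L,
                              np.empty(0, np.int64),
                              np.zeros((n, 0), np.uint8), labels)
    bits = np.arange(n, dtype=np.uint64)
    haps = ((site_masks[None, :] >> bits[:, None]) & uint64(1)).astype(np.uint8)
    return HaplotypeBlock(contig, start, start + L, pos, haps, labels)


def simulate_genome(model: DemographicModel, n_w: int, n_e: int,
                    n_windows: int, L: int, seed, *, contig: str = "chr1",
                    chunk_size: int = DEFAULT_CHUNK) -> list[HaplotypeBlock]:
    """Independent windows tiled consecutively along one contig.

    Per-window seeds come from a counter-based split of the master seed, so
    the same master seed always reproduces the same genome and any window
    can be re-simulated individually.
    """
    if n_windows < 1:
        raise ParameterError("n_windows must be >= 1")
    seeds = _seedseq(seed).generate_state(n_windows)
    return [
        simulate_window(model, n_w, n_e, L, int(seeds[i]), contig=contig,
                        start=i * int(L), chunk_size=chunk_size)
        for i in range(n_windows)
    ]


def plant_divergent_region(model: DemographicModel, block: HaplotypeBlock,
                           pop: str, shrink: float, seed, *,
                           chunk_size: int = DEFAULT_CHUNK) -> HaplotypeBlock:
    """Re-simulate a window with the focal deme's current size shrunk.

    Multiplying the focal population's present-day size by ``shrink``
    (0 < shrink < 1) strengthens local drift, depressing within-population
    diversity there and inflating window Fst - a stand-in for a locally
    swept/divergent region with a known location, used to generate
    true-positive windows for power checks.
    """
    if not 0 < shrink < 1:
        raise ParameterError("shrink must lie in (0, 1)")
    if pop not in ("west", "east"):
        raise ValueError("pop must be 'west' or 'east'")
    import dataclasses as _dc

    # constant-size models must be promoted so the local size can differ
    promoted = {"M1": "M3", "M2": "M4"}.get(model.model_id, model.model_id)
    key = "N_w1" if pop == "west" else "N_e1"
    local = _dc.replace(model, model_id=promoted,
                        **{key: getattr(model, key) * shrink})
    n_w = int(np.sum(block.pop_labels == "west"))
    n_e = int(np.sum(block.pop_labels == "east"))
    return simulate_window(local, n_w, n_e, block.length, seed,
                           contig=block.contig, start=block.start,
                           chunk_size=chunk_size)


def branch_length_sfs(model: DemographicModel, n_w: int, n_e: int,
                      n_sims: int, seed) -> np.ndarray:
    """Mean branch length subtending each joint frequency class.

    Entry (i, j) is the Monte-Carlo mean, over ``n_sims`` genealogies, of
    the total branch length whose mutations would appear in i of the west
    and j of the east haplotypes.  Multiplying by ``mu * L`` gives the
    expected count of such sites per window of length L, the basis of the
    expected joint SFS.
    """
    _check_sample(model, n_w, n_e)
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    out = np.zeros((n_w + 1, n_e + 1), np.float64)
    seed32 = _kernel_seed(_seedseq(seed))
    _sfs_branch_lengths(n_w, n_e, *_kernel_args(model), n_sims, seed32, out)
    return out / n_sims
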
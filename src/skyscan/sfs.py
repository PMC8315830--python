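"""Joint-SFS demographic inference for the divergence models M1-M4.

The observed data are summarized as a two-dimensional *unfolded* site
frequency spectrum over the two populations, **including the monomorphic
class** - keeping invariant sites anchors the absolute mutation input
``mu * L`` and hence the size/time scaling of the models, given the fixed
per-generation mutation rate.

Fitting is by multinomial composite likelihood against a Monte-Carlo
expected SFS: cell probabilities are obtained from simulated genealogy
branch lengths under the candidate parameters (probability of a site
falling in joint class (i, j) is ``mu`` times the mean branch length
subtending i west / j east samples; the remaining mass is monomorphic).
Each *estimation loop* refreshes the Monte-Carlo expectation and takes one
bounded Nelder-Mead improvement pass over log-scaled parameters, with
common random numbers within a loop so the search optimizes a fixed
(noisy-but-frozen) surface.  Model choice is by AIC; replicate fits give
top-fraction confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import MODEL_IDS, DemographicModel, ParameterError
from .simulate import HaplotypeBlock, branch_length_sfs

__all__ = [
    "Sfs2D",
    "FitResult",
    "build_sfs",
    "build_sfs_from_vcf",
    "expected_sfs",
    "composite_loglik",
    "fit_model",
    "select_model",
    "param_ci",
    "SEARCH_BOUNDS",
]

log = logging.getLogger(__name__)

#: log10 search bounds for the free parameters
SEARCH_BOUNDS = {
    "N_w0": (2.0, 6.0),
    "N_e0": (2.0, 6.0),
    "N_w1": (2.0, 6.0),
    "N_e1": (2.0, 6.0),
    "T_split": (1.0, 5.0),
    "m_we": (-4.0, 1.0),
    "m_ew": (-4.0, 1.0),
}


@dataclass
class Sfs2D:
    """2-D unfolded site frequency spectrum including the monomorphic class.

    ``counts[i, j]`` is the number of sites with i derived copies among the
    west haplotypes and j among the east; cell (0, 0) holds the monomorphic
    (all-ancestral) sites, so ``total_sites`` is the full sequence length
    analysed.
    """

    counts: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_w(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n_e(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts,
                          index=[f"w{i}" for i in range(self.n_w + 1)],
                          columns=[f"e{j}" for j in range(self.n_e + 1)])
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "Sfs2D":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float))


@dataclass
class FitResult:
    """One replicate fit of a demographic model."""

    model: DemographicModel
    loglik: float
    replicate_id: int = 0

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def k(self) -> int:
        return self.model.n_free_params

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


def build_sfs(blocks: Iterable[HaplotypeBlock]) -> Sfs2D:
    """Joint SFS from haplotype blocks, monomorphic complement included."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks supplied")
    n_w = int((blocks[0].pop_labels == "west").sum())
    n_e = int((blocks[0].pop_labels == "east").sum())
    counts = np.zeros((n_w + 1, n_e + 1), np.float64)
    total_len = 0
    for b in blocks:
        total_len += b.length
        if b.n_sites:
            np.add.at(counts, (b.derived_counts("west"), b.derived_counts("east")), 1.0)
    counts[0, 0] += total_len - counts.sum()
    return Sfs2D(counts)


def build_sfs_from_vcf(path, pops: Mapping[str, str],
                       contig_lengths: Mapping[str, int]) -> Sfs2D:
    """Joint SFS from a polarized VCF plus total callable contig lengths.

    Re-polarizes sites whose ``AA`` matches ALT and drops sites whose
    ancestral call matches neither allele (count kept in ``n_dropped``);
    the monomorphic class is the callable length not occupied by retained
    variants.
    """
    from .io import read_vcf

    blocks = read_vcf(path, pops)
    if not blocks:
        raise ValueError("no variants found in VCF")
    dropped = blocks[0].n_dropped_polarization
    n_w = int((blocks[0].pop_labels == "west").sum())
    n_e = int((blocks[0].pop_labels == "east").sum())
    counts = np.zeros((n_w + 1, n_e + 1), np.float64)
    for b in blocks:
        if b.n_sites:
            np.add.at(counts, (b.derived_counts("west"), b.derived_counts("east")), 1.0)
    total_len = sum(int(v) for v in contig_lengths.values())
    mono = total_len - counts.sum() - dropped
    if mono < 0:
        raise ValueError("contig lengths smaller than variant count")
    counts[0, 0] += mono
    return Sfs2D(counts, n_dropped=dropped)


def expected_total_branch_length(model: DemographicModel, n_w: int,
                                 n_e: int) -> float:
    """Exact expected total genealogy branch length under the step model.

    Works on the continuous-time Markov chain over lineage counts
    ``(k_west, k_east)`` (coalescence and backward migration moves),
    integrating occupation times over the two post-split epochs by the
    augmented-matrix exponential identity and solving the absorbed
    single-deme chain for the ancestral phase.  E[TBL] is the
    occupation-weighted lineage count over all states with >= 2 lineages.

    This scalar anchors the monomorphic class of the expected SFS: using
    it exactly removes the dominant Monte-Carlo noise term from the
    composite likelihood (the polymorphic *shape* still comes from
    simulation).
    """
    from scipy.linalg import expm, solve

    n_tot = n_w + n_e
    states = [(kw, ke) for kw in range(n_tot + 1) for ke in range(n_tot + 1)
              if 1 <= kw + ke <= n_tot]
    index = {s: i for i, s in enumerate(states)}
    S = len(states)

    def epoch_Q(Nw, Ne, m_we, m_ew):
        Q = np.zeros((S, S))
        for (kw, ke), i in index.items():
            if kw + ke == 1:
                continue  # absorbed
            if kw >= 2:
                Q[i, index[(kw - 1, ke)]] += kw * (kw - 1) / (4.0 * Nw)
            if ke >= 2:
                Q[i, index[(kw, ke - 1)]] += ke * (ke - 1) / (4.0 * Ne)
            if ke >= 1:
                Q[i, index[(kw + 1, ke - 1)]] += ke * m_we / Ne
            if kw >= 1:
                Q[i, index[(kw - 1, ke + 1)]] += kw * m_ew / Nw
            Q[i, i] = -Q[i].sum()
        return Q

    p = np.zeros(S)
    p[index[(n_w, n_e)]] = 1.0
    kvec = np.array([kw + ke for kw, ke in states], dtype=float)
    active = (kvec >= 2).astype(float)
    tbl = 0.0
    for tau, Nw, Ne in ((model.T_change, model.N_w1, model.N_e1),
                        (model.T_split - model.T_change, model.N_w0,
                         model.N_e0)):
        if tau <= 0:
            continue
        Q = epoch_Q(Nw, Ne, model.m_we, model.m_ew)
        M = np.zeros((2 * S, 2 * S))
        M[:S, :S] = Q
        M[:S, S:] = np.eye(S)
        E = expm(M * tau)
        occ = p @ E[:S, S:]
        tbl += float(occ @ (kvec * active))
        p = p @ E[:S, :S]
    # ancestral phase: one deme, absorb at a single lineage
    n = n_w + n_e
    pk = np.zeros(n + 1)
    for (kw, ke), i in index.items():
        pk[kw + ke] += p[i]
    if n >= 2:
        trans = list(range(2, n + 1))
        Qa = np.zeros((len(trans), len(trans)))
        for a, k in enumerate(trans):
            rate = k * (k - 1) / (4.0 * model.N_anc)
            Qa[a, a] = -rate
            if k - 1 >= 2:
                Qa[a, trans.index(k - 1)] = rate
        occ = solve(-Qa.T, pk[2:])
        tbl += float(occ @ np.array(trans, dtype=float))
    return tbl


def expected_sfs(model: DemographicModel, n_w: int, n_e: int, n_sims: int,
                 seed, *, floor: float | None = None,
                 exact_scale: bool = True) -> np.ndarray:
    """Expected per-site cell probabilities under ``model``.

    The polymorphic-cell *shape* is Monte-Carlo (simulated genealogy
    branch lengths); with ``exact_scale`` the overall polymorphic mass is
    anchored by the exact expected total branch length, which removes the
    dominant source of likelihood noise.  Zero cells are floored at
    ``0.1 / n_sims`` (a guard against -inf composite likelihoods for
    classes the finite simulation never produced) and the matrix is
    renormalized to sum to one.
    """
    bl = branch_length_sfs(model, n_w, n_e, n_sims, seed)
    if exact_scale:
        mc_total = bl.sum()
        if mc_total > 0:
            bl = bl * (expected_total_branch_length(model, n_w, n_e)
                       / mc_total)
    p = bl * model.mu
    mono = 1.0 - p.sum()
    if mono <= 0:
        raise ParameterError(
            "expected polymorphic mass exceeds 1; mu or sizes unrealistic")
    p[0, 0] = mono
    if floor is None:
        floor = 0.1 / n_sims
    zero = p == 0.0
    if zero.any():
        p[zero] = floor
    return p / p.sum()


def composite_loglik(obs: Sfs2D, exp_probs: np.ndarray) -> float:
    """Multinomial composite log-likelihood sum(obs * log p) over cells."""
    p = np.asarray(exp_probs, dtype=float)
    o = obs.counts
    if p.shape != o.shape:
        raise ValueError("observed and expected SFS shapes differ")
    mask = o > 0
    if np.any(p[mask] <= 0):
        bad = int(np.sum(p[mask] <= 0))
        log.warning("flooring %d zero expected cells with observed mass", bad)
        p = p.copy()
        p[p <= 0] = np.finfo(float).tiny
    return float(np.sum(o[mask] * np.log(p[mask])))


def sfs_moments(obs: Sfs2D) -> tuple[float, float, float]:
    """(pi_west, pi_east, dxy) per site implied by a joint SFS."""
    n_w, n_e = obs.n_w, obs.n_e
    i = np.arange(n_w + 1)[:, None] / n_w
    j = np.arange(n_e + 1)[None, :] / n_e
    c = obs.counts
    tot = obs.total_sites
    pi_w = float((c * (2 * i * (1 - i) * n_w / max(n_w - 1, 1))).sum() / tot)
    pi_e = float((c * (2 * j * (1 - j) * n_e / max(n_e - 1, 1))).sum() / tot)
    d = float((c * (i * (1 - j) + j * (1 - i))).sum() / tot)
    return pi_w, pi_e, d


def _pair_moments(T: float, Nc: float, N0: float, m: float) -> tuple[float, float]:
    """Exact (E[T2 within], E[T2 between]) for a symmetric two-deme pair.

    Backward 3-state chain over the unordered pair locations (same deme /
    different demes) with symmetric migration ``m`` migrants/generation,
    current size ``Nc`` to T/2, founding size ``N0`` to T, then one
    ancestral pool of size ``2 N0``.  Occupation times come from the
    augmented matrix exponential per epoch.  These moments drive the
    method-of-moments candidate grid: pi = 2 mu E[T2 within] and
    dxy = 2 mu E[T2 between].
    """
    from scipy.linalg import expm

    # states: 0 = same deme (uncoalesced), 1 = different demes
    occ = np.zeros(2)
    p = np.eye(2)  # rows: starting state
    for tau, N in ((T / 2.0, Nc), (T / 2.0, N0)):
        if tau <= 0:
            continue
        coal = 1.0 / (2.0 * N)
        mig = m / N
        Q = np.array([[-(coal + 2 * mig), 2 * mig],
                      [2 * mig, -2 * mig]])
        M = np.zeros((4, 4))
        M[:2, :2] = Q
        M[:2, 2:] = np.eye(2)
        E = expm(M * tau)
        occ = occ + p @ E[:2, 2:] @ np.ones(2)
        p = p @ E[:2, :2]
    # ancestral pool of size N_anc = 2 N0
    occ = occ + p @ np.ones(2) * 2.0 * (2.0 * N0)
    return float(occ[0]), float(occ[1])


def _moment_candidates(obs: Sfs2D, model_id: str, mu: float) -> list[np.ndarray]:
    """Method-of-moments candidate starting points from pi and dxy.

    ``dxy = 2 mu (T + 2 N_anc)`` with ``N_anc = N_w0 + N_e0`` ties the
    founding sizes to any candidate split time.  Matching the observed
    within-population diversity then leaves, for the constant-size models,
    a handful of split times and, for the decline models, a whole
    (T, N_current) ridge - pi and dxy alone cannot separate a recent hard
    decline from an old mild one.  All ridge points are returned; the
    likelihood screening stage discriminates along the ridge using the
    full SFS shape.  Parameters are on the natural scale.
    """
    pi_w, pi_e, d = sfs_moments(obs)
    if d <= 0 or pi_w <= 0 or pi_e <= 0:
        return []
    pi_bar = 0.5 * (pi_w + pi_e)
    T_grid = np.logspace(1.1, 4.8, 14)
    m_grid = [1e-4] if model_id in ("M1", "M3") else [1e-4, 0.05, 0.5, 2.0]
    with_decline = model_id in ("M3", "M4")
    with_mig = model_id in ("M2", "M4")

    def solve_n0(T, Nc_of, m):
        """N0 matching observed dxy at (T, m), or None; Nc may track N0."""
        lo_, hi_ = 2.0, 6.0
        f_lo = 2 * mu * _pair_moments(T, Nc_of(10 ** lo_), 10 ** lo_, m)[1] - d
        f_hi = 2 * mu * _pair_moments(T, Nc_of(10 ** hi_), 10 ** hi_, m)[1] - d
        if f_lo > 0 or f_hi < 0:
            return None
        for _ in range(12):
            mid = 0.5 * (lo_ + hi_)
            f = 2 * mu * _pair_moments(T, Nc_of(10 ** mid), 10 ** mid, m)[1] - d
            if f > 0:
                hi_ = mid
            else:
                lo_ = mid
        return 10 ** (0.5 * (lo_ + hi_))

    out = []
    Nc_grid = np.logspace(2.1, 5.7, 16) if with_decline else [None]
    for T in T_grid:
        for m in m_grid:
            best = None
            for Nc in Nc_grid:
                nc_of = (lambda n0, _Nc=Nc: _Nc) if with_decline else (lambda n0: n0)
                N0 = solve_n0(T, nc_of, m)
                if N0 is None:
                    continue
                nc = Nc if with_decline else N0
                pred = 2 * mu * _pair_moments(T, nc, N0, m)[0]
                err = abs(np.log(pred / pi_bar))
                if best is None or err < best[0]:
                    best = (err, N0, nc)
            if best is None or best[0] > np.log(1.4):
                continue
            _, N0, nc = best
            vec = [N0, N0]
            if with_decline:
                vec += [nc, nc]
            vec += [T]
            if with_mig:
                vec += [m, m]
            out.append(np.array(vec))
    return out


def _template(model_id: str) -> DemographicModel:
    """A valid mid-bounds model used to carry fixed fields during fitting."""
    base = dict(model_id=model_id, N_w0=1e4, N_e0=1e4, N_w1=1e4, N_e1=1e4,
                T_split=1e3)
    if model_id in ("M2", "M4"):
        base.update(m_we=0.01, m_ew=0.01)
    return DemographicModel(**base)


def _from_log10(template: DemographicModel, x: np.ndarray,
                names: Sequence[str]) -> DemographicModel:
    lo = np.array([SEARCH_BOUNDS[p][0] for p in names])
    hi = np.array([SEARCH_BOUNDS[p][1] for p in names])
    vals = 10.0 ** np.clip(x, lo, hi)
    return template.with_free_params(vals)


def _entropy(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


def fit_model(obs: Sfs2D, model_id: str, *, n_loops: int = 20,
              n_sims_per_loop: int = 200_000, seed=0, replicate_id: int = 0,
              init: Sequence[float] | None = None, mu: float | None = None,
              n_starts: int = 24, n_polish: int = 3,
              n_sims_per_eval: int | None = None,
              final_sims: int | None = None, final_seed=None) -> FitResult:
    """Fit one model to an observed joint SFS by iterated Monte-Carlo search.

    The search runs in three phases, all on log10-scaled free parameters
    and all using common random numbers (a frozen per-phase RNG stream) so
    that the Monte-Carlo expected SFS is a deterministic function of the
    parameters within a phase:

    1. *multistart screening* - ``n_starts`` log-uniform draws inside the
       search bounds are scored cheaply and the best becomes the start
       point (skipped when ``init`` is given);
    2. *estimation loops* - each of the ``n_loops`` loops refreshes the
       Monte-Carlo stream and spends roughly ``n_sims_per_loop``
       simulations across one bounded Nelder-Mead improvement pass;
    3. *final evaluation* - the log-likelihood at the best parameters is
       recomputed with ``final_sims`` fresh simulations (default: the
       per-loop budget).  Passing the same ``final_seed`` when fitting
       competing models correlates their Monte-Carlo error, sharpening
       AIC comparisons.

    Deterministic for fixed ``seed``/``replicate_id``.
    """
    if model_id not in MODEL_IDS:
        raise ParameterError(f"unknown model_id {model_id!r}")
    if n_loops < 1 or n_sims_per_loop < 100:
        raise ParameterError("n_loops >= 1 and n_sims_per_loop >= 100 required")
    template = _template(model_id)
    if mu is not None:
        import dataclasses
        template = dataclasses.replace(template, mu=mu)
    names = template.free_param_names()
    k = len(names)
    n_w, n_e = obs.n_w, obs.n_e
    if isinstance(seed, (list, tuple, np.ndarray)):
        entropy = [int(v) & 0x7FFFFFFF for v in seed]
    else:
        entropy = [int(seed) & 0x7FFFFFFF]
    ss = np.random.SeedSequence(entropy + [replicate_id])
    ss_init, ss_screen, *loop_seeds = ss.spawn(n_loops + 3)
    rng = np.random.default_rng(ss_init)
    lo = np.array([SEARCH_BOUNDS[p][0] for p in names])
    hi = np.array([SEARCH_BOUNDS[p][1] for p in names])
    maxfev = 40 + 12 * k
    if n_sims_per_eval is None:
        n_sims_per_eval = max(2000, n_sims_per_loop // maxfev)
    n_eval_sims = n_sims_per_eval

    def make_objective(stream_seed, n_sims):
        def objective(xv):
            m = _from_log10(template, xv, names)
            p = expected_sfs(m, n_w, n_e, n_sims, stream_seed,
                             exact_scale=False)
            ll = composite_loglik(obs, p)
            if not np.isfinite(ll):
                raise ParameterError(
                    f"non-finite composite likelihood for {model_id} at {m}")
            return -ll
        return objective

    if init is not None:
        seeds_x = [np.log10(np.asarray(init, dtype=float))]
    else:
        starts = [np.clip(np.log10(m), lo, hi)
                  for m in _moment_candidates(obs, model_id, template.mu)]
        starts += [rng.uniform(lo, hi) for _ in range(max(1, n_starts))]
        screen = make_objective(ss_screen, max(20_000, n_sims_per_loop // 10))
        scores = np.array([screen(s) for s in starts])
        # Histories differing mainly in split time can mimic each other
        # closely in the joint SFS (a short hard decline vs a long mild
        # one), so a single best-score start would often land in the wrong
        # basin.  Bin the candidates by log10 split time, keep the best
        # start per bin, and polish the best few bins; the final
        # large-simulation paired evaluation ranks the basins.
        t_idx = names.index("T_split")
        bins: dict[int, int] = {}
        for idx in np.argsort(scores):
            b = int(starts[idx][t_idx] / 0.4)
            if b not in bins:
                bins[b] = idx
        reps = sorted(bins.values(), key=lambda i: scores[i])
        seeds_x = [starts[i] for i in reps[:max(1, n_polish)]]

    polished = []
    for c, x in enumerate(seeds_x):
        for loop in range(n_loops):
            objective = make_objective(
                np.random.SeedSequence([_entropy(loop_seeds[loop]), c]),
                n_eval_sims)
            res = minimize(objective, x, method="Nelder-Mead",
                           options={"maxfev": maxfev, "xatol": 1e-3,
                                    "fatol": 0.5, "adaptive": True})
            x = np.clip(res.x, lo, hi)
        polished.append(x)
    # the starting points themselves stay in contention: a Nelder-Mead pass
    # on a noisy surface can drift out of a shallow true basin
    polished.extend(seeds_x)

    if final_sims is None:
        final_sims = max(n_sims_per_loop, 10 * n_eval_sims)
    if final_seed is None:
        final_seed = loop_seeds[-1]
    best_model, best_ll = None, -np.inf
    for x in polished:
        m = _from_log10(template, x, names)
        p = expected_sfs(m, n_w, n_e, final_sims, final_seed)
        ll = composite_loglik(obs, p)
        if np.isfinite(ll) and ll > best_ll:
            best_model, best_ll = m, ll
    if best_model is None:
        raise ParameterError(f"non-finite final likelihood for {model_id}")
    return FitResult(model=best_model, loglik=best_ll,
                     replicate_id=replicate_id)


def select_model(fits: Sequence[FitResult]) -> tuple[str, pd.DataFrame]:
    """Minimum-AIC model among per-model fits; ties go to fewer parameters.

    Returns the winning model id and an AIC table sorted best-first.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = [{"model_id": f.model_id, "k": f.k, "loglik": f.loglik,
             "aic": f.aic} for f in fits]
    table = pd.DataFrame(rows).sort_values(["aic", "k"]).reset_index(drop=True)
    return str(table.loc[0, "model_id"]), table


def param_ci(fits: Sequence[FitResult], top_frac: float = 0.05) -> pd.DataFrame:
    """Point estimates and intervals from the most likely replicate fits.

    Keeps the ``top_frac`` highest-likelihood replicates (at least one) and
    reports, per free parameter, the median, min-max range and the
    2.5-97.5 percentile interval among them.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    ids = {f.model_id for f in fits}
    if len(ids) > 1:
        raise ValueError("replicates mix model ids")
    n_keep = max(1, int(round(top_frac * len(fits))))
    top = sorted(fits, key=lambda f: f.loglik, reverse=True)[:n_keep]
    names = top[0].model.free_param_names() + ("N_anc",)
    rows = []
    for p in names:
        vals = np.array([getattr(f.model, p) for f in top])
        rows.append({
            "param": p,
            "estimate": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "q2.5": float(np.percentile(vals, 2.5)),
            "q97.5": float(np.percentile(vals, 97.5)),
            "n_kept": n_keep,
        })
    return pd.DataFrame(rows)
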
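"""Validation experiments: simulator calibration, scan power and error rates.

These are the package's self-checks, driven both by the test suite and by
the reproduction script: closed-form coalescent calibration of the
simulator, false-positive/sensitivity rates of the simulation-calibrated
outlier scan, sweep-scan separation on planted signals, permutation-test
validity, and parameter/model recovery for the demographic fits.  Each
experiment is a plain function returning a dict of numbers, deterministic
for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ranksums

from . import calibrate as cal
from . import enrich as enr
from . import sweep as swp
from .io import make_annotation
from .models import DemographicModel, constant_size_model, m1_default, m4_paper
from .sfs import build_sfs, fit_model, select_model
from .simulate import plant_divergent_region, simulate_genome, simulate_window
from .windows import window_table

__all__ = [
    "watterson_calibration",
    "fst_split_time_trend",
    "outlier_calibration_experiment",
    "sweep_separation_experiment",
    "enrichment_validity_experiment",
    "enrichment_power_experiment",
    "recovery_experiment",
    "model_selection_experiment",
]


def watterson_calibration(n_reps: int = 10_000, N: float = 1000.0,
                          n_hap: int = 8, L: int = 50_000,
                          seed=0) -> dict:
    """Single-population calibration against closed-form expectations.

    Simulates ``n_reps`` windows from one constant-size deme and compares
    mean per-site diversity against E[pi] = 4 N mu and the mean
    segregating-site count against Watterson's E[S] = 4 N mu L sum(1/i);
    the z columns are Monte-Carlo standard-error distances.
    """
    model = constant_size_model(N)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    pis = np.empty(n_reps)
    Ss = np.empty(n_reps)
    for r in range(n_reps):
        b = simulate_window(model, n_hap, 0, L, int(seeds[r]))
        p = b.derived_counts("west") / n_hap
        pis[r] = np.sum(2 * p * (1 - p) * n_hap / (n_hap - 1)) / L
        Ss[r] = b.n_sites
    exp_pi = 4.0 * N * model.mu
    a_n = sum(1.0 / i for i in range(1, n_hap))
    exp_S = 4.0 * N * model.mu * L * a_n
    se_pi = pis.std(ddof=1) / np.sqrt(n_reps)
    se_S = Ss.std(ddof=1) / np.sqrt(n_reps)
    return {
        "n_reps": n_reps,
        "mean_pi": float(pis.mean()), "expected_pi": exp_pi,
        "z_pi": float((pis.mean() - exp_pi) / se_pi),
        "mean_S": float(Ss.mean()), "expected_S": exp_S,
        "z_S": float((Ss.mean() - exp_S) / se_S),
    }


def fst_split_time_trend(T_values=(500.0, 2206.0, 8000.0),
                         n_reps: int = 2000, seed=0) -> dict:
    """Mean Hudson Fst across split times (no migration): must increase."""
    means = []
    ss = np.random.SeedSequence(seed)
    for child, T in zip(ss.spawn(len(T_values)), T_values):
        model = m1_default(T_split=float(T))
        blocks = simulate_genome(model, 8, 8, n_reps, 50_000, child)
        df = window_table(blocks, min_snps=1, z=False)
        means.append(float(df["fst"].mean()))
    return {"T_values": list(map(float, T_values)), "mean_fst": means,
            "monotone": bool(np.all(np.diff(means) > 0))}


def outlier_calibration_experiment(model: DemographicModel | None = None,
                                   n_genomes: int = 200,
                                   n_windows: int = 500,
                                   n_null_replicates: int = 200,
                                   n_planted_genomes: int = 10,
                                   n_planted: int = 10,
                                   shrink: float = 0.05,
                                   seed=0) -> dict:
    """False-positive rate and planted-window sensitivity of the outlier scan.

    The Z(Fst) cutoff is simulated under the true generating model, then
    (i) ``n_genomes`` fresh neutral genomes measure the fraction of windows
    flagged (nominally 5%), and (ii) genomes carrying ``n_planted``
    locally divergent windows (current east size shrunk by ``shrink``)
    measure sensitivity at known locations.
    """
    model = model or m4_paper()
    ss = np.random.SeedSequence(seed)
    ss_null, ss_neutral, ss_plant = ss.spawn(3)
    null = cal.simulate_null(model, 8, 8, n_windows, 50_000,
                             n_replicates=n_null_replicates, seed=ss_null)

    n_flagged = 0
    n_total = 0
    for child in ss_neutral.spawn(n_genomes):
        blocks = simulate_genome(model, 8, 8, n_windows, 50_000, child)
        df = window_table(blocks)
        z = df["z_fst"].to_numpy()
        ok = np.isfinite(z)
        n_flagged += int((z[ok] > null.cutoff).sum())
        n_total += int(ok.sum())
    fpr = n_flagged / n_total

    found = 0
    planted_total = 0
    rng_children = ss_plant.spawn(n_planted_genomes)
    for child in rng_children:
        rng = np.random.default_rng(child)
        blocks = simulate_genome(model, 8, 8, n_windows, 50_000, child)
        idx = rng.choice(n_windows, size=n_planted, replace=False)
        for w in idx:
            blocks[w] = plant_divergent_region(
                model, blocks[w], "east", shrink, int(rng.integers(2 ** 31)))
        df = window_table(blocks)
        flagged, _ = cal.call_outliers(df, null)
        found += int(flagged["outlier"].to_numpy()[idx].sum())
        planted_total += n_planted
    return {
        "cutoff": null.cutoff,
        "false_positive_rate": float(fpr),
        "n_neutral_windows": n_total,
        "sensitivity": found / planted_total,
        "n_planted": planted_total,
    }


def sweep_separation_experiment(model: DemographicModel | None = None,
                                n_windows: int = 500,
                                n_planted: int = 50,
                                shrink: float = 0.05,
                                seed=0) -> dict:
    """Planted-sweep CLR separation and neutral supra-threshold rate.

    Plants ``n_planted`` locally swept windows (east deme) and compares
    their window-maximum CLR against neutral windows (one-sided Wilcoxon),
    plus the fraction of neutral grid points exceeding the simulated 95%
    CLR threshold.
    """
    model = model or m4_paper()
    ss = np.random.SeedSequence(seed)
    ss_data, ss_null, ss_pl = ss.spawn(3)
    rng = np.random.default_rng(ss_pl)
    blocks = simulate_genome(model, 8, 8, n_windows, 50_000, ss_data)
    idx = set(rng.choice(n_windows, size=n_planted, replace=False).tolist())
    for w in idx:
        blocks[w] = plant_divergent_region(
            model, blocks[w], "east", shrink, int(rng.integers(2 ** 31)))
    bg = swp.background_sfs(blocks, "east")
    null_blocks = simulate_genome(model, 8, 8, max(100, n_windows // 2),
                                  50_000, ss_null)
    null_track, _ = swp.scan(null_blocks, "east", background=bg)
    thr = float(np.percentile(null_track["clr"], 95.0))
    track, _ = swp.scan(blocks, "east", background=bg, threshold=thr)
    window_of = (track["pos"] // 50_000).to_numpy()
    per_window_max = track.groupby(window_of)["clr"].max()
    planted_mask = per_window_max.index.isin(idx)
    clr_planted = per_window_max[planted_mask].to_numpy()
    clr_neutral = per_window_max[~planted_mask].to_numpy()
    stat, p = ranksums(clr_planted, clr_neutral, alternative="greater")
    neutral_points = track.loc[~np.isin(window_of, list(idx)), "clr"]
    return {
        "mean_clr_planted": float(clr_planted.mean()),
        "mean_clr_neutral": float(clr_neutral.mean()),
        "wilcoxon_p": float(p),
        "threshold": thr,
        "neutral_exceed_rate": float((neutral_points > thr).mean()),
    }


def enrichment_validity_experiment(n_genomes: int = 200, n_genes: int = 1000,
                                   dev_fraction: float = 0.2008,
                                   n_regions: int = 25,
                                   B: int = 2000, seed=0) -> dict:
    """False-verdict rate of the permutation test under random regions.

    Regions are placed uniformly at random (no real signal), so the strict
    95th-percentile verdict should fire in at most ~5% of genomes.
    """
    genome_windows = [("chr1", i * 50_000, (i + 1) * 50_000)
                      for i in range(1000)]
    fired = 0
    tested = 0
    for child in np.random.SeedSequence(seed).spawn(n_genomes):
        rng = np.random.default_rng(child)
        genes = make_annotation(n_genes, dev_fraction, genome_windows,
                                rng.integers(2 ** 31))
        widx = rng.choice(len(genome_windows), size=n_regions, replace=False)
        regions = [genome_windows[i] for i in widx]
        try:
            res = enr.enrichment_test(regions, genes, B=B,
                                      seed=rng.integers(2 ** 31))
        except ValueError:
            continue  # no gene overlapped: nothing to test
        fired += int(res.significant)
        tested += 1
    return {"false_verdict_rate": fired / tested, "n_genomes": tested}


def enrichment_power_experiment(model: DemographicModel | None = None,
                                n_genomes: int = 10, n_windows: int = 500,
                                n_planted: int = 10, shrink: float = 0.05,
                                focus_prob: float = 0.3,
                                n_genes: int = 1000,
                                dev_fraction: float = 0.2008,
                                n_null_replicates: int = 100,
                                B: int = 2000, seed=0) -> dict:
    """End-to-end enrichment power on planted divergence + biased annotation.

    Each genome carries planted divergent windows; development genes are
    placed inside them with probability ``focus_prob``.  The outlier scan
    is run with a simulated cutoff and the detected regions are tested for
    development-gene enrichment; reports how often the permutation verdict
    fires.
    """
    model = model or m4_paper()
    ss = np.random.SeedSequence(seed)
    ss_null, ss_g = ss.spawn(2)
    null = cal.simulate_null(model, 8, 8, n_windows, 50_000,
                             n_replicates=n_null_replicates, seed=ss_null)
    fired = 0
    tested = 0
    for child in ss_g.spawn(n_genomes):
        rng = np.random.default_rng(child)
        blocks = simulate_genome(model, 8, 8, n_windows, 50_000, child)
        idx = rng.choice(n_windows, size=n_planted, replace=False)
        planted = []
        for w in idx:
            blocks[w] = plant_divergent_region(
                model, blocks[w], "east", shrink, int(rng.integers(2 ** 31)))
            planted.append((blocks[w].contig, blocks[w].start, blocks[w].end))
        windows = [(b.contig, b.start, b.end) for b in blocks]
        genes = make_annotation(n_genes, dev_fraction, windows,
                                rng.integers(2 ** 31),
                                focus_intervals=planted,
                                focus_prob=focus_prob)
        df = window_table(blocks)
        _, regions = cal.call_outliers(df, null)
        if not len(regions):
            continue
        try:
            res = enr.enrichment_test(regions, genes, B=B,
                                      seed=rng.integers(2 ** 31))
        except ValueError:
            continue
        fired += int(res.significant)
        tested += 1
    return {"verdict_rate": fired / max(tested, 1), "n_genomes": tested}


_FIT_KW = dict(n_loops=1, n_sims_per_loop=40_000, n_sims_per_eval=8_000,
               final_sims=300_000)


def recovery_experiment(truth: DemographicModel, n_seeds: int = 20,
                        n_windows: int = 2000, tol: float = 0.25,
                        seed=0, fit_kw: dict | None = None) -> dict:
    """Fit the generating model to its own simulations across seeds.

    Success per seed requires both the ancestral size and the split time
    within ``tol`` relative error.
    """
    fit_kw = dict(_FIT_KW, **(fit_kw or {}))
    hits = []
    rows = []
    for sd in range(n_seeds):
        blocks = simulate_genome(truth, 8, 8, n_windows, 50_000,
                                 [int(seed), sd])
        obs = build_sfs(blocks)
        fit = fit_model(obs, truth.model_id, seed=[int(seed), sd], **fit_kw)
        m = fit.model
        eN = m.N_anc / truth.N_anc - 1
        eT = m.T_split / truth.T_split - 1
        rows.append({"seed": sd, "N_anc": m.N_anc, "T_split": m.T_split,
                     "err_N_anc": eN, "err_T_split": eT})
        hits.append(abs(eN) <= tol and abs(eT) <= tol)
    return {
        "model_id": truth.model_id,
        "n_seeds": n_seeds,
        "n_within_tol": int(sum(hits)),
        "fraction_within_tol": float(np.mean(hits)),
        "fits": rows,
    }


def model_selection_experiment(truth: DemographicModel, n_seeds: int = 10,
                               n_windows: int = 2000, seed=0,
                               candidates=("M1", "M2", "M3", "M4"),
                               fit_kw: dict | None = None) -> dict:
    """How often AIC picks the generating model among all four candidates.

    All candidate models are fit to the same datasets with a shared final
    evaluation stream, so nested models with essentially identical optima
    differ mainly by their parameter-count penalty.  Note that with a
    composite likelihood over linked sites the AIC comparison is
    anti-conservative for the *simpler* generating model: the overfitting
    gain of a richer nested model scales with the per-genealogy linkage
    (tens of log-likelihood units) while the AIC penalty is only 2 per
    parameter, so selection is reliable when the generating model is the
    richest candidate and fragile when it is the simplest.
    """
    fit_kw = dict(_FIT_KW, final_sims=600_000, **(fit_kw or {}))
    wins = 0
    picks = []
    for sd in range(n_seeds):
        blocks = simulate_genome(truth, 8, 8, n_windows, 50_000,
                                 [int(seed) + 7919, sd])
        obs = build_sfs(blocks)
        fits = [fit_model(obs, mid, seed=[int(seed) + 7919, sd], **fit_kw)
                for mid in candidates]
        best, _ = select_model(fits)
        picks.append(best)
        wins += int(best == truth.model_id)
    return {
        "truth": truth.model_id,
        "n_seeds": n_seeds,
        "n_selected_truth": wins,
        "picks": picks,
    }
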
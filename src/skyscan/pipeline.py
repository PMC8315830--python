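"""End-to-end orchestration: simulate -> scan -> fit -> calibrate -> enrich.

The pipeline runs the full analysis on a synthetic genome: simulate a
two-population genome under a divergence scenario (optionally planting
locally divergent windows and an annotation whose development genes favour
them), compute window statistics, fit the demographic models to the joint
SFS and pick one by AIC, calibrate the Z(Fst) outlier cutoff by simulation
under the fitted model, call divergent regions, run the per-population
sweep scans, and test the outlier/sweep gene sets for category enrichment.

Every stage draws from a named substream of the master seed, so re-running
a config reproduces all outputs bit-identically and any stage can be
re-run alone.  A JSON manifest records per-stage inputs, outputs, seeds
and wall time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from . import enrich as enr
from . import io as sio
from . import sfs as ssfs
from . import sweep as swp
from .models import DemographicModel, m4_paper
from .simulate import plant_divergent_region, simulate_genome
from .windows import window_table

__all__ = ["RunConfig", "run_all", "report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "skyscan_run"
    seed: int = 1
    # simulation
    model: dict | None = None          # DemographicModel fields; default M4
    n_windows: int = 200
    window_size: int = 50_000
    n_individuals: int = 4             # diploid individuals per population
    n_planted: int = 0                 # locally divergent windows to plant
    plant_shrink: float = 0.05
    plant_pop: str = "east"
    # annotation
    n_genes: int = 1000
    dev_fraction: float = sio.DEV_FRACTION
    focus_prob: float = 0.0            # P(development gene placed in a planted window)
    # demographic fitting
    fit_models: tuple = ("M1", "M2", "M3", "M4")
    fit_replicates: int = 1
    fit_loops: int = 8
    fit_sims_per_loop: int = 10_000
    # outlier calibration
    null_replicates: int = 2000
    null_percentile: float = 95.0
    # enrichment
    permutations: int = 10_000
    category: str = "development"

    def __post_init__(self) -> None:
        self.fit_models = tuple(self.fit_models)
        for name in ("n_windows", "window_size", "n_individuals", "n_genes",
                     "fit_replicates", "fit_loops", "fit_sims_per_loop",
                     "null_replicates", "permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def demographic_model(self) -> DemographicModel:
        if self.model is None:
            return m4_paper()
        return DemographicModel.from_dict(dict(self.model))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fit_models"] = list(d["fit_models"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage(manifest: dict, name: str, seed, func):
    t0 = time.perf_counter()
    entry = {"stage": name, "seed": int(seed), "status": "ok",
             "outputs": []}
    try:
        outputs = func()
        entry["outputs"] = [str(p) for p in outputs]
    except Exception as exc:  # record partial state; downstream is skipped
        entry["status"] = "failed"
        entry["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)
    return outputs


def run_all(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.demographic_model()
    n_hap = 2 * config.n_individuals
    W = config.window_size
    ss = np.random.SeedSequence(config.seed)
    sub = {name: s for name, s in zip(
        ("simulate", "plant", "annotate", "fit", "null", "sweep", "enrich"),
        ss.spawn(7))}
    seeds = {k: int(v.generate_state(1)[0] & 0x7FFFFFFF) for k, v in sub.items()}
    manifest = {"config": dataclasses.asdict(config), "seed": config.seed,
                "stages": []}
    samples = ([f"west{i}" for i in range(config.n_individuals)]
               + [f"east{i}" for i in range(config.n_individuals)])

    # ---- stage 1: simulate genome (+ planted windows), write inputs
    state = {}

    def sim_stage():
        blocks = simulate_genome(model, n_hap, n_hap, config.n_windows, W,
                                 seeds["simulate"])
        planted_idx = []
        if config.n_planted:
            rng = np.random.default_rng(sub["plant"])
            planted_idx = sorted(rng.choice(config.n_windows,
                                            size=config.n_planted,
                                            replace=False).tolist())
            for j, widx in enumerate(planted_idx):
                blocks[widx] = plant_divergent_region(
                    model, blocks[widx], config.plant_pop,
                    config.plant_shrink, int(rng.integers(2 ** 31)))
        planted = [(b.contig, b.start, b.end)
                   for i, b in enumerate(blocks) if i in set(planted_idx)]
        windows = [(b.contig, b.start, b.end) for b in blocks]
        genes = sio.make_annotation(
            config.n_genes, config.dev_fraction, windows, sub["annotate"],
            focus_intervals=planted or None, focus_prob=config.focus_prob)
        vcf = out / "genome.vcf"
        sio.write_vcf(blocks, samples, vcf)
        fai = out / "contigs.tsv"
        sio.write_contig_lengths({"chr1": config.n_windows * W}, fai)
        bed = out / "genes.bed"
        sio.write_gene_bed(genes, bed)
        (out / "planted.bed").write_text(
            "".join(f"{c}\t{s}\t{e}\n" for c, s, e in planted))
        state.update(blocks=blocks, genes=genes, planted=planted)
        return [vcf, fai, bed, out / "planted.bed"]

    _stage(manifest, "simulate", seeds["simulate"], sim_stage)

    # ---- stage 2: window statistics
    def window_stage():
        df = window_table(state["blocks"])
        path = out / "windows.tsv"
        df.to_csv(path, sep="\t", index=False)
        state["windows"] = df
        return [path]

    _stage(manifest, "windows", seeds["simulate"], window_stage)

    # ---- stage 3: joint SFS + demographic fit + AIC selection
    def fit_stage():
        obs = ssfs.build_sfs(state["blocks"])
        obs.to_tsv(out / "observed.sfs.tsv")
        fits = []
        for mid in config.fit_models:
            for rep in range(config.fit_replicates):
                fits.append(ssfs.fit_model(
                    obs, mid, n_loops=config.fit_loops,
                    n_sims_per_loop=config.fit_sims_per_loop,
                    seed=seeds["fit"], replicate_id=rep, mu=model.mu))
        by_model = {}
        for f in fits:
            if (f.model_id not in by_model
                    or f.loglik > by_model[f.model_id].loglik):
                by_model[f.model_id] = f
        best_id, table = ssfs.select_model(list(by_model.values()))
        table.to_csv(out / "aic.tsv", sep="\t", index=False)
        best = by_model[best_id]
        reps = [f for f in fits if f.model_id == best_id]
        ci = ssfs.param_ci(reps, top_frac=0.05) if len(reps) > 1 else None
        if ci is not None:
            ci.to_csv(out / "param_ci.tsv", sep="\t", index=False)
        fitted = best.model
        (out / "fit.json").write_text(json.dumps({
            "best_model": best_id, "loglik": best.loglik, "aic": best.aic,
            "params": fitted.to_dict(),
            "split_time_years": fitted.split_time_years}, indent=2))
        state["fitted"] = fitted
        return [out / "observed.sfs.tsv", out / "aic.tsv", out / "fit.json"]

    _stage(manifest, "fit", seeds["fit"], fit_stage)

    # ---- stage 4: simulated null + outlier calling
    def null_stage():
        nulls = cal.simulate_nulls(
            state["fitted"], n_hap, n_hap, config.n_windows, W,
            n_replicates=config.null_replicates, seed=seeds["null"],
            percentile=config.null_percentile)
        nulls["z_fst"].to_json(out / "null.json")
        nulls["z_dxy"].to_json(out / "null_dxy.json")
        stats, regions = cal.call_outliers(state["windows"], nulls["z_fst"])
        stats, dxy_regions = cal.call_outliers(stats.rename(
            columns={"outlier": "outlier_fst"}), nulls["z_dxy"])
        stats = stats.rename(columns={"outlier": "outlier_dxy"})
        stats.to_csv(out / "windows_flagged.tsv", sep="\t", index=False)
        cal.write_regions_bed(regions, out / "outliers.bed")
        cal.write_regions_bed(dxy_regions, out / "outliers_dxy.bed")
        state.update(null=nulls["z_fst"], regions=regions,
                     dxy_regions=dxy_regions, flagged=stats)
        return [out / "null.json", out / "null_dxy.json",
                out / "windows_flagged.tsv", out / "outliers.bed",
                out / "outliers_dxy.bed"]

    _stage(manifest, "null", seeds["null"], null_stage)

    # ---- stage 5: sweep scans + population comparison
    def sweep_stage():
        blocks = state["blocks"]
        null_blocks = simulate_genome(
            state["fitted"], n_hap, n_hap,
            max(2, min(config.n_windows, 200)), W, seeds["sweep"])
        outputs = []
        tracks = {}
        regions = {}
        for pop in ("west", "east"):
            bg = swp.background_sfs(blocks, pop)
            null_track, _ = swp.scan(null_blocks, pop, background=bg)
            thr = float(np.percentile(null_track["clr"], 95.0))
            track, regs = swp.scan(blocks, pop, background=bg, threshold=thr)
            path = out / f"sweep_{pop}.tsv"
            track.to_csv(path, sep="\t", index=False)
            cal.write_regions_bed(regs, out / f"sweep_{pop}.bed")
            tracks[pop], regions[pop] = track, regs
            outputs += [path, out / f"sweep_{pop}.bed"]
        comp = swp.compare_populations(
            tracks["west"]["clr"], tracks["east"]["clr"],
            len(regions["west"]), len(regions["east"]))
        (out / "sweep_compare.json").write_text(json.dumps(comp, indent=2))
        state.update(sweep_tracks=tracks, sweep_regions=regions)
        return outputs + [out / "sweep_compare.json"]

    _stage(manifest, "sweep", seeds["sweep"], sweep_stage)

    # ---- stage 6: enrichment of outlier and sweep gene sets
    def enrich_stage():
        region_sets = {"fst": state["regions"], "dxy": state["dxy_regions"]}
        for pop in ("west", "east"):
            if len(state["sweep_regions"][pop]):
                region_sets[f"sweep_{pop}"] = state["sweep_regions"][pop]
        results = {}
        for name, regs in region_sets.items():
            if not len(regs):
                continue
            try:
                results[name] = enr.enrichment_test(
                    regs, state["genes"], category=config.category,
                    B=config.permutations, seed=seeds["enrich"])
            except ValueError as exc:
                log.info("enrichment %s skipped: %s", name, exc)
        payload = {k: v.to_dict() for k, v in results.items()}
        (out / "enrichment.json").write_text(json.dumps(payload, indent=2))
        for k, v in results.items():
            np.savetxt(out / f"enrichment_null_{k}.tsv", v.perm_null)
        state["enrichment"] = results
        return [out / "enrichment.json"]

    _stage(manifest, "enrich", seeds["enrich"], enrich_stage)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def report(out_dir) -> list[Path]:
    """Summary plots and tables for a completed run (formatting only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    produced = []
    flagged = pd.read_csv(out / "windows_flagged.tsv", sep="\t")
    null = cal.NullDistribution.from_json(out / "null.json")

    fig, axes = plt.subplots(3, 1, figsize=(10, 8), sharex=True)
    mid = (flagged["start"] + flagged["end"]) / 2
    axes[0].plot(mid, flagged["fst"], ".", ms=3)
    axes[0].set_ylabel("Fst")
    axes[1].plot(mid, flagged["dxy"], ".", ms=3, color="tab:green")
    axes[1].set_ylabel("Dxy")
    axes[2].plot(mid, flagged["z_fst"], ".", ms=3, color="tab:orange")
    axes[2].axhline(null.cutoff, ls="--", color="k",
                    label=f"cutoff {null.cutoff:.2f}")
    axes[2].set_ylabel("Z(Fst)")
    axes[2].set_xlabel("position (bp)")
    axes[2].legend()
    n_out = int(flagged["outlier_fst"].sum())
    axes[0].set_title(f"{n_out} outlier windows" if n_out else "0 regions")
    fig.tight_layout()
    p = out / "scan.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    produced.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(null.values, bins=60, density=True, alpha=0.7)
    ax.axvline(null.cutoff, color="k", ls="--")
    ax.set_xlabel("Z(Fst) (simulated null)")
    fig.tight_layout()
    p = out / "null.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    produced.append(p)

    enr_path = out / "enrichment.json"
    if enr_path.exists():
        payload = json.loads(enr_path.read_text())
        if payload:
            fig, axes = plt.subplots(1, len(payload), squeeze=False,
                                     figsize=(4 * len(payload), 3.2))
            for ax, (name, d) in zip(axes[0], sorted(payload.items())):
                nulls = np.loadtxt(out / f"enrichment_null_{name}.tsv")
                ax.hist(nulls, bins=40, alpha=0.7)
                ax.axvline(d["prop_observed"], color="r",
                           label=f"obs {d['prop_observed']:.2f}")
                ax.axvline(d["perm_percentile_95"], color="k", ls="--")
                ax.set_title(name)
                ax.legend(fontsize=8)
            fig.tight_layout()
            p = out / "enrichment.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            produced.append(p)
    return produced
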
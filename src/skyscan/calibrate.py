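"""Simulation-calibrated outlier thresholds for the divergence scan.

Instead of an arbitrary Z(Fst) cutoff, the null distribution of the window
statistic is generated by simulating replicate genomes under the *fitted*
demographic history, Z-transforming within each replicate exactly as the
empirical pipeline does, pooling the nominal values, and taking the 95th
percentile as the outlier threshold.  Windows above the threshold (strict
inequality) are flagged and adjacent flagged windows are merged into
candidate divergent regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import DemographicModel, ParameterError
from .simulate import simulate_genome
from .windows import window_table

__all__ = ["NullDistribution", "simulate_null", "simulate_nulls",
           "call_outliers", "merge_regions", "write_regions_bed"]


@dataclass
class NullDistribution:
    """Pooled simulated window statistics and the percentile cutoff."""

    values: np.ndarray
    n_replicates: int
    statistic: str = "z_fst"
    percentile: float = 95.0
    cutoff: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty null distribution")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        self.cutoff = float(np.percentile(self.values, self.percentile))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "statistic": self.statistic,
            "n_replicates": self.n_replicates,
            "percentile": self.percentile,
            "cutoff": self.cutoff,
            "values": self.values.tolist(),
        }))

    @classmethod
    def from_json(cls, path) -> "NullDistribution":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["values"]), d["n_replicates"], d["statistic"],
                   d["percentile"])


def simulate_null(model: DemographicModel, n_w: int, n_e: int,
                  n_windows: int, L: int, n_replicates: int = 2000, seed=0,
                  *, percentile: float = 95.0, min_snps: int = 3) -> NullDistribution:
    """Null distribution of Z(Fst) under the fitted demography.

    Each replicate simulates a genome of ``n_windows`` independent windows,
    computes window Fst and Z-transforms it *within the replicate*
    (mirroring how the empirical statistic is standardized), then pools the
    nominal values across replicates.  Deterministic for a fixed seed.
    """
    return simulate_nulls(model, n_w, n_e, n_windows, L,
                          n_replicates=n_replicates, seed=seed,
                          percentile=percentile, min_snps=min_snps,
                          statistics=("z_fst",))["z_fst"]


def simulate_nulls(model: DemographicModel, n_w: int, n_e: int,
                   n_windows: int, L: int, n_replicates: int = 2000, seed=0,
                   *, percentile: float = 95.0, min_snps: int = 3,
                   statistics=("z_fst", "z_dxy")) -> dict[str, NullDistribution]:
    """As :func:`simulate_null` but pooling several window statistics from
    the same replicate simulations (e.g. Z(Fst) and Z(Dxy))."""
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if n_windows < 2:
        raise ParameterError("need >= 2 windows per replicate to Z-transform")
    seeds = (seed if isinstance(seed, np.random.SeedSequence)
             else np.random.SeedSequence(seed)).generate_state(n_replicates)
    pooled = {s: [] for s in statistics}
    for r in range(n_replicates):
        blocks = simulate_genome(model, n_w, n_e, n_windows, L, int(seeds[r]))
        df = window_table(blocks, min_snps=min_snps)
        for s in statistics:
            z = df[s].to_numpy()
            pooled[s].append(z[np.isfinite(z)])
    return {s: NullDistribution(np.concatenate(pooled[s]), n_replicates, s,
                                percentile)
            for s in statistics}


def merge_regions(flagged: pd.DataFrame, *, gap: int = 0) -> pd.DataFrame:
    """Merge flagged windows into regions, joining neighbours within ``gap`` bp."""
    regions = []
    for contig, grp in flagged.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for _, row in grp.iterrows():
            if cur_end is not None and row["start"] - cur_end <= gap:
                cur_end = max(cur_end, row["end"])
            else:
                if cur_end is not None:
                    regions.append((contig, cur_start, cur_end))
                cur_start, cur_end = row["start"], row["end"]
        if cur_end is not None:
            regions.append((contig, cur_start, cur_end))
    return pd.DataFrame(regions, columns=["contig", "start", "end"])


def call_outliers(stats: pd.DataFrame, null: NullDistribution, *,
                  gap: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag windows whose statistic strictly exceeds the simulated cutoff.

    Returns the statistic table with an added ``outlier`` column and a
    merged-region table (0-based half-open, BED-compatible).  Windows with
    a missing statistic are never flagged.
    """
    if null.statistic not in stats.columns:
        raise ValueError(f"stats table lacks column {null.statistic!r}")
    out = stats.copy()
    vals = out[null.statistic].to_numpy(dtype=float)
    out["outlier"] = np.isfinite(vals) & (vals > null.cutoff)
    regions = merge_regions(out[out["outlier"]], gap=gap)
    return out, regions


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['contig']}\t{int(r['start'])}\t{int(r['end'])}\n")
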
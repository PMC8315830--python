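"""Functional-category enrichment of genes in candidate regions.

Regions from the divergence and sweep scans are mapped to genes by
half-open interval overlap, tested for over-representation of a focal
category (by default "development") with a one-sided hypergeometric
Fisher test, and validated against a permutation null: repeatedly draw the
same number of genes uniformly without replacement from the annotated
universe and record the category proportion; the observed proportion is
called significant when it strictly exceeds the null's 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneAnnotation

__all__ = [
    "EnrichmentResult",
    "genes_in_regions",
    "fisher_enrichment",
    "permutation_null",
    "enrichment_test",
    "run_enrichment_suite",
]


def _region_tuples(regions) -> list[tuple[str, int, int]]:
    if isinstance(regions, pd.DataFrame):
        return [(str(r["contig"]), int(r["start"]), int(r["end"]))
                for _, r in regions.iterrows()]
    return [(str(c), int(s), int(e)) for c, s, e in regions]


def genes_in_regions(regions, genes: Sequence[GeneAnnotation]) -> set[str]:
    """Ids of genes overlapping any region by >= 1 bp (half-open intervals)."""
    out: set[str] = set()
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in _region_tuples(regions):
        by_contig.setdefault(contig, []).append((start, end))
    for g in genes:
        for start, end in by_contig.get(g.contig, ()):
            if g.start < end and start < g.end:
                out.add(g.gene_id)
                break
    return out


def fisher_enrichment(n_selected_cat: int, n_selected: int,
                      n_genome_cat: int, n_genome: int) -> tuple[float, float]:
    """One-sided hypergeometric enrichment test.

    ``p = P(X >= n_selected_cat)`` for X hypergeometric with population
    ``n_genome``, ``n_genome_cat`` successes and ``n_selected`` draws.  The
    odds ratio comes from the 2x2 table (selected vs not) x (category vs
    not) with the selected genes excluded from the background margin.
    """
    if not (0 <= n_selected_cat <= n_selected <= n_genome):
        raise ValueError("counts violate 0 <= k <= n_selected <= n_genome")
    if not (n_selected_cat <= n_genome_cat <= n_genome):
        raise ValueError("category counts inconsistent")
    if (n_selected - n_selected_cat) > (n_genome - n_genome_cat):
        raise ValueError("more non-category selections than non-category genes")
    p = float(hypergeom.sf(n_selected_cat - 1, n_genome, n_genome_cat,
                           n_selected))
    a = n_selected_cat
    b = n_selected - n_selected_cat
    c = n_genome_cat - n_selected_cat
    d = (n_genome - n_genome_cat) - b
    odds = float("inf") if b * c == 0 and a * d > 0 else (
        float("nan") if b * c == 0 else a * d / (b * c))
    return odds, p


def permutation_null(is_category: np.ndarray, n_selected: int,
                     B: int = 10_000, seed=0) -> np.ndarray:
    """Null category proportions for uniform draws from the gene universe.

    Each of the ``B`` draws samples ``n_selected`` genes without
    replacement from the universe and records the focal-category fraction.
    Deterministic for a fixed seed.
    """
    is_cat = np.asarray(is_category, dtype=bool)
    G = is_cat.size
    if not 1 <= n_selected <= G:
        raise ValueError("n_selected must lie in [1, universe size]")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(B, np.float64)
    for b in range(B):
        idx = rng.choice(G, size=n_selected, replace=False)
        out[b] = is_cat[idx].mean()
    return out


@dataclass
class EnrichmentResult:
    """Observed enrichment with its Fisher test and permutation null."""

    n_selected: int
    n_selected_cat: int
    n_genome: int
    n_genome_cat: int
    odds_ratio: float
    fisher_p: float
    perm_null: np.ndarray
    perm_percentile_95: float
    perm_p: float
    significant: bool

    @property
    def prop_observed(self) -> float:
        return self.n_selected_cat / self.n_selected

    def to_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_selected_cat": self.n_selected_cat,
            "n_genome": self.n_genome,
            "n_genome_cat": self.n_genome_cat,
            "prop_observed": self.prop_observed,
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "perm_percentile_95": self.perm_percentile_95,
            "perm_p": self.perm_p,
            "significant": self.significant,
        }


def enrichment_test(regions, genes: Sequence[GeneAnnotation],
                    category: str = "development", B: int = 10_000,
                    seed=0) -> EnrichmentResult:
    """Full enrichment analysis of one region set against a gene universe.

    Raises when no gene overlaps the regions (the observed proportion is
    undefined for an empty selection).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene universe")
    selected = genes_in_regions(regions, genes)
    if not selected:
        raise ValueError("no genes overlap the supplied regions")
    is_cat = np.array([category in g.category for g in genes])
    sel_mask = np.array([g.gene_id in selected for g in genes])
    n_selected = int(sel_mask.sum())
    n_selected_cat = int((sel_mask & is_cat).sum())
    n_genome = len(genes)
    n_genome_cat = int(is_cat.sum())
    odds, fisher_p = fisher_enrichment(n_selected_cat, n_selected,
                                       n_genome_cat, n_genome)
    null = permutation_null(is_cat, n_selected, B=B, seed=seed)
    q95 = float(np.percentile(null, 95.0))
    obs = n_selected_cat / n_selected
    perm_p = float((1 + np.sum(null >= obs)) / (B + 1))
    return EnrichmentResult(
        n_selected=n_selected, n_selected_cat=n_selected_cat,
        n_genome=n_genome, n_genome_cat=n_genome_cat,
        odds_ratio=odds, fisher_p=fisher_p, perm_null=null,
        perm_percentile_95=q95, perm_p=perm_p,
        significant=bool(obs > q95),
    )


def run_enrichment_suite(region_sets: Mapping[str, object],
                         genes: Sequence[GeneAnnotation],
                         category: str = "development", B: int = 10_000,
                         seed=0) -> dict[str, EnrichmentResult]:
    """One permutation enrichment test per region source (Fst, Dxy, sweeps).

    All analyses share the gene universe; each gets an independent,
    reproducible permutation stream derived from the master seed.
    """
    results = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(region_sets))
    for child, (name, regions) in zip(children, sorted(region_sets.items())):
        results[name] = enrichment_test(regions, genes, category=category,
                                        B=B, seed=child)
    return results
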
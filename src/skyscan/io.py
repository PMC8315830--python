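"""File interchange: VCF, gene BED, contig lengths and synthetic annotations.

VCFs are written as plain-text v4.2 with phased diploid genotypes and the
ancestral allele carried in the ``AA`` INFO tag (reference polarization:
``AA`` equals ``REF``, so ALT is the derived allele).  Gene annotations use
0-based half-open BED with the gene id in column 4 and a comma-separated
category label set (or ``.``) in column 5.  Contig lengths travel as a
two-column ``name<TAB>length`` table, the first two columns of a FASTA
``.fai`` index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import HaplotypeBlock

__all__ = [
    "GeneAnnotation",
    "write_vcf",
    "read_vcf",
    "write_gene_bed",
    "read_gene_bed",
    "write_contig_lengths",
    "read_contig_lengths",
    "make_annotation",
    "genotype_matrix",
    "DEV_FRACTION",
]

#: genome-background fraction of genes carrying the "development" label
#: (3568 of 17 770 annotated genes)
DEV_FRACTION = 3568 / 17770

_REF, _ALT = "A", "G"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with a functional-category label set."""

    gene_id: str
    contig: str
    start: int
    end: int
    category: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        object.__setattr__(self, "category", frozenset(self.category))


def write_vcf(blocks: Sequence[HaplotypeBlock], samples: Sequence[str],
              path) -> None:
    """Write haplotype blocks as a phased, polarized VCF v4.2.

    Haplotype rows are taken pairwise per diploid sample, so every block
    must carry ``2 * len(samples)`` haplotypes in the same order.
    """
    blocks = list(blocks)
    for b in blocks:
        if b.n_haplotypes != 2 * len(samples):
            raise ValueError("blocks must have 2 haplotypes per sample")
    contig_len: dict[str, int] = {}
    for b in blocks:
        contig_len[b.contig] = max(contig_len.get(b.contig, 0), b.end)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=skyscan",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for name, ln in contig_len.items():
        lines.append(f"##contig=<ID={name},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    records = []
    for b in blocks:
        for s in range(b.n_sites):
            col = b.haplotypes[:, s]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(len(samples)))
            records.append((b.contig, int(b.positions[s]), gts))
    records.sort(key=lambda r: (r[0], r[1]))
    for contig, pos, gts in records:
        lines.append(f"{contig}\t{pos + 1}\t.\t{_REF}\t{_ALT}\t.\tPASS\t"
                     f"AA={_REF}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, pops: Mapping[str, str]) -> list[HaplotypeBlock]:
    """Read a phased biallelic VCF into one haplotype block per contig.

    ``pops`` maps sample id to population label ("west"/"east"); block ends
    come from the header contig lengths (or the last variant position + 1
    when absent).  Sites whose ``AA`` tag matches the ALT allele are
    re-polarized (genotypes flipped); sites whose ``AA`` matches neither
    allele are dropped.  The drop count is attached to each block as
    ``block.n_dropped_polarization``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    labels = np.array([pops[s] for s in samples for _ in range(2)])
    contig_len = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    per_contig: dict[str, list] = {}
    dropped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        aa = (v.INFO.get("AA") or v.REF).upper()
        if aa == v.REF.upper():
            flip = False
        elif aa == v.ALT[0].upper():
            flip = True
        else:
            dropped += 1
            continue
        g = np.array(v.genotypes)[:, :2].reshape(-1).astype(np.uint8)
        if flip:
            g = 1 - g
        per_contig.setdefault(v.CHROM, []).append((v.POS - 1, g))
    vcf.close()
    blocks = []
    for contig, sites in per_contig.items():
        pos = np.array([p for p, _ in sites], dtype=np.int64)
        haps = np.column_stack([g for _, g in sites]) if sites else \
            np.zeros((len(labels), 0), np.uint8)
        end = contig_len.get(contig, int(pos[-1]) + 1 if pos.size else 1)
        b = HaplotypeBlock(contig, 0, int(end), pos, haps, labels)
        b.n_dropped_polarization = dropped
        blocks.append(b)
    return blocks


def genotype_matrix(block: HaplotypeBlock) -> np.ndarray:
    """Diploid derived-allele dosages, pairing consecutive haplotype rows."""
    h = block.haplotypes
    if h.shape[0] % 2:
        raise ValueError("odd haplotype count; cannot pair into diploids")
    return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int8)


def write_gene_bed(genes: Iterable[GeneAnnotation], path) -> None:
    lines = []
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        cat = ",".join(sorted(g.category)) if g.category else "."
        lines.append(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t{cat}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_bed(path) -> list[GeneAnnotation]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        contig, start, end, gene_id, cat = line.split("\t")[:5]
        category = frozenset() if cat == "." else frozenset(cat.split(","))
        genes.append(GeneAnnotation(gene_id, contig, int(start), int(end), category))
    return genes


def write_contig_lengths(lengths: Mapping[str, int], path) -> None:
    Path(path).write_text(
        "".join(f"{name}\t{ln}\n" for name, ln in lengths.items()))


def read_contig_lengths(path) -> dict[str, int]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        out[parts[0]] = int(parts[1])
    return out


def make_annotation(n_genes: int, dev_fraction: float,
                    windows: Sequence[tuple[str, int, int]], seed, *,
                    gene_len: int = 5_000,
                    focus_intervals: Sequence[tuple[str, int, int]] | None = None,
                    focus_prob: float = 0.0) -> list[GeneAnnotation]:
    """Generate a synthetic gene annotation over the given genome windows.

    ``round(n_genes * dev_fraction)`` genes carry the "development" label
    (deterministic count; which genes carry it is randomized).  Genes are
    placed uniformly across the supplied windows with fixed length
    ``gene_len`` (clipped to the window).  When ``focus_intervals`` is
    given, each development gene is instead placed inside a random focal
    interval with probability ``focus_prob`` - the hook used to plant a
    true enrichment signal at known locations.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= dev_fraction <= 1:
        raise ValueError("dev_fraction must lie in [0, 1]")
    if not windows:
        raise ValueError("need at least one window to place genes in")
    rng = np.random.default_rng(seed)
    n_dev = int(round(n_genes * dev_fraction))
    is_dev = np.zeros(n_genes, bool)
    is_dev[rng.choice(n_genes, size=n_dev, replace=False)] = True
    windows = list(windows)
    genes = []
    width = len(str(n_genes))
    for i in range(n_genes):
        pool = windows
        if is_dev[i] and focus_intervals and rng.random() < focus_prob:
            pool = list(focus_intervals)
        contig, w_start, w_end = pool[rng.integers(len(pool))]
        glen = min(gene_len, w_end - w_start)
        start = int(rng.integers(w_start, w_end - glen + 1))
        cat = frozenset({"development"}) if is_dev[i] else frozenset()
        genes.append(GeneAnnotation(f"gene{i:0{width}d}", contig, start,
                                    start + glen, cat))
    return genes
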
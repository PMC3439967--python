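"""Promoter target-gene assignment and M-binned enrichment scoring.

A peak targets a gene when its summit falls in the strand-aware promoter
window, 8 kb upstream to 2 kb downstream of the TSS by default.  Targeted
genes are binned by the normalized M of their representative peak (integer
bins from -4 to 4 with open-ended outer bins), small bins are merged into
the larger neighbor, and each bin's overlap with a differentially-expressed
gene list is scored as observed/expected:

    enrichment(G) = (|G ∩ D| / |G|) / (|D| / |U|)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GeneAnnotation

DEFAULT_UPSTREAM = 8000
DEFAULT_DOWNSTREAM = 2000


@dataclass
class GeneGroup:
    """Genes whose representative M falls in (m_lo, m_hi]."""

    m_lo: float
    m_hi: float
    genes: set[str] = field(default_factory=set)
    enrichment: float | None = None

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def center(self) -> float:
        lo = self.m_lo if np.isfinite(self.m_lo) else self.m_hi - 1
        hi = self.m_hi if np.isfinite(self.m_hi) else self.m_lo + 1
        return (lo + hi) / 2.0


def promoter_window(gene: GeneAnnotation, upstream: int, downstream: int) -> tuple[int, int]:
    """Half-open promoter interval around the TSS, mirrored for '-' genes."""
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream, gene.tss + upstream


def assign_targets(
    peak_chroms: Sequence[str],
    peak_summits: Sequence[int],
    m_values: Sequence[float],
    a_values: Sequence[float],
    genes: Sequence[GeneAnnotation],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> dict[str, float]:
    """Representative M per gene: the M of the peak whose summit is nearest
    the TSS among peaks inside the promoter window (tie: larger A)."""
    by_chrom: dict[str, list[int]] = {}
    for i, chrom in enumerate(peak_chroms):
        by_chrom.setdefault(chrom, []).append(i)
    index = {}
    for chrom, idx in by_chrom.items():
        idx_arr = np.asarray(idx)
        summits = np.asarray([peak_summits[i] for i in idx])
        order = np.argsort(summits, kind="stable")
        index[chrom] = (idx_arr[order], summits[order])

    gene_m: dict[str, float] = {}
    for gene in genes:
        entry = index.get(gene.chrom)
        if entry is None:
            continue
        idx_arr, summits = entry
        lo, hi = promoter_window(gene, upstream, downstream)
        i0 = np.searchsorted(summits, lo, side="left")
        i1 = np.searchsorted(summits, hi, side="left")
        if i0 == i1:
            continue
        # nearest summit to the TSS; ties favor the higher-A peak
        best = min(
            (
                (abs(int(summits[k]) - gene.tss), -a_values[idx_arr[k]], idx_arr[k])
                for k in range(i0, i1)
            )
        )
        gene_m[gene.gene_id] = float(m_values[best[2]])
    return gene_m


def _initial_bins(gene_ms: Mapping[str, float]) -> list[GeneGroup]:
    edges = [-np.inf] + list(range(-4, 5)) + [np.inf]
    groups = [GeneGroup(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    for gene, m in gene_ms.items():
        for g in groups:
            if g.m_lo < m <= g.m_hi:
                g.genes.add(gene)
                break
    return groups


def bin_and_score(
    gene_ms: Mapping[str, float],
    de_genes: set[str],
    universe: set[str],
    min_group: int = 50,
) -> list[GeneGroup]:
    """Bin genes by representative M and score DE-gene enrichment per bin.

    Bins of fewer than ``min_group`` genes are merged, smallest first, into
    the larger of their two neighbors (tie: the neighbor nearer M = 0),
    until every bin reaches the minimum or only one remains.
    """
    if not universe:
        raise ValueError("gene universe must be non-empty")
    groups = _initial_bins(gene_ms)

    while len(groups) > 1:
        sizes = [g.size for g in groups]
        small = [i for i, s in enumerate(sizes) if s < min_group]
        if not small:
            break
        i = min(small, key=lambda k: (sizes[k], abs(groups[k].center)))
        neighbors = []
        if i > 0:
            neighbors.append(i - 1)
        if i < len(groups) - 1:
            neighbors.append(i + 1)
        j = max(neighbors, key=lambda k: (sizes[k], -abs(groups[k].center)))
        lo, hi = min(i, j), max(i, j)
        merged = GeneGroup(
            groups[lo].m_lo, groups[hi].m_hi, groups[lo].genes | groups[hi].genes
        )
        groups[lo : hi + 1] = [merged]

    de_rate = len(de_genes & universe) / len(universe)
    for g in groups:
        if g.size == 0 or de_rate == 0:
            g.enrichment = 0.0 if g.size else None
        else:
            g.enrichment = (len(g.genes & de_genes) / g.size) / de_rate
    return groups
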
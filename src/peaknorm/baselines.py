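"""Genome-wide baseline normalizations for comparison with the MA method.

Three alternatives that normalize on the whole genome rather than on common
peaks: total-read scaling, quantile matching of genome-bin counts, and
genome-wide MA with LOWESS trend removal.  All operate on non-overlapping
genome bins of the same width as the peak-counting window (2,000 bp
default); peak-level values are projected from the bin containing the peak
summit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import SequenceTag
from .model import compute_ma_arrays
from .quantify import DEFAULT_SHIFT, effective_tag_position

DEFAULT_LOWESS_FRAC = 0.3
LOWESS_ROBUST_ITER = 2


@dataclass
class GenomeBins:
    """Per-bin tag counts of both samples over the whole genome."""

    bin_width: int
    chrom_sizes: dict[str, int]
    counts1: np.ndarray
    counts2: np.ndarray
    offsets: dict[str, tuple[int, int]]  # chrom -> (first bin index, n bins)

    def bin_index(self, chrom: str, position: int) -> int:
        """Global index of the bin containing ``position`` (-1 if unknown)."""
        entry = self.offsets.get(chrom)
        if entry is None:
            return -1
        first, n_bins = entry
        k = position // self.bin_width
        if not 0 <= k < n_bins:
            return -1
        return first + k


def bin_genome(
    tags1: Iterable[SequenceTag],
    tags2: Iterable[SequenceTag],
    chrom_sizes: Mapping[str, int],
    bin_width: int = 2000,
    shift: int = DEFAULT_SHIFT,
) -> GenomeBins:
    """Count shifted tag positions in non-overlapping genome-wide bins."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    chroms = sorted(chrom_sizes)
    offsets: dict[str, tuple[int, int]] = {}
    first = 0
    for chrom in chroms:
        n_bins = -(-int(chrom_sizes[chrom]) // bin_width)
        offsets[chrom] = (first, n_bins)
        first += n_bins
    total_bins = first

    def fill(tags) -> np.ndarray:
        counts = np.zeros(total_bins, dtype=np.int64)
        for tag in tags:
            entry = offsets.get(tag.chrom)
            if entry is None:
                continue
            start, n_bins = entry
            k = effective_tag_position(tag, shift) // bin_width
            if 0 <= k < n_bins:
                counts[start + k] += 1
        return counts

    return GenomeBins(bin_width, dict(chrom_sizes), fill(tags1), fill(tags2), offsets)


def total_read_m(x1: int, x2: int, total1: int, total2: int) -> float:
    """M after scaling each sample's pseudocounted peak count by its library size."""
    if total1 <= 0 or total2 <= 0:
        raise ValueError("library totals must be > 0")
    return float(np.log2(((x1 + 1) / total1) / ((x2 + 1) / total2)))


def quantile_normalize_bins(
    counts1: Sequence[float], counts2: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Match the two samples' per-bin count distributions quantile-by-quantile.

    Each sample's k-th order statistic is replaced by the mean of the two
    k-th order statistics; tied counts receive consecutive order-statistic
    means by stable sort order, so each output is an exact permutation of
    the shared reference distribution.
    """
    c1 = np.asarray(counts1, dtype=np.float64)
    c2 = np.asarray(counts2, dtype=np.float64)
    if c1.shape != c2.shape:
        raise ValueError("both samples must be binned identically")
    reference = (np.sort(c1) + np.sort(c2)) / 2.0

    def apply(c: np.ndarray) -> np.ndarray:
        out = np.empty_like(reference)
        out[np.argsort(c, kind="stable")] = reference
        return out

    return apply(c1), apply(c2)


def quantile_peak_m(bins: GenomeBins, chroms, summits) -> np.ndarray:
    """Per-peak M from quantile-normalized bin values at each peak's summit bin."""
    q1, q2 = quantile_normalize_bins(bins.counts1, bins.counts2)
    m = np.zeros(len(chroms))
    for i, (chrom, summit) in enumerate(zip(chroms, summits)):
        k = bins.bin_index(chrom, summit)
        if k >= 0:
            m[i] = np.log2((q1[k] + 1.0) / (q2[k] + 1.0))
    return m


def genome_ma_lowess(
    bins: GenomeBins, frac: float = DEFAULT_LOWESS_FRAC
) -> dict[str, np.ndarray]:
    """Genome-wide MA with LOWESS trend removal over non-empty bins.

    Computes per-bin (M, A) with the +1 pseudocount, fits a locally weighted
    regression of M on A (tricube weights, 2 robustifying iterations) and
    subtracts the fitted trend.  Returns arrays ``index`` (global bin
    indices used), ``M``, ``A``, ``M_corrected``.
    """
    if not (0 < frac <= 1):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    nonempty = np.flatnonzero((bins.counts1 + bins.counts2) > 0)
    if nonempty.size < 10:
        raise ValueError(
            f"need >= 10 non-empty bins for LOWESS, got {nonempty.size}"
        )
    m, a = compute_ma_arrays(bins.counts1[nonempty], bins.counts2[nonempty])
    fitted = lowess(
        m, a, frac=frac, it=LOWESS_ROBUST_ITER, return_sorted=False
    )
    return {"index": nonempty, "M": m, "A": a, "M_corrected": m - fitted}
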
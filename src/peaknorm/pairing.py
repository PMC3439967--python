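"""Common/unique peak classification and one-to-one pairing across samples.

A peak is *common* if it has a qualifying partner in the other sample —
either an interval overlap of at least one nucleotide (``overlap`` mode) or
a summit within a distance cutoff (``summit_distance`` mode; 500 bp is the
usual histone-modification setting, 250 bp for transcription factors).
Common peaks anchor the normalization model under the assumption that their
true binding is unchanged between samples.

When a peak qualifies against several peaks of the other sample, the partner
with the smallest summit-to-summit distance is selected (ties: smaller start
coordinate, then earlier input index, so output is deterministic under input
permutation).  The pair list used for model fitting is the deduplicated
union of nearest-partner links made from both sides, which makes the pair
set invariant under swapping the two samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomicInterval, Peak


@dataclass(frozen=True)
class PeakClass:
    """Classification of one peak relative to the other sample."""

    label: str  # "common" or "unique"
    partner_index: int | None = None
    summit_distance: int | None = None

    @property
    def is_common(self) -> bool:
        return self.label == "common"


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 nucleotide."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class _ChromIndex:
    """Per-chromosome arrays of one sample's peaks, sorted by start."""

    def __init__(self, peaks: Sequence[Peak]):
        self.by_chrom: dict[str, dict[str, np.ndarray]] = {}
        groups: dict[str, list[int]] = {}
        for i, p in enumerate(peaks):
            groups.setdefault(p.chrom, []).append(i)
        for chrom, idx in groups.items():
            idx_arr = np.asarray(idx)
            starts = np.asarray([peaks[i].start for i in idx])
            order = np.argsort(starts, kind="stable")
            idx_arr = idx_arr[order]
            self.by_chrom[chrom] = {
                "idx": idx_arr,
                "start": starts[order],
                "end": np.asarray([peaks[i].end for i in idx_arr]),
                "summit": np.asarray([peaks[i].summit for i in idx_arr]),
            }

    def candidates_overlap(self, peak: Peak) -> np.ndarray:
        arrs = self.by_chrom.get(peak.chrom)
        if arrs is None:
            return np.empty(0, dtype=int)
        hi = np.searchsorted(arrs["start"], peak.end, side="left")
        mask = arrs["end"][:hi] > peak.start
        return arrs["idx"][:hi][mask]

    def candidates_summit(self, peak: Peak, max_dist: int) -> np.ndarray:
        arrs = self.by_chrom.get(peak.chrom)
        if arrs is None:
            return np.empty(0, dtype=int)
        mask = np.abs(arrs["summit"] - peak.summit) <= max_dist
        return arrs["idx"][mask]


def _nearest_partner(
    peak: Peak, candidates: np.ndarray, others: Sequence[Peak]
) -> tuple[int, int]:
    """Pick the candidate minimizing (summit distance, start, input index)."""
    best = min(
        (
            (abs(others[j].summit - peak.summit), others[j].start, j)
            for j in candidates
        ),
    )
    return best[2], best[0]


def pair_and_classify(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    mode: str = "overlap",
    max_summit_dist: int | None = None,
) -> tuple[list[PeakClass], list[PeakClass], list[tuple[int, int]]]:
    """Classify both peak sets and build the common-peak pair list.

    Returns
    -------
    classes_a, classes_b
        One :class:`PeakClass` per input peak, in input order.
    pairs
        Sorted, deduplicated ``(index_a, index_b)`` couples: the union of
        each common peak's nearest-partner link from both samples' sides.
    """
    if mode not in ("overlap", "summit_distance"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    if mode == "summit_distance":
        if max_summit_dist is None or max_summit_dist <= 0:
            raise ValueError("summit_distance mode requires max_summit_dist > 0")

    index_a = _ChromIndex(peaks_a)
    index_b = _ChromIndex(peaks_b)

    def classify(
        peaks: Sequence[Peak], other_index: _ChromIndex, others: Sequence[Peak]
    ) -> list[PeakClass]:
        out = []
        for p in peaks:
            if mode == "overlap":
                cand = other_index.candidates_overlap(p)
            else:
                cand = other_index.candidates_summit(p, max_summit_dist)
            if cand.size == 0:
                out.append(PeakClass("unique"))
            else:
                j, dist = _nearest_partner(p, cand, others)
                out.append(PeakClass("common", j, dist))
        return out

    classes_a = classify(peaks_a, index_b, peaks_b)
    classes_b = classify(peaks_b, index_a, peaks_a)

    couples = {
        (i, c.partner_index) for i, c in enumerate(classes_a) if c.is_common
    }
    couples |= {
        (c.partner_index, j) for j, c in enumerate(classes_b) if c.is_common
    }
    return classes_a, classes_b, sorted(couples)
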
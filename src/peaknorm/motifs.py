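"""PWM motif scanning, enrichment filtering, and motif/M clustering.

Motifs are scanned over summit-centered sequence windows with a log2
likelihood-ratio score against a mononucleotide background estimated from
random genomic segments (10,000 x 1,000 bp by default):

    raw(P) = max over offsets s and both strands of sum_i log2 P(S_i|F) / P(S_i|B)

The motif score is the raw score divided by the raw score of the motif's
consensus sequence (per-position argmax), so a score of 1 means the
consensus occurs in the window.  Motifs enriched in peaks versus background
regions (enrichment score > 1.2 and Bonferroni-corrected one-sided Fisher
exact P < 1e-5 by default) are retained, and their per-peak scores are
clustered together with the peaks' M values using Ward linkage on the
1 - Pearson-correlation distance; motifs most correlated with M nominate
candidate cell-type-specific regulators.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}
PWM_CELL_PSEUDO = 1e-3
JASPAR_COUNT_PSEUDO = 0.8


class DegenerateMotifError(ValueError):
    """Consensus score <= 0: the motif cannot be normalized."""


@dataclass(frozen=True)
class BackgroundModel:
    """Genome mononucleotide frequencies (A, C, G, T), all > 0."""

    freq: np.ndarray
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=np.float64)
        if freq.shape != (4,) or np.any(freq <= 0) or abs(freq.sum() - 1) > 1e-6:
            raise ValueError("background must be 4 positive frequencies summing to 1")
        object.__setattr__(self, "freq", freq)


UNIFORM_BACKGROUND = BackgroundModel(np.full(4, 0.25), n_samples=0)


@dataclass(frozen=True)
class PWM:
    """Position probability matrix, rows (positions) x columns (A, C, G, T)."""

    id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.float64)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if np.any(mat <= 0):
            raise ValueError("PWM probabilities must be > 0 after regularization")
        if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM rows must sum to 1")
        object.__setattr__(self, "matrix", mat)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_probabilities(cls, motif_id: str, matrix, pseudo: float = PWM_CELL_PSEUDO) -> "PWM":
        """Regularize a probability matrix: add ``pseudo`` per cell, renormalize."""
        mat = np.asarray(matrix, dtype=np.float64) + pseudo
        return cls(motif_id, mat / mat.sum(axis=1, keepdims=True))

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts,
        background: BackgroundModel = UNIFORM_BACKGROUND,
        pseudocount: float = JASPAR_COUNT_PSEUDO,
    ) -> "PWM":
        """Convert a count matrix (JASPAR PFM) to probabilities with a total
        pseudocount split proportionally to the background frequencies."""
        counts = np.asarray(counts, dtype=np.float64)
        if counts.ndim != 2 or counts.shape[1] != 4 or np.any(counts < 0):
            raise ValueError("count matrix must be L x 4 and non-negative")
        mat = counts + pseudocount * background.freq
        mat /= mat.sum(axis=1, keepdims=True)
        return cls.from_probabilities(motif_id, mat)


def read_jaspar(
    path: str | Path, background: BackgroundModel = UNIFORM_BACKGROUND
) -> list[PWM]:
    """Read JASPAR PFM flat format: '>id' header then 4 rows (A, C, G, T) of
    whitespace-separated counts, with or without 'A [ ... ]' decoration."""
    pwms: list[PWM] = []
    motif_id = None
    rows: list[list[float]] = []

    def flush():
        if motif_id is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {motif_id}: expected 4 count rows, got {len(rows)}")
        counts = np.asarray(rows).T  # rows are per-base; transpose to L x 4
        pwms.append(PWM.from_counts(motif_id, counts, background))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = []
            else:
                cleaned = re.sub(r"^[ACGTacgt]\s*\[?", "", line).rstrip("]")
                rows.append([float(v) for v in cleaned.split()])
    flush()
    return pwms


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, anything else 4 (N)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def estimate_background(
    sequences: Mapping[str, str],
    n: int = 10000,
    length: int = 1000,
    seed: int = 0,
) -> BackgroundModel:
    """Estimate mononucleotide background from ``n`` random ``length``-bp
    segments sampled uniformly (with replacement) from the genome, skipping
    segments that are more than 50% N."""
    names = sorted(sequences)
    capacities = np.asarray(
        [max(0, len(sequences[name]) - length + 1) for name in names], dtype=np.float64
    )
    if capacities.sum() <= 0:
        raise ValueError(f"no chromosome is at least {length} bp long")
    rng = np.random.default_rng(seed)
    probs = capacities / capacities.sum()
    counts = np.zeros(4, dtype=np.float64)
    accepted = 0
    attempts = 0
    while accepted < n and attempts < 20 * n:
        attempts += 1
        ci = rng.choice(len(names), p=probs)
        start = rng.integers(0, int(capacities[ci]))
        enc = encode_sequence(sequences[names[ci]][start : start + length])
        if np.count_nonzero(enc == 4) > length / 2:
            continue
        counts += np.bincount(enc[enc < 4], minlength=4)
        accepted += 1
    if accepted == 0:
        raise ValueError("could not sample any segment with <= 50% N")
    freq = counts / counts.sum()
    freq = (freq + 1e-3) / (1.0 + 4e-3)  # keep all four strictly positive
    return BackgroundModel(freq, n_samples=accepted, seed=seed)


def _log_odds(pwm: PWM, background: BackgroundModel) -> np.ndarray:
    """L x 5 log2-odds matrix; the N column scores 0 by convention."""
    lom = np.zeros((len(pwm), 5))
    lom[:, :4] = np.log2(pwm.matrix / background.freq)
    return lom


def _best_offset_score(lom: np.ndarray, enc: np.ndarray) -> float:
    length = lom.shape[0]
    n_off = enc.size - length + 1
    scores = np.zeros(n_off)
    for i in range(length):
        scores += lom[i, enc[i : i + n_off]]
    return float(scores.max())


def motif_raw_score(pwm: PWM, sequence: str, background: BackgroundModel) -> float:
    """Best log2 likelihood-ratio score over all offsets on both strands."""
    if len(sequence) < len(pwm):
        raise ValueError(
            f"sequence length {len(sequence)} < motif length {len(pwm)}"
        )
    lom = _log_odds(pwm, background)
    enc = encode_sequence(sequence)
    rc = np.array([_COMPLEMENT[int(c)] for c in enc[::-1]], dtype=np.int8)
    return max(_best_offset_score(lom, enc), _best_offset_score(lom, rc))


def consensus_score(pwm: PWM, background: BackgroundModel) -> float:
    """Raw score of the consensus sequence: per-position max log2-odds."""
    return float(np.log2(pwm.matrix / background.freq).max(axis=1).sum())


def motif_norm_score(pwm: PWM, sequence: str, background: BackgroundModel) -> float:
    """Raw score divided by the consensus (maximum possible) score; <= 1."""
    cmax = consensus_score(pwm, background)
    if cmax <= 0:
        raise DegenerateMotifError(
            f"motif {pwm.id}: consensus score {cmax:.3g} <= 0"
        )
    return motif_raw_score(pwm, sequence, background) / cmax


def score_sequences(
    pwms: Sequence[PWM], sequences: Sequence[str], background: BackgroundModel
) -> np.ndarray:
    """Normalized score matrix, sequences (rows) x motifs (columns)."""
    out = np.empty((len(sequences), len(pwms)))
    for j, pwm in enumerate(pwms):
        cmax = consensus_score(pwm, background)
        if cmax <= 0:
            raise DegenerateMotifError(f"motif {pwm.id}: consensus score <= 0")
        lom = _log_odds(pwm, background)
        for i, seq in enumerate(sequences):
            enc = encode_sequence(seq)
            rc = np.array([_COMPLEMENT[int(c)] for c in enc[::-1]], dtype=np.int8)
            out[i, j] = (
                max(_best_offset_score(lom, enc), _best_offset_score(lom, rc)) / cmax
            )
    return out


@dataclass
class MotifEnrichment:
    motif_id: str
    enrichment_score: float
    p_value: float
    p_bonferroni: float
    retained: bool


def fisher_enrichment_filter(
    motif_ids: Sequence[str],
    peak_scores: np.ndarray,
    background_scores: np.ndarray,
    presence_threshold: float = 0.7,
    es_min: float = 1.2,
    p_max: float = 1e-5,
) -> list[MotifEnrichment]:
    """Retain motifs enriched in peaks over background regions.

    A motif is "present" in a region when its normalized score reaches
    ``presence_threshold``.  Each motif gets a 2x2 present/absent x
    peak/background table, a one-sided Fisher exact P (enrichment
    direction), Bonferroni correction by the number of motifs tested, and an
    enrichment score = peak presence rate / background presence rate (with a
    +0.5 continuity correction on all four cells when the background
    presence is zero).
    """
    if not (0 < presence_threshold < 1):
        raise ValueError("presence_threshold must be in (0, 1)")
    peak_scores = np.asarray(peak_scores)
    background_scores = np.asarray(background_scores)
    n_motifs = len(motif_ids)
    n_peaks = peak_scores.shape[0]
    n_bg = background_scores.shape[0]
    results = []
    for j, motif_id in enumerate(motif_ids):
        a = int(np.count_nonzero(peak_scores[:, j] >= presence_threshold))
        c = int(np.count_nonzero(background_scores[:, j] >= presence_threshold))
        b, d = n_peaks - a, n_bg - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        if c == 0:
            logger.warning(
                "motif %s: zero background presence; ES uses +0.5 continuity",
                motif_id,
            )
            es = ((a + 0.5) / (a + b + 1.0)) / ((c + 0.5) / (c + d + 1.0))
        else:
            es = (a / n_peaks) / (c / n_bg)
        p_bonf = min(1.0, p * n_motifs)
        retained = bool(es > es_min and p_bonf < p_max and a > 0)
        results.append(MotifEnrichment(motif_id, float(es), float(p), p_bonf, retained))
    return results


@dataclass
class MotifClustering:
    """Ward dendrogram over {M} + motif variables and motifs ranked by rho."""

    labels: list[str]
    linkage: np.ndarray
    correlations_with_m: list[tuple[str, float]]


def cluster_m_with_motifs(
    m_values: np.ndarray,
    score_matrix: np.ndarray,
    motif_ids: Sequence[str],
) -> MotifClustering:
    """Ward-linkage clustering of the M value with per-peak motif scores,
    using 1 - Pearson correlation as the distance between variables.

    Zero-variance variables are dropped with a warning.  The returned
    ranking orders motifs by their correlation with M, descending.
    """
    m_values = np.asarray(m_values, dtype=np.float64)
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    columns = [("M", m_values)] + [
        (motif_ids[j], score_matrix[:, j]) for j in range(score_matrix.shape[1])
    ]
    kept = []
    for label, col in columns:
        if np.std(col) == 0:
            logger.warning("dropping zero-variance variable %s", label)
            continue
        kept.append((label, col))
    if len(kept) < 2:
        raise ValueError("need at least two variables with nonzero variance")
    labels = [label for label, _ in kept]
    data = np.column_stack([col for _, col in kept])
    corr = np.corrcoef(data, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    rho_m = {
        label: float(corr[0, i]) for i, label in enumerate(labels) if label != "M"
    }
    ranked = sorted(rho_m.items(), key=lambda kv: -kv[1])
    return MotifClustering(labels, z, ranked)
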
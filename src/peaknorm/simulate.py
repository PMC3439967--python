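"""Synthetic two-sample ChIP-seq experiments with known ground truth.

The generator embodies the model assumption the normalization relies on:
the true binding intensity of most common peaks is unchanged between
samples, while the samples differ by a global signal-to-noise / depth ratio
``scale_c``.  Per-peak sample-2 mean window counts are log-normal (a heavy
right tail like real peak intensities); sample-1 means are ``scale_c``
times larger, with an optional extra true log2 effect on a subset of common
peaks.  Observed tags are Poisson in number, normally spread around the
summit (sigma 150 bp), and strand-split +-100 bp around the binding point to
emulate sequencing fragment ends, so the default 100-bp 3'-ward tag shift
re-centers them.  Uniform background tags are added to both samples.

Everything is deterministic given the seed; the same seed yields
byte-identical BED outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomicInterval, Peak, SequenceTag

_READ_LENGTH = 36


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated two-sample experiment.

    Defaults describe a realistic desk-scale histone-modification
    comparison: 1,000 shared binding sites plus 150 sample-specific sites
    each, a four-fold global intensity ratio, log-normal per-peak mean
    counts with median ~55 tags (so typical peaks are well above noise),
    2 background tags per kb, and a 10% subset of common peaks carrying a
    true 2-fold-squared (log2 effect = 2) binding change.
    """

    n_common: int = 1000
    n_unique1: int = 150
    n_unique2: int = 150
    scale_c: float = 4.0
    intensity_log_mean: float = 4.0  # natural-log mean of sample-2 lambda
    intensity_log_sd: float = 0.8
    background_rate: float = 2.0  # tags per kb in sample 2; sample 1 gets scale_c times this
    frac_true_diff: float = 0.1
    effect_size: float = 2.0  # log2 units, applied to sample 1
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    peak_halfwidth: int = 1000
    summit_jitter: int = 50
    tag_spread: float = 150.0
    strand_offset: int = 100
    min_spacing: int = 5000
    seed: int = 0


@dataclass
class SimulatedExperiment:
    """In-memory result of one simulation plus its ground-truth table."""

    config: SimulationConfig
    peaks1: list[Peak]
    peaks2: list[Peak]
    tags1: list[SequenceTag]
    tags2: list[SequenceTag]
    truth: pd.DataFrame


def _place_loci(config: SimulationConfig, rng: np.random.Generator):
    """Deterministically scatter peak loci on a spaced grid (no collisions)."""
    margin = config.peak_halfwidth + 4 * config.summit_jitter
    slots = []
    for chrom in sorted(config.genome):
        size = config.genome[chrom]
        usable = size - 2 * margin
        n_slots = max(0, usable // config.min_spacing)
        slots.extend(
            (chrom, margin + k * config.min_spacing + config.min_spacing // 2)
            for k in range(n_slots)
        )
    n_needed = config.n_common + config.n_unique1 + config.n_unique2
    if n_needed > len(slots):
        raise ValueError(
            f"{n_needed} peaks exceed genome capacity of {len(slots)} loci "
            f"at {config.min_spacing} bp spacing"
        )
    chosen = rng.choice(len(slots), size=n_needed, replace=False)
    return [slots[i] for i in chosen]


def _signal_tags(
    rng: np.random.Generator,
    chrom: str,
    summit: int,
    expected: float,
    config: SimulationConfig,
) -> list[SequenceTag]:
    n = rng.poisson(expected)
    if n == 0:
        return []
    centers = np.rint(rng.normal(summit, config.tag_spread, size=n)).astype(int)
    plus = rng.random(n) < 0.5
    tags = []
    for center, is_plus in zip(centers, plus):
        if is_plus:
            tags.append(SequenceTag(chrom, max(0, center - config.strand_offset), "+"))
        else:
            tags.append(SequenceTag(chrom, max(0, center + config.strand_offset), "-"))
    return tags


def _background_tags(
    rng: np.random.Generator, config: SimulationConfig, rate_per_kb: float
) -> list[SequenceTag]:
    tags = []
    for chrom in sorted(config.genome):
        size = config.genome[chrom]
        n = rng.poisson(rate_per_kb * size / 1000.0)
        positions = rng.integers(0, size, size=n)
        strands = rng.random(n) < 0.5
        tags.extend(
            SequenceTag(chrom, int(p), "+" if s else "-")
            for p, s in zip(positions, strands)
        )
    return tags


def _make_peak(chrom: str, summit: int, name: str, halfwidth: int) -> Peak:
    start = max(0, summit - halfwidth)
    # keep the summit exactly at the interval midpoint so midpoint summit
    # parsing recovers it after a BED round trip
    end = summit + (summit - start)
    if end <= summit:
        end = summit + 1
    return Peak(GenomicInterval(chrom, start, end), summit, name)


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedExperiment:
    """Generate peaks, tags and a truth table; optionally write BED/TSV files.

    When ``outdir`` is given, writes ``peaks1.bed``, ``peaks2.bed``,
    ``tags1.bed``, ``tags2.bed`` and ``truth.tsv`` there.  The truth table
    records each locus's class (common / unique1 / unique2), its sample-2
    mean window count ``lam2``, and its true log2 effect (0 for null common
    peaks).
    """
    rng = np.random.default_rng(config.seed)
    loci = _place_loci(config, rng)
    common_loci = loci[: config.n_common]
    unique1_loci = loci[config.n_common : config.n_common + config.n_unique1]
    unique2_loci = loci[config.n_common + config.n_unique1 :]

    n_diff = int(round(config.frac_true_diff * config.n_common))
    diff_flags = np.zeros(config.n_common, dtype=bool)
    if n_diff:
        diff_flags[rng.choice(config.n_common, size=n_diff, replace=False)] = True

    peaks1: list[Peak] = []
    peaks2: list[Peak] = []
    tags1: list[SequenceTag] = []
    tags2: list[SequenceTag] = []
    truth_rows = []

    for i, (chrom, pos) in enumerate(common_loci):
        summit1 = pos + int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
        summit2 = summit1 + int(
            rng.integers(-config.summit_jitter, config.summit_jitter + 1)
        )
        lam2 = float(rng.lognormal(config.intensity_log_mean, config.intensity_log_sd))
        effect = config.effect_size if diff_flags[i] else 0.0
        lam1 = config.scale_c * lam2 * 2.0**effect
        name = f"common_{i}"
        peaks1.append(_make_peak(chrom, summit1, name, config.peak_halfwidth))
        peaks2.append(_make_peak(chrom, summit2, name, config.peak_halfwidth))
        tags1.extend(_signal_tags(rng, chrom, summit1, lam1, config))
        tags2.extend(_signal_tags(rng, chrom, summit2, lam2, config))
        truth_rows.append((name, chrom, summit1, summit2, "common", lam2, effect))

    for i, (chrom, pos) in enumerate(unique1_loci):
        summit = pos + int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
        lam2 = float(rng.lognormal(config.intensity_log_mean, config.intensity_log_sd))
        name = f"unique1_{i}"
        peaks1.append(_make_peak(chrom, summit, name, config.peak_halfwidth))
        tags1.extend(_signal_tags(rng, chrom, summit, config.scale_c * lam2, config))
        truth_rows.append((name, chrom, summit, -1, "unique1", lam2, 0.0))

    for i, (chrom, pos) in enumerate(unique2_loci):
        summit = pos + int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
        lam2 = float(rng.lognormal(config.intensity_log_mean, config.intensity_log_sd))
        name = f"unique2_{i}"
        peaks2.append(_make_peak(chrom, summit, name, config.peak_halfwidth))
        tags2.extend(_signal_tags(rng, chrom, summit, lam2, config))
        truth_rows.append((name, chrom, summit, -1, "unique2", lam2, 0.0))

    # scale_c is a library-wide intensity ratio, so sample 1's background is
    # scaled by it as well (a deeper/stronger library is brighter everywhere)
    tags1.extend(_background_tags(rng, config, config.scale_c * config.background_rate))
    tags2.extend(_background_tags(rng, config, config.background_rate))

    key = lambda p: (p.chrom, p.start, p.summit)
    peaks1.sort(key=key)
    peaks2.sort(key=key)
    tkey = lambda t: (t.chrom, t.pos5, t.strand)
    tags1.sort(key=tkey)
    tags2.sort(key=tkey)

    truth = pd.DataFrame(
        truth_rows,
        columns=["name", "chrom", "summit1", "summit2", "class", "lam2", "log2_effect"],
    )
    result = SimulatedExperiment(config, peaks1, peaks2, tags1, tags2, truth)
    if outdir is not None:
        write_experiment(result, outdir)
    return result


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the four BED inputs and the truth TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks1": outdir / "peaks1.bed",
        "peaks2": outdir / "peaks2.bed",
        "tags1": outdir / "tags1.bed",
        "tags2": outdir / "tags2.bed",
        "truth": outdir / "truth.tsv",
    }
    for which, peaks in (("peaks1", experiment.peaks1), ("peaks2", experiment.peaks2)):
        with open(paths[which], "w") as fh:
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\n")
    for which, tags in (("tags1", experiment.tags1), ("tags2", experiment.tags2)):
        with open(paths[which], "w") as fh:
            for i, t in enumerate(tags):
                if t.strand == "+":
                    start, end = t.pos5, t.pos5 + _READ_LENGTH
                else:
                    start, end = max(0, t.pos5 + 1 - _READ_LENGTH), t.pos5 + 1
                fh.write(f"{t.chrom}\t{start}\t{end}\tr{i}\t0\t{t.strand}\n")
    experiment.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same conditions with no truly differential common peaks."""
    return replace(config, frac_true_diff=0.0)
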
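"""End-to-end pipeline: four BED files in, normalized peak tables out.

Steps: parse peaks and tags, classify common/unique peaks and pair them,
count reads in summit-centered windows, fit the robust line M = a + b*A to
the common-peak pairs (each pair's window is centered at the midpoint of
the two summits, so the fit is symmetric in the two samples), normalize all
peaks of both samples, attach Audic–Claverie P-values, and classify
differential binding with combined |M| and P cutoffs.

Outputs: one all-peaks TSV, three class BED files, two WIG tracks of
normalized M (one per input peak list), before/after MA plots, and a JSON
run manifest with the fitted model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .model import (
    LinearModel,
    ac_pvalues,
    classify_differential,
    compute_ma_arrays,
    fit_robust_line,
    normalize_all,
)
from .pairing import pair_and_classify
from .quantify import QuantConfig, TagIndex

TSV_COLUMNS = [
    "chrom", "start", "end", "summit", "sample", "raw_x1", "raw_x2",
    "M_raw", "A_raw", "M_norm", "A_norm", "d1_norm", "d2_norm",
    "p_value", "class", "partner",
]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings; serialized into the run manifest."""

    peaks1: str
    peaks2: str
    reads1: str
    reads2: str
    name1: str = "sample1"
    name2: str = "sample2"
    window: int = 2000
    summit_dist: int = 500
    pairing: str = "overlap"  # or "summit_distance"
    shift: int = 100
    m_cutoff: float = 1.0
    p_cutoff: float = 0.01
    norm_mode: str = "rescale"  # or "residual"
    summit_mode: str = "midpoint"  # or "column4_offset"
    seed: int = 0
    output_dir: str | None = None
    make_plots: bool = True


@dataclass
class RunResult:
    config: RunConfig
    model: LinearModel
    table: pd.DataFrame
    pairs: list[tuple[int, int]]
    manifest: dict = field(default_factory=dict)


def _fit_common_pairs(peaks1, peaks2, pairs, index1: TagIndex, index2: TagIndex, window: int) -> LinearModel:
    """Fit the normalization line on pair windows centered between summits."""
    if len(pairs) < 2:
        raise ValueError(
            f"only {len(pairs)} common-peak pairs; cannot fit a normalization line"
        )
    x1 = np.empty(len(pairs), dtype=np.int64)
    x2 = np.empty(len(pairs), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        chrom = peaks1[i].chrom
        center = (peaks1[i].summit + peaks2[j].summit) // 2
        x1[k] = index1.count(chrom, center, window)
        x2[k] = index2.count(chrom, center, window)
    m, a = compute_ma_arrays(x1, x2)
    return fit_robust_line((a, m))


def _sample_table(
    peaks, classes, sample_name: str, x1, x2, model: LinearModel, config: RunConfig
) -> pd.DataFrame:
    m_raw, a_raw = compute_ma_arrays(x1, x2)
    norm = normalize_all(x1, x2, model, mode=config.norm_mode)
    p_values = ac_pvalues(norm["d1_norm"], norm["d2_norm"])
    klass = classify_differential(
        norm["M_norm"], p_values, config.m_cutoff, config.p_cutoff
    )
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "summit": [p.summit for p in peaks],
            "sample": sample_name,
            "raw_x1": x1,
            "raw_x2": x2,
            "M_raw": m_raw,
            "A_raw": a_raw,
            "M_norm": norm["M_norm"],
            "A_norm": norm["A_norm"],
            "d1_norm": norm["d1_norm"],
            "d2_norm": norm["d2_norm"],
            "p_value": p_values,
            "class": klass,
            "partner": [
                c.partner_index if c.is_common else -1 for c in classes
            ],
        }
    )


def _ma_plot(table: pd.DataFrame, model: LinearModel, path: Path, normalized: bool) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if normalized:
        a_col, m_col, title = "A_norm", "M_norm", "After normalization"
    else:
        a_col, m_col, title = "A_raw", "M_raw", "Before normalization"
    common = table["class_pairing"] == "common"
    ax.scatter(table[a_col][~common], table[m_col][~common], s=4, alpha=0.4,
               color="tab:gray", label="unique")
    ax.scatter(table[a_col][common], table[m_col][common], s=4, alpha=0.4,
               color="tab:blue", label="common")
    xs = np.linspace(table[a_col].min(), table[a_col].max(), 50)
    if normalized:
        ax.axhline(0.0, color="tab:red", lw=1, label="M = 0")
    else:
        ax.plot(xs, model.a + model.b * xs, color="tab:red", lw=1,
                label=f"M = {model.a:.2f} + {model.b:.2f} A")
    ax.set_xlabel("A")
    ax.set_ylabel("M")
    ax.set_title(title)
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_manorm(config: RunConfig) -> RunResult:
    """Run the whole normalization pipeline; write outputs if requested."""
    peaks1 = gio.parse_peak_bed(config.peaks1, config.summit_mode)
    peaks2 = gio.parse_peak_bed(config.peaks2, config.summit_mode)
    tags1 = gio.parse_tag_bed(config.reads1)
    tags2 = gio.parse_tag_bed(config.reads2)
    index1 = TagIndex(tags1, config.shift)
    index2 = TagIndex(tags2, config.shift)

    classes1, classes2, pairs = pair_and_classify(
        peaks1,
        peaks2,
        mode="overlap" if config.pairing == "overlap" else "summit_distance",
        max_summit_dist=config.summit_dist,
    )
    model = _fit_common_pairs(peaks1, peaks2, pairs, index1, index2, config.window)

    quant = QuantConfig(config.window, config.shift)
    x1_s1, x2_s1 = _quantify(peaks1, index1, index2, quant)
    x1_s2, x2_s2 = _quantify(peaks2, index1, index2, quant)

    table1 = _sample_table(peaks1, classes1, config.name1, x1_s1, x2_s1, model, config)
    table2 = _sample_table(peaks2, classes2, config.name2, x1_s2, x2_s2, model, config)
    table1["class_pairing"] = [c.label for c in classes1]
    table2["class_pairing"] = [c.label for c in classes2]
    table = pd.concat([table1, table2], ignore_index=True)

    manifest = {
        "config": asdict(config),
        "model": {
            "intercept_a": model.a,
            "slope_b": model.b,
            "n_pairs": model.n_points,
            "converged": model.converged,
        },
        "n_peaks1": len(peaks1),
        "n_peaks2": len(peaks2),
        "n_tags1": index1.total,
        "n_tags2": index2.total,
        "n_common_pairs": len(pairs),
        "n_common1": int(sum(c.is_common for c in classes1)),
        "n_common2": int(sum(c.is_common for c in classes2)),
        "class_counts": table["class"].value_counts().to_dict(),
        "seed": config.seed,
    }
    result = RunResult(config, model, table, pairs, manifest)
    if config.output_dir is not None:
        _write_outputs(result, peaks1, peaks2, table1, table2)
    return result


def _quantify(peaks, index1: TagIndex, index2: TagIndex, quant: QuantConfig):
    x1 = np.asarray(
        [index1.count(p.chrom, p.summit, quant.window) for p in peaks], dtype=np.int64
    )
    x2 = np.asarray(
        [index2.count(p.chrom, p.summit, quant.window) for p in peaks], dtype=np.int64
    )
    return x1, x2


def _write_outputs(result: RunResult, peaks1, peaks2, table1, table2) -> None:
    config = result.config
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{config.name1}_vs_{config.name2}"
    table = result.table

    table[TSV_COLUMNS].to_csv(outdir / f"{stem}_all_peaks.tsv", sep="\t", index=False)

    all_peaks = list(peaks1) + list(peaks2)
    for klass, suffix in (
        ("sample1_biased", f"biased_{config.name1}"),
        ("sample2_biased", f"biased_{config.name2}"),
        ("unbiased", "unbiased"),
    ):
        keep = [p for p, k in zip(all_peaks, table["class"]) if k == klass]
        gio.write_interval_bed(keep, outdir / f"{stem}_{suffix}.bed")

    gio.write_m_wig(
        peaks1, list(table1["M_norm"]), outdir / f"{stem}_{config.name1}_Mnorm.wig",
        f"{stem} M_norm ({config.name1} peaks)",
    )
    gio.write_m_wig(
        peaks2, list(table2["M_norm"]), outdir / f"{stem}_{config.name2}_Mnorm.wig",
        f"{stem} M_norm ({config.name2} peaks)",
    )
    if config.make_plots:
        _ma_plot(table, result.model, outdir / f"{stem}_MA_before.png", normalized=False)
        _ma_plot(table, result.model, outdir / f"{stem}_MA_after.png", normalized=True)

    with open(outdir / f"{stem}_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
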
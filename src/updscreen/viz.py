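"""Diagnostic plots: cohort ROH/IR scatter and per-chromosome allele-fraction view.

Both plots are pure functions of saved tables; threshold overlays come from
the analysis config so the shading always matches the tagging cutoffs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import UpdScreenError
from .roh import RohSegment, merge_segments

log = logging.getLogger(__name__)


def plot_cohort_scatter(
    table: pd.DataFrame,
    out_path: str | Path,
    config: AnalysisConfig | None = None,
) -> Path:
    """One point per (sample, chromosome).

    Duo/trio rows: ROH fraction vs inheritance ratio, with background bands at
    the configured thresholds. Single rows: ROH fraction vs chromosome index.
    Candidate rows (upd_call != none) are labeled.
    """
    if table is None or len(table) == 0:
        raise UpdScreenError("cannot plot an empty cohort table")
    config = config or AnalysisConfig()
    thr = config.thresholds
    out_path = Path(out_path)

    parental = table.loc[table["setup"] != "single"]
    single = table.loc[table["setup"] == "single"]
    n_panels = int(len(parental) > 0) + int(len(single) > 0)
    n_panels = max(n_panels, 1)
    fig, axes = plt.subplots(1, n_panels, figsize=(6.5 * n_panels, 5.5))
    if n_panels == 1:
        axes = [axes]
    panel = 0

    def _shade_roh(ax):
        ax.axvspan(thr.roh_low_max, thr.roh_high_min, color="#F5D76E", alpha=0.35,
                   label=f"ROH {thr.roh_low_max}-{thr.roh_high_min}")
        ax.axvspan(thr.roh_high_min, 1.0, color="#E67E22", alpha=0.30,
                   label=f"ROH > {thr.roh_high_min}")
        ax.set_xlim(-0.02, 1.02)
        ax.set_xlabel("ROH fraction")

    if len(parental):
        ax = axes[panel]
        panel += 1
        _shade_roh(ax)
        ir = parental["ir"].to_numpy(dtype=float)
        plotted_ir = np.where(np.isnan(ir), 0.9, ir)
        ax.scatter(
            parental["roh_fraction"], plotted_ir, s=12, alpha=0.5,
            c="#4C72B0", edgecolors="none",
        )
        ax.set_yscale("log")
        ax.axhline(thr.ir_duo, color="#777777", ls="--", lw=1,
                   label=f"IR duo > {thr.ir_duo:g}")
        ax.axhline(thr.ir_trio, color="#333333", ls="--", lw=1,
                   label=f"IR trio > {thr.ir_trio:g}")
        for r in parental.loc[parental["upd_call"] != "none"].itertuples(index=False):
            y = 0.9 if pd.isna(r.ir) else r.ir
            ax.annotate(
                f"{r.sample} chr{r.chrom}: {r.upd_call}",
                (r.roh_fraction, y), fontsize=7,
                textcoords="offset points", xytext=(4, 4),
            )
        ax.set_ylabel("inheritance ratio")
        ax.set_title("duo/trio chromosomes")
        ax.legend(loc="upper center", fontsize=7)

    if len(single):
        ax = axes[panel]
        _shade_roh(ax)
        chrom_idx = single["chrom"].astype(int)
        ax.scatter(single["roh_fraction"], chrom_idx, s=12, alpha=0.5,
                   c="#4C72B0", edgecolors="none")
        for r in single.loc[single["upd_call"] != "none"].itertuples(index=False):
            ax.annotate(
                f"{r.sample} chr{r.chrom}: {r.upd_call}",
                (r.roh_fraction, int(r.chrom)), fontsize=7,
                textcoords="offset points", xytext=(4, 4),
            )
        ax.set_yticks(range(1, 23))
        ax.set_ylabel("chromosome")
        ax.set_title("single chromosomes")

    fig.tight_layout()
    fig.savefig(out_path, dpi=config.plot.dpi)
    plt.close(fig)
    return out_path


def plot_chromosome_af(
    sites: pd.DataFrame,
    out_path: str | Path,
    chrom: str,
    chrom_length: int,
    segments: Sequence[RohSegment] = (),
    relative_ir: float | None = None,
    roh_fraction: float | None = None,
    config: AnalysisConfig | None = None,
    sample: str = "",
) -> Path:
    """Alt fraction vs position colored by parental origin, ROH track, and a
    side panel with the relative IR and ROH fraction bars."""
    config = config or AnalysisConfig()
    out_path = Path(out_path)
    sub = sites.loc[sites["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        log.warning("no sites for chromosome %s; writing empty plot", chrom)

    fig, (ax, side) = plt.subplots(
        1, 2, figsize=(10, 4), gridspec_kw={"width_ratios": [5, 1]}
    )
    colors = config.plot.origin_colors
    origin = (
        sub["origin"] if "origin" in sub.columns else pd.Series("unknown", index=sub.index)
    ).fillna("unknown")
    for cls, color in colors.items():
        pts = sub.loc[origin == cls]
        if len(pts):
            ax.scatter(
                pts["pos"] / 1e6, pts["alt_fraction"], s=9, alpha=0.7,
                color=color, label=cls, edgecolors="none",
            )
    for seg in merge_segments(list(segments)):
        ax.axvspan(seg.start / 1e6, seg.end / 1e6, ymin=0.96, ymax=1.0,
                   color="#2C3E50", alpha=0.8)
    ax.set_xlim(0, chrom_length / 1e6)
    ax.set_ylim(-0.02, 1.05)
    ax.set_xlabel(f"chromosome {chrom} position (Mb)")
    ax.set_ylabel("alt allele fraction")
    title = f"{sample} chr{chrom}" if sample else f"chr{chrom}"
    ax.set_title(f"{title} (ROH track on top)")
    if len(sub):
        ax.legend(loc="center right", fontsize=7)

    bars, labels = [], []
    if relative_ir is not None:
        bars.append(relative_ir)
        labels.append("relative IR")
    if roh_fraction is not None:
        bars.append(roh_fraction)
        labels.append("ROH fraction")
    if bars:
        side.bar(range(len(bars)), bars, color=["#CC79A7", "#2C3E50"][: len(bars)])
        side.set_xticks(range(len(bars)))
        side.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        side.axhline(0.5, color="#AAAAAA", lw=0.8, ls=":")
    side.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(out_path, dpi=config.plot.dpi)
    plt.close(fig)
    return out_path
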
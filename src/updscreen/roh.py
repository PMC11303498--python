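"""Run-of-homozygosity calling and per-chromosome metrics.

The caller is a deterministic rule-based scanner rather than an HMM: maximal
runs of homozygous calls tolerating a bounded number of het interruptions,
broken at large gaps between informative sites. Segment boundaries are the
first/last supporting homozygous site. The ROH fraction divides the merged
segment span by the full chromosome length by default ("span" mode divides by
the first-to-last-variant distance instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RohParams
from .errors import ConfigurationError
from .vcf_io import HET, HOM_ALT, HOM_REF, VariantSite


@dataclass(frozen=True)
class RohSegment:
    """A called homozygous run; coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    n_sites: int
    n_het_interruptions: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ChromosomeMetrics:
    """Per (sample, chromosome) screening statistics."""

    sample: str
    chrom: str
    roh_fraction: float
    n_sites_used: int
    maternal_only: int = 0
    paternal_only: int = 0
    biparental: int = 0
    neither: int = 0
    ir: float | None = None
    ir_direction: str = "none"
    relative_ir: float | None = None


def _scan_block(
    chrom: str, pos: np.ndarray, is_het: np.ndarray, params: RohParams
) -> list[RohSegment]:
    """Greedy scan of one gap-free block: from each leftmost feasible
    homozygous start take the longest window with <= max_het_interruptions
    het sites, emit it when it has enough homozygous support."""
    segments: list[RohSegment] = []
    n = len(pos)
    i = 0
    while i < n:
        if is_het[i]:
            i += 1
            continue
        j = i
        hets = 0
        k = i + 1
        while k < n:
            if is_het[k]:
                if hets + 1 > params.max_het_interruptions:
                    break
                hets += 1
            else:
                j = k
            k += 1
        hets_inside = int(is_het[i : j + 1].sum())
        n_hom = (j - i + 1) - hets_inside
        if n_hom >= params.min_sites:
            segments.append(
                RohSegment(
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_sites=n_hom,
                    n_het_interruptions=hets_inside,
                )
            )
            i = j + 1
        else:
            i += 1
    return segments


def call_roh_segments(
    sites: Sequence[VariantSite] | tuple[np.ndarray, np.ndarray, str],
    params: RohParams | None = None,
) -> list[RohSegment]:
    """Call ROH segments on one chromosome.

    ``sites`` is either a position-sorted sequence of VariantSites for one
    chromosome, or a ``(pos, gt, chrom)`` triple of aligned arrays. Only
    informative sites (hom_ref, het, hom_alt) participate; runs are broken at
    gaps larger than ``max_gap_bp`` between consecutive informative sites,
    and a het at a would-be boundary terminates the run before it.
    """
    params = params or RohParams()
    if isinstance(sites, tuple):
        pos, gt, chrom = sites
        pos = np.asarray(pos, dtype=np.int64)
        gt = np.asarray(gt, dtype=object)
    else:
        if not sites:
            return []
        chrom = sites[0].chrom
        pos = np.array([s.pos for s in sites], dtype=np.int64)
        gt = np.array([s.gt for s in sites], dtype=object)

    informative = (gt == HOM_REF) | (gt == HOM_ALT) | (gt == HET)
    pos = pos[informative]
    gt = gt[informative]
    if len(pos) == 0:
        return []
    if np.any(np.diff(pos) < 0):
        order = np.argsort(pos, kind="stable")
        pos, gt = pos[order], gt[order]
    is_het = gt == HET

    segments: list[RohSegment] = []
    breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp) + 1
    for block_pos, block_het in zip(
        np.split(pos, breaks), np.split(is_het, breaks)
    ):
        segments.extend(_scan_block(chrom, block_pos, block_het, params))
    return segments


def merge_segments(segments: Sequence[RohSegment]) -> list[RohSegment]:
    """Union of overlapping/adjacent segments on one chromosome."""
    if not segments:
        return []
    ordered = sorted(segments, key=lambda s: (s.start, s.end))
    merged = [ordered[0]]
    for seg in ordered[1:]:
        last = merged[-1]
        if seg.start <= last.end + 1:
            merged[-1] = RohSegment(
                chrom=last.chrom,
                start=last.start,
                end=max(last.end, seg.end),
                n_sites=last.n_sites + seg.n_sites,
                n_het_interruptions=last.n_het_interruptions
                + seg.n_het_interruptions,
            )
        else:
            merged.append(seg)
    return merged


def roh_fraction(segments: Sequence[RohSegment], chrom_length: int) -> float:
    """Fraction of the chromosome covered by the union of segments."""
    if chrom_length <= 0:
        raise ConfigurationError(f"chromosome length must be > 0, got {chrom_length}")
    covered = sum(s.span for s in merge_segments(segments))
    return min(1.0, covered / chrom_length)


LOCATION_CLASSES = ("terminal", "interstitial", "centromeric-spanning", "mixed", "none")


def roh_location_class(
    segments: Sequence[RohSegment],
    chrom_length: int,
    centromere: tuple[int, int] | None = None,
    terminal_margin_bp: int = 2_000_000,
) -> str:
    """Annotate where merged segments sit on the chromosome.

    Terminal dominates; a centromere-spanning segment mixed with interstitial
    ones (and no terminal) yields 'mixed'. Annotation only — the label does
    not feed the tagging logic.
    """
    merged = merge_segments(segments)
    if not merged:
        return "none"
    classes = set()
    for seg in merged:
        if seg.start - 1 < terminal_margin_bp or chrom_length - seg.end < terminal_margin_bp:
            classes.add("terminal")
        elif centromere and seg.start <= centromere[0] and seg.end >= centromere[1]:
            classes.add("centromeric-spanning")
        else:
            classes.add("interstitial")
    if "terminal" in classes:
        return "terminal"
    if len(classes) > 1:
        return "mixed"
    return classes.pop()


def segments_to_bed(segments: Sequence[RohSegment]) -> str:
    """BED text (0-based half-open) for a set of segments."""
    lines = [
        f"{s.chrom}\t{s.start - 1}\t{s.end}\tROH\t{s.n_sites}\t."
        for s in sorted(segments, key=lambda s: (s.chrom, s.start))
    ]
    return "\n".join(lines) + ("\n" if lines else "")
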
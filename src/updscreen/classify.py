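"""Cutoff-based tagging, UPD candidate calls, consanguinity flag, cohort table.

Tag semantics (fraction f of a chromosome covered by ROH, inheritance ratio
ir): f < 0.2 is 'low'; 0.2 <= f <= 0.7 is 'high_mixed' (segmental-isodisomy
band, boundaries inclusive per the printed range); f > 0.7 is 'high'
(whole-chromosome isodisomy band). ir strictly above 2 (duo) or 5 (trio) is
'high' and suggestive of heterodisomy; single setups have no IR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ConsanguinityRule, TagThresholds
from .errors import CohortIntegrityError
from .genome import AUTOSOMES, GenomeBuild, get_build
from .inheritance import (
    MATERNAL,
    MATERNAL_ONLY,
    NO_DIRECTION,
    PATERNAL,
    PATERNAL_ONLY,
    BIPARENTAL,
    NEITHER,
    classify_origin_frame,
    count_origins,
    params_ir,
    relative_ir,
)
from .roh import ChromosomeMetrics, RohSegment, call_roh_segments, roh_fraction
from .vcf_io import Pedigree, SiteTable, apply_site_filters, join_family

log = logging.getLogger(__name__)

# roh tags
ROH_LOW = "low"
ROH_HIGH_MIXED = "high_mixed"
ROH_HIGH = "high"
UNINFORMATIVE = "uninformative"

# ir tags
IR_LOW = "low"
IR_HIGH = "high"
NOT_APPLICABLE = "not_applicable"

# upd calls
CALL_NONE = "none"
CALL_IUPD = "iUPD_candidate"
CALL_SEG_IUPD = "segmental_iUPD_candidate"
CALL_HUPD = "hUPD_candidate"
CALL_MIXED = "mixed_UPD_candidate"
ROH_DRIVEN_CALLS = (CALL_IUPD, CALL_SEG_IUPD, CALL_MIXED)

PARENT_UNKNOWN = "unknown"


@dataclass(frozen=True)
class ChromosomeTag:
    roh_tag: str
    ir_tag: str
    upd_call: str
    upd_parent: str = PARENT_UNKNOWN


def tag_chromosome(
    metrics: ChromosomeMetrics,
    setup: str,
    thresholds: TagThresholds | None = None,
) -> ChromosomeTag:
    """Total, deterministic step function of (roh_fraction, ir, setup)."""
    thr = thresholds or TagThresholds()

    if metrics.n_sites_used < thr.min_informative_sites:
        roh_tag = UNINFORMATIVE
    elif metrics.roh_fraction < thr.roh_low_max:
        roh_tag = ROH_LOW
    elif metrics.roh_fraction > thr.roh_high_min:
        roh_tag = ROH_HIGH
    else:
        roh_tag = ROH_HIGH_MIXED

    if setup == "single":
        ir_tag = NOT_APPLICABLE
    elif metrics.ir is None:
        ir_tag = UNINFORMATIVE
    else:
        cutoff = thr.ir_trio if setup == "trio" else thr.ir_duo
        ir_tag = IR_HIGH if metrics.ir > cutoff else IR_LOW

    if roh_tag == ROH_HIGH:
        call = CALL_IUPD
    elif roh_tag == ROH_HIGH_MIXED:
        call = CALL_MIXED if ir_tag == IR_HIGH else CALL_SEG_IUPD
    elif roh_tag == ROH_LOW and ir_tag == IR_HIGH:
        call = CALL_HUPD
    else:
        call = CALL_NONE

    parent = PARENT_UNKNOWN
    if call != CALL_NONE and ir_tag == IR_HIGH and metrics.ir_direction in (
        MATERNAL,
        PATERNAL,
    ):
        parent = metrics.ir_direction
    return ChromosomeTag(roh_tag=roh_tag, ir_tag=ir_tag, upd_call=call, upd_parent=parent)


def flag_consanguinity(
    metrics: dict[str, ChromosomeMetrics],
    tags: dict[str, ChromosomeTag],
    build: GenomeBuild,
    rule: ConsanguinityRule | None = None,
) -> tuple[bool, dict]:
    """Sample-level heuristic: many elevated-ROH autosomes, or a high
    genome-wide ROH fraction (optionally excluding the single largest
    contributor so one whole-chromosome isodisomy never looks consanguine)."""
    rule = rule or ConsanguinityRule()
    affected = [
        c for c in AUTOSOMES
        if c in tags and tags[c].roh_tag in (ROH_HIGH_MIXED, ROH_HIGH)
    ]
    roh_bp = {
        c: metrics[c].roh_fraction * build.length(c)
        for c in AUTOSOMES
        if c in metrics
    }
    total_bp = sum(build.length(c) for c in roh_bp)
    covered = sum(roh_bp.values())
    genome_fraction = covered / total_bp if total_bp else 0.0
    if rule.exclude_top_chromosome and len(roh_bp) > 1:
        top = max(roh_bp, key=roh_bp.get)
        gw = (covered - roh_bp[top]) / (total_bp - build.length(top))
    else:
        gw = genome_fraction
    flag = (
        len(affected) >= rule.min_affected_autosomes
        or gw > rule.genome_roh_fraction
    )
    evidence = {
        "n_affected_autosomes": len(affected),
        "affected_autosomes": affected,
        "genome_roh_fraction": genome_fraction,
        "genome_roh_fraction_rule": gw,
    }
    return flag, evidence


@dataclass
class SampleReport:
    """All per-chromosome metrics, tags and sample-level flags for one child."""

    sample: str
    family: str
    setup: str
    metrics: dict[str, ChromosomeMetrics]
    tags: dict[str, ChromosomeTag]
    raw_upd_calls: dict[str, str]
    consanguinity_flag: bool
    consanguinity_evidence: dict
    roh_segments: dict[str, list[RohSegment]] = field(default_factory=dict)
    site_table: SiteTable | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in AUTOSOMES:
            m = self.metrics[chrom]
            t = self.tags[chrom]
            rows.append(
                {
                    "family": self.family,
                    "sample": self.sample,
                    "setup": self.setup,
                    "chrom": chrom,
                    "roh_fraction": m.roh_fraction,
                    "n_sites_used": m.n_sites_used,
                    "maternal_only": m.maternal_only,
                    "paternal_only": m.paternal_only,
                    "biparental": m.biparental,
                    "neither": m.neither,
                    "ir": np.nan if m.ir is None else m.ir,
                    "ir_direction": m.ir_direction,
                    "relative_ir": np.nan if m.relative_ir is None else m.relative_ir,
                    "roh_tag": t.roh_tag,
                    "ir_tag": t.ir_tag,
                    "upd_call": t.upd_call,
                    "raw_upd_call": self.raw_upd_calls[chrom],
                    "upd_parent": t.upd_parent,
                    "consanguinity_flag": self.consanguinity_flag,
                }
            )
        return pd.DataFrame(rows)


def analyze_site_table(
    table: SiteTable,
    sample: str,
    family: str,
    config: AnalysisConfig | None = None,
    build: GenomeBuild | None = None,
) -> SampleReport:
    """Compute metrics, tags and flags from a joined (filtered) site table."""
    config = config or AnalysisConfig()
    build = build or get_build(config.genome_build)
    setup = table.pedigree.setup

    frame = classify_origin_frame(table.frame)
    metrics: dict[str, ChromosomeMetrics] = {}
    segments: dict[str, list[RohSegment]] = {}
    grouped = dict(tuple(frame.groupby("chrom", sort=False)))
    for chrom in AUTOSOMES:
        sub = grouped.get(chrom)
        if sub is None or sub.empty:
            metrics[chrom] = ChromosomeMetrics(
                sample=sample, chrom=chrom, roh_fraction=0.0, n_sites_used=0
            )
            segments[chrom] = []
            continue
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        gt = sub["gt"].to_numpy(dtype=object)
        segs = call_roh_segments((pos, gt, chrom), config.roh)
        segments[chrom] = segs
        if config.roh.denominator == "span" and len(pos) > 1:
            denom = int(pos[-1] - pos[0] + 1)
        else:
            denom = build.length(chrom)
        frac = roh_fraction(segs, denom)
        counts = count_origins(sub)
        m, p = counts[MATERNAL_ONLY], counts[PATERNAL_ONLY]
        if setup == "single":
            ir, direction, rel = None, NO_DIRECTION, None
        else:
            ir, direction = params_ir(m, p, config.inheritance)
            rel = relative_ir(m, p)
        n_used = int(((gt == "het") | (gt == "hom_alt") | (gt == "hom_ref")).sum())
        metrics[chrom] = ChromosomeMetrics(
            sample=sample,
            chrom=chrom,
            roh_fraction=frac,
            n_sites_used=n_used,
            maternal_only=m,
            paternal_only=p,
            biparental=counts[BIPARENTAL],
            neither=counts[NEITHER],
            ir=ir,
            ir_direction=direction,
            relative_ir=rel,
        )

    tags = {
        c: tag_chromosome(metrics[c], setup, config.thresholds) for c in AUTOSOMES
    }
    flag, evidence = flag_consanguinity(metrics, tags, build, config.consanguinity)
    raw_calls = {c: tags[c].upd_call for c in AUTOSOMES}
    if flag:
        # ROH-driven candidates on a suspected-consanguine sample are
        # downgraded: the pattern is not distinguishable from consanguinity.
        for c in AUTOSOMES:
            if tags[c].upd_call in ROH_DRIVEN_CALLS:
                tags[c] = ChromosomeTag(
                    roh_tag=tags[c].roh_tag,
                    ir_tag=tags[c].ir_tag,
                    upd_call=CALL_NONE,
                    upd_parent=PARENT_UNKNOWN,
                )
    table_with_origin = SiteTable(frame=frame, pedigree=table.pedigree)
    return SampleReport(
        sample=sample,
        family=family,
        setup=setup,
        metrics=metrics,
        tags=tags,
        raw_upd_calls=raw_calls,
        consanguinity_flag=flag,
        consanguinity_evidence=evidence,
        roh_segments=segments,
        site_table=table_with_origin,
    )


def analyze_family(
    child,
    mother,
    father,
    pedigree: Pedigree,
    family: str,
    config: AnalysisConfig | None = None,
    build: GenomeBuild | None = None,
) -> SampleReport:
    """Filter the child's sites, join parents, and produce a SampleReport.

    ``child``/``mother``/``father`` are VariantSite sequences or site frames;
    parents may be None when absent from the pedigree.
    """
    config = config or AnalysisConfig()
    filtered = apply_site_filters(child, config.filters)
    table = join_family(filtered, mother, father, pedigree)
    return analyze_site_table(
        table, sample=pedigree.child_id, family=family, config=config, build=build
    )


COHORT_COLUMNS = [
    "family", "sample", "setup", "chrom", "roh_fraction", "n_sites_used",
    "maternal_only", "paternal_only", "biparental", "neither", "ir",
    "ir_direction", "relative_ir", "roh_tag", "ir_tag", "upd_call",
    "raw_upd_call", "upd_parent", "consanguinity_flag",
]


def build_cohort_table(reports: list[SampleReport]) -> pd.DataFrame:
    """Long-format batch table: one row per (sample, autosome), filterable."""
    if not reports:
        raise CohortIntegrityError("cannot build a cohort table from zero reports")
    table = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    dup = table.duplicated(["sample", "chrom"])
    if dup.any():
        dups = table.loc[dup, ["sample", "chrom"]].drop_duplicates()
        raise CohortIntegrityError(
            f"duplicate (sample, chromosome) rows: {dups.to_dict('records')}"
        )
    table["_chrom_order"] = table["chrom"].map({c: i for i, c in enumerate(AUTOSOMES)})
    table = (
        table.sort_values(["sample", "_chrom_order"], kind="stable")
        .drop(columns="_chrom_order")
        .reset_index(drop=True)
    )
    return table[COHORT_COLUMNS]


def summarize_cohort(table: pd.DataFrame) -> dict:
    """Candidate counts per class plus consanguinity-flag tally."""
    calls = table["upd_call"].value_counts().to_dict()
    flagged = (
        table.drop_duplicates("sample")["consanguinity_flag"].sum()
        if len(table)
        else 0
    )
    return {
        "n_samples": int(table["sample"].nunique()),
        "n_rows": int(len(table)),
        "candidates": {
            c: int(calls.get(c, 0))
            for c in (CALL_IUPD, CALL_SEG_IUPD, CALL_HUPD, CALL_MIXED)
        },
        "consanguinity_flagged_samples": int(flagged),
    }
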
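"""Synthetic single/duo/trio exome-style cohorts with ground-truth UPD events.

Model: per site a population alt-allele frequency is drawn from a truncated
Beta; each parent carries two haplotypes with independent Bernoulli(af)
alleles; the child inherits one whole haplotype per parent per chromosome
(no recombination — sufficient statistical structure for ROH/IR screening).

Event injection over an interval:
  * iUPD / segUPD_iso — the child receives two copies of one randomly chosen
    haplotype of the designated parent (homozygous throughout).
  * hUPD — the child receives both haplotypes of the designated parent
    (child genotype equals that parent's), nothing from the other parent.
  * consanguinity — IBD segments shared between the parents; the child is
    autozygous across them (mimics an inbred pedigree without simulating one).

Read noise: depth ~ Poisson(mean); alt reads ~ Binomial(depth, e) with
e = 0.5 (het), 1 - eps (hom_alt), eps (hom_ref). Genotypes are re-called from
the noisy alt fractions, and every individual additionally carries a band of
low-allele-fraction artifact het calls (af ~ N(0.2, 0.03)) on all chromosomes.
Identical seed + config gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genome import AUTOSOMES, GenomeBuild, get_build
from .vcf_io import HET, HOM_ALT, HOM_REF, MISSING, Pedigree

BASES = np.array(list("ACGT"))

EVENT_IUPD = "iUPD"
EVENT_HUPD = "hUPD"
EVENT_SEG_IUPD = "segUPD_iso"
EVENT_CONSANGUINITY = "consanguinity"
EVENTS = (EVENT_IUPD, EVENT_HUPD, EVENT_SEG_IUPD, EVENT_CONSANGUINITY)

ROLES = ("child", "mother", "father")


@dataclass(frozen=True)
class SyntheticTruth:
    """One injected ground-truth event; consanguinity uses chrom='*'."""

    family: str
    chrom: str
    event: str
    parent: str = ""
    start: int = 0
    end: int = 0
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ConfigurationError(f"unknown event type {self.event!r}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 1
    #: proportions of (single, duo, trio) families; duos alternate which
    #: parent is sequenced.
    setup_mix: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sites_per_chromosome: int = 1500
    af_beta_a: float = 0.3
    af_beta_b: float = 0.3
    af_min: float = 0.01
    af_max: float = 0.99
    mean_depth: float = 60.0
    error_rate: float = 0.01
    #: caller bands used to re-derive genotype classes from noisy fractions
    call_het_min_af: float = 0.10
    call_hom_min_af: float = 0.85
    artifact_sites_per_chromosome: int = 30
    artifact_af_mean: float = 0.2
    artifact_af_sd: float = 0.03
    #: target autozygous genome fraction of a consanguine child
    consanguinity_fraction: float = 0.125
    consanguinity_segment_frac: tuple[float, float] = (0.25, 0.40)
    genome_build: str = "GRCh38"
    events: list[SyntheticTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.setup_mix) - 1.0) > 1e-9:
            raise ConfigurationError("setup_mix proportions must sum to 1")
        if min(self.setup_mix) < 0:
            raise ConfigurationError("setup_mix proportions must be >= 0")
        for name in ("sites_per_chromosome", "artifact_sites_per_chromosome"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class FamilySim:
    """Simulated genotypes and noisy calls for one family."""

    family: str
    setup: str
    pedigree: Pedigree
    sites: pd.DataFrame  # chrom,pos,ref,alt,pop_af for the shared site set
    true_gt: dict[str, np.ndarray]  # role -> alt-allele dosage (0/1/2)
    calls: dict[str, pd.DataFrame]  # role -> called variant frame
    truth: list[SyntheticTruth]


def _family_rng(seed: int, family_index: int) -> np.random.Generator:
    # substream keyed by family index: output independent of cohort ordering
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, family_index))
    )


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = rng.beta(a, b, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def simulate_family(
    cfg: SimulationConfig,
    family_id: str,
    setup: str,
    events: list[SyntheticTruth],
    rng: np.random.Generator,
    build: GenomeBuild | None = None,
) -> FamilySim:
    """Draw one family's true genotypes and noisy calls.

    ``events`` are this family's truth entries (at most one per chromosome).
    Both parents are always simulated internally — the setup only controls
    which members receive called output.
    """
    build = build or get_build(cfg.genome_build)
    by_chrom = {e.chrom: e for e in events if e.event != EVENT_CONSANGUINITY}
    if len(by_chrom) != sum(1 for e in events if e.event != EVENT_CONSANGUINITY):
        raise ConfigurationError(f"family {family_id}: multiple events on one chromosome")
    consang = next((e for e in events if e.event == EVENT_CONSANGUINITY), None)

    S = cfg.sites_per_chromosome
    chrom_arrays, pos_arrays = [], []
    for chrom in AUTOSOMES:
        L = build.length(chrom)
        p = _unique_positions(rng, L, S)
        pos_arrays.append(p)
        chrom_arrays.append(np.full(len(p), chrom, dtype=object))
    pos = np.concatenate(pos_arrays)
    chrom_col = np.concatenate(chrom_arrays)
    chrom_idx = np.repeat(np.arange(len(AUTOSOMES)), [len(p) for p in pos_arrays])
    n = len(pos)

    af = _truncated_beta(rng, cfg.af_beta_a, cfg.af_beta_b, cfg.af_min, cfg.af_max, n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    mother = rng.random((n, 2)) < af[:, None]
    father = rng.random((n, 2)) < af[:, None]

    # consanguinity: shared parental IBD segments; child autozygous across them
    forced = np.zeros(n, dtype=bool)
    truth = list(events)
    if consang is not None:
        seg_lo, seg_hi = cfg.consanguinity_segment_frac
        p_seg = min(1.0, cfg.consanguinity_fraction / ((seg_lo + seg_hi) / 2))
        for ci, chrom in enumerate(AUTOSOMES):
            hit = rng.random() < p_seg
            frac = rng.uniform(seg_lo, seg_hi)
            start_frac = rng.uniform(0.0, 1.0 - frac)
            if not hit:
                continue
            L = build.length(chrom)
            s = int(start_frac * L) + 1
            e = min(L, s + int(frac * L))
            mask = (chrom_idx == ci) & (pos >= s) & (pos <= e)
            father[mask, 0] = mother[mask, 0]
            forced |= mask

    mat_hap = rng.integers(0, 2, size=len(AUTOSOMES))[chrom_idx]
    pat_hap = rng.integers(0, 2, size=len(AUTOSOMES))[chrom_idx]
    child_m = mother[np.arange(n), mat_hap]
    child_p = father[np.arange(n), pat_hap]
    child_m = np.where(forced, mother[:, 0], child_m)
    child_p = np.where(forced, father[:, 0], child_p)
    child = child_m.astype(np.int8) + child_p.astype(np.int8)

    chrom_pos_in_names = {c: i for i, c in enumerate(AUTOSOMES)}
    for event in by_chrom.values():
        ci = chrom_pos_in_names.get(event.chrom)
        if ci is None:
            raise ConfigurationError(f"event on unknown chromosome {event.chrom!r}")
        L = build.length(event.chrom)
        start = event.start or 1
        end = event.end or L
        if start < 1 or end > L or start > end:
            raise ConfigurationError(
                f"event interval [{start},{end}] outside chromosome {event.chrom}"
            )
        mask = (chrom_idx == ci) & (pos >= start) & (pos <= end)
        if not mask.any():
            raise ConfigurationError(
                f"event interval on {event.chrom} covers no simulated sites"
            )
        parent_h = mother if event.parent == "maternal" else father
        if event.event in (EVENT_IUPD, EVENT_SEG_IUPD):
            hap = int(rng.integers(0, 2))
            child[mask] = 2 * parent_h[mask, hap].astype(np.int8)
        elif event.event == EVENT_HUPD:
            child[mask] = parent_h[mask, 0].astype(np.int8) + parent_h[
                mask, 1
            ].astype(np.int8)

    sites = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos.astype(np.int64),
            "ref": BASES[ref_idx],
            "alt": BASES[alt_idx],
            "pop_af": af,
        }
    )
    true_gt = {
        "child": child,
        "mother": mother.sum(axis=1).astype(np.int8),
        "father": father.sum(axis=1).astype(np.int8),
    }

    ped = Pedigree(
        child_id=f"{family_id}_child",
        mother_id=f"{family_id}_mother" if setup in ("trio", "duo_mother") else None,
        father_id=f"{family_id}_father" if setup in ("trio", "duo_father") else None,
    )
    roles = ["child"] + [
        r for r in ("mother", "father") if getattr(ped, f"{r}_id") is not None
    ]
    calls: dict[str, pd.DataFrame] = {}
    for role in roles:
        noisy = add_read_noise(sites, true_gt[role], cfg, rng)
        variant = noisy.loc[noisy["gt"].isin([HET, HOM_ALT])].reset_index(drop=True)
        artifacts = make_artifact_sites(cfg, rng, build, sites)
        combined = pd.concat([variant, artifacts], ignore_index=True)
        combined["_order"] = combined["chrom"].map(chrom_pos_in_names)
        combined = (
            combined.sort_values(["_order", "pos"], kind="stable")
            .drop(columns="_order")
            .reset_index(drop=True)
        )
        calls[role] = combined

    return FamilySim(
        family=family_id,
        setup=setup,
        pedigree=ped,
        sites=sites,
        true_gt=true_gt,
        calls=calls,
        truth=truth,
    )


def add_read_noise(
    sites: pd.DataFrame,
    gt_codes: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Apply the read-depth/binomial noise model and re-call genotypes.

    Returns one row per input site (including re-called hom_ref sites, which
    callers would not emit; downstream code selects the variant rows).
    """
    n = len(sites)
    gt_codes = np.asarray(gt_codes)
    depth = rng.poisson(cfg.mean_depth, size=n)
    eps = cfg.error_rate
    p = np.choose(gt_codes, [eps, 0.5, 1.0 - eps])
    alt = rng.binomial(depth, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    called = np.select(
        [depth == 0, af >= cfg.call_hom_min_af, af >= cfg.call_het_min_af],
        [MISSING, HOM_ALT, HET],
        default=HOM_REF,
    )
    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    out["gt"] = called
    out["depth"] = depth.astype(np.int64)
    out["alt_reads"] = alt.astype(np.int64)
    out["alt_fraction"] = af
    out["artifact"] = False
    return out


def make_artifact_sites(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    build: GenomeBuild,
    existing_sites: pd.DataFrame,
) -> pd.DataFrame:
    """Low-allele-fraction artifact het calls, a fixed count per chromosome."""
    A = cfg.artifact_sites_per_chromosome
    if A == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gt", "depth", "alt_reads",
                     "alt_fraction", "artifact"]
        )
    taken = {
        c: set(existing_sites.loc[existing_sites["chrom"] == c, "pos"])
        for c in AUTOSOMES
    }
    frames = []
    for chrom in AUTOSOMES:
        L = build.length(chrom)
        pos = _unique_positions(rng, L, A)
        clash = np.array([p in taken[chrom] for p in pos])
        while clash.any():
            pos = pos[~clash]
            extra = _unique_positions(rng, L, A - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))[:A]
            clash = np.array([p in taken[chrom] for p in pos])
        af = _truncated_normal(
            rng, cfg.artifact_af_mean, cfg.artifact_af_sd, 0.0, 1.0, A
        )
        depth = np.maximum(1, rng.poisson(cfg.mean_depth, size=A))
        alt = np.clip(np.rint(af * depth).astype(np.int64), 1, depth)
        ref_idx = rng.integers(0, 4, size=A)
        alt_idx = (ref_idx + rng.integers(1, 4, size=A)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "ref": BASES[ref_idx],
                    "alt": BASES[alt_idx],
                    "gt": HET,
                    "depth": depth.astype(np.int64),
                    "alt_reads": alt,
                    "alt_fraction": alt / depth,
                    "artifact": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plan_setups(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Assign setups to families by largest-remainder apportionment."""
    n = cfg.n_families
    raw = np.array(cfg.setup_mix) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    setups: list[str] = ["single"] * counts[0]
    setups += ["duo_mother" if i % 2 == 0 else "duo_father" for i in range(counts[1])]
    setups += ["trio"] * counts[2]
    setups = list(np.array(setups, dtype=object)[rng.permutation(n)])
    return setups


def make_event_plan(
    family_ids: list[str],
    rng: np.random.Generator,
    build: GenomeBuild,
    n_iupd: int = 0,
    n_hupd: int = 0,
    n_segupd: int = 0,
    n_consanguinity: int = 0,
    seg_frac_range: tuple[float, float] = (0.3, 0.6),
    consanguinity_fraction: float = 0.125,
) -> list[SyntheticTruth]:
    """Assign at most one event per family, random chromosome and parent."""
    total = n_iupd + n_hupd + n_segupd + n_consanguinity
    if total > len(family_ids):
        raise ConfigurationError(
            f"{total} events requested for {len(family_ids)} families"
        )
    chosen = rng.choice(len(family_ids), size=total, replace=False)
    kinds = (
        [EVENT_IUPD] * n_iupd
        + [EVENT_HUPD] * n_hupd
        + [EVENT_SEG_IUPD] * n_segupd
        + [EVENT_CONSANGUINITY] * n_consanguinity
    )
    events: list[SyntheticTruth] = []
    for fam_i, kind in zip(chosen, kinds):
        family = family_ids[int(fam_i)]
        parent = "maternal" if rng.random() < 0.5 else "paternal"
        if kind == EVENT_CONSANGUINITY:
            events.append(
                SyntheticTruth(
                    family=family, chrom="*", event=kind,
                    fraction=consanguinity_fraction,
                )
            )
            continue
        chrom = AUTOSOMES[int(rng.integers(0, len(AUTOSOMES)))]
        L = build.length(chrom)
        if kind == EVENT_SEG_IUPD:
            frac = rng.uniform(*seg_frac_range)
            start = int(rng.uniform(0.0, 1.0 - frac) * L) + 1
            end = min(L, start + int(frac * L))
        else:
            start, end = 1, L
        events.append(
            SyntheticTruth(
                family=family, chrom=chrom, event=kind, parent=parent,
                start=start, end=end,
                fraction=(end - start + 1) / L,
            )
        )
    return events


def simulate_cohort(
    cfg: SimulationConfig, build: GenomeBuild | None = None
) -> list[FamilySim]:
    """Simulate all families; per-family RNG substreams keyed by index."""
    build = build or get_build(cfg.genome_build)
    plan_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
    )
    setups = plan_setups(cfg, plan_rng)
    family_ids = [f"F{i:04d}" for i in range(cfg.n_families)]
    by_family: dict[str, list[SyntheticTruth]] = {f: [] for f in family_ids}
    for event in cfg.events:
        if event.family not in by_family:
            raise ConfigurationError(f"event references unknown family {event.family!r}")
        by_family[event.family].append(event)
    families = []
    for i, (family_id, setup) in enumerate(zip(family_ids, setups)):
        rng = _family_rng(cfg.seed, i)
        families.append(
            simulate_family(cfg, family_id, setup, by_family[family_id], rng, build)
        )
    return families


def iter_cohort(
    cfg: SimulationConfig, build: GenomeBuild | None = None
) -> Iterator[FamilySim]:
    """Generator twin of :func:`simulate_cohort` for large cohorts."""
    build = build or get_build(cfg.genome_build)
    plan_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
    )
    setups = plan_setups(cfg, plan_rng)
    family_ids = [f"F{i:04d}" for i in range(cfg.n_families)]
    by_family: dict[str, list[SyntheticTruth]] = {f: [] for f in family_ids}
    for event in cfg.events:
        if event.family not in by_family:
            raise ConfigurationError(f"event references unknown family {event.family!r}")
        by_family[event.family].append(event)
    for i, (family_id, setup) in enumerate(zip(family_ids, setups)):
        rng = _family_rng(cfg.seed, i)
        yield simulate_family(cfg, family_id, setup, by_family[family_id], rng, build)


def cohort_from_sims(
    families: Iterable[FamilySim],
    config=None,
    build: GenomeBuild | None = None,
    drop_parents: bool = False,
    keep_sites: bool = False,
):
    """Analyze simulated families and assemble the cohort table.

    With ``drop_parents`` every family is re-analyzed as a single setup,
    discarding parental calls. Returns (cohort_table, reports).
    """
    from .classify import analyze_family, build_cohort_table

    reports = []
    for fam in families:
        if drop_parents:
            ped = Pedigree(child_id=fam.pedigree.child_id)
            mother = father = None
        else:
            ped = fam.pedigree
            mother = fam.calls.get("mother")
            father = fam.calls.get("father")
        report = analyze_family(
            fam.calls["child"], mother, father, ped, fam.family,
            config=config, build=build,
        )
        if not keep_sites:
            report.site_table = None
        reports.append(report)
    return build_cohort_table(reports), reports


def run_simulated_screen(
    cfg: SimulationConfig,
    config=None,
    build: GenomeBuild | None = None,
    drop_parents: bool = False,
):
    """Simulate, analyze and score in one streaming pass (memory-friendly).

    Returns (cohort_table, truth_table, reports).
    """
    from .classify import analyze_family, build_cohort_table

    build = build or get_build(cfg.genome_build)
    reports = []
    truth_rows = []
    for fam in iter_cohort(cfg, build):
        if drop_parents:
            ped = Pedigree(child_id=fam.pedigree.child_id)
            mother = father = None
        else:
            ped = fam.pedigree
            mother = fam.calls.get("mother")
            father = fam.calls.get("father")
        report = analyze_family(
            fam.calls["child"], mother, father, ped, fam.family,
            config=config, build=build,
        )
        report.site_table = None
        reports.append(report)
        truth_rows.extend(fam.truth)
    cohort = build_cohort_table(reports)
    truth = pd.DataFrame(
        [
            {
                "family": t.family, "chrom": t.chrom, "event": t.event,
                "parent": t.parent, "start": t.start, "end": t.end,
                "fraction": t.fraction,
            }
            for t in truth_rows
        ],
        columns=["family", "chrom", "event", "parent", "start", "end", "fraction"],
    )
    return cohort, truth, reports


def truth_frame(families: Iterable[FamilySim]) -> pd.DataFrame:
    rows = [
        {
            "family": t.family, "chrom": t.chrom, "event": t.event,
            "parent": t.parent, "start": t.start, "end": t.end,
            "fraction": t.fraction,
        }
        for fam in families
        for t in fam.truth
    ]
    return pd.DataFrame(
        rows,
        columns=["family", "chrom", "event", "parent", "start", "end", "fraction"],
    )


# ---------------------------------------------------------------------------
# output


def _write_vcf(
    path: Path, calls: pd.DataFrame, sample_id: str, build: GenomeBuild
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=updscreen-simulate",
    ]
    lines += [
        f"##contig=<ID={c},length={build.length(c)}>" for c in AUTOSOMES
    ]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    gt_codes = {HET: "0/1", HOM_ALT: "1/1"}
    for r in calls.itertuples(index=False):
        dp = int(r.depth)
        ad_alt = int(r.alt_reads)
        lines.append(
            f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
            f"GT:AD:DP\t{gt_codes[r.gt]}:{dp - ad_alt},{ad_alt}:{dp}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_cohort(
    families: list[FamilySim],
    out_dir: str | Path,
    build: GenomeBuild | None = None,
) -> tuple[Path, Path]:
    """Write one VCF per individual plus manifest.tsv and truth.tsv.

    Returns (manifest_path, truth_path). Manifest paths are relative to the
    output directory, so the directory is relocatable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    build = build or GRCH38_DEFAULT
    manifest_rows = []
    truth_rows = []
    for fam in families:
        for role, frame in fam.calls.items():
            sample_id = f"{fam.family}_{role}"
            vcf_name = f"{sample_id}.vcf"
            _write_vcf(out / vcf_name, frame, sample_id, build)
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "role": role,
                    "family_id": fam.family,
                    "path": vcf_name,
                }
            )
        for t in fam.truth:
            truth_rows.append(
                {
                    "family": t.family,
                    "chrom": t.chrom,
                    "event": t.event,
                    "parent": t.parent,
                    "start": t.start,
                    "end": t.end,
                    "fraction": t.fraction,
                }
            )
    manifest_path = out / "manifest.tsv"
    truth_path = out / "truth.tsv"
    pd.DataFrame(
        manifest_rows, columns=["sample_id", "role", "family_id", "path"]
    ).to_csv(manifest_path, sep="\t", index=False)
    pd.DataFrame(
        truth_rows,
        columns=["family", "chrom", "event", "parent", "start", "end", "fraction"],
    ).to_csv(truth_path, sep="\t", index=False)
    return manifest_path, truth_path


GRCH38_DEFAULT = get_build("GRCh38")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "family": str})


def score_recovery(cohort: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare a cohort table against a simulator truth table.

    Normal (family, chromosome) pairs exclude all chromosomes of consanguine
    families (their elevated ROH is intentional background, not a false call).
    """
    consang_families = set(
        truth.loc[truth["event"] == EVENT_CONSANGUINITY, "family"]
    )
    event_pairs = {
        (r.family, r.chrom): r
        for r in truth.itertuples(index=False)
        if r.event != EVENT_CONSANGUINITY
    }
    expected_call = {
        EVENT_IUPD: "iUPD_candidate",
        EVENT_HUPD: "hUPD_candidate",
        EVENT_SEG_IUPD: "segmental_iUPD_candidate",
    }
    per_event: dict[str, dict[str, int]] = {
        e: {"n": 0, "recovered": 0, "parent_correct": 0} for e in expected_call
    }
    rows_by_pair = {
        (r.family, r.chrom): r for r in cohort.itertuples(index=False)
    }
    for (family, chrom), ev in event_pairs.items():
        stats = per_event[ev.event]
        stats["n"] += 1
        row = rows_by_pair.get((family, chrom))
        if row is None:
            continue
        call = row.raw_upd_call if family in consang_families else row.upd_call
        if call == expected_call[ev.event]:
            stats["recovered"] += 1
            if row.upd_parent == ev.parent:
                stats["parent_correct"] += 1

    normal = cohort.loc[
        [
            (r.family, r.chrom) not in event_pairs
            and r.family not in consang_families
            for r in cohort.itertuples(index=False)
        ]
    ]
    false_candidates = normal.loc[normal["upd_call"] != "none"]
    flagged = set(
        cohort.loc[cohort["consanguinity_flag"], "family"].unique()
    )
    return {
        "per_event": per_event,
        "n_normal_pairs": int(len(normal)),
        "n_false_candidates": int(len(false_candidates)),
        "false_candidate_rate": (
            len(false_candidates) / len(normal) if len(normal) else 0.0
        ),
        "consanguine_families": sorted(consang_families),
        "consanguine_flagged": sorted(consang_families & flagged),
        "all_consanguine_flagged": consang_families <= flagged,
    }
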
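"""VCF ingestion, site filters, and family-wise site joining.

Variant observations are normalized into flat tables keyed by
(chrom, pos, ref, alt) after decomposition of multi-allelic records and
chr-prefix normalization. A child variant absent from a sequenced parent's
VCF is treated as not carried by that parent: exome VCFs emit variant sites
only, so absence is the operative "does not carry" signal. Coverage dropouts
are mitigated by the min-depth filter on the child.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .config import FilterConfig
from .errors import CohortIntegrityError, SampleNotFoundError, VcfParseError
from .genome import CHROM_ORDER, normalize_chrom

log = logging.getLogger(__name__)

# genotype classes
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GT_CLASSES = (HOM_REF, HET, HOM_ALT, MISSING)

# parent carrier statuses
CARRIES = "carries"
DOES_NOT_CARRY = "does_not_carry"
UNKNOWN = "unknown"
PARENT_STATUSES = (CARRIES, DOES_NOT_CARRY, UNKNOWN)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "gt", "depth", "alt_fraction"]
JOINED_COLUMNS = SITE_COLUMNS + ["mother_status", "father_status"]


@dataclass(frozen=True)
class VariantSite:
    """One normalized variant observation for one individual."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt: str
    depth: int
    alt_fraction: float  # NaN when depth is 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.gt not in GT_CLASSES:
            raise ValueError(f"invalid genotype class {self.gt!r}")
        af = self.alt_fraction
        if af == af and not 0.0 <= af <= 1.0:  # af == af filters NaN
            raise ValueError(f"alt_fraction out of [0,1]: {af}")


SETUPS = ("single", "duo_mother", "duo_father", "trio")


@dataclass(frozen=True)
class Pedigree:
    """Family membership; the setup is derived from which parents exist."""

    child_id: str
    mother_id: str | None = None
    father_id: str | None = None

    @property
    def setup(self) -> str:
        if self.mother_id and self.father_id:
            return "trio"
        if self.mother_id:
            return "duo_mother"
        if self.father_id:
            return "duo_father"
        return "single"


@dataclass
class SiteTable:
    """Joined child/parent observations, one row per retained child site."""

    frame: pd.DataFrame
    pedigree: Pedigree

    def __post_init__(self) -> None:
        for col in JOINED_COLUMNS:
            if col not in self.frame.columns:
                raise ValueError(f"SiteTable frame missing column {col!r}")

    def to_tsv(self, path: str | Path, provenance: str | None = None) -> None:
        path = Path(path)
        ped = self.pedigree
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write(
                f"# pedigree child={ped.child_id}"
                f" mother={ped.mother_id or '.'}"
                f" father={ped.father_id or '.'}\n"
            )
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteTable":
        path = Path(path)
        ped = Pedigree(child_id="unknown")
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                if line.startswith("# pedigree"):
                    fields = dict(
                        kv.split("=", 1) for kv in line[2:].split()[1:]
                    )
                    ped = Pedigree(
                        child_id=fields.get("child", "unknown"),
                        mother_id=None if fields.get("mother") in (None, ".") else fields["mother"],
                        father_id=None if fields.get("father") in (None, ".") else fields["father"],
                    )
                pos = fh.tell()
            frame = pd.read_csv(
                fh, sep="\t", dtype={"chrom": str, "ref": str, "alt": str}
            )
        return cls(frame=frame, pedigree=ped)


def sites_to_frame(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Flatten VariantSites into the canonical column layout."""
    rows = [
        (s.chrom, s.pos, s.ref, s.alt, s.gt, s.depth, s.alt_fraction)
        for s in sites
    ]
    frame = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if frame.empty:
        frame = frame.astype(
            {"pos": np.int64, "depth": np.int64, "alt_fraction": float}
        )
    return frame


def frame_to_sites(frame: pd.DataFrame) -> list[VariantSite]:
    return [
        VariantSite(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            gt=str(r.gt), depth=int(r.depth), alt_fraction=float(r.alt_fraction),
        )
        for r in frame.itertuples(index=False)
    ]


def _classify_gt(alleles: tuple, allele_number: int) -> str:
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return MISSING
    count = sum(1 for a in alleles if a == allele_number)
    if count == len(alleles):
        return HOM_ALT
    if count > 0:
        return HET
    return HOM_REF


def read_vcf(path: str | Path, sample: str | None = None) -> list[VariantSite]:
    """Read one sample of a VCF into decomposed, normalized variant sites.

    Multi-allelic records are decomposed into one site per alt allele, each
    with ``alt_fraction = AD[alt] / sum(AD)`` and ``depth = sum(AD)``.
    Records with missing GT are retained with ``gt='missing'``. Symbolic and
    spanning-deletion alts are skipped.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if sample is None:
        if len(samples) != 1:
            raise SampleNotFoundError(
                f"{path}: VCF has {len(samples)} samples; specify one of {samples}"
            )
        sample = samples[0]
    elif sample not in samples:
        raise SampleNotFoundError(
            f"{path}: sample {sample!r} not found (available: {samples})"
        )

    sites: list[VariantSite] = []
    try:
        for rec in vcf:
            if not rec.alts:
                continue
            call = rec.samples[sample]
            alleles = call.get("GT")
            ad = call.get("AD")
            if ad is not None and any(x is None for x in ad):
                ad = None
            depth = int(sum(ad)) if ad is not None else int(call.get("DP") or 0)
            chrom = normalize_chrom(rec.chrom)
            for i, alt in enumerate(rec.alts):
                if alt is None or alt.startswith("<") or alt == "*":
                    continue
                if ad is not None and depth > 0 and len(ad) > i + 1:
                    af = float(ad[i + 1]) / depth
                else:
                    af = float("nan")
                sites.append(
                    VariantSite(
                        chrom=chrom,
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        gt=_classify_gt(alleles, i + 1),
                        depth=depth,
                        alt_fraction=af,
                    )
                )
    except (OSError, ValueError) as exc:
        raise VcfParseError(
            f"malformed VCF record in {path} near line for {exc}"
        ) from exc
    finally:
        vcf.close()
    return sites


def read_vcf_frame(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    return sites_to_frame(read_vcf(path, sample))


def filter_mask(frame: pd.DataFrame, cfg: FilterConfig) -> np.ndarray:
    """Boolean mask of sites passing depth and allele-fraction criteria."""
    gt = frame["gt"].to_numpy()
    depth = frame["depth"].to_numpy()
    af = frame["alt_fraction"].to_numpy(dtype=float)

    keep = depth >= cfg.min_depth
    with np.errstate(invalid="ignore"):
        is_het = gt == HET
        is_hom_alt = gt == HOM_ALT
        keep &= np.where(
            is_het, (af >= cfg.het_af_min) & (af <= cfg.het_af_max), True
        )
        keep &= np.where(is_hom_alt, af >= cfg.hom_alt_af_min, True)
    if cfg.drop_missing:
        keep &= gt != MISSING
    return keep


def apply_site_filters(
    sites: Sequence[VariantSite] | pd.DataFrame, cfg: FilterConfig
) -> list[VariantSite] | pd.DataFrame:
    """Drop sites failing depth/allele-fraction criteria; logs removals."""
    as_frame = isinstance(sites, pd.DataFrame)
    frame = sites if as_frame else sites_to_frame(sites)
    if frame.empty:
        return frame if as_frame else []
    keep = filter_mask(frame, cfg)
    removed = frame.loc[~keep]
    if len(removed):
        per_chrom = removed.groupby("chrom").size()
        for chrom, n in per_chrom.items():
            log.info("filters removed %d sites on chromosome %s", n, chrom)
    out = frame.loc[keep].reset_index(drop=True)
    return out if as_frame else frame_to_sites(out)


def _parent_status_columns(
    child: pd.DataFrame, parent: pd.DataFrame | None, present: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Return (status, ref_mismatch) arrays aligned to the child frame."""
    n = len(child)
    if not present:
        return np.full(n, UNKNOWN, dtype=object), np.zeros(n, dtype=bool)
    assert parent is not None
    carried = parent.loc[
        parent["gt"].isin([HET, HOM_ALT]), ["chrom", "pos", "ref", "alt"]
    ].drop_duplicates()
    hit = child.merge(
        carried.assign(_hit=True), on=["chrom", "pos", "ref", "alt"], how="left"
    )["_hit"].notna().to_numpy()
    status = np.where(hit, CARRIES, DOES_NOT_CARRY).astype(object)

    # a parent record at the same chrom/pos with a different REF is suspect
    refs = parent[["chrom", "pos", "ref"]].drop_duplicates(["chrom", "pos"])
    merged = child.merge(
        refs.rename(columns={"ref": "_parent_ref"}), on=["chrom", "pos"], how="left"
    )
    mismatch = (
        merged["_parent_ref"].notna() & (merged["_parent_ref"] != merged["ref"])
    ).to_numpy(dtype=bool)
    return status, mismatch


def join_family(
    child: Sequence[VariantSite] | pd.DataFrame,
    mother: Sequence[VariantSite] | pd.DataFrame | None,
    father: Sequence[VariantSite] | pd.DataFrame | None,
    pedigree: Pedigree,
) -> SiteTable:
    """Join parent carrier status onto each child site.

    A parent status is 'unknown' only when that parent is absent from the
    pedigree; otherwise absence of the exact (chrom, pos, ref, alt) key from
    the parent's table yields 'does_not_carry'. Child sites whose REF
    disagrees with a parent record at the same position are dropped with a
    warning.
    """
    cf = child if isinstance(child, pd.DataFrame) else sites_to_frame(child)
    cf = cf.sort_values(["chrom", "pos", "ref", "alt"], kind="stable").reset_index(
        drop=True
    )
    mf = (
        mother
        if (mother is None or isinstance(mother, pd.DataFrame))
        else sites_to_frame(mother)
    )
    ff = (
        father
        if (father is None or isinstance(father, pd.DataFrame))
        else sites_to_frame(father)
    )

    m_status, m_bad = _parent_status_columns(
        cf, mf, pedigree.mother_id is not None
    )
    f_status, f_bad = _parent_status_columns(
        cf, ff, pedigree.father_id is not None
    )
    bad = m_bad | f_bad
    if bad.any():
        log.warning(
            "dropping %d child sites with inconsistent reference alleles",
            int(bad.sum()),
        )
    out = cf.copy()
    out["mother_status"] = m_status
    out["father_status"] = f_status
    out = out.loc[~bad].reset_index(drop=True)
    return SiteTable(frame=out, pedigree=pedigree)


MANIFEST_COLUMNS = ["sample_id", "role", "family_id", "path"]
ROLES = ("child", "mother", "father")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV; relative paths resolve next to it."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortIntegrityError(f"manifest {path} missing columns {missing}")
    if frame.empty:
        raise CohortIntegrityError(f"manifest {path} has no rows")
    bad_roles = sorted(set(frame["role"]) - set(ROLES))
    if bad_roles:
        raise CohortIntegrityError(f"manifest {path} has invalid roles {bad_roles}")
    frame["path"] = [
        str(p if Path(p).is_absolute() else path.parent / p) for p in frame["path"]
    ]
    dup = frame.duplicated(["family_id", "role"])
    if dup.any():
        raise CohortIntegrityError(
            f"manifest {path}: duplicate (family_id, role) rows"
        )
    return frame


@dataclass
class FamilyFiles:
    family_id: str
    pedigree: Pedigree
    paths: dict = field(default_factory=dict)  # role -> vcf path


def families_from_manifest(manifest: pd.DataFrame) -> list[FamilyFiles]:
    families: list[FamilyFiles] = []
    for family_id, grp in manifest.groupby("family_id", sort=True):
        by_role = {r.role: r for r in grp.itertuples(index=False)}
        if "child" not in by_role:
            raise CohortIntegrityError(f"family {family_id} lacks a child row")
        ped = Pedigree(
            child_id=by_role["child"].sample_id,
            mother_id=by_role["mother"].sample_id if "mother" in by_role else None,
            father_id=by_role["father"].sample_id if "father" in by_role else None,
        )
        families.append(
            FamilyFiles(
                family_id=str(family_id),
                pedigree=ped,
                paths={role: by_role[role].path for role in by_role},
            )
        )
    return families


def sort_key(chrom: pd.Series) -> pd.Series:
    """Sortable integer key for canonical chromosome names."""
    return chrom.map(lambda c: CHROM_ORDER.get(str(c), 99))
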
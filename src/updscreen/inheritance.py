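"""Parental-origin classification and inheritance ratios.

The inheritance ratio (IR) is a symmetric imbalance statistic between variants
attributable exclusively to the mother vs. exclusively to the father:
``ir = (max(m, p) + pseudocount) / (min(m, p) + pseudocount)``. A biparental
background gives IR near 1; a heterodisomy starves one side of the count and
drives IR far above the setup-specific cutoff. The plotting companion is
``relative_ir = m / (m + p)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import IRParams
from .vcf_io import CARRIES, DOES_NOT_CARRY, HET, HOM_ALT, UNKNOWN

MATERNAL_ONLY = "maternal_only"
PATERNAL_ONLY = "paternal_only"
BIPARENTAL = "biparental"
NEITHER = "neither"
ORIGIN_UNKNOWN = "unknown"
ORIGINS = (MATERNAL_ONLY, PATERNAL_ONLY, BIPARENTAL, NEITHER, ORIGIN_UNKNOWN)

MATERNAL = "maternal"
PATERNAL = "paternal"
NO_DIRECTION = "none"


def classify_origin(
    child_gt: str, mother_status: str, father_status: str
) -> str | None:
    """Deterministic parental-origin truth table for one joined site.

    Returns None (site skipped) when the child genotype is not an alt call.
    In duo setups the sequenced parent's carrier status decides: carried
    variants go to that parent, everything else is pooled onto the missing
    parent (de novos and artifacts included).
    """
    if child_gt not in (HET, HOM_ALT):
        return None
    m, f = mother_status, father_status
    if m == UNKNOWN and f == UNKNOWN:
        return ORIGIN_UNKNOWN
    if m == UNKNOWN:  # duo with father sequenced
        return PATERNAL_ONLY if f == CARRIES else MATERNAL_ONLY
    if f == UNKNOWN:  # duo with mother sequenced
        return MATERNAL_ONLY if m == CARRIES else PATERNAL_ONLY
    if m == CARRIES and f == CARRIES:
        return BIPARENTAL
    if m == CARRIES:
        return MATERNAL_ONLY
    if f == CARRIES:
        return PATERNAL_ONLY
    return NEITHER


def classify_origin_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized origin column for a joined site frame."""
    gt = frame["gt"].to_numpy(dtype=object)
    m = frame["mother_status"].to_numpy(dtype=object)
    f = frame["father_status"].to_numpy(dtype=object)
    informative = (gt == HET) | (gt == HOM_ALT)
    mc, fc = m == CARRIES, f == CARRIES
    mu, fu = m == UNKNOWN, f == UNKNOWN

    origin = np.select(
        [
            ~informative,
            mu & fu,
            mu & fc,
            mu & ~fc,
            fu & mc,
            fu & ~mc,
            mc & fc,
            mc,
            fc,
        ],
        [
            None,
            ORIGIN_UNKNOWN,
            PATERNAL_ONLY,
            MATERNAL_ONLY,
            MATERNAL_ONLY,
            PATERNAL_ONLY,
            BIPARENTAL,
            MATERNAL_ONLY,
            PATERNAL_ONLY,
        ],
        default=NEITHER,
    )
    out = frame.copy()
    out["origin"] = origin
    return out


def count_origins(frame: pd.DataFrame) -> dict[str, int]:
    """Origin-class counts over a (already origin-classified) frame."""
    counts = frame["origin"].value_counts()
    return {o: int(counts.get(o, 0)) for o in ORIGINS}


def inheritance_ratio(
    maternal_only: int,
    paternal_only: int,
    pseudocount: float = 1.0,
    min_informative: int = 10,
) -> tuple[float | None, str]:
    """Symmetric IR and its direction.

    Returns (None, 'none') when too few exclusively-parental sites are
    available (the chromosome is uninformative rather than 'low').
    """
    m, p = int(maternal_only), int(paternal_only)
    if m < 0 or p < 0:
        raise ValueError("origin counts must be non-negative")
    if m + p < min_informative:
        return None, NO_DIRECTION
    ir = (max(m, p) + pseudocount) / (min(m, p) + pseudocount)
    if m > p:
        direction = MATERNAL
    elif p > m:
        direction = PATERNAL
    else:
        direction = NO_DIRECTION
    return float(ir), direction


def relative_ir(maternal_only: int, paternal_only: int) -> float | None:
    """Fraction of maternal over maternal + paternal exclusive variants."""
    m, p = int(maternal_only), int(paternal_only)
    if m < 0 or p < 0:
        raise ValueError("origin counts must be non-negative")
    if m + p == 0:
        return None
    return m / (m + p)


def params_ir(
    maternal_only: int, paternal_only: int, params: IRParams
) -> tuple[float | None, str]:
    return inheritance_ratio(
        maternal_only,
        paternal_only,
        pseudocount=params.pseudocount,
        min_informative=params.min_informative,
    )
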
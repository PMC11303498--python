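"""Genome builds: autosome lengths and chromosome-name normalization.

Only the 22 autosomes participate in screening; X and Y are parsed but
excluded by default because hemizygosity mimics runs of homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Ordering index for canonical chromosome names (autosomes first, then X, Y).
CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(AUTOSOMES + ("X", "Y"))}

_GRCH38_LENGTHS = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468,
}

_GRCH37_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}


def normalize_chrom(name: str) -> str:
    """Map 'chr1'/'1' style names onto the canonical '1'..'22','X','Y'."""
    c = str(name).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "MT":
        c = "M"
    return c


@dataclass(frozen=True)
class GenomeBuild:
    """Autosome lengths (bp) and optional centromere intervals for one build.

    ``centromeres`` maps chromosome -> (start, end), 1-based inclusive; it is
    optional and only used for annotating ROH location classes.
    """

    name: str
    autosome_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in AUTOSOMES if c not in self.autosome_lengths]
        if missing:
            raise ConfigurationError(
                f"genome build {self.name!r} lacks autosomes: {missing}"
            )
        bad = [c for c, n in self.autosome_lengths.items() if n <= 0]
        if bad:
            raise ConfigurationError(
                f"genome build {self.name!r} has non-positive lengths for: {bad}"
            )

    def length(self, chrom: str) -> int:
        try:
            return self.autosome_lengths[normalize_chrom(chrom)]
        except KeyError:
            raise ConfigurationError(
                f"chromosome {chrom!r} not in build {self.name!r}"
            ) from None

    @property
    def total_autosome_bp(self) -> int:
        return sum(self.autosome_lengths[c] for c in AUTOSOMES)


GRCH38 = GenomeBuild("GRCh38", _GRCH38_LENGTHS)
GRCH37 = GenomeBuild("GRCh37", _GRCH37_LENGTHS)

_BUILDS = {"GRCh38": GRCH38, "GRCh37": GRCH37, "hg38": GRCH38, "hg19": GRCH37}


def get_build(name: str) -> GenomeBuild:
    try:
        return _BUILDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown genome build {name!r}; choose from {sorted(set(_BUILDS))}"
        ) from None
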
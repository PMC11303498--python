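"""Configuration dataclasses and YAML round-trip.

Every tunable that affects calls lives here so a single config hash pins an
analysis. Threshold defaults are the published screening cutoffs; filter and
ROH-caller defaults are this implementation's documented choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class FilterConfig:
    """Site-quality filters applied to the proband's variant table.

    The het allele-fraction band doubles as the artifact filter: recurrent
    caller artifacts cluster around alt fraction 0.2 on every chromosome and
    fall below ``het_af_min``.
    """

    min_depth: int = 10
    het_af_min: float = 0.25
    het_af_max: float = 0.75
    hom_alt_af_min: float = 0.85
    drop_missing: bool = True


@dataclass
class RohParams:
    """Rule-based ROH scanner parameters (exome-sparse defaults)."""

    min_sites: int = 15
    max_het_interruptions: int = 1
    max_gap_bp: int = 3_000_000
    terminal_margin_bp: int = 2_000_000
    #: "chromosome" divides by the build length; "span" by first-to-last site.
    denominator: str = "chromosome"


@dataclass
class IRParams:
    pseudocount: float = 1.0
    min_informative: int = 10


@dataclass
class TagThresholds:
    """Published tagging cutoffs.

    roh fraction f: f < roh_low_max -> low; roh_low_max <= f <= roh_high_min
    -> high_mixed; f > roh_high_min -> high. IR is 'high' strictly above the
    setup-specific cutoff.
    """

    roh_low_max: float = 0.2
    roh_high_min: float = 0.7
    ir_duo: float = 2.0
    ir_trio: float = 5.0
    #: fewer usable child sites than this on a chromosome -> uninformative.
    min_informative_sites: int = 10


@dataclass
class ConsanguinityRule:
    """Heuristic sample-level consanguinity flag.

    Flag when >= ``min_affected_autosomes`` autosomes are in the elevated ROH
    bands, or when the genome-wide ROH fraction exceeds
    ``genome_roh_fraction``. With ``exclude_top_chromosome`` the genome-wide
    fraction is computed after removing the single largest contributor, so one
    whole-chromosome isodisomy can never trigger the flag by itself.
    """

    min_affected_autosomes: int = 3
    genome_roh_fraction: float = 0.05
    exclude_top_chromosome: bool = True


@dataclass
class PlotConfig:
    """Colors are Okabe-Ito (color-blind safe)."""

    origin_colors: dict = field(
        default_factory=lambda: {
            "maternal_only": "#CC79A7",
            "paternal_only": "#0072B2",
            "biparental": "#999999",
            "neither": "#E69F00",
            "unknown": "#555555",
        }
    )
    format: str = "png"
    dpi: int = 150


@dataclass
class AnalysisConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    roh: RohParams = field(default_factory=RohParams)
    inheritance: IRParams = field(default_factory=IRParams)
    thresholds: TagThresholds = field(default_factory=TagThresholds)
    consanguinity: ConsanguinityRule = field(default_factory=ConsanguinityRule)
    plot: PlotConfig = field(default_factory=PlotConfig)
    genome_build: str = "GRCh38"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        sections = {
            "filters": FilterConfig,
            "roh": RohParams,
            "inheritance": IRParams,
            "thresholds": TagThresholds,
            "consanguinity": ConsanguinityRule,
            "plot": PlotConfig,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key == "genome_build":
                kwargs[key] = str(value)
            elif key in sections:
                klass = sections[key]
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value) - known
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in config section {key!r}: {sorted(unknown)}"
                    )
                kwargs[key] = klass(**value)
            elif key == "simulate":
                # simulator settings are parsed by the simulate module
                continue
            else:
                raise ConfigurationError(f"unknown config section {key!r}")
        return cls(**kwargs)
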
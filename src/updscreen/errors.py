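"""Exception hierarchy for updscreen."""


class UpdScreenError(Exception):
    """Base class for all updscreen errors."""


class ConfigurationError(UpdScreenError):
    """Invalid configuration value or missing resource referenced by config."""


class VcfParseError(UpdScreenError):
    """A VCF record or header could not be parsed."""


class SampleNotFoundError(ConfigurationError):
    """The requested sample id is not present in the VCF."""


class CohortIntegrityError(UpdScreenError):
    """A cohort table violates structural invariants (e.g. duplicate rows)."""
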
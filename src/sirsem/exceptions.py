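"""Exception hierarchy used across the package."""


class SirsemError(Exception):
    """Base class for all package errors."""


class InputError(SirsemError):
    """Malformed user input (unknown trait, bad coefficient map, bad file)."""


class StructuralIdentifiabilityError(SirsemError):
    """The declared causal structure cannot identify the model (e.g. a cycle)."""


class PedigreeError(SirsemError):
    """Inconsistent pedigree (ancestry cycle, impossible parentage)."""


class NumericalError(SirsemError):
    """A numerical failure that signals inconsistent inputs (non-PD matrix etc.)."""


class ConfigError(SirsemError):
    """Invalid or contradictory run configuration."""
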
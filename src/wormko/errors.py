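"""Exception hierarchy shared across the toolkit."""


class WormkoError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(WormkoError):
    """Invalid parameter, scenario, or fixture configuration."""


class OutOfRangeError(WormkoError):
    """A coordinate falls outside the span it must map into."""


class NoDeletionFoundError(WormkoError):
    """A product sequence cannot be explained as a deletion of the amplicon."""


class AssemblyError(WormkoError):
    """Sequencing reads fail to overlap or to anchor on the amplicon."""


class LowQualityError(WormkoError):
    """Read merge exceeded the allowed mismatch rate."""


class DataError(WormkoError):
    """Input tables violate their declared structure (subsets, chromosomes...)."""
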
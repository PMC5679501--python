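"""Exception hierarchy shared across the package."""


class MirpairError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirpairError):
    """A tabular input file is malformed (e.g. a required column is absent)."""


class IntegrityError(MirpairError):
    """Input data violate an integrity constraint (duplicates, invalid Ct)."""


class ConfigurationError(MirpairError):
    """A configuration value is inconsistent or references missing entities."""


class InsufficientDataError(MirpairError):
    """Too few observations to carry out the requested computation."""
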
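"""Exception hierarchy."""


class RhodosimError(Exception):
    """Base class for all package errors."""


class ParseError(RhodosimError):
    """Malformed input file (PDB, XYZ, force-field text)."""


class UsageError(RhodosimError):
    """A caller violated an operation precondition."""


class BuildError(RhodosimError):
    """Model construction failed (e.g. residue without a Cα)."""


class ConfigurationError(RhodosimError):
    """A required parameter-table or config key is missing or invalid."""


class EvaluationError(RhodosimError):
    """Energy/force evaluation hit a degenerate geometry."""


class IntegrationError(RhodosimError):
    """The integrator produced non-finite forces or coordinates."""
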
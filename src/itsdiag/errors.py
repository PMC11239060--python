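"""Exception hierarchy for itsdiag."""


class ItsdiagError(Exception):
    """Base class for all itsdiag errors."""


class InputError(ItsdiagError):
    """Malformed or inconsistent user input (bad characters, unknown samples...)."""


class AlignmentError(ItsdiagError):
    """Rows of an alignment disagree in length."""


class AnchorNotFoundError(ItsdiagError):
    """No window of a sequence is compatible with the ITS start motif."""


class CoordinateError(ItsdiagError):
    """A local coordinate is undefined (gap column, or column before the anchor)."""


class ConfigError(ItsdiagError):
    """An infeasible or inconsistent simulation/pipeline configuration."""
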
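"""Exception hierarchy.

All naspatial errors derive from :class:`NaspatialError` so callers can
catch the package's failures with one clause.  The subclasses mirror the
kinds of contract violation that occur in areal analyses: malformed input
tables or graphs, parameters outside their domain, and internal contract
breaches (e.g. requesting an improper prior where a proper one is required).
"""


class NaspatialError(Exception):
    """Base class for all errors raised by naspatial."""


class InputError(NaspatialError, ValueError):
    """Malformed or inconsistent input data (tables, edge lists, orderings)."""


class ParameterError(NaspatialError, ValueError):
    """A numeric parameter outside its admissible domain."""


class ContractError(NaspatialError, RuntimeError):
    """An internal contract violated (e.g. improper prior where proper required)."""


class ConfigError(NaspatialError, ValueError):
    """Invalid run or generator configuration."""
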
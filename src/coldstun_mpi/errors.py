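"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`MPIError`,
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class MPIError(Exception):
    """Base class for all errors raised by coldstun_mpi."""


class DomainError(MPIError, ValueError):
    """An input value is outside its physically meaningful range."""


class ConfigurationError(MPIError):
    """A coefficient set, band table or run configuration is unusable."""


class UnknownAnalyteError(MPIError, KeyError):
    """An analyte name is not present in the scoring table consulted."""


class ScoringError(MPIError):
    """A panel cannot be scored for the requested index.

    The message names the missing analyte.
    """


class CohortError(MPIError, ValueError):
    """A scored cohort or cohort specification violates its invariants."""


class PanelCSVError(MPIError, ValueError):
    """A panel CSV file is malformed; the message names row and column."""
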
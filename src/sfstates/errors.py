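"""Exception hierarchy for sfstates.

All package errors derive from :class:`SFStatesError` so callers can catch one
base class. Errors that indicate bad user input (files, selections, mappings)
are distinguished from bad arguments so the CLI can map them to distinct exit
codes (2 for argument errors, 3 for input errors).
"""


class SFStatesError(Exception):
    """Base class for all sfstates errors."""


class ArgumentError(SFStatesError, ValueError):
    """An argument violates an operation's contract (CLI exit code 2)."""


class InputError(SFStatesError):
    """A problem with user-supplied input data (CLI exit code 3)."""


class ParseError(InputError):
    """A structure or trajectory file could not be parsed."""


class AtomCountMismatchError(InputError):
    """Topology and trajectory disagree on the number of atoms."""

    def __init__(self, topology_count: int, trajectory_count: int):
        self.topology_count = topology_count
        self.trajectory_count = trajectory_count
        super().__init__(
            f"atom count mismatch: topology has {topology_count} atoms, "
            f"trajectory has {trajectory_count}"
        )


class ResolutionError(InputError):
    """A (residue, atom, subunit) reference could not be resolved."""


class MappingError(InputError):
    """A residue correspondence between two structures is invalid."""


class ConfigurationError(SFStatesError):
    """The analysis configuration is incomplete or inconsistent."""


class SpecificationError(ArgumentError):
    """A synthetic-ensemble specification is internally inconsistent."""


class TopologyWarning(UserWarning):
    """The structure does not look like a four-subunit channel pore."""
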
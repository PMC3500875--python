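"""Exception hierarchy shared by all dynpath modules.

Everything user-facing derives from :class:`DynpathError` so the CLI can map
any contract violation to a single exit code.
"""


class DynpathError(Exception):
    """Base class for all dynpath errors."""


class ValidationError(DynpathError, ValueError):
    """Input data or configuration violates a documented contract."""


class NodeLookupError(DynpathError, KeyError):
    """A node reference does not resolve to a known process."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return ValueError.__str__(self)


class UnsupportedConfigurationError(DynpathError):
    """The operation is defined only for a restricted model configuration."""


class UnsupportedStructureError(DynpathError):
    """The graph structure (e.g. a cycle) is outside the operation's domain."""


class NoPathError(DynpathError):
    """No directed path exists between the requested nodes."""


class EmptyFitError(DynpathError):
    """No usable observations (no events / no fittable time points)."""


class SizeGuardError(DynpathError):
    """Exhaustive reference computation refused on a too-large input."""
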
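"""Exception hierarchy shared across the package."""


class CommphyloError(Exception):
    """Base class for all package errors."""


class ValidationError(CommphyloError, ValueError):
    """An input object violates one of its documented invariants."""


class NewickParseError(CommphyloError, ValueError):
    """Malformed Newick/NEXUS input."""


class AssemblyError(CommphyloError, RuntimeError):
    """A community-assembly simulation could not satisfy its constraints."""


class PreflightError(CommphyloError, ValueError):
    """Consolidated cross-input consistency failures, raised before any computation."""
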
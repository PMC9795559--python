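"""Exception hierarchy for bilayerlab.

All errors derive from :class:`BilayerlabError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad file contents, bad topologies, bad numeric inputs, and degenerate
geometry.
"""


class BilayerlabError(Exception):
    """Base class for all bilayerlab errors."""


class FormatError(BilayerlabError):
    """A file could not be parsed, or parsed parts disagree (e.g. atom counts)."""


class UnsupportedGeometryError(BilayerlabError):
    """The simulation box is not orthorhombic."""


class TopologyError(BilayerlabError):
    """The topology violates an invariant (missing anchor, bad electron count, ...)."""


class DomainError(BilayerlabError, ValueError):
    """A numeric argument is outside the operation's domain."""


class DegenerateGeometryError(BilayerlabError):
    """A geometric quantity is undefined (zero-length bond vector, flat bilayer)."""


class NormalizationError(BilayerlabError):
    """A normalization constant is zero (e.g. no form-factor peak in the window)."""
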
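"""Exception hierarchy for cernaforge.

All exceptions derive from :class:`CernaForgeError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
malformed files, incompatible inputs and invalid configuration.
"""


class CernaForgeError(Exception):
    """Base class for all cernaforge errors."""


class FormatError(CernaForgeError, ValueError):
    """A file or table violates the expected dialect (duplicates, bad cells)."""


class AlignmentError(CernaForgeError, ValueError):
    """Sample alignment across layers is impossible (empty intersection)."""


class ExportError(CernaForgeError, ValueError):
    """A network export was requested for an empty or inconsistent network."""


class ConfigurationError(CernaForgeError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(CernaForgeError, ValueError):
    """Operation inputs violate a precondition (sizes, domains, overlap)."""
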
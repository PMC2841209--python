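"""Exception and warning hierarchy.

All domain failures derive from :class:`MitoprofileError` so the CLI can map
them to a single exit code, distinct from usage errors.
"""


class MitoprofileError(Exception):
    """Base class for every domain error raised by this package."""


class VariantParseError(MitoprofileError, ValueError):
    """A variant token does not match the rCRS-difference grammar."""


class DuplicateKeyError(MitoprofileError, ValueError):
    """Two variant calls share the same (position, insertion_index) key."""


class ReportFormatError(MitoprofileError, ValueError):
    """A mutation-report file is malformed (bad extension, line, or ID)."""


class ComparisonError(MitoprofileError, ValueError):
    """Profiles cannot be compared (e.g. sample-ID mismatch)."""


class StoreError(MitoprofileError, RuntimeError):
    """Persistence-layer failure (duplicate project, unknown sample, ...)."""


class AccessDeniedError(StoreError):
    """The acting user's role does not permit the requested operation."""


class ExportError(MitoprofileError, ValueError):
    """An export cannot be produced for the requested project state."""


class PhantomVariantWarning(UserWarning):
    """A variant call whose observed base equals the reference base.

    Such calls are suspect (possible transcription or encoding artefact)
    but are still applied verbatim.
    """


class ExportWarning(UserWarning):
    """Non-fatal export condition (excluded variant, long insertion run...)."""
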
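"""Exception hierarchy shared across the package.

All errors derive from :class:`CeusKitError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs rather than internal faults.
"""


class CeusKitError(Exception):
    """Base class for all ceuskit errors."""


class InvalidSpecError(CeusKitError, ValueError):
    """A generator or cohort specification violates its invariants."""


class EmptyInputError(CeusKitError, ValueError):
    """An operation that needs at least one sample received none."""


class InvalidInputError(CeusKitError, ValueError):
    """Arguments are structurally valid Python but violate a precondition."""


class CorruptStreamError(CeusKitError, ValueError):
    """A compressed stream cannot be decoded.

    ``category`` names the defect: ``truncated``, ``bad-block-type``,
    ``oversubscribed-code``, ``incomplete-code``, ``bad-distance``,
    ``bad-stored-length``, ``crc-mismatch``, ``malformed-pair``.
    """

    def __init__(self, message: str, category: str = "corrupt"):
        super().__init__(message)
        self.category = category


class ReconstructionError(CeusKitError, ValueError):
    """Exact reconstruction is impossible (e.g. overflow of declared width)."""


class UndefinedMetricError(CeusKitError, ValueError):
    """A metric's denominator is zero (all-zero signal, zero variance...)."""


class FlatCurveError(CeusKitError, ValueError):
    """A time-intensity curve shows no enhancement above baseline."""


class FormatError(CeusKitError, ValueError):
    """A file does not conform to the expected on-disk format.

    ``offset`` is the byte offset at which the defect was detected, when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset
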
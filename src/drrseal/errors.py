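"""Exception hierarchy for drrseal.

All package-specific failures derive from :class:`DRRSealError` so callers
can catch one type at the tool boundary.  The verification pipeline never
lets these escape: it converts them into FAIL reports with a reason.
"""


class DRRSealError(Exception):
    """Base class for every drrseal-specific error."""


class EmptySeriesError(DRRSealError):
    """No parseable DICOM file was found in the series directory."""


class SeriesParseError(DRRSealError):
    """A file looked like DICOM but could not be parsed; names the file."""


class UnsortableSeriesError(DRRSealError):
    """Neither Slice Location nor Instance Number is uniformly available."""


class GeometryMismatchError(DRRSealError):
    """Slices disagree on rows/columns/pixel spacing, or spacing is not square."""


class DegenerateSeriesError(DRRSealError):
    """The series cannot span a volume (e.g. all slice locations equal)."""


class BlockGridError(DRRSealError):
    """DRR dimensions are not divisible by the block grid (padding disabled)."""


class SerializationError(DRRSealError):
    """A block byte stream is malformed or inconsistent with its header."""


class MalformedManifestError(DRRSealError):
    """A sealed manifest violates its structural invariants."""


class WrongKeyError(DRRSealError):
    """Decryption failed in a way consistent with a wrong passphrase or
    corrupted ciphertext (PKCS#7 padding failure or garbage block header)."""


class ShapeMismatchError(DRRSealError):
    """Two images or histograms being compared have incompatible shape,
    direction or bin range."""
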
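"""Exception hierarchy shared across the package."""


class FearleakError(Exception):
    """Base class for all package-specific errors."""


# --- I/O ---------------------------------------------------------------


class MissingColumn(FearleakError):
    """A required column is absent from an input frame table."""


class MalformedRow(FearleakError):
    """A data row contains a non-numeric cell in a numeric column."""


class EmptyTable(FearleakError):
    """The input table contains a header but no data rows."""


class MixedIdentity(FearleakError):
    """Clips with differing participant/condition/frame rate were merged."""


# --- features / episodes ----------------------------------------------


class OutOfRange(FearleakError):
    """A presence or intensity value lies outside its allowed range."""


class MissingChannel(FearleakError):
    """A frame record lacks one of the required AU channels."""


class EmptyClip(FearleakError):
    """An operation requiring frames received an empty clip."""


class NonPositiveRate(FearleakError):
    """Frame rate must be strictly positive."""


class EmptyEpisodeList(FearleakError):
    """Summary statistics require at least one episode."""


# --- synthesis ---------------------------------------------------------


class InvalidSpec(FearleakError):
    """A cohort specification violates its invariants."""


class OutOfBounds(FearleakError):
    """An injected episode does not fit within the series bounds."""


# --- symmetry ----------------------------------------------------------


class MissingLandmarks(FearleakError):
    """A clip lacks the landmark columns needed for distance signals."""


class LengthMismatch(FearleakError):
    """Two paired series/arrays have different lengths."""


class TooShort(FearleakError):
    """A series is too short for the wavelet transform."""


class EmptyMask(FearleakError):
    """A coherence map has no in-cone entries to average."""


# --- statistics --------------------------------------------------------


class TooFewPairs(FearleakError):
    """Paired tests need at least three pairs."""


class TooFewValues(FearleakError):
    """Independent-sample tests need at least two values per group."""


class DegenerateGroups(FearleakError):
    """All values identical across both groups; permutation undefined."""


# --- machine learning --------------------------------------------------


class TooFewMinority(FearleakError):
    """SMOTE requires more minority instances than neighbors."""


class ParticipantOverlap(FearleakError):
    """Train and test participant sets intersect."""


class SingleParticipant(FearleakError):
    """Leave-one-person-out needs at least two participants."""
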
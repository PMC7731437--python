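"""Exception hierarchy for quadratcover."""


class QuadratCoverError(Exception):
    """Base class for all quadratcover errors."""


class DegenerateBandError(QuadratCoverError):
    """A band has zero variance, so it cannot be standardized or normalized."""


class ImageFormatError(QuadratCoverError):
    """Input file is not an 8-bit 3-band RGB image."""


class SpectrumError(QuadratCoverError):
    """Spectrum is malformed or does not cover a required wavelength."""


class ValidationError(QuadratCoverError):
    """Cover/spectra validation cannot be performed (join or size problems)."""
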
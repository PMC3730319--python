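"""Exception hierarchy for the hypoxmet pipeline."""


class HypoxmetError(Exception):
    """Base class for all package-specific errors."""


class NotInPanelError(HypoxmetError, KeyError):
    """A metabolite was requested that is not part of the quantified panel."""


class ReferenceNotFoundError(HypoxmetError):
    """No qualifying reference peak in the search window."""


class DegenerateSpectrumError(HypoxmetError):
    """A spectrum whose normalization statistic is non-positive."""


class CoverageError(HypoxmetError):
    """Spectrum does not span the requested analysis window."""


class RankError(HypoxmetError):
    """Requested more principal components than the data rank supports."""


class UnpairedError(HypoxmetError):
    """Hypoxia/normoxia replicate pairing failed."""


class IllConditionedError(HypoxmetError):
    """Template overlap makes the targeted fit rank-deficient."""

    def __init__(self, pair, message=None):
        self.pair = tuple(pair)
        super().__init__(message or f"near-collinear templates: {pair[0]} vs {pair[1]}")


class ZeroMedianError(HypoxmetError):
    """A group median of zero makes the fold ratio undefined."""


class DegenerateSampleError(HypoxmetError):
    """A sample with no positive concentrations cannot be normalized."""


class WrongDesignError(HypoxmetError):
    """Sample layout does not match the expected study design."""


class DegenerateClassError(HypoxmetError):
    """A training class is empty or too small."""


class MalformedXMLError(HypoxmetError):
    """KGML input could not be parsed."""


class UnknownFormatError(HypoxmetError):
    """Unsupported graph export format."""


class ConfigError(HypoxmetError):
    """Invalid pipeline configuration."""
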
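"""Exception hierarchy shared across the pipeline."""


class PhotoscreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PhotoscreenError):
    """Malformed input table (bad columns, labels, or ordering)."""


class CoverageError(PhotoscreenError):
    """A spectrum does not cover the required wavelength band."""


class EmptyPlateError(PhotoscreenError):
    """A plate table contains no usable wells."""


class AssayError(PhotoscreenError):
    """Assay arithmetic is undefined (e.g. nonpositive blank mean)."""


class CurveError(PhotoscreenError):
    """A standard curve is unusable (zero slope, rank-deficient fit)."""


class FitError(PhotoscreenError):
    """A model fit could not be performed."""


class UndefinedMetricError(PhotoscreenError):
    """A spectral metric is undefined for this input (e.g. all-zero spectrum)."""


class FormulaError(PhotoscreenError):
    """A molecular formula could not be parsed or contains unsupported elements."""


class AdductError(PhotoscreenError):
    """Unknown adduct label."""


class InputError(PhotoscreenError):
    """Generic invalid argument (negative geometry, negative axis value...)."""
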
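"""Exception hierarchy shared across the package."""


class EEGTextureError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EEGTextureError, ValueError):
    """An argument violates an operation's precondition."""


class ParseError(EEGTextureError, ValueError):
    """A signal file contains a value that cannot be parsed."""

    def __init__(self, path, line_no, line):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}: non-numeric value on line {line_no}: {line!r}")


class FormatError(EEGTextureError, ValueError):
    """A signal file is structurally invalid (e.g. empty)."""


class ConfigurationError(EEGTextureError, ValueError):
    """A dataset layout or analysis configuration is unusable."""


class FeatureUndefinedError(EEGTextureError, ValueError):
    """A texture statistic is undefined for the given input (e.g. empty GLCM)."""


class TrainingError(EEGTextureError, ValueError):
    """Classifier training is impossible for the given labels/folds."""
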
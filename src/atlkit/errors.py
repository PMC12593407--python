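"""Exception hierarchy shared across the package."""


class AtlError(Exception):
    """Base class for all package errors."""


class ResolutionError(AtlError):
    """An identifier does not resolve in the reagent catalog."""

    def __init__(self, reagent_class: str, identifier: str):
        self.reagent_class = reagent_class
        self.identifier = identifier
        super().__init__(f"unknown {reagent_class} identifier: {identifier!r}")


class SchemaError(AtlError):
    """Inconsistent featurization layout (e.g. ragged descriptor vectors)."""


class DimensionError(AtlError):
    """Feature width does not match the width a model was trained on."""


class ValidationError(AtlError):
    """Malformed on-disk input or configuration."""


class TrainingError(AtlError):
    """Model training cannot proceed (e.g. empty training set)."""
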
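"""Exception hierarchy. All are ValueError subclasses so callers may catch broadly."""


class SpatbeatError(ValueError):
    """Base class for all spatbeat errors."""


class ParameterError(SpatbeatError):
    """A numeric parameter is out of its admissible range."""


class GeometryError(SpatbeatError):
    """A pixel region falls outside the frame or regions overlap."""


class ConfigurationError(SpatbeatError):
    """A scene/cohort/protocol configuration violates an invariant."""


class FormatError(SpatbeatError):
    """An on-disk artifact (CSV, YAML) does not match the expected dialect."""
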
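"""Exception hierarchy shared across the package."""


class TMHKitError(Exception):
    """Base class for all tmhkit errors."""


class InvalidSpecError(TMHKitError, ValueError):
    """A phantom specification violates its geometric or intensity invariants."""


class InvalidConfigError(TMHKitError, ValueError):
    """A network or training configuration violates its invariants."""


class InvalidArgumentError(TMHKitError, ValueError):
    """A scalar argument is outside its documented domain."""


class InputError(TMHKitError, ValueError):
    """An array input has the wrong shape, dtype, or value range."""


class NoTargetError(TMHKitError, ValueError):
    """A mask expected to contain foreground pixels is empty."""


class DegenerateFitError(TMHKitError, ValueError):
    """A geometric or statistical fit is underdetermined (e.g. a component
    thinner than 3 px, or a regression predictor with zero variance)."""


class MissingEdgeError(TMHKitError, ValueError):
    """A tear-meniscus measurement column has no meniscus pixels."""


class DataError(TMHKitError, ValueError):
    """A dataset is empty, unreadable, or inconsistent with its manifest."""
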
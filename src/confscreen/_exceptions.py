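"""Exception hierarchy for confscreen."""


class ConfscreenError(Exception):
    """Base class for all confscreen errors."""


class ParameterError(ConfscreenError, ValueError):
    """A configuration value is outside its allowed range."""


class InputError(ConfscreenError, ValueError):
    """Malformed data passed to an operation (shape, sign, length mismatch)."""


class FitError(ConfscreenError, RuntimeError):
    """The proper-training part of a split cannot support model fitting."""


class CalibrationError(ConfscreenError, RuntimeError):
    """A calibration set is empty or missing a class."""


class StratificationError(ConfscreenError, RuntimeError):
    """The initial screen drew no compounds of one class.

    The random 20% draw is what keeps the data exchangeable, so the fix is
    a larger library (or, accepting a broken validity guarantee, the
    stratified initial-split option).
    """
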
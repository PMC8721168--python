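"""Exception hierarchy shared across the pipeline."""


class SweeptxError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(SweeptxError):
    """An input value violates a documented invariant."""


class ConfigError(SweeptxError):
    """A configuration value is out of range or inconsistent."""


class LabeledSampleError(SweeptxError):
    """A sample is missing from, or inconsistent with, a sample/group map."""


class OrderingError(SweeptxError):
    """Records are not sorted as the operation requires."""


class EmptyInputError(SweeptxError):
    """No usable records remain after parsing."""


class FormatError(SweeptxError):
    """A file violates its format contract."""


class DegenerateInputError(SweeptxError):
    """Input is structurally valid but degenerate (e.g. all depths zero)."""
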
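"""Exception hierarchy.

Every anticipated failure raises :class:`McdaError` (or a subclass) with a
short machine-greppable message; the CLI maps these to non-zero exit codes.
"""


class McdaError(ValueError):
    """Base class for all domain errors raised by this package."""


class CriterionSetError(McdaError):
    """Structural problem with a criterion set (unknown id, bad weights...)."""


class RatingError(McdaError):
    """A criterion could not be rated from the supplied evidence."""


class PanelError(McdaError):
    """Invalid panel session operation (too few raters, bad consensus...)."""


class SchemaError(McdaError):
    """A serialized file failed validation; message names field and record."""
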
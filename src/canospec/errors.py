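"""Exception hierarchy for canospec."""


class CanospecError(Exception):
    """Base class for all canospec errors."""


class FormatError(CanospecError):
    """A file is missing, malformed, or in an unsupported variant."""


class DegenerateInputError(CanospecError):
    """Input violates a geometric or statistical precondition."""


class ProjectionError(CanospecError):
    """A point cannot be projected (behind camera / on the perspective plane)."""


class ConstantInputError(CanospecError):
    """A statistic is undefined on constant input."""


class ConfigError(CanospecError):
    """Pipeline configuration is invalid; message names the offending key."""


class PipelineError(CanospecError):
    """A pipeline stage failed; message names the stage."""
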
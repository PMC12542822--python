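"""Exception types shared across the pipeline stages."""


class PhoskitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhoskitError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(PhoskitError):
    """Malformed input table or record; the message names the column/row."""


class ConsistencyError(PhoskitError):
    """Cross-referenced data disagree (e.g. site residue vs protein FASTA)."""


class DegenerateDataError(PhoskitError):
    """Data carry no usable signal for the requested estimate."""
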
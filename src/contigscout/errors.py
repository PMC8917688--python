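"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/format problems exit 1,
usage problems (bad flag combinations, out-of-range parameters) exit 2.
"""


class ContigScoutError(Exception):
    """Base class for all errors raised by contigscout."""


class InputError(ContigScoutError):
    """A required input file is missing or unreadable."""


class FormatError(ContigScoutError):
    """An input file exists but violates its expected dialect."""


class ParameterError(ContigScoutError):
    """A parameter value is out of range or inconsistent."""
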
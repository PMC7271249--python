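"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage problems -> 2, input-format
problems -> 3, unresolvable identifiers -> 4.
"""


class PpirefError(Exception):
    """Base class for all package errors."""


class ParseError(PpirefError):
    """An input file violates its expected format; the message names the line."""


class ConfigError(PpirefError):
    """A scoring or query configuration violates its invariants."""


class NotFoundError(PpirefError):
    """A queried identifier or term does not resolve."""


class EndpointError(PpirefError):
    """No usable source/sink endpoints for direction inference."""
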
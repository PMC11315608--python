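"""Exception hierarchy for communet.

All domain errors derive from :class:`CommunetError` so the CLI can map them
to exit code 2 uniformly; everything else is a genuine bug and propagates.
"""


class CommunetError(Exception):
    """Base class for all contract violations raised by communet."""


class SBMLParseError(CommunetError):
    """The SBML document is malformed (message names the offending line)."""


class ConventionError(CommunetError):
    """The model violates the community-model naming conventions."""


class FormatError(CommunetError):
    """A flux/FVA TSV file violates its column contract."""


class ParameterError(CommunetError):
    """A user-supplied parameter is out of its documented domain."""
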
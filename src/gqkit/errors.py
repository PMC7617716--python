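"""Exception hierarchy for gqkit."""


class GQKitError(Exception):
    """Base class for all gqkit errors."""


class ParseError(GQKitError):
    """A structure file could not be parsed (carries the offending line number)."""


class TopologyError(GQKitError):
    """Frames of a multi-model file or ensemble disagree on atom content."""


class FormatError(GQKitError):
    """A structure cannot be encoded in the requested output format."""


class BuildError(GQKitError):
    """A synthetic-structure builder failed its geometric self-check."""


class PlacementError(GQKitError):
    """A rigid peptide placement could not satisfy its distance/clash constraints."""
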
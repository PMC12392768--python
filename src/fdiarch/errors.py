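"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or file-format invariant."""


class LandmarkError(ValidationError):
    """A scan lacks the landmark teeth (first molars / central incisors)
    required to construct the standard pose."""


class PlyParseError(ValidationError):
    """A PLY file could not be parsed."""
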
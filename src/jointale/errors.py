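"""Exception hierarchy for jointale."""


class JointAleError(Exception):
    """Base class for all jointale errors."""


class FociFormatError(JointAleError):
    """A foci table violates the expected schema (missing column, bad header)."""


class FociInputError(JointAleError):
    """A foci table is well-formed but semantically invalid (bad value, wrong
    number of condition labels, out-of-range coordinate)."""


class GridMismatchError(JointAleError):
    """Two maps that must share a grid do not."""


class DegenerateClusterError(JointAleError):
    """A cluster carries zero joint likelihood mass, so no contribution ratio
    can be formed."""
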
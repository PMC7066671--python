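"""Package exception hierarchy."""


class VoxDeltaError(Exception):
    """Base class for all voxdelta errors."""


class ParseError(VoxDeltaError):
    """A structure file could not be parsed."""


class EmptyStructureError(VoxDeltaError):
    """A structure file yielded zero usable atoms."""


class UnsupportedElementError(VoxDeltaError):
    """A ligand contains an element outside the supported ten-element set."""


class InsufficientDataError(VoxDeltaError):
    """Not enough labelled ligands to build training pairs."""


class UnitError(VoxDeltaError):
    """An affinity value or unit is out of domain."""
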
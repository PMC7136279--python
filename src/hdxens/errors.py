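"""Exception hierarchy."""


class HDXError(Exception):
    """Base class for all hdxens errors."""


class TopologyError(HDXError):
    """Structure/trajectory inconsistent with the topology."""


class EmptyEnsembleError(HDXError):
    """An operation produced or received an ensemble with zero frames."""


class ReconstructionError(HDXError):
    """Amide-hydrogen reconstruction failed for a residue."""


class FeatureError(HDXError):
    """Contact / H-bond feature extraction failed."""


class ConvergenceError(HDXError):
    """Iterative reweighting failed to converge."""


class InputError(HDXError):
    """Malformed or inconsistent user input."""
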
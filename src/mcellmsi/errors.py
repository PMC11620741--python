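"""Exception hierarchy for the mcellmsi pipeline."""


class McellError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(McellError, ValueError):
    """Invalid stimulus protocol construction."""


class SimulationError(McellError, ValueError):
    """Inconsistent simulator inputs."""


class TraceError(McellError, ValueError):
    """Trace does not satisfy a quantification precondition."""


class BundleError(McellError, IOError):
    """Trial bundle cannot be written or read."""


class CorruptBundleError(BundleError):
    """Bundle manifest hashes do not match file contents."""


class AbfImportError(McellError, ValueError):
    """Axon Binary Format file cannot be interpreted."""


class UndefinedIndexError(McellError, ValueError):
    """Integration index requested with a non-positive denominator."""


class StatError(McellError, ValueError):
    """Statistical test precondition violated."""
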
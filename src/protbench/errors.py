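"""Exception hierarchy shared across the library."""


class ProtbenchError(Exception):
    """Base class for all protbench errors."""


class EmptySequence(ProtbenchError):
    pass


class LengthMismatch(ProtbenchError):
    pass


class LabelOutOfRange(ProtbenchError):
    pass


class TooFewRecords(ProtbenchError):
    pass


class EmptyBatch(ProtbenchError):
    pass


class UnsupportedResidue(ProtbenchError):
    pass


class UnknownElement(ProtbenchError):
    pass


class IncompatibleArchitecture(ProtbenchError):
    pass


class IncompatibleTask(ProtbenchError):
    pass


class ShapeMismatch(ProtbenchError):
    pass


class DimensionMismatch(ProtbenchError):
    pass


class EmptyGraph(ProtbenchError):
    pass


class NonFiniteLoss(ProtbenchError):
    pass


class SingleClass(ProtbenchError):
    pass


class NoPositives(ProtbenchError):
    pass


class ZeroVariance(ProtbenchError):
    pass


class TooFewReplicates(ProtbenchError):
    pass


class InvalidSpec(ProtbenchError):
    pass


class MalformedFasta(ProtbenchError):
    pass


class MissingColumn(ProtbenchError):
    pass


class UnknownDataset(ProtbenchError):
    pass
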
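"""Exception hierarchy for protfuse."""


class ProtfuseError(Exception):
    """Base class for all protfuse errors."""


class ParseError(ProtfuseError):
    """Malformed input file (FASTA, TSV, checkpoint)."""


class ParameterError(ProtfuseError, ValueError):
    """Invalid parameter value or configuration."""


class SequenceRejectedError(ProtfuseError):
    """A sequence became empty (or otherwise invalid) under the cleaning policy."""


class ShapeError(ProtfuseError, ValueError):
    """Tensor shape mismatch in the model forward pass."""


class IntegrityError(ProtfuseError):
    """A stored artifact (embedding container, checkpoint) failed validation."""


class EmbedderUnavailableError(ProtfuseError):
    """The requested protein-language-model runtime cannot be imported."""


class TrainingDivergedError(ProtfuseError):
    """Training loss became non-finite.

    Carries the last finite-loss parameter checkpoint in ``checkpoint``.
    """

    def __init__(self, message: str, checkpoint=None):
        super().__init__(message)
        self.checkpoint = checkpoint
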
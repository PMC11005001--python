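"""Exception types shared across the pipeline."""


class EpiphosError(Exception):
    """Base class for pipeline errors."""


class FormatError(EpiphosError):
    """A required column or field is missing or malformed."""


class DesignError(EpiphosError):
    """The sample design is inconsistent with the data or rank-deficient."""


class AccessionError(EpiphosError):
    """A protein accession could not be resolved in the FASTA."""


class AnnotationConflictError(EpiphosError):
    """A stated phosphosite residue disagrees with the FASTA sequence."""


class PipelineError(EpiphosError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
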
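"""Exception hierarchy for the prioritization pipeline."""


class PipelineError(Exception):
    """Base class for all trioprio errors."""


class FormatError(PipelineError):
    """A file does not conform to its declared dialect (PED, GMT, sidecar)."""


class NormalizationError(PipelineError):
    """A VCF record violates the normalized-input contract (e.g. multiallelic)."""


class MissingAnnotationError(PipelineError):
    """A VCF record has no matching row in the annotation sidecar."""


class PedigreeMismatchError(PipelineError):
    """A VCF sample cannot be reconciled with the pedigree."""


class UsageError(PipelineError):
    """An operation was invoked outside its contract (wrong consequence class,
    empty graph, hom-ref proband, ...)."""


class ConfigError(PipelineError):
    """An invalid configuration value (simulation capacity, thresholds)."""


class UniverseError(PipelineError):
    """An enrichment query contains genes outside the background universe."""


class EvaluationError(PipelineError):
    """Pipeline output and truth table cannot be matched up."""
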
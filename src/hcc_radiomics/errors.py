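"""Exception hierarchy for the radiomics pipeline.

Every stage raises a subclass of :class:`RadiomicsError` so the pipeline
driver can attach lesion/stage context and abort with a nonzero status.
"""


class RadiomicsError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RadiomicsError):
    """A configuration value is outside its admissible range."""


class ValidationError(RadiomicsError):
    """An input volume or table violates its contract (domain, finiteness)."""


class AlignmentError(RadiomicsError):
    """Paired volumes disagree in shape or voxel spacing."""


class DegenerateMatrixError(RadiomicsError):
    """A texture matrix cannot be formed (no valid voxel pairs/zones)."""


class CohortError(RadiomicsError):
    """The cohort table is malformed (unknown grade, duplicate lesion id)."""


class TrainingError(RadiomicsError):
    """The classifier cannot be trained (e.g. a single-class design)."""


class EvaluationError(RadiomicsError):
    """A metric cannot be computed (e.g. a super-class absent out-of-bag)."""
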
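"""Typed exceptions raised across the pipeline.

Every reader rejects malformed input with :class:`FormatError` or
:class:`ConsistencyError` rather than coercing it; every model-feasibility
violation raises :class:`ModelInfeasibleError` so callers can fall back to
an alternative copy-number/multiplicity model.
"""


class ClonescapeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ClonescapeError):
    """A configuration value violates its documented domain."""


class FormatError(ClonescapeError):
    """A file is syntactically malformed (bad counts, bad coordinates...)."""


class ConsistencyError(ClonescapeError):
    """Inputs are individually well-formed but mutually inconsistent."""


class InconsistentTruthError(ClonescapeError):
    """A simulation truth object is incomplete or self-contradictory."""


class ModelInfeasibleError(ClonescapeError):
    """A copy-number/multiplicity model implies f or g outside [0, 1].

    Signals that an alternative model must be considered, never that the
    data are unusable.
    """

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class DegenerateModelError(ClonescapeError):
    """t*f*n = 0: the mutation fraction g is undefined."""


class UndefinedStateError(ClonescapeError):
    """Copy-neutral states (M = 2) cannot be inferred from composite copy."""


class NoTumorError(ClonescapeError):
    """Purity t = 0 makes tumor-cell fractions undefined."""


class ImpossibleModelError(ClonescapeError):
    """Observed VAF exceeds what the founder copy model allows."""


class UnresolvableSuperclone(ClonescapeError):
    """Superclone correction would require purity > 1."""


class InvalidTreeError(ClonescapeError):
    """Parent map is cyclic, multi-rooted, or disconnected."""


class InvalidCompositionError(ClonescapeError):
    """Clone fractions are negative or sum beyond 1."""


class InfeasiblePhylogenyError(ClonescapeError):
    """No rooted tree satisfies the sum and crossing rules.

    Carries the list of violated constraints; usually indicates a
    clustering or purity-estimation problem upstream.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []


class ClassificationUndefinedError(ClonescapeError):
    """Fewer than two usable tumor samples: truncal/shared/private undefined."""


class IncomparableClustersError(ClonescapeError):
    """Two clusters share no sample with a defined CCF."""


class StageError(ClonescapeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
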
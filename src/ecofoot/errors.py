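"""Exception hierarchy for the accounting pipeline."""


class EcofootError(Exception):
    """Base class for all package errors."""


class StructuralError(EcofootError):
    """Dimension / geometry mismatch between objects that must align."""


class ValidationError(EcofootError):
    """Input violates a value-level contract (negativity, gaps, zeros)."""


class NonProductiveEconomyError(EcofootError):
    """The block coefficient matrix has spectral radius >= 1."""


class AllocationGapError(EcofootError):
    """Land use demanded for a (region, product, category) with no
    spatial distribution layer to allocate it to."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "no usable spatial layer for land-using entries: "
            + ", ".join(map(str, self.missing))
        )


class CoverageError(EcofootError):
    """Characterization factors missing for land-bearing cells in
    strict mode."""


class AnalysisError(EcofootError):
    """A statistical analysis cannot be carried out (e.g. all rank
    correlations undefined)."""


class PipelineDependencyError(EcofootError):
    """A pipeline stage was run without the outputs of the stage it
    depends on."""


class ConfigError(EcofootError):
    """Invalid generator or pipeline configuration."""
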
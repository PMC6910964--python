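"""Exception hierarchy shared across the package."""


class CosolvMapError(Exception):
    """Base class for all package errors."""


class StructureParseError(CosolvMapError):
    """A structure or trajectory file could not be parsed."""


class UnsupportedFormatError(CosolvMapError):
    """File format (or box geometry) not supported."""


class TopologyError(CosolvMapError):
    """Inconsistency between a topology and dependent data."""


class ParameterError(CosolvMapError):
    """Missing or invalid nonbonded parameters."""


class GeometryError(CosolvMapError):
    """Invalid geometric query (bad cutoff, empty selection, ...)."""


class ScoringError(CosolvMapError):
    """Scoring cannot proceed (no frames, empty protein, ...)."""


class FixtureError(CosolvMapError):
    """Synthetic-system generation failed."""


class SitesError(CosolvMapError):
    """Known-site definition invalid or unresolvable."""
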
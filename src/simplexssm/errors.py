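"""Exception types shared across the package."""


class SimplexSSMError(Exception):
    """Base class for all package errors."""


class NonManifoldMeshError(SimplexSSMError):
    """Input triangle mesh is open or non-manifold."""


class DegenerateGeometryError(SimplexSSMError):
    """Local simplex geometry is undefined (e.g. collinear neighbors)."""


class EvolutionDivergedError(SimplexSSMError):
    """Greedy evolution displacement grew monotonically; mesh is diverging."""


class PipelineStageError(SimplexSSMError):
    """A pipeline stage failed; message names the stage and the input."""
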
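"""Exception hierarchy shared across the package."""


class EpistatError(Exception):
    """Base class for all package errors."""


class PDBParseError(EpistatError):
    """Raised when PDB-format input cannot be interpreted."""


class ResidueLookupError(EpistatError, KeyError):
    """A residue named in a request is absent from the model."""


class AtomLookupError(EpistatError, KeyError):
    """An atom named in a request is absent from its residue."""


class UsageError(EpistatError, ValueError):
    """Arguments are individually valid but jointly inconsistent."""


class SelectionError(EpistatError, ValueError):
    """An atom/residue selection cannot be honoured (empty, too short, mismatched)."""


class DegenerateGeometryError(EpistatError, ValueError):
    """Point sets too small or collinear for a unique superposition."""


class EmptyWindowError(EpistatError, ValueError):
    """No frames remain after applying the burn-in window."""


class MissingParameterError(EpistatError, KeyError):
    """Topology atoms lack nonbonded parameters; message lists them."""


class CapabilityError(EpistatError, RuntimeError):
    """An optional reader/back-end is not available in this installation."""


class FitError(EpistatError, RuntimeError):
    """Nonlinear fit failed to converge from every start."""


class NoPeakError(EpistatError, ValueError):
    """A thermogram has no interior heat-capacity maximum."""


class GenerationError(EpistatError, ValueError):
    """A synthetic-data specification is infeasible or self-contradictory."""


class StageError(EpistatError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
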
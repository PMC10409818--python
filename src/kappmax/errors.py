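"""Exception types shared across the package."""


class KappmaxError(Exception):
    """Base class for all package-specific errors."""


class GEMParseError(KappmaxError):
    """Raised when an SBML document cannot be parsed into a network."""


class GPRParseError(KappmaxError):
    """Raised for malformed gene-protein-reaction boolean expressions."""


class CurationError(KappmaxError):
    """Raised when a curation rule references an absent reaction."""


class InfeasibleModelError(KappmaxError):
    """Raised when an optimization problem has no feasible solution."""


class SolverError(KappmaxError):
    """Raised when a solver fails for reasons other than infeasibility."""
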
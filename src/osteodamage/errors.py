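"""Exception hierarchy.

Validation failures (bad inputs, malformed files, parameter constraint
violations) map to CLI exit code 2; solver failures (Newton non-convergence,
damage saturation, degenerate states) map to exit code 3.
"""


class OsteoDamageError(Exception):
    """Base class for all package errors."""


class ValidationError(OsteoDamageError):
    """Invalid input data, parameters or file format."""


class SolverError(OsteoDamageError):
    """Numerical solver failed to converge."""


class DegenerateStrainError(SolverError):
    """Operation undefined because the undamaged strain energy vanishes."""


class DamageSaturationError(SolverError):
    """The damage variable reached 1: the material point has fully failed."""
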
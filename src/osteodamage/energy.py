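"""Strain-energy polynomials and the monotonic damage function.

The undamaged transversely isotropic material stores the quadratic strain
energy density (units MPa = MJ/m^3)

    psi0 = P2 = mu2 I1^2 + nu2 I2 + rho2 I4^2 + tau2 I5,

positive definite when mu2 > -nu2/2 > 0, rho2 > 0, tau2 > 0. Damage under
monotonic loading is encoded by a cubic extension

    P3 = P2 + mu3 I1^3 + nu3 I1 I2 + sigma3 I3 + rho3 I4^3 + tau3 I4 I5,

with the damage variable defined by (1 - alpha~) psi0 = P3, i.e.

    alpha~ = -(cubic terms) / P2,

which grows linearly along proportional strain paths. The per-crack-step
macrostate energy is E_k / k = (1 - alpha) psi0.

Parameters carry stress units (MPa); ``beta`` is the quenched-disorder
parameter in 1/MPa, ``r`` the lattice branching parameter (1 < r <= 3),
``N`` the maximum number of crack-advance steps (the cortical thickness /
osteon diameter ratio bounds it: ~0.8 mm / 0.2 mm => N < 5, though values
up to 8 are accepted), and ``eps0`` the initial damage-onset threshold
strain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import DamageSaturationError, DegenerateStrainError, ValidationError
from .kinematics import Invariants, as_fiber_axis, as_strain, invariants

_PARAM_FIELDS = (
    "mu2", "nu2", "rho2", "tau2",
    "mu3", "nu3", "sigma3", "rho3", "tau3",
    "beta", "r", "N", "eps0",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the constitutive model.

    Quadratic (``*2``) and cubic (``*3``) polynomial coefficients are in
    MPa; ``beta`` in 1/MPa; ``r``, ``N``, ``eps0`` dimensionless.
    """

    mu2: float
    nu2: float
    rho2: float
    tau2: float
    mu3: float
    nu3: float
    sigma3: float
    rho3: float
    tau3: float
    beta: float
    r: float
    N: int
    eps0: float

    def __post_init__(self) -> None:
        if not (self.nu2 < 0.0 and self.mu2 > -self.nu2 / 2.0):
            raise ValidationError(
                "sign constraints violated: need mu2 > -nu2/2 > 0 "
                f"(mu2={self.mu2}, nu2={self.nu2})"
            )
        if self.rho2 <= 0.0 or self.tau2 <= 0.0:
            raise ValidationError("rho2 and tau2 must be positive")
        if not (1.0 < self.r <= 3.0):
            raise ValidationError(f"lattice parameter r must lie in (1, 3], got {self.r}")
        if not (isinstance(self.N, (int, np.integer)) and 1 <= self.N <= 8):
            raise ValidationError(f"N must be an integer in 1..8, got {self.N!r}")
        if self.beta <= 0.0:
            raise ValidationError(f"beta must be positive, got {self.beta}")
        if self.eps0 < 0.0:
            raise ValidationError(f"eps0 must be nonnegative, got {self.eps0}")
        # alpha~ >= 0 along fiber-aligned tension eps = diag(e,0,0):
        # alpha~(e) = -(mu3+rho3+tau3) e / (mu2+rho2+tau2), linear in e,
        # so nonnegativity over any probe range reduces to one sign check.
        if self.mu3 + self.rho3 + self.tau3 > 0.0:
            raise ValidationError(
                "cubic coefficients must give alpha~ >= 0 in fiber-aligned "
                "tension: need mu3 + rho3 + tau3 <= 0"
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["N"] = int(d["N"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        missing = set(_PARAM_FIELDS) - set(d)
        if missing:
            raise ValidationError(f"parameter document missing fields: {sorted(missing)}")
        extra = set(d) - set(_PARAM_FIELDS)
        if extra:
            raise ValidationError(f"parameter document has unknown fields: {sorted(extra)}")
        kwargs = {k: (int(d[k]) if k == "N" else float(d[k])) for k in _PARAM_FIELDS}
        return cls(**kwargs)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed parameter JSON {path}: {exc}") from exc
        return cls.from_dict(doc)

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


#: Implementation defaults (the source study's fitted tables are not part of
#: this package). Chosen so the fiber-aligned uniaxial initial modulus is
#: ~15 GPa, damage onset eps0 = 0.004, and softening is visible by a strain
#: of ~0.02; beta is order 1 in 1/MPa for realistic bone energy densities.
DEFAULT_PARAMETERS = ModelParameters(
    mu2=1800.0, nu2=-2000.0, rho2=500.0, tau2=500.0,
    mu3=-5000.0, nu3=0.0, sigma3=0.0, rho3=-30000.0, tau3=-30000.0,
    beta=0.4, r=2.0, N=4, eps0=0.004,
)


class EnergyBreakdown(NamedTuple):
    """psi0 and P3 values with the implied damage at one strain state."""

    psi0: float        # MPa, quadratic SEDF
    p3: float          # MPa, cubic polynomial (1 - alpha~) psi0
    alpha_tilde: float # dimensionless damage in [0, 1)
    ek_per_k: float    # MPa, per-step macrostate energy (1 - alpha~) psi0


def psi0(inv: Invariants, theta: ModelParameters) -> float:
    """Quadratic strain energy density P2 (MPa); homogeneous of degree 2."""
    return (
        theta.mu2 * inv.I1 ** 2
        + theta.nu2 * inv.I2
        + theta.rho2 * inv.I4 ** 2
        + theta.tau2 * inv.I5
    )


def cubic_part(inv: Invariants, theta: ModelParameters) -> float:
    """The degree-3 terms of P3 (MPa); homogeneous of degree 3."""
    return (
        theta.mu3 * inv.I1 ** 3
        + theta.nu3 * inv.I1 * inv.I2
        + theta.sigma3 * inv.I3
        + theta.rho3 * inv.I4 ** 3
        + theta.tau3 * inv.I4 * inv.I5
    )


def p3_and_alpha(inv: Invariants, theta: ModelParameters) -> tuple[float, float]:
    """(P3, alpha~) at one strain state.

    alpha~ = -(cubic)/P2, so (1 - alpha~) psi0 == P3 identically.

    Raises
    ------
    DegenerateStrainError
        If psi0 <= 0 (the damage ratio is undefined there).
    DamageSaturationError
        If alpha~ >= 1 (material fully failed).
    """
    p2 = psi0(inv, theta)
    if p2 <= 0.0:
        raise DegenerateStrainError(
            f"psi0 = {p2} <= 0: damage ratio undefined at degenerate strain"
        )
    cubic = cubic_part(inv, theta)
    alpha_tilde = -cubic / p2
    if alpha_tilde >= 1.0:
        raise DamageSaturationError(
            f"alpha~ = {alpha_tilde:.4f} >= 1: damage saturated (material failed)"
        )
    return p2 + cubic, alpha_tilde


def energy_breakdown(eps, a, theta: ModelParameters) -> EnergyBreakdown:
    """Convenience wrapper evaluating psi0, P3, alpha~ from a strain tensor."""
    inv = invariants(eps, a)
    p3, at = p3_and_alpha(inv, theta)
    return EnergyBreakdown(psi0(inv, theta), p3, at, p3)


# -- analytic strain gradients --------------------------------------------
#
# dI1/de = Id
# dI2/de = I1 Id - eps
# dI3/de = adj(eps) = eps^2 - I1 eps + I2 Id   (Cayley-Hamilton)
# dI4/de = a (x) a
# dI5/de = a (x) eps a + eps a (x) a


def grad_psi0(eps, a, theta: ModelParameters) -> np.ndarray:
    """Analytic d(psi0)/d(eps), a symmetric 3x3 tensor in MPa."""
    e = as_strain(eps)
    av = as_fiber_axis(a)
    inv = invariants(e, av)
    eye = np.eye(3)
    aa = np.outer(av, av)
    ea = e @ av
    a_ea = np.outer(av, ea) + np.outer(ea, av)
    return (
        2.0 * theta.mu2 * inv.I1 * eye
        + theta.nu2 * (inv.I1 * eye - e)
        + 2.0 * theta.rho2 * inv.I4 * aa
        + theta.tau2 * a_ea
    )


def grad_cubic(eps, a, theta: ModelParameters) -> np.ndarray:
    """Analytic gradient of the cubic terms of P3 (MPa per unit strain)."""
    e = as_strain(eps)
    av = as_fiber_axis(a)
    inv = invariants(e, av)
    eye = np.eye(3)
    aa = np.outer(av, av)
    ea = e @ av
    a_ea = np.outer(av, ea) + np.outer(ea, av)
    d_i2 = inv.I1 * eye - e
    d_i3 = e @ e - inv.I1 * e + inv.I2 * eye
    return (
        3.0 * theta.mu3 * inv.I1 ** 2 * eye
        + theta.nu3 * (inv.I2 * eye + inv.I1 * d_i2)
        + theta.sigma3 * d_i3
        + 3.0 * theta.rho3 * inv.I4 ** 2 * aa
        + theta.tau3 * (inv.I5 * aa + inv.I4 * a_ea)
    )


def grad_p3(eps, a, theta: ModelParameters) -> np.ndarray:
    """Analytic d(P3)/d(eps) = d(psi0)/d(eps) + d(cubic)/d(eps)."""
    return grad_psi0(eps, a, theta) + grad_cubic(eps, a, theta)


def grad_alpha(eps, a, theta: ModelParameters) -> np.ndarray:
    """Analytic d(alpha~)/d(eps) by the quotient rule (1 / unit strain).

    alpha~ = -C/P2  =>  d(alpha~) = -(dC P2 - C dP2) / P2^2.
    """
    inv = invariants(eps, a)
    p2 = psi0(inv, theta)
    if p2 <= 0.0:
        raise DegenerateStrainError(
            f"psi0 = {p2} <= 0: alpha~ gradient undefined at degenerate strain"
        )
    c = cubic_part(inv, theta)
    dc = grad_cubic(eps, a, theta)
    dp2 = grad_psi0(eps, a, theta)
    return -(dc * p2 - c * dp2) / p2 ** 2
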
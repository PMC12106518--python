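"""History-dependent damage state with a directional threshold field.

Damage accumulates only when the equivalent strain (Macaulay bracket of
the largest principal strain) exceeds the largest value previously reached
in the current principal direction, and only while it is increasing. The
directional memory eps+(n) is stored on a fixed antipodally symmetric grid
of unit directions (Fibonacci hemisphere); every visited strain state
raises each direction's threshold to the normal strain <n . eps n>+ seen
there, and thresholds never decrease.

Under proportional monotonic loading the incremental law integrates the
exact differential d(alpha~), so the accumulated damage equals the
closed-form monotonic damage alpha~(eps): on first activation from a
virgin state the damage variable catches up to <alpha~(eps)>+, and from
then on grows by the Macaulay-clamped increment <(d alpha~/d eps) : d eps>+.
Damage is therefore non-decreasing along any strain path, and a closed
loop that stays below the onset threshold leaves the state bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import ModelParameters, p3_and_alpha, grad_alpha, psi0 as _psi0
from .errors import DamageSaturationError, ValidationError
from .kinematics import as_strain, invariants, macaulay, principal_strains

_PSI0_FLOOR = 1e-14  # below this the alpha~ ratio is numerically undefined


def equivalent_strain(eps) -> float:
    """Macaulay bracket of the largest principal strain (eigenstrain)."""
    w, _ = principal_strains(eps)
    return macaulay(float(w[0]))


def fibonacci_hemisphere(m: int) -> np.ndarray:
    """m unit directions quasi-uniformly covering the upper hemisphere.

    Directions are used with antipodal symmetry (n and -n equivalent), so
    a hemisphere covers all of direction space.
    """
    if m < 4:
        raise ValidationError(f"direction grid needs at least 4 points, got {m}")
    i = np.arange(m, dtype=float)
    z = (i + 0.5) / m                      # heights in (0, 1)
    phi = i * np.pi * (3.0 - np.sqrt(5.0)) # golden angle
    rho = np.sqrt(1.0 - z ** 2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class ThresholdField:
    """Directional damage-onset memory eps+(n) on a fixed direction grid."""

    directions: np.ndarray  # (M, 3) unit vectors, upper hemisphere
    thresholds: np.ndarray  # (M,) nonnegative strains, never decreasing
    eps0: float             # initial isotropic threshold

    @classmethod
    def initial(cls, eps0: float, m: int = 128, per_direction=None) -> "ThresholdField":
        """Isotropic initialization at eps0 (or a per-direction array)."""
        if eps0 < 0.0:
            raise ValidationError(f"eps0 must be nonnegative, got {eps0}")
        dirs = fibonacci_hemisphere(m)
        if per_direction is None:
            thr = np.full(m, float(eps0))
        else:
            thr = np.asarray(per_direction, dtype=float).copy()
            if thr.shape != (m,):
                raise ValidationError("per-direction thresholds must have shape (m,)")
            if np.any(thr < eps0):
                raise ValidationError("per-direction thresholds must be >= eps0")
        return cls(dirs, thr, float(eps0))

    def threshold_at(self, n) -> float:
        """Threshold of the grid direction nearest to n (sign-invariant)."""
        n = np.asarray(n, dtype=float)
        idx = int(np.argmax(np.abs(self.directions @ n)))
        return float(self.thresholds[idx])

    def raised_by(self, eps) -> "ThresholdField":
        """New field with each threshold raised to <n . eps n>+ if larger."""
        e = as_strain(eps)
        normal = np.einsum("mi,ij,mj->m", self.directions, e, self.directions)
        raised = np.maximum(self.thresholds, np.maximum(normal, 0.0))
        return ThresholdField(self.directions, raised, self.eps0)

    def copy(self) -> "ThresholdField":
        return ThresholdField(self.directions.copy(), self.thresholds.copy(), self.eps0)


@dataclass
class DamageState:
    """Damage variable, directional memory and the last visited strain."""

    alpha: float
    field: ThresholdField
    eps_bar_prev: float
    eps_prev: np.ndarray     # last strain tensor (needed for the increment)
    activated: bool = False  # whether the damage branch has ever fired

    @classmethod
    def initial(cls, theta: ModelParameters, m: int = 128) -> "DamageState":
        return cls(
            alpha=0.0,
            field=ThresholdField.initial(theta.eps0, m),
            eps_bar_prev=0.0,
            eps_prev=np.zeros((3, 3)),
            activated=False,
        )

    # -- serialization (driver checkpointing) -----------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "eps0": self.field.eps0,
            "grid": {"kind": "fibonacci_hemisphere", "m": len(self.field.thresholds)},
            "thresholds": self.field.thresholds.tolist(),
            "eps_bar_prev": self.eps_bar_prev,
            "eps_prev": self.eps_prev.tolist(),
            "activated": self.activated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DamageState":
        m = int(d["grid"]["m"])
        field = ThresholdField(
            fibonacci_hemisphere(m),
            np.asarray(d["thresholds"], dtype=float),
            float(d["eps0"]),
        )
        return cls(
            alpha=float(d["alpha"]),
            field=field,
            eps_bar_prev=float(d["eps_bar_prev"]),
            eps_prev=np.asarray(d["eps_prev"], dtype=float),
            activated=bool(d["activated"]),
        )


def update(state: DamageState, eps_new, theta: ModelParameters, a=(1.0, 0.0, 0.0)) -> DamageState:
    """Advance the damage state to a new strain (one load step).

    Implements the two-branch evolution: damage grows only if the
    equivalent strain meets the stored directional threshold and is
    increasing; otherwise only the threshold memory is updated. Raises
    DamageSaturationError when alpha reaches 1.
    """
    e_new = as_strain(eps_new)
    w, v = principal_strains(e_new)
    eps_bar = macaulay(float(w[0]))
    n_t = v[:, 0]

    thr = state.field.threshold_at(n_t)
    active = (eps_bar >= thr * (1.0 - 1e-12)) and (eps_bar > state.eps_bar_prev)

    alpha_new = state.alpha
    activated = state.activated
    if active:
        inv = invariants(e_new, a)
        if _psi0(inv, theta) > _PSI0_FLOOR:
            if not state.activated:
                # catch up with the monotonic closed form at first activation
                _, alpha_tilde = p3_and_alpha(inv, theta)
                alpha_new = max(state.alpha, macaulay(alpha_tilde))
            else:
                d_eps = e_new - state.eps_prev
                g_new = grad_alpha(e_new, a, theta)
                inv_prev = invariants(state.eps_prev, a)
                if _psi0(inv_prev, theta) > _PSI0_FLOOR:
                    g = 0.5 * (grad_alpha(state.eps_prev, a, theta) + g_new)
                else:
                    g = g_new
                # only the sub-step portion above the stored threshold
                # accumulates damage (re-loading up to the old maximum is
                # elastic; crossing it mid-step counts fractionally)
                denom = eps_bar - state.eps_bar_prev
                frac = (eps_bar - max(thr, state.eps_bar_prev)) / denom if denom > 0 else 0.0
                frac = min(max(frac, 0.0), 1.0)
                alpha_new = state.alpha + frac * macaulay(float(np.tensordot(g, d_eps)))
            activated = True
        if alpha_new >= 1.0:
            raise DamageSaturationError(
                f"damage variable reached {alpha_new:.4f} >= 1 (material failed)"
            )

    return DamageState(
        alpha=alpha_new,
        field=state.field.raised_by(e_new),
        eps_bar_prev=eps_bar,
        eps_prev=e_new,
        activated=activated,
    )
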
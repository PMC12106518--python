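"""Small-strain tensor algebra for a transversely isotropic material.

Cortical bone is modelled here in the infinitesimal (engineering) strain
regime: the strain is a symmetric 3x3 tensor ``eps`` whose components stay
well below the ``STRAIN_LIMIT`` guard (bone fractures at strains of order
1e-2). Transverse isotropy enters through a unit fiber axis ``a`` aligned
with the osteons; the material response depends on the five classical
invariants

    I1 = tr(eps)                    I4 = a . eps a
    I2 = (tr^2(eps) - tr(eps^2))/2  I5 = a . eps^2 a
    I3 = det(eps)

(I1, I2, I3) are the elementary symmetric functions of the principal
strains; (I4, I5) measure normal and shear loading along the fiber axis and
are invariant under the sign flip a -> -a.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import ValidationError

#: Guard against silent misuse of the small-strain model: bone fracture
#: strains are well below this.
STRAIN_LIMIT = 0.2

_UNIT_TOL = 1e-12


def as_strain(eps, *, check_magnitude: bool = True) -> np.ndarray:
    """Validate and return a symmetric 3x3 strain tensor as float ndarray.

    Raises
    ------
    ValidationError
        If the array is not 3x3, not exactly symmetric as stored, or has a
        component magnitude above ``STRAIN_LIMIT``.
    """
    arr = np.asarray(eps, dtype=float)
    if arr.shape != (3, 3):
        raise ValidationError(f"strain must be a 3x3 tensor, got shape {arr.shape}")
    if not np.array_equal(arr, arr.T):
        raise ValidationError("strain tensor must be symmetric as stored")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("strain tensor contains non-finite components")
    if check_magnitude and np.max(np.abs(arr)) > STRAIN_LIMIT:
        raise ValidationError(
            f"strain component magnitude exceeds the small-strain guard {STRAIN_LIMIT}"
        )
    return arr


def symmetrize(m) -> np.ndarray:
    """Return the exactly-symmetric part (m + m.T)/2 of a 3x3 array."""
    arr = np.asarray(m, dtype=float)
    return (arr + arr.T) / 2.0


def as_fiber_axis(a) -> np.ndarray:
    """Validate a unit fiber direction (sign is immaterial downstream)."""
    vec = np.asarray(a, dtype=float)
    if vec.shape != (3,):
        raise ValidationError(f"fiber axis must be a 3-vector, got shape {vec.shape}")
    norm = float(np.linalg.norm(vec))
    if abs(norm - 1.0) > 1e-9:
        raise ValidationError(f"fiber axis must be unit norm, |a| = {norm!r}")
    # re-normalize so downstream algebra sees |a| = 1 to machine precision
    return vec / norm


class Invariants(NamedTuple):
    """The five strain invariants of transverse isotropy."""

    I1: float
    I2: float
    I3: float
    I4: float
    I5: float


def invariants(eps, a) -> Invariants:
    """Compute (I1..I5) for strain ``eps`` and fiber axis ``a``.

    (I1, I2, I3) are isotropic (rotation-invariant); (I4, I5) are invariant
    under simultaneous rotation of ``eps`` and ``a`` and under a -> -a.
    """
    e = as_strain(eps)
    av = as_fiber_axis(a)
    tr = float(np.trace(e))
    e2 = e @ e
    i2 = 0.5 * (tr * tr - float(np.trace(e2)))
    i3 = float(np.linalg.det(e))
    ea = e @ av
    i4 = float(av @ ea)
    i5 = float(ea @ ea)  # a . eps^2 a = |eps a|^2 for symmetric eps
    return Invariants(tr, i2, i3, i4, i5)


def principal_strains(eps) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and orthonormal eigendirections (columns).

    Symmetric real tensors always diagonalize; the reconstruction
    ``V diag(w) V.T`` matches ``eps`` to ~1e-10.
    """
    e = as_strain(eps)
    w, v = np.linalg.eigh(e)  # ascending
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def macaulay(x: float) -> float:
    """Macaulay bracket <x>+ : x if x > 0, else 0."""
    return x if x > 0.0 else 0.0


def cayley_hamilton_residual(eps, a=None) -> float:
    """Max-abs residual of eps^3 - I1 eps^2 + I2 eps - I3 Id (diagnostic)."""
    e = as_strain(eps)
    axis = np.array([1.0, 0.0, 0.0]) if a is None else as_fiber_axis(a)
    inv = invariants(e, axis)
    res = e @ e @ e - inv.I1 * (e @ e) + inv.I2 * e - inv.I3 * np.eye(3)
    return float(np.max(np.abs(res)))
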
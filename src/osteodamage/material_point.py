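"""Stress evaluation, stability checks and loading drivers.

Stress derives from the strain-damage energy density Psi = -(1/beta) ln Z:

    sigma = m1 [ (1 - alpha) d(psi0)/d(eps)
                 - psi0 d(alpha~)/d(eps) * 1(damage growing) ],

where m1 is the mean cracking number of the canonical ensemble. At frozen
damage this is exactly the numeric gradient of Psi; the decomposition into
a crackless stress sigma_0 = d(psi0)/d(eps), the correction factor
m1 (1 - alpha), and the increasing-damage stress -m1 psi0 d(alpha~)/d(eps)
mirrors the ensemble picture (the damage term only acts while the damage
variable is actually growing).

Two uniaxial plane-stress drivers are provided. The general one steps a
history-dependent DamageState and solves the lateral strain so the
transverse stress vanishes at every step. The monotonic one exploits that
along increasing proportional fiber-aligned paths the incremental damage
law integrates to the closed-form monotonic damage, which collapses the
lateral solve to a quadratic equation and vectorizes over the whole
schedule; it is the engine behind curve fitting, cohort synthesis and the
layered-beam bending reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import damage as damage_mod
from .curves import CurveTable
from .damage import DamageState
from .energy import ModelParameters, grad_alpha, grad_psi0, psi0 as _psi0_of
from .errors import DamageSaturationError, SolverError, ValidationError
from .kinematics import as_fiber_axis, as_strain, invariants
from .statmech import entropy as _entropy, mean_crack_number_closed

FIBER_X = np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# stress and tangent stiffness
# ---------------------------------------------------------------------------

def stress(eps, a, state, theta: ModelParameters, damage_active: bool = False) -> np.ndarray:
    """Cauchy stress tensor (MPa) at a strain state.

    ``state`` may be a DamageState or a plain damage value alpha. With
    ``damage_active=False`` the damage variable is frozen and sigma equals
    the numeric gradient of the free energy; with ``damage_active=True``
    the increasing-damage term -m1 psi0 d(alpha~)/d(eps) is added.
    """
    e = as_strain(eps)
    av = as_fiber_axis(a)
    alpha = state.alpha if isinstance(state, DamageState) else float(state)
    if not 0.0 <= alpha < 1.0:
        raise DamageSaturationError(f"alpha = {alpha} outside [0, 1)")
    inv = invariants(e, av)
    p2 = _psi0_of(inv, theta)
    g0 = grad_psi0(e, av, theta)
    m1 = mean_crack_number_closed(p2, alpha, theta.beta, theta.r, theta.N)
    sig = m1 * (1.0 - alpha) * g0
    if damage_active:
        sig = sig - m1 * p2 * grad_alpha(e, av, theta)
    return sig


def tangent_stiffness(eps, a, alpha: float, theta: ModelParameters, h: float = 1e-7) -> np.ndarray:
    """Numeric tangent K_ijkl = d(sigma_ij)/d(eps_kl) at frozen damage."""
    e = as_strain(eps)
    k_tensor = np.zeros((3, 3, 3, 3))
    for i in range(3):
        for j in range(i, 3):
            basis = np.zeros((3, 3))
            basis[i, j] = basis[j, i] = 1.0 if i == j else 0.5
            sp = stress(e + h * basis, a, alpha, theta)
            sm = stress(e - h * basis, a, alpha, theta)
            d = (sp - sm) / (2.0 * h)
            k_tensor[:, :, i, j] = d
            k_tensor[:, :, j, i] = d
    return k_tensor


def tangent_ellipticity(
    eps, a, state, theta: ModelParameters, n_probe: int = 1000, seed: int = 0
) -> tuple[float, bool]:
    """Min of the quadratic form K:E:E over random symmetric unit tensors.

    Returns (min value, pass flag); pass means pointwise mechanical
    stability (positive definiteness of the frozen-damage tangent).
    """
    alpha = state.alpha if isinstance(state, DamageState) else float(state)
    k_tensor = tangent_stiffness(eps, a, alpha, theta)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_probe)
    for idx in range(n_probe):
        raw = rng.standard_normal((3, 3))
        sym = (raw + raw.T) / 2.0
        sym /= np.linalg.norm(sym)
        vals[idx] = np.einsum("ijkl,ij,kl->", k_tensor, sym, sym)
    min_val = float(vals.min())
    return min_val, min_val > 0.0


# ---------------------------------------------------------------------------
# fast monotonic fiber-aligned uniaxial response (vectorized)
# ---------------------------------------------------------------------------

class MonotonicUniaxial(NamedTuple):
    """Pointwise plane-stress response along a monotonic schedule."""

    e: np.ndarray        # axial strain
    s: np.ndarray        # lateral strain (eps22 = eps33)
    sigma: np.ndarray    # axial stress, MPa
    alpha: np.ndarray    # damage (0 where the damage branch is inactive)
    psi0: np.ndarray     # quadratic SEDF, MPa
    active: np.ndarray   # bool mask where damage is growing


def _m1_vec(x, r: float, n: int) -> np.ndarray:
    """Vectorized mean cracking number; q = r e^{-x}, limit (N+1)/2 at q=1."""
    q = r * np.exp(-np.asarray(x, dtype=float))
    singular = np.abs(1.0 - q) < 1e-9
    q_safe = np.where(singular, 0.5, q)
    m1 = 1.0 / (1.0 - q_safe) - n * q_safe ** n / (1.0 - q_safe ** n)
    return np.where(singular, (n + 1) / 2.0, m1)


def uniaxial_monotonic(e_axial, theta: ModelParameters, saturation: str = "raise") -> MonotonicUniaxial:
    """Plane-stress response sigma11(e) for monotonically applied strains.

    Solves the lateral strain s (eps22 = eps33 = s by transverse isotropy)
    such that sigma22 = 0, exactly: the transverse equilibrium condition is
    linear in s on the undamaged branch and quadratic on the damaged
    branch. Damage follows the closed-form monotonic law, gated by the
    onset threshold eps0 on the equivalent strain.

    ``saturation``: 'raise' raises DamageSaturationError if alpha~ >= 1
    anywhere; 'nan' marks such points with NaN stress instead.
    """
    e = np.asarray(e_axial, dtype=float)
    mu2, nu2 = theta.mu2, theta.nu2
    mu3, nu3, sg3 = theta.mu3, theta.nu3, theta.sigma3
    rt2 = theta.rho2 + theta.tau2
    rt3 = theta.rho3 + theta.tau3

    # undamaged branch: d(P2)/d(eps22) = 0 is linear in s
    s_el = -e * (2.0 * mu2 + nu2) / (4.0 * mu2 + nu2)

    # damaged branch: d(P3)/d(eps22) = 0 is A s^2 + B s + C = 0
    quad_a = 12.0 * mu3 + 3.0 * nu3
    quad_b = 4.0 * mu2 + nu2 + (12.0 * mu3 + 5.0 * nu3 + sg3) * e
    quad_c = (2.0 * mu2 + nu2) * e + (3.0 * mu3 + nu3) * e ** 2
    near_linear = np.abs(quad_a) * np.maximum(np.abs(e), 1e-12) < 1e-12 * np.abs(quad_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = quad_b ** 2 - 4.0 * quad_a * quad_c
        no_root = (disc < 0.0) & ~near_linear  # model breakdown past saturation
        sq = np.sqrt(np.maximum(disc, 0.0))
        qq = -0.5 * (quad_b + np.sign(np.where(quad_b == 0.0, 1.0, quad_b)) * sq)
        a_safe = np.where(quad_a == 0.0, 1.0, quad_a)
        qq_safe = np.where(qq == 0.0, 1.0, qq)
        root1 = np.where(quad_a == 0.0, np.inf, qq / a_safe)
        root2 = np.where(qq == 0.0, np.inf, quad_c / qq_safe)
        s_lin = -quad_c / np.where(quad_b == 0.0, 1.0, quad_b)
    pick1 = np.abs(root1 - s_el) <= np.abs(root2 - s_el)
    s_quad = np.where(pick1, root1, root2)
    s_act = np.where(near_linear, s_lin, s_quad)

    def _fields(e_, s_):
        i1 = e_ + 2.0 * s_
        i2 = 2.0 * e_ * s_ + s_ ** 2
        i3 = e_ * s_ ** 2
        p2 = mu2 * i1 ** 2 + nu2 * i2 + rt2 * e_ ** 2
        c3 = mu3 * i1 ** 3 + nu3 * i1 * i2 + sg3 * i3 + rt3 * e_ ** 3
        dp2_d11 = 2.0 * mu2 * i1 + 2.0 * nu2 * s_ + 2.0 * rt2 * e_
        dc3_d11 = (
            3.0 * mu3 * i1 ** 2
            + nu3 * (i2 + 2.0 * s_ * i1)
            + sg3 * s_ ** 2
            + 3.0 * rt3 * e_ ** 2
        )
        return p2, c3, dp2_d11, dc3_d11

    p2_act, c3_act, dp2_act, dc3_act = _fields(e, s_act)
    p2_el, _, dp2_el, _ = _fields(e, s_el)

    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_t = np.where(p2_act > 0.0, -c3_act / np.where(p2_act > 0.0, p2_act, 1.0), 0.0)
    eps_bar = np.maximum(np.maximum(e, s_act), 0.0)
    active = (eps_bar >= theta.eps0) & (alpha_t > 0.0) & (p2_act > 0.0)

    saturated = (active & (alpha_t >= 1.0)) | no_root
    if np.any(saturated):
        if saturation == "raise":
            idx = int(np.argmax(saturated))
            raise DamageSaturationError(
                f"damage saturates (alpha~ >= 1) at schedule index {idx}, e = {e.flat[idx] if e.ndim else e:.5g}"
            )
        if saturation != "nan":
            raise ValidationError("saturation must be 'raise' or 'nan'")

    p3_act = p2_act + c3_act
    sigma_act = _m1_vec(theta.beta * p3_act, theta.r, theta.N) * (dp2_act + dc3_act)
    sigma_el = _m1_vec(theta.beta * np.maximum(p2_el, 0.0), theta.r, theta.N) * dp2_el

    sigma = np.where(active, sigma_act, sigma_el)
    sigma = np.where(saturated, np.nan, sigma)
    s_out = np.where(active, s_act, s_el)
    alpha_out = np.where(active, np.clip(alpha_t, 0.0, None), 0.0)
    alpha_out = np.where(saturated, np.nan, alpha_out)
    psi0_out = np.where(active, p2_act, p2_el)
    return MonotonicUniaxial(e, s_out, sigma, alpha_out, psi0_out, active)


def initial_modulus(theta: ModelParameters) -> float:
    """Analytic initial uniaxial tangent modulus Y0 (MPa) of the driver curve."""
    mu2, nu2 = theta.mu2, theta.nu2
    rt2 = theta.rho2 + theta.tau2
    nu_p = (2.0 * mu2 + nu2) / (4.0 * mu2 + nu2)  # lateral contraction ratio
    y_poly = 2.0 * mu2 * (1.0 - 2.0 * nu_p) - 2.0 * nu2 * nu_p + 2.0 * rt2
    m1_0 = mean_crack_number_closed(0.0, 0.0, theta.beta, theta.r, theta.N)
    return float(m1_0 * y_poly)


def strain_at_alpha(theta: ModelParameters, alpha_target: float, e_hi: float = 0.15) -> float:
    """Axial strain at which the monotonic damage reaches ``alpha_target``."""
    if not 0.0 < alpha_target < 1.0:
        raise ValidationError("alpha_target must lie in (0, 1)")
    grid = np.linspace(theta.eps0 if theta.eps0 > 0 else 1e-5, e_hi, 4096)
    resp = uniaxial_monotonic(grid, theta, saturation="nan")
    above = np.where(resp.alpha >= alpha_target)[0]
    if len(above) == 0:
        raise SolverError(
            f"damage never reaches {alpha_target} below strain {e_hi}"
        )
    j = int(above[0])
    if j == 0:
        return float(grid[0])
    # linear interpolation in alpha between the bracketing grid points
    a0, a1 = resp.alpha[j - 1], resp.alpha[j]
    t = (alpha_target - a0) / (a1 - a0)
    return float(grid[j - 1] + t * (grid[j] - grid[j - 1]))


# ---------------------------------------------------------------------------
# general incremental uniaxial driver
# ---------------------------------------------------------------------------

class PathState(NamedTuple):
    """One step of a driver path, for entropy evaluation."""

    strain: float  # axial strain (or layer strain)
    alpha: float
    psi0: float    # MPa


def uniaxial_response(
    strain_schedule: Sequence[float],
    theta: ModelParameters,
    m_directions: int = 128,
    return_states: bool = False,
    newton_max_iter: int = 50,
):
    """Uniaxial plane-stress tension with full damage history tracking.

    At each scheduled axial strain the lateral strain (eps22 = eps33, by
    transverse isotropy of fiber-aligned loading) is solved so that
    sigma22 = 0, with the damage state evolving step by step. Returns a
    (strain, stress) CurveTable; with ``return_states=True`` also the list
    of PathState steps for entropy evaluation.
    """
    sched = np.asarray(strain_schedule, dtype=float)
    if len(sched) == 0 or sched[0] != 0.0:
        raise ValidationError("strain schedule must start at 0")
    if len(sched) > 1 and not np.all(np.diff(sched) > 0.0):
        raise ValidationError("strain schedule must be strictly increasing")

    state = DamageState.initial(theta, m_directions)
    stresses = [0.0]
    states = [PathState(0.0, 0.0, 0.0)]
    nu_p = (2.0 * theta.mu2 + theta.nu2) / (4.0 * theta.mu2 + theta.nu2)
    s_warm_ratio = -nu_p

    committed = state
    for e_ax in sched[1:]:

        def trial(s_lat):
            eps = np.diag([e_ax, s_lat, s_lat])
            new_state = damage_mod.update(committed, eps, theta, FIBER_X)
            active = new_state.alpha > committed.alpha
            sig = stress(eps, FIBER_X, new_state, theta, damage_active=active)
            return sig, new_state

        # secant iteration on sigma22(s) = 0, warm-started from the last ratio
        s0 = s_warm_ratio * e_ax
        s1 = s0 - max(abs(e_ax), 1e-6) * 1e-3
        sig0, st0 = trial(s0)
        f0 = sig0[1, 1]
        converged = False
        tol = 1e-8 * abs(sig0[0, 0]) + 1e-10
        if abs(f0) <= tol:
            s_sol, sig_sol, st_sol = s0, sig0, st0
            converged = True
        else:
            sig1, st1 = trial(s1)
            f1 = sig1[1, 1]
            for _ in range(newton_max_iter):
                if f1 == f0:
                    break
                s2 = s1 - f1 * (s1 - s0) / (f1 - f0)
                sig2, st2 = trial(s2)
                f2 = sig2[1, 1]
                s0, f0 = s1, f1
                s1, f1, sig1, st1 = s2, f2, sig2, st2
                tol = 1e-8 * abs(sig1[0, 0]) + 1e-10
                if abs(f1) <= tol:
                    converged = True
                    break
            s_sol, sig_sol, st_sol = s1, sig1, st1
        if not converged:
            raise SolverError(
                f"lateral plane-stress Newton failed at e = {e_ax:.5g}: "
                f"residual sigma22 = {f1:.3e} MPa after {newton_max_iter} iterations"
            )

        committed = st_sol
        s_warm_ratio = s_sol / e_ax if e_ax != 0.0 else s_warm_ratio
        stresses.append(float(sig_sol[0, 0]))
        inv = invariants(np.diag([e_ax, s_sol, s_sol]), FIBER_X)
        states.append(PathState(float(e_ax), committed.alpha, _psi0_of(inv, theta)))

    curve = CurveTable(sched, np.asarray(stresses), "tension", {"test_type": "tension"})
    if return_states:
        return curve, states
    return curve


# ---------------------------------------------------------------------------
# bending of a prismatic layered section
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionSpec:
    """Rectangular prismatic beam section for the bending reduction."""

    width: float = 4.0       # mm
    thickness: float = 0.5   # mm (coupon-scale default)
    layers: int = 50
    span: float = 100.0      # mm, three-point bending

    def __post_init__(self) -> None:
        if min(self.width, self.thickness, self.span) <= 0.0:
            raise ValidationError("section dimensions must be positive")
        if self.layers < 20:
            raise ValidationError("section needs at least 20 layers")


def bending_response(
    section: SectionSpec,
    curvature_schedule: Sequence[float],
    theta: ModelParameters,
) -> CurveTable:
    """Moment-curvature curve of a prismatic beam, layer by layer.

    Each of the ``layers`` through-thickness layers is an independent
    material point at strain eps11(y) = kappa * y with its own lateral
    plane-stress solve and damage history (monotonic in kappa, so the
    closed-form monotonic response applies per layer). Tension-side layers
    accumulate damage; the curve is truncated (and flagged in metadata)
    at the softening limit where dM/dkappa would turn negative, or where
    an extreme layer saturates.
    """
    kappa = np.asarray(curvature_schedule, dtype=float)
    if len(kappa) == 0 or kappa[0] != 0.0:
        raise ValidationError("curvature schedule must start at 0")
    if len(kappa) > 1 and not np.all(np.diff(kappa) > 0.0):
        raise ValidationError("curvature schedule must be strictly increasing")

    dy = section.thickness / section.layers
    y = (np.arange(section.layers) + 0.5) * dy - section.thickness / 2.0
    e_layers = np.outer(kappa, y)  # (steps, layers)
    resp = uniaxial_monotonic(e_layers, theta, saturation="nan")
    moments = section.width * np.nansum(resp.sigma * y * dy, axis=1)
    moments[0] = 0.0

    meta = {"test_type": "bending", "softening_limited": False}
    bad = np.any(np.isnan(resp.sigma), axis=1)
    n_keep = len(kappa)
    if np.any(bad):
        n_keep = int(np.argmax(bad))
        meta["softening_limited"] = True
    dm = np.diff(moments[:n_keep])
    drop = np.where(dm <= 0.0)[0]
    if len(drop):
        n_keep = int(drop[0]) + 1
        meta["softening_limited"] = True
    if n_keep < 2:
        raise SolverError("bending response softens immediately; reduce curvature step")
    return CurveTable(kappa[:n_keep], moments[:n_keep], "bending", meta)


def three_point_force_deflection(curve: CurveTable, section: SectionSpec) -> pd.DataFrame:
    """Midspan force-deflection from a monotone moment-curvature curve.

    The midspan moment is M_max = F L / 4; along the half-span the moment
    varies linearly, the curvature follows by inverting the M-kappa curve,
    and the midspan deflection comes from unit-load integration
    delta = 2 * int_0^{L/2} kappa(x) (x/2) dx.
    """
    if curve.kind != "bending":
        raise ValidationError("force-deflection requires a bending (moment-curvature) curve")
    length = section.span
    x = np.linspace(0.0, length / 2.0, 201)
    rows = []
    for m_max in curve.ordinate:
        force = 4.0 * m_max / length
        m_x = 2.0 * m_max * x / length
        kappa_x = np.interp(m_x, curve.ordinate, curve.abscissa)
        deflection = 2.0 * np.trapezoid(kappa_x * x / 2.0, x)
        rows.append((force, deflection))
    return pd.DataFrame(rows, columns=["force", "deflection"])


# ---------------------------------------------------------------------------
# entropy along a driver path
# ---------------------------------------------------------------------------

def entropy_along_path(states: Sequence[PathState], theta: ModelParameters) -> pd.DataFrame:
    """Entropy H and cumulative damage-driven entropy production along a path.

    H is the ensemble entropy at each step; the production increment is
    (dH/dalpha) * d(alpha) >= 0, which vanishes identically while the
    strain stays below the damage-onset threshold and grows monotonically
    once damage activates.
    """
    strain = np.array([st.strain for st in states])
    h_vals = np.empty(len(states))
    dh_cum = np.zeros(len(states))
    acc = 0.0
    prev_alpha = 0.0
    for idx, st in enumerate(states):
        res = _entropy(st.psi0, min(st.alpha, 1.0 - 1e-12), theta.beta, theta.r, theta.N)
        h_vals[idx] = res.H
        d_alpha = st.alpha - prev_alpha
        if d_alpha > 0.0:
            acc += res.dH_dalpha * d_alpha
        dh_cum[idx] = acc
        prev_alpha = st.alpha
    return pd.DataFrame({"strain": strain, "H": h_vals, "delta_H_cum": dh_cum})
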
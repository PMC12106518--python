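"""Canonical-ensemble thermodynamics of the microcrack ensemble.

A material point carries a finite ensemble of crack configurations indexed
by the cracking number k = 1..N (total microcracking length / osteon
length). Each macrostate has energy E_k = k (1 - alpha) psi0 and microstate
multiplicity g_k = r^k (paths on the osteon lattice). With the
quenched-disorder parameter beta (1/MPa) the partition function is

    Z = sum_{k=1}^{N} r^k exp(-k beta (1 - alpha) psi0),

a truncated geometric series in q = r exp(-beta (1 - alpha) psi0), with a
removable singularity at q = 1. The strain-damage energy density (SDEDF)
is Psi = -(1/beta) ln Z; the crack-number distribution is the canonical
weight p_k = q^k / Z, with moments m1, m2 and Gibbs entropy

    H = -sum_k p_k (ln p_k - k ln r) = ln Z + beta m1 (1 - alpha) psi0.

The stress-correction factor Phi is the bracket
1/(1-q) - N q^N / (1 - q^N), numerically identical to m1; it decreases in
beta, which is why a larger quenched disorder (older bone) yields lower
stress at equal strain.

All sums are evaluated in log-space with a max shift, so large beta*psi0
or r^N cannot overflow.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError

#: |1 - q| below this is treated as the q = 1 removable singularity.
Q_SINGULAR_TOL = 1e-9


def _check_args(psi0: float, alpha: float, beta: float, r: float, N: int) -> None:
    if beta < 0.0:
        raise ValidationError(f"beta must be >= 0, got {beta}")
    if r <= 0.0:
        raise ValidationError(f"r must be > 0, got {r}")
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValidationError(f"N must be a positive integer, got {N!r}")
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must lie in [0, 1), got {alpha}")
    if psi0 < 0.0:
        raise ValidationError(f"psi0 must be >= 0, got {psi0}")


def _log_weights(psi0: float, alpha: float, beta: float, r: float, N: int) -> np.ndarray:
    """log of the unnormalized weights r^k e^{-k x}, x = beta (1-alpha) psi0."""
    k = np.arange(1, N + 1, dtype=float)
    x = beta * (1.0 - alpha) * psi0
    return k * (np.log(r) - x)


def partition_function(psi0: float, alpha: float, beta: float, r: float, N: int) -> float:
    """Z by direct (log-space) summation of the N canonical terms."""
    _check_args(psi0, alpha, beta, r, N)
    z = float(np.exp(logsumexp(_log_weights(psi0, alpha, beta, r, N))))
    if not np.isfinite(z):
        raise ValidationError("partition function overflowed even in log space")
    return z


def partition_function_closed(psi0: float, alpha: float, beta: float, r: float, N: int) -> float:
    """Z by the closed geometric form q (1 - q^N) / (1 - q), q = r e^{-x}.

    The removable singularity at q = 1 is handled by the limit Z = N.
    """
    _check_args(psi0, alpha, beta, r, N)
    x = beta * (1.0 - alpha) * psi0
    q = r * np.exp(-x)
    if abs(1.0 - q) < Q_SINGULAR_TOL:
        return float(N)
    return float(q * (1.0 - q ** N) / (1.0 - q))


def free_energy(psi0: float, alpha: float, beta: float, r: float, N: int) -> float:
    """SDEDF Psi = -(1/beta) ln Z, in MPa. Undefined at beta = 0."""
    if beta <= 0.0:
        raise ValidationError(f"free energy requires beta > 0, got {beta}")
    _check_args(psi0, alpha, beta, r, N)
    log_z = float(logsumexp(_log_weights(psi0, alpha, beta, r, N)))
    return -log_z / beta


class CrackDistribution(NamedTuple):
    p: np.ndarray  # canonical probabilities over k = 1..N
    m1: float      # mean cracking number E[k]
    m2: float      # second moment E[k^2]


def crack_distribution(psi0: float, alpha: float, beta: float, r: float, N: int) -> CrackDistribution:
    """Canonical distribution p_k = r^k e^{-k beta (1-alpha) psi0} / Z and moments."""
    _check_args(psi0, alpha, beta, r, N)
    logw = _log_weights(psi0, alpha, beta, r, N)
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    k = np.arange(1, N + 1, dtype=float)
    m1 = float(p @ k)
    m2 = float(p @ k ** 2)
    return CrackDistribution(p, m1, m2)


def mean_crack_number_closed(psi0: float, alpha: float, beta: float, r: float, N: int) -> float:
    """m1 via the closed bracket 1/(1-q) - N q^N / (1-q^N); limit (N+1)/2 at q = 1."""
    _check_args(psi0, alpha, beta, r, N)
    x = beta * (1.0 - alpha) * psi0
    q = r * np.exp(-x)
    if abs(1.0 - q) < Q_SINGULAR_TOL:
        return (N + 1) / 2.0
    return float(1.0 / (1.0 - q) - N * q ** N / (1.0 - q ** N))


class EntropyResult(NamedTuple):
    H: float               # dimensionless entropy (k_B = 1)
    dH_dalpha: float       # numeric central difference in alpha (ground truth)
    H_gibbs: float         # Gibbs form, for the two-formula consistency check


def _entropy_value(psi0: float, alpha: float, beta: float, r: float, N: int) -> float:
    """H = ln Z + beta <E> = beta^2 dPsi/dbeta evaluated analytically."""
    log_z = float(logsumexp(_log_weights(psi0, alpha, beta, r, N)))
    m1 = crack_distribution(psi0, alpha, beta, r, N).m1
    return log_z + beta * m1 * (1.0 - alpha) * psi0


def entropy(
    psi0: float, alpha: float, beta: float, r: float, N: int, *, dalpha: float = 1e-6
) -> EntropyResult:
    """Entropy of the crack ensemble and its numeric alpha-derivative.

    Computed two equivalent ways: thermodynamically, H = beta^2 dPsi/dbeta
    = ln Z + beta m1 (1-alpha) psi0, and statistically (Gibbs form,
    counting the r^k path multiplicity of each k):
    H = -sum_k p_k (ln p_k - k ln r). The two agree to ~1e-12.

    dH/dalpha is returned as a central finite difference; it is positive
    whenever psi0 > 0, beta > 0 and var(k) > 0, which is the
    thermodynamic-consistency claim (entropy grows with damage).
    """
    if beta <= 0.0:
        raise ValidationError(f"entropy requires beta > 0, got {beta}")
    _check_args(psi0, alpha, beta, r, N)
    h = _entropy_value(psi0, alpha, beta, r, N)

    dist = crack_distribution(psi0, alpha, beta, r, N)
    k = np.arange(1, N + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(dist.p > 0.0, np.log(np.where(dist.p > 0.0, dist.p, 1.0)), 0.0)
    h_gibbs = float(-(dist.p * (log_p - k * np.log(r))).sum())

    step = min(dalpha, (1.0 - alpha) / 2.0) if alpha + dalpha >= 1.0 else dalpha
    lo = max(alpha - step, 0.0)
    hi = alpha + step
    dh = (_entropy_value(psi0, hi, beta, r, N) - _entropy_value(psi0, lo, beta, r, N)) / (hi - lo)
    return EntropyResult(h, dh, h_gibbs)


class CorrectionFactor(NamedTuple):
    Phi: float
    dPhi_dbeta: float


def correction_factor(
    psi0: float, alpha: float, beta: float, r: float, N: int, *, dbeta_rel: float = 1e-6
) -> CorrectionFactor:
    """Stress-correction factor Phi and its beta-derivative.

    Phi is the closed bracket 1/(1-q) - N q^N/(1-q^N) (= m1 numerically);
    dPhi/dbeta is a central finite difference and is < 0 for all
    admissible states with psi0 > 0 (quenched disorder weakens the
    response), vanishing only in degenerate cases (N = 1 or psi0 = 0).
    """
    if beta <= 0.0:
        raise ValidationError(f"correction factor requires beta > 0, got {beta}")
    phi = mean_crack_number_closed(psi0, alpha, beta, r, N)
    db = beta * dbeta_rel
    dphi = (
        mean_crack_number_closed(psi0, alpha, beta + db, r, N)
        - mean_crack_number_closed(psi0, alpha, beta - db, r, N)
    ) / (2.0 * db)
    return CorrectionFactor(phi, dphi)


class StatmechState(NamedTuple):
    """All scalar ensemble quantities at one (psi0, alpha) state."""

    Z: float
    Psi: float
    p: np.ndarray
    m1: float
    m2: float
    H: float
    Phi: float


def statmech_state(psi0: float, alpha: float, beta: float, r: float, N: int) -> StatmechState:
    """Evaluate Z, Psi, p, m1, m2, H, Phi together."""
    dist = crack_distribution(psi0, alpha, beta, r, N)
    return StatmechState(
        Z=partition_function(psi0, alpha, beta, r, N),
        Psi=free_energy(psi0, alpha, beta, r, N),
        p=dist.p,
        m1=dist.m1,
        m2=dist.m2,
        H=entropy(psi0, alpha, beta, r, N).H,
        Phi=mean_crack_number_closed(psi0, alpha, beta, r, N),
    )
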
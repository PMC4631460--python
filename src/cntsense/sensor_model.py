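"""Stochastic occupancy model of a single-molecule adsorption sensor.

A nanotube sensor exposes ``NT`` equivalent binding sites to an analyte at
bulk concentration ``C`` [M].  Each empty site fills at rate ``kA*C`` and each
occupied site empties at rate ``kD``, so the occupancy count performs a
birth-death Markov chain on ``{0, ..., NT}`` — a monomolecular reaction
network whose chemical master equation (CME) admits a closed-form solution.

Over one sampling interval ``dt`` with ``C`` held constant, sites evolve
independently, so the count at the next sample conditioned on the previous
count ``y_prev`` is the convolution of two binomials::

    y_k ~ Binomial(y_prev, lamF) * Binomial(NT - y_prev, lamE)

where ``lamF`` is the probability an occupied site is still (or again)
occupied after ``dt`` and ``lamE`` the probability an empty site has become
occupied.  With ``a = kA*C + kD`` and ``rho = kA*C / a`` (the stationary
occupied fraction)::

    lamE = rho * (1 - exp(-a*dt))
    lamF = lamE + exp(-a*dt)

This module provides the exact transition kernel, the CME generator and its
matrix-exponential propagation (the oracle for the kernel), the deterministic
continuum (mean-field) update, and the moment-matched Gaussian approximation
used by the Kalman filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import comb

__all__ = [
    "SensorParams",
    "OccupancyFractions",
    "ObsMoments",
    "occupancy_fractions",
    "occupancy_fraction_arrays",
    "occupancy_fraction_derivatives",
    "continuum_update",
    "transition_pmf",
    "cme_generator",
    "cme_propagate",
    "stationary_dist",
    "gaussian_obs_moments",
    "count_loglik",
]

#: Log-density cap substituted for the +inf spike of a zero-variance Gaussian
#: observation that exactly matches its mean.
GAUSSIAN_LOGLIK_CAP = 700.0


@dataclass(frozen=True)
class SensorParams:
    """Kinetic constants and geometry of one sensor.

    Parameters
    ----------
    kA : float
        Adsorption rate prefactor [M^-1 s^-1]; the effective adsorption rate
        constant is ``kA * C`` for bulk concentration ``C``.
    kD : float
        Desorption rate constant [s^-1].
    NT : int
        Total number of adsorption sites (>= 1).
    dt : float
        Sampling interval [s].
    """

    kA: float
    kD: float
    NT: int
    dt: float

    def __post_init__(self) -> None:
        if not self.kA > 0:
            raise ValueError(f"kA must be positive, got {self.kA}")
        if self.kD < 0:
            raise ValueError(f"kD must be nonnegative, got {self.kD}")
        if not (isinstance(self.NT, (int, np.integer)) and self.NT >= 1):
            raise ValueError(f"NT must be a positive integer, got {self.NT}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def stationary_fraction(self, C: float) -> float:
        """Stationary occupied fraction kA*C / (kA*C + kD)."""
        a = self.kA * C + self.kD
        if a == 0.0:
            return 0.0
        return self.kA * C / a


@dataclass(frozen=True)
class OccupancyFractions:
    """One-interval site transition probabilities.

    ``lamF`` is the survival probability of an occupied site, ``lamE`` the
    fill probability of an empty site.  Always ``0 <= lamE <= lamF <= 1``
    and ``lamF - lamE = exp(-(kA*C + kD)*dt)``.
    """

    lamF: float
    lamE: float


@dataclass(frozen=True)
class ObsMoments:
    """Moments of the Gaussian approximation to the transition kernel.

    The occupied-subset binomial contributes ``(muF, varF)`` and the
    empty-subset binomial ``(muE, varE)``; their convolution has mean
    ``muF + muE`` and variance ``varF + varE``.  Moment matching is exact
    for binomials, so ``mean``/``var`` equal the exact kernel's first two
    moments.
    """

    muF: float
    varF: float
    muE: float
    varE: float

    @property
    def mean(self) -> float:
        return self.muF + self.muE

    @property
    def var(self) -> float:
        return self.varF + self.varE


def _check_conc(C: float) -> None:
    if C < 0:
        raise ValueError(f"concentration must be nonnegative, got {C}")


def _check_count(params: SensorParams, y: int, name: str = "count") -> None:
    if not float(y).is_integer():
        raise ValueError(f"{name} must be an integer, got {y}")
    if not 0 <= y <= params.NT:
        raise ValueError(f"{name} must lie in [0, {params.NT}], got {y}")


def occupancy_fraction_arrays(
    params: SensorParams, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (lamF, lamE) over an array of concentrations.

    Uses ``lamE = rho*(1 - E)``, ``lamF = lamE + E`` with ``E = exp(-a*dt)``,
    which is finite and accurate down to C = 0 (no 0/0 branch needed unless
    both C = 0 and kD = 0, where the kernel is the identity).
    """
    C = np.asarray(C, dtype=float)
    a = params.kA * C + params.kD
    E = np.exp(-a * params.dt)
    with np.errstate(invalid="ignore"):
        rho = np.where(a > 0.0, params.kA * C / np.where(a > 0.0, a, 1.0), 0.0)
    lamE = rho * (1.0 - E)
    lamF = lamE + E
    return lamF, lamE


def occupancy_fractions(params: SensorParams, C: float) -> OccupancyFractions:
    """One-interval occupied-site survival and empty-site fill probabilities."""
    _check_conc(C)
    lamF, lamE = occupancy_fraction_arrays(params, np.asarray(C))
    return OccupancyFractions(lamF=float(lamF), lamE=float(lamE))


def occupancy_fraction_derivatives(
    params: SensorParams, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic d(lamF)/dC and d(lamE)/dC, vectorized over C.

    With a = kA*C + kD, E = exp(-a*dt), rho = kA*C/a:

        dlamE/dC = kA*kD*(1-E)/a**2 + rho*kA*dt*E
        dlamF/dC = dlamE/dC - kA*dt*E

    For kD = 0 (rho = 1, lamF = 1): dlamE/dC = kA*dt*E, dlamF/dC = 0.
    """
    C = np.asarray(C, dtype=float)
    kA, kD, dt = params.kA, params.kD, params.dt
    a = kA * C + kD
    E = np.exp(-a * dt)
    if kD == 0.0:
        dlamE = kA * dt * E
        dlamF = np.zeros_like(dlamE)
        return dlamF, dlamE
    rho = kA * C / a
    dlamE = kA * kD * (1.0 - E) / a**2 + rho * kA * dt * E
    dlamF = dlamE - kA * dt * E
    return dlamF, dlamE


def continuum_update(params: SensorParams, N_prev: float, C: float) -> float:
    """Mean-field occupancy after one interval from a (real) previous count.

    This is the exact solution of dN/dt = kA*C*(NT - N) - kD*N over ``dt``
    with C constant, written as ``N_prev*lamF + (NT - N_prev)*lamE`` — which
    is also the exact conditional mean of the stochastic kernel.
    """
    _check_conc(C)
    if not 0 <= N_prev <= params.NT:
        raise ValueError(f"N_prev must lie in [0, {params.NT}], got {N_prev}")
    lam = occupancy_fractions(params, C)
    out = N_prev * lam.lamF + (params.NT - N_prev) * lam.lamE
    return float(min(max(out, 0.0), params.NT))


def transition_pmf(params: SensorParams, y_prev: int, C: float) -> np.ndarray:
    """Exact one-interval conditional pmf of the occupancy count.

    Returns a length ``NT + 1`` probability vector: the convolution of
    ``Binomial(y_prev, lamF)`` with ``Binomial(NT - y_prev, lamE)``.
    """
    _check_conc(C)
    _check_count(params, y_prev, "y_prev")
    y_prev = int(y_prev)
    lam = occupancy_fractions(params, C)
    pmf_f = _binom_pmf_vector(y_prev, lam.lamF)
    pmf_e = _binom_pmf_vector(params.NT - y_prev, lam.lamE)
    pmf = np.convolve(pmf_f, pmf_e)
    # guard against tiny negative round-off before renormalizing
    pmf = np.clip(pmf, 0.0, None)
    return pmf / pmf.sum()


def _binom_pmf_vector(n: int, p: float) -> np.ndarray:
    """Binomial(n, p) pmf over {0..n} without scipy.stats overhead."""
    if n == 0:
        return np.ones(1)
    k = np.arange(n + 1)
    coef = comb(n, k)
    if p == 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p == 1.0:
        out = np.zeros(n + 1)
        out[-1] = 1.0
        return out
    logpmf = np.log(coef) + k * math.log(p) + (n - k) * math.log1p(-p)
    return np.exp(logpmf)


def cme_generator(params: SensorParams, C: float) -> np.ndarray:
    """Tridiagonal CME generator G with dP/dt = G @ P over states {0..NT}.

    Column j holds the outflow of state j (diagonal) and its inflows to the
    neighbours: adsorption j -> j+1 at rate ``kA*C*(NT - j)`` and desorption
    j -> j-1 at rate ``kD*j``.
    """
    _check_conc(C)
    n = params.NT + 1
    j = np.arange(n)
    ads = params.kA * C * (params.NT - j)  # rate j -> j+1
    des = params.kD * j  # rate j -> j-1
    G = np.zeros((n, n))
    G[j, j] = -(ads + des)
    G[j[1:], j[:-1]] = ads[:-1]
    G[j[:-1], j[1:]] = des[1:]
    return G


def cme_propagate(
    params: SensorParams, init: np.ndarray, C: float, duration: float
) -> np.ndarray:
    """Propagate an occupancy distribution through the CME for ``duration``.

    Matrix exponential of the tridiagonal generator; exact at the NT <= ~50
    sizes this sensor model targets.  Serves as the independent oracle for
    :func:`transition_pmf`.
    """
    _check_conc(C)
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    init = np.asarray(init, dtype=float)
    if init.shape != (params.NT + 1,):
        raise ValueError(f"init must have shape ({params.NT + 1},)")
    if np.any(init < -1e-12) or abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("init must be a normalized probability vector")
    if duration == 0:
        return init.copy()
    P = expm(cme_generator(params, C) * duration) @ init
    P = np.clip(P, 0.0, None)
    return P / P.sum()


def stationary_dist(params: SensorParams, C: float) -> np.ndarray:
    """Stationary occupancy law: Binomial(NT, kA*C/(kA*C + kD))."""
    _check_conc(C)
    return _binom_pmf_vector(params.NT, params.stationary_fraction(C))


def gaussian_obs_moments(params: SensorParams, y_prev: int, C: float) -> ObsMoments:
    """Moment-matched Gaussian approximation of the transition kernel.

    Each binomial factor is replaced by a normal with the same mean and
    variance; their convolution is normal with summed means and variances.
    """
    _check_conc(C)
    _check_count(params, y_prev, "y_prev")
    y_prev = int(y_prev)
    lam = occupancy_fractions(params, C)
    nE = params.NT - y_prev
    return ObsMoments(
        muF=y_prev * lam.lamF,
        varF=y_prev * lam.lamF * (1.0 - lam.lamF),
        muE=nE * lam.lamE,
        varE=nE * lam.lamE * (1.0 - lam.lamE),
    )


def count_loglik(
    params: SensorParams,
    y: int,
    y_prev: int,
    C: float,
    mode: str = "exact",
) -> float:
    """Log-likelihood of observing count ``y`` after ``y_prev`` at concentration C.

    mode="exact" evaluates the convolved-binomial kernel; mode="gaussian"
    evaluates the continuous normal density of the moment-matched
    approximation at the integer ``y`` (no continuity correction).  A
    zero-variance Gaussian returns ``-inf`` off the mean and a large finite
    cap (:data:`GAUSSIAN_LOGLIK_CAP`) on it.
    """
    _check_count(params, y, "y")
    if mode == "exact":
        p = transition_pmf(params, y_prev, C)[int(y)]
        return float(np.log(p)) if p > 0 else -np.inf
    if mode == "gaussian":
        m = gaussian_obs_moments(params, y_prev, C)
        if m.var == 0.0:
            return GAUSSIAN_LOGLIK_CAP if y == m.mean else -np.inf
        return float(
            -0.5 * (math.log(2.0 * math.pi * m.var) + (y - m.mean) ** 2 / m.var)
        )
    raise ValueError(f"mode must be 'exact' or 'gaussian', got {mode!r}")
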
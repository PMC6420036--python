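"""Long-term growth of the structured model: spectral bounds, stationary
copy-number distributions, persistence in switching environments, and
forward integration of the reduced linear system.

The plasmid-bearing block ``y' = A y`` is linear with constant coefficients,
so its long-term growth rate is the spectral bound ``lambda1`` of ``A`` (the
eigenvalue of largest real part), which is real with a positive eigenvector
``y_hat`` by Perron-Frobenius.  The plasmid-free line grows at the
time-averaged rate ``lambda0_bar = (1 - phi)*beta0 - phi*mu0`` where ``phi``
is the fraction of time with antibiotics.  The plasmid persists in the
population iff ``lambda0_bar < lambda1``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import linalg

from .core import (
    EnvironmentSchedule,
    GeneratorSystem,
    ModelParameters,
    SegregationStrategy,
    build_generator,
)

__all__ = [
    "SpectralResult",
    "StationaryDistribution",
    "PersistenceVerdict",
    "Trajectory",
    "DaughterLoads",
    "spectral_bound",
    "stationary_distribution",
    "plasmid_free_growth",
    "persistence_check",
    "integrate_population",
    "expected_daughter_loads",
    "local_maxima",
]


@dataclasses.dataclass(frozen=True)
class SpectralResult:
    """Dominant eigenpair of the plasmid-bearing generator.

    ``lambda1`` is the spectral bound (per hour); ``y_hat`` the positive
    right eigenvector normalised to sum 1 (the asymptotic copy-number
    distribution); ``w_hat`` the matching left eigenvector (used for
    eigenvalue sensitivities), scaled so that ``w_hat @ y_hat = 1``.
    """

    lambda1: float
    y_hat: np.ndarray
    w_hat: np.ndarray
    residual: float

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "residual": self.residual,
            "y_hat": self.y_hat.tolist(),
        }


def spectral_bound(system: GeneratorSystem) -> SpectralResult:
    """Dominant eigenpair of ``A`` by dense eigendecomposition.

    The sizes here (z_hat <= a few hundred) make the dense solver both the
    fastest and the most robust choice.  Raises if the dominant eigenvalue
    has a non-negligible imaginary part or the residual is large.
    """
    A = system.A
    lam, vl, vr = linalg.eig(A, left=True, right=True)
    idx = int(np.argmax(lam.real))
    lam1 = lam[idx]
    if abs(lam1.imag) > 1e-8 * max(1.0, abs(lam1.real)):
        raise ArithmeticError(f"dominant eigenvalue not real: {lam1}")
    v = vr[:, idx].real
    w = vl[:, idx].real
    # orient positively: Perron vector has one sign
    if v.sum() < 0:
        v = -v
    if w.sum() < 0:
        w = -w
    v = np.clip(v, 0.0, None)
    s = v.sum()
    if s <= 0:
        raise ArithmeticError("degenerate dominant eigenvector")
    v = v / s
    wv = float(w @ v)
    if wv == 0:
        raise ArithmeticError("left/right eigenvector pairing degenerate")
    w = w / wv
    residual = float(np.linalg.norm(A @ v - lam1.real * v, ord=np.inf))
    return SpectralResult(lambda1=float(lam1.real), y_hat=v, w_hat=w, residual=residual)


def local_maxima(y: np.ndarray) -> list[int]:
    """Strict local maxima of a vector indexed by z = 1..len(y).

    Boundary states count with a one-sided comparison.  Returns copy
    numbers (1-based), ascending.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    out = []
    for i in range(n):
        left_ok = i == 0 or y[i] > y[i - 1]
        right_ok = i == n - 1 or y[i] > y[i + 1]
        if left_ok and right_ok:
            out.append(i + 1)
    return out


@dataclasses.dataclass(frozen=True)
class StationaryDistribution:
    """Asymptotic copy-number distribution of the plasmid-bearing block."""

    z: np.ndarray
    density: np.ndarray
    modes: list[int]
    lambda1: float

    @property
    def mean(self) -> float:
        return float(self.z @ self.density)


def stationary_distribution(
    params: ModelParameters, strategy: SegregationStrategy
) -> StationaryDistribution:
    """Normalised dominant eigenvector over z = 1..z_hat with its local maxima."""
    res = spectral_bound(build_generator(params, strategy))
    z = np.arange(1, params.z_hat + 1)
    return StationaryDistribution(
        z=z, density=res.y_hat, modes=local_maxima(res.y_hat), lambda1=res.lambda1
    )


def plasmid_free_growth(schedule: EnvironmentSchedule, params: ModelParameters) -> float:
    """Time-averaged growth rate of the plasmid-free line over one period:
    lambda0_bar = (1 - phi)*beta0 - phi*mu0."""
    phi = schedule.antibiotic_fraction
    return (1.0 - phi) * params.beta0 - phi * params.mu0


@dataclasses.dataclass(frozen=True)
class PersistenceVerdict:
    """Outcome of the persistence dichotomy.

    The plasmid is lost iff the plasmid-free line outgrows the
    plasmid-bearing block (lambda0_bar > lambda1); it persists iff
    lambda0_bar < lambda1; within ``tol`` the case is marginal.
    """

    lambda0_bar: float
    lambda1: float
    verdict: str

    @property
    def margin(self) -> float:
        return self.lambda1 - self.lambda0_bar


def persistence_check(
    schedule: EnvironmentSchedule,
    params: ModelParameters,
    strategy: SegregationStrategy,
    tol: float = 1e-6,
) -> PersistenceVerdict:
    lam0 = plasmid_free_growth(schedule, params)
    lam1 = spectral_bound(build_generator(params, strategy)).lambda1
    if abs(lam1 - lam0) < tol:
        verdict = "marginal"
    elif lam0 > lam1:
        verdict = "lost"
    else:
        verdict = "persists"
    return PersistenceVerdict(lambda0_bar=lam0, lambda1=lam1, verdict=verdict)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Deterministic trajectory of (x0(t), y(t))."""

    t: np.ndarray
    x0: np.ndarray
    y: np.ndarray  # shape (len(t), z_hat)

    @property
    def plasmid_bearing_total(self) -> np.ndarray:
        return self.y.sum(axis=1)

    @property
    def plasmid_bearing_fraction(self) -> np.ndarray:
        tot = self.x0 + self.plasmid_bearing_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.plasmid_bearing_total / tot, 0.0)


def integrate_population(
    params: ModelParameters,
    strategy: SegregationStrategy,
    schedule: EnvironmentSchedule,
    x0_init: float,
    y_init: Sequence[float],
    t_end: float,
    n_out: int = 201,
) -> Trajectory:
    """Integrate x0' = (beta(0,a) - mu(0,a)) x0 + B@y,  y' = A y.

    alpha(t) is piecewise constant, so each piece is propagated exactly with
    a matrix exponential of the full (z_hat+1) block system; output times are
    a uniform grid refined with the segment boundaries.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y_init = np.asarray(y_init, dtype=float)
    if y_init.shape != (params.z_hat,):
        raise ValueError("y_init must have length z_hat")
    if x0_init < 0 or np.any(y_init < 0):
        raise ValueError("initial state must be non-negative")
    sys = build_generator(params, strategy)
    zh = params.z_hat

    def block(alpha: int) -> np.ndarray:
        M = np.zeros((zh + 1, zh + 1))
        lam0 = (params.beta0 if alpha == 0 else 0.0) - (params.mu0 if alpha == 1 else 0.0)
        M[0, 0] = lam0
        M[0, 1:] = sys.B
        M[1:, 1:] = sys.A
        return M

    M = {0: block(0), 1: block(1)}
    grid = np.linspace(0.0, t_end, n_out)
    times = [0.0]
    states = [np.concatenate([[x0_init], y_init])]
    state = states[0]
    t = 0.0
    gi = 1  # next output grid index
    for t0, t1, alpha in schedule.iter_segments(t_end):
        # output points that fall inside this segment
        while gi < n_out and grid[gi] <= t1 + 1e-12:
            dt = grid[gi] - t
            if dt > 0:
                state = linalg.expm(M[alpha] * dt) @ state
                t = grid[gi]
            times.append(t)
            states.append(state)
            gi += 1
        if t1 - t > 1e-12:
            state = linalg.expm(M[alpha] * (t1 - t)) @ state
            t = t1
    arr = np.asarray(states)
    # exact propagation can undershoot zero by rounding only
    arr = np.clip(arr, 0.0, None)
    return Trajectory(t=np.asarray(times), x0=arr[:, 0], y=arr[:, 1:])


@dataclasses.dataclass(frozen=True)
class DaughterLoads:
    """Expected plasmid loads of the two daughters of a mother with z0.

    ``lower``/``higher`` follow the role convention: the selected daughter
    receives ``p*z0`` in expectation, the other ``(1-p)*z0`` (with p
    canonicalised to [0, 0.5] the selected daughter is the lower one).
    ``order_lower``/``order_higher`` are the exact means of
    min(Z, z0-Z) and max(Z, z0-Z) with Z ~ Binomial(z0, p).
    """

    lower: float
    higher: float
    order_lower: float
    order_higher: float


def expected_daughter_loads(strategy: SegregationStrategy, z0: int) -> DaughterLoads:
    if not 1 <= z0 <= strategy.z_hat:
        raise ValueError(f"z0 must lie in 1..{strategy.z_hat}")
    p = strategy.p_of(z0)
    from .core import binomial_pmf

    g = binomial_pmf(z0, p)
    k = np.arange(z0 + 1)
    mn = float(np.minimum(k, z0 - k) @ g)
    mx = float(np.maximum(k, z0 - k) @ g)
    return DaughterLoads(
        lower=p * z0, higher=(1.0 - p) * z0, order_lower=mn, order_higher=mx
    )
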
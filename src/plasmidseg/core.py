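"""Copy-number-structured model of a bacterial population carrying a
high-copy plasmid.

A cell is characterised by its plasmid copy number ``z`` (an integer between
0 and the carrying capacity ``z_hat``).  Plasmids replicate inside a cell as a
logistic birth process at rate ``b*z*(1 - z/z_hat)``.  Cells divide at a rate
that decreases linearly with the metabolic burden of the plasmid load,
``beta0*(1 - c*z/z_hat)+``, and at division the plasmids are partitioned
between the two daughters by a binomial draw whose success probability
``p_z`` may depend on the mother's copy number — the *segregation strategy*.
Plasmid-free cells die at rate ``mu0`` when antibiotics are present and are
otherwise unaffected; plasmid-bearing cells are resistant.

This module holds the parameter containers, the elementary rates, the
binomial segregation kernel, and the assembly of the linear generator

    x0' = (beta(0, alpha) - mu(0, alpha)) * x0 + B @ y
    y'  = A @ y

where ``y`` is the vector of plasmid-bearing abundances over ``z = 1..z_hat``,
``x0`` is the plasmid-free abundance, ``A`` is the generator of the
plasmid-bearing block and ``B`` collects the flux of plasmid-free daughters
produced by plasmid-bearing mothers.  ``A`` and ``B`` depend on the
segregation strategy but not on the environment.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = [
    "ModelParameters",
    "SegregationStrategy",
    "EnvironmentSchedule",
    "GeneratorSystem",
    "division_rate",
    "death_rate",
    "plasmid_birth_rate",
    "segregation_pmf",
    "segregation_kernel",
    "kernel_weights",
    "binomial_pmf",
    "binomial_pmf_derivative",
    "build_generator",
    "per_plasmid_burden_percent",
]


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Rates and copy-number cap of the structured model.

    Parameters
    ----------
    z_hat : int
        Maximal plasmid copy number per cell (carrying capacity), >= 2
        for a non-degenerate model (1 is allowed as an edge case).
    b : float
        Logistic plasmid replication parameter, per hour.
    beta0 : float
        Maximal bacterial division rate (plasmid-free, no antibiotics),
        per hour.
    mu0 : float
        Death rate of plasmid-free cells under antibiotics, per hour.
    burden_scale : float
        Dimensionless factor ``c`` in ``beta(z) = beta0*(1 - c*z/z_hat)+``
        scaling the metabolic burden of the plasmid load on division.
        ``c = 1`` (default) makes division stop exactly at ``z = z_hat``;
        ``c = 0`` removes the burden entirely.
    """

    z_hat: int = 50
    b: float = 1.2
    beta0: float = 1.0
    mu0: float = 5.0
    burden_scale: float = 1.0

    def __post_init__(self) -> None:
        if int(self.z_hat) != self.z_hat or self.z_hat < 1:
            raise ValueError(f"z_hat must be a positive integer, got {self.z_hat}")
        object.__setattr__(self, "z_hat", int(self.z_hat))
        for name in ("b", "beta0", "mu0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.burden_scale <= 1.0:
            raise ValueError("burden_scale must lie in [0, 1]")

    # vectorised views over z = 1..z_hat (index z-1) ---------------------
    def division_rates(self) -> np.ndarray:
        """beta(z) for z = 1..z_hat (environment independent for z >= 1)."""
        z = np.arange(1, self.z_hat + 1, dtype=float)
        return self.beta0 * np.clip(1.0 - self.burden_scale * z / self.z_hat, 0.0, None)

    def plasmid_birth_rates(self) -> np.ndarray:
        """b*z*(1 - z/z_hat) for z = 1..z_hat."""
        z = np.arange(1, self.z_hat + 1, dtype=float)
        return self.b * z * (1.0 - z / self.z_hat)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


def _check_z(z: int, z_hat: int) -> int:
    if int(z) != z:
        raise ValueError(f"copy number must be an integer, got {z}")
    z = int(z)
    if not 0 <= z <= z_hat:
        raise ValueError(f"copy number {z} outside [0, {z_hat}]")
    return z


def division_rate(z: int, alpha: int, params: ModelParameters) -> float:
    """Bacterial division rate beta(z, alpha), per hour.

    Plasmid-free cells (z=0) divide at ``beta0`` without antibiotics and not
    at all under antibiotics.  Plasmid-bearing cells are resistant and divide
    at ``beta0*(1 - c*z/z_hat)+`` in either environment.
    """
    z = _check_z(z, params.z_hat)
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 or 1")
    if z == 0:
        return params.beta0 if alpha == 0 else 0.0
    return params.beta0 * max(0.0, 1.0 - params.burden_scale * z / params.z_hat)


def death_rate(z: int, alpha: int, params: ModelParameters) -> float:
    """Death rate mu(z, alpha): only plasmid-free cells under antibiotics die."""
    z = _check_z(z, params.z_hat)
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 or 1")
    return params.mu0 if (z == 0 and alpha == 1) else 0.0


def plasmid_birth_rate(z: int, params: ModelParameters) -> float:
    """Within-cell plasmid replication rate b*z*(1 - z/z_hat), per hour."""
    z = _check_z(z, params.z_hat)
    return params.b * z * (1.0 - z / params.z_hat)


def per_plasmid_burden_percent(params: ModelParameters) -> float:
    """Fitness (division-rate) reduction per plasmid, in percent.

    With the linear burden ``beta(z) = beta0*(1 - c*z/z_hat)`` each plasmid
    lowers the division rate by ``100*c/z_hat`` percent of ``beta0``:
    2% at z_hat=50, 0.125% at z_hat=800 (for c=1).
    """
    return 100.0 * params.burden_scale / params.z_hat


@dataclasses.dataclass(frozen=True)
class SegregationStrategy:
    """Segregation probabilities ``p_z`` for mothers with z = 1..z_hat plasmids.

    ``p_z`` is the probability that each plasmid of a dividing mother moves
    into one randomly selected daughter.  The segregation kernel is invariant
    under ``p -> 1 - p``, so strategies are canonicalised to ``[0, 0.5]``:
    entries above 0.5 are reflected (with a warning).
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float).copy()
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a 1-d vector of length z_hat")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("segregation probabilities must lie in [0, 1]")
        if np.any(p > 0.5):
            warnings.warn(
                "segregation probabilities above 0.5 reflected to 1-p "
                "(the kernel is symmetric under p <-> 1-p)",
                stacklevel=2,
            )
            p = np.minimum(p, 1.0 - p)
        p.setflags(write=False)
        object.__setattr__(self, "p", p)

    @property
    def z_hat(self) -> int:
        return self.p.size

    def p_of(self, z0: int) -> float:
        """Probability for a mother with z0 plasmids (z0 in 1..z_hat)."""
        z0 = _check_z(z0, self.z_hat)
        if z0 == 0:
            raise ValueError("segregation is defined for mothers with z0 >= 1")
        return float(self.p[z0 - 1])

    @classmethod
    def uniform(cls, z_hat: int, value: float = 0.5) -> "SegregationStrategy":
        return cls(np.full(int(z_hat), float(value)))

    def with_value(self, z0: int, value: float) -> "SegregationStrategy":
        p = self.p.copy()
        p[z0 - 1] = value
        return SegregationStrategy(p)


@dataclasses.dataclass(frozen=True)
class EnvironmentSchedule:
    """Periodic antibiotic schedule alpha(t) in {0, 1}.

    ``segments`` is an ordered tuple of ``(duration_hours, alpha)`` repeated
    periodically.  ``antibiotic_fraction`` is the fraction of the period with
    alpha = 1.
    """

    segments: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(d), int(a)) for d, a in self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        for d, a in segs:
            if d <= 0:
                raise ValueError("segment durations must be positive")
            if a not in (0, 1):
                raise ValueError("alpha must be 0 or 1")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, alpha: int) -> "EnvironmentSchedule":
        return cls(((1.0, int(alpha)),))

    @classmethod
    def periodic(cls, on_hours: float, off_hours: float) -> "EnvironmentSchedule":
        """off_hours without antibiotics followed by on_hours with them."""
        return cls(((float(off_hours), 0), (float(on_hours), 1)))

    @property
    def period(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def antibiotic_fraction(self) -> float:
        return sum(d for d, a in self.segments if a == 1) / self.period

    def alpha_at(self, t: float) -> int:
        tau = float(t) % self.period
        for d, a in self.segments:
            if tau < d:
                return a
            tau -= d
        return self.segments[-1][1]

    def iter_segments(self, t_end: float) -> Iterable[tuple[float, float, int]]:
        """Yield (t_start, t_stop, alpha) pieces covering [0, t_end]."""
        t = 0.0
        while t < t_end:
            for d, a in self.segments:
                if t >= t_end:
                    return
                stop = min(t + d, t_end)
                yield t, stop, a
                t = stop


# ----------------------------------------------------------------------
# binomial segregation kernel
# ----------------------------------------------------------------------

def binomial_pmf(z0: int, p: float) -> np.ndarray:
    """Binomial(z0, p) pmf over z = 0..z0 (computed in log space by scipy)."""
    return stats.binom.pmf(np.arange(z0 + 1), z0, p)


def binomial_pmf_derivative(z0: int, p: float) -> np.ndarray:
    """d/dp of the Binomial(z0, p) pmf over z = 0..z0.

    Uses the exact shift identity d/dp g(z; z0, p) =
    z0 * (g(z-1; z0-1, p) - g(z; z0-1, p)), valid at p = 0 and 1.
    """
    if z0 == 0:
        return np.zeros(1)
    g = stats.binom.pmf(np.arange(z0), z0 - 1, p)
    out = np.empty(z0 + 1)
    out[0] = -z0 * g[0]
    out[z0] = z0 * g[z0 - 1]
    if z0 > 1:
        out[1:z0] = z0 * (g[0 : z0 - 1] - g[1:z0])
    return out


def segregation_pmf(z: int, z0: int, p: float) -> float:
    """Probability that the selected daughter of a mother with z0 plasmids
    inherits exactly z of them: Binomial(z0, p) mass at z."""
    if int(z0) != z0 or z0 < 0:
        raise ValueError("z0 must be a non-negative integer")
    if int(z) != z or z < 0 or z > z0:
        raise ValueError(f"daughter copy number {z} outside [0, {z0}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(stats.binom.pmf(int(z), int(z0), p))


def kernel_weights(z0: int, p: float) -> np.ndarray:
    """Segregation kernel k(z; z0) = g(z; z0) + g(z0-z; z0) over z = 0..z0.

    Total mass is 2 (one mother yields two daughters) and the kernel is
    symmetric, k(z; z0) = k(z0-z; z0).
    """
    g = binomial_pmf(z0, p)
    return g + g[::-1]


def segregation_kernel(z: int, z0: int, strategy: "SegregationStrategy | float") -> float:
    """Kernel weight k(z; z0) for one daughter copy number z of a mother z0.

    ``strategy`` may be a :class:`SegregationStrategy` (p taken at z0) or a
    bare probability.
    """
    if z0 < 1:
        raise ValueError("mothers must carry at least one plasmid (z0 >= 1)")
    p = strategy.p_of(z0) if isinstance(strategy, SegregationStrategy) else float(strategy)
    return segregation_pmf(z, z0, p) + segregation_pmf(z0 - z, z0, p)


# ----------------------------------------------------------------------
# generator assembly
# ----------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneratorSystem:
    """The reduced linear system for the plasmid-bearing block.

    ``A`` is the (z_hat x z_hat) generator over z = 1..z_hat with
    non-negative off-diagonal entries; ``B`` is the per-capita flux of
    plasmid-free daughters, B_z0 = k(0; z0)*beta(z0).  Mass balance holds
    column-wise: column_sum(A)_z + B_z = beta(z).
    """

    A: np.ndarray
    B: np.ndarray
    params: ModelParameters
    strategy: SegregationStrategy

    @property
    def z_hat(self) -> int:
        return self.params.z_hat

    def beta(self) -> np.ndarray:
        return self.params.division_rates()


def _assemble(params: ModelParameters, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (A, B) from a raw probability vector (no canonicalisation).

    Used internally by the optimiser, which needs lambda1 as a smooth
    function of p on [0, 1].
    """
    zh = params.z_hat
    beta = params.division_rates()
    birth = params.plasmid_birth_rates()
    A = np.zeros((zh, zh))
    B = np.empty(zh)
    # logistic plasmid replication: loss on the diagonal, gain one state up
    A[np.arange(zh), np.arange(zh)] -= birth
    if zh > 1:
        A[np.arange(1, zh), np.arange(zh - 1)] += birth[:-1]
    for z0 in range(1, zh + 1):
        col = z0 - 1
        A[col, col] -= beta[col]
        k = kernel_weights(z0, p[col])  # over daughter z = 0..z0
        B[col] = k[0] * beta[col]
        A[0:z0, col] += k[1 : z0 + 1] * beta[col]
    return A, B


def build_generator(params: ModelParameters, strategy: SegregationStrategy) -> GeneratorSystem:
    """Assemble the generator ``A`` and plasmid-loss flux ``B``.

    For each mother state z0, division at rate beta(z0) removes the mother
    (diagonal) and adds two daughters distributed by the segregation kernel;
    daughters with z = 0 leave the plasmid-bearing block through ``B``.
    Plasmid replication moves cells one state up at rate b*z*(1 - z/z_hat).
    """
    if strategy.z_hat != params.z_hat:
        raise ValueError(
            f"strategy length {strategy.z_hat} does not match z_hat {params.z_hat}"
        )
    A, B = _assemble(params, np.asarray(strategy.p))
    return GeneratorSystem(A=A, B=B, params=params, strategy=strategy)
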
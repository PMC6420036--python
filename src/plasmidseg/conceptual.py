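"""Closed-form two-generation model of plasmid segregation.

A deterministic caricature of the full structured model that isolates the
two forces shaping the optimal strategy.  A newborn cell with ``z0``
plasmids divides after the deterministic time ``T(z0) = 1/(beta0*(1 -
z0/z_hat))``; during its cycle the plasmid load grows logistically,
reaching ``F(z0) = z(T(z0))`` just before division.  Splitting the load
with asymmetry ``a`` (one daughter gets ``(1+a)F/2``, the other
``(1-a)F/2``):

* the burden alone is linear in the load, so the first-generation average
  fitness is independent of ``a`` — but, because ``F`` is concave, the
  second-generation average fitness strictly increases with ``a``
  (asymmetry pays once plasmids are merely a burden);
* plasmids also protect against antibiotics.  Weighting each daughter's
  fitness by the saturating protection factor ``q(z) = z/(K + z)`` makes
  the first-generation average fitness strictly decrease in ``a``
  (asymmetry risks leaving a daughter unprotected).

Copy numbers are treated as continuous here; the trade-off between the two
effects is what the full eigenvalue optimisation resolves generation by
generation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ConceptualParams",
    "fitness_f0",
    "division_time",
    "end_of_cycle_load",
    "daughter_fitnesses",
    "gen2_average_fitness",
    "protection_factor",
    "protected_gen1_fitness",
    "tabulate",
]


@dataclasses.dataclass(frozen=True)
class ConceptualParams:
    """Parameters of the two-generation model.

    ``beta0`` and ``b`` in per hour, ``z_hat`` the plasmid carrying
    capacity, ``K`` the copy number at which the protection factor reaches
    one half.
    """

    beta0: float = 1.0
    b: float = 1.0
    z_hat: float = 50.0
    K: float = 5.0

    def __post_init__(self) -> None:
        if self.beta0 <= 0 or self.b < 0:
            raise ValueError("beta0 must be positive and b non-negative")
        if self.z_hat <= 0:
            raise ValueError("z_hat must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")


def _check_z0(z0: float, params: ConceptualParams, *, strict: bool = False) -> float:
    z0 = float(z0)
    hi = params.z_hat
    if z0 < 0 or z0 > hi or (strict and z0 == hi):
        raise ValueError(f"z0 = {z0} outside the valid range [0, {hi}{')' if strict else ']'}")
    return z0


def fitness_f0(z0: float, params: ConceptualParams) -> float:
    """Division rate (= fitness) of a newborn with z0 plasmids:
    beta0*(1 - z0/z_hat), per hour."""
    z0 = _check_z0(z0, params)
    return params.beta0 * (1.0 - z0 / params.z_hat)


def division_time(z0: float, params: ConceptualParams) -> float:
    """Deterministic time to the next division, T(z0) = 1/f0(z0), hours."""
    z0 = _check_z0(z0, params, strict=True)
    return 1.0 / fitness_f0(z0, params)


def end_of_cycle_load(z0: float, params: ConceptualParams) -> float:
    """Plasmid load just before division: the logistic solution at T(z0),

        F(z0) = z0*z_hat / (z0 + (z_hat - z0)*exp(-(b/beta0)/(1 - z0/z_hat))).

    F(0) = 0, F is concave and bounded by z_hat; z0 = z_hat returns the
    limit z_hat (division time diverges, the load saturates).
    """
    z0 = _check_z0(z0, params)
    zh = params.z_hat
    if z0 == 0.0:
        return 0.0
    if z0 == zh:
        return zh
    e = np.exp(-(params.b / params.beta0) / (1.0 - z0 / zh))
    return z0 * zh / (z0 + (zh - z0) * e)


def daughter_fitnesses(z0: float, a: float, params: ConceptualParams) -> tuple[float, float]:
    """Fitnesses (f_plus, f_minus) of the two daughters at asymmetry a.

    The plus-daughter inherits (1+a)F(z0)/2 plasmids and has the lower
    fitness f_plus = beta0*(1 - (1+a)F(z0)/(2*z_hat)) <= f_minus.  Both are
    non-negative because F <= z_hat.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("asymmetry a must lie in [0, 1]")
    F = end_of_cycle_load(z0, params)
    zh = params.z_hat
    f_plus = params.beta0 * (1.0 - (1.0 + a) * F / (2.0 * zh))
    f_minus = params.beta0 * (1.0 - (1.0 - a) * F / (2.0 * zh))
    return f_plus, f_minus


def gen2_average_fitness(z0: float, a: float, params: ConceptualParams) -> float:
    """Average fitness of the four grandchildren,

        fbar2 = beta0*(1 - [F((1+a)z1/2) + F((1-a)z1/2)] / (4*z_hat)),

    with z1 = F(z0).  Concavity of F makes this strictly increasing in a on
    (0, 1] whenever z1 > 0.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("asymmetry a must lie in [0, 1]")
    z1 = end_of_cycle_load(z0, params)
    zh = params.z_hat
    Fp = end_of_cycle_load((1.0 + a) * z1 / 2.0, params)
    Fm = end_of_cycle_load((1.0 - a) * z1 / 2.0, params)
    return params.beta0 * (1.0 - (Fp + Fm) / (4.0 * zh))


def protection_factor(z: float, K: float) -> float:
    """Saturating protection against antibiotics, q(z) = z/(K + z).

    Increasing and concave with q(0) = 0, q(K) = 1/2, q -> 1 for large z.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if K <= 0:
        raise ValueError("K must be positive")
    return z / (K + z)


def protected_gen1_fitness(
    z0: float, a: float, K: float | None, params: ConceptualParams
) -> float:
    """First-generation average fitness with protection weighting,

        fbar1 = (q((1+a)z1/2)*f_plus + q((1-a)z1/2)*f_minus) / 2,

    z1 = F(z0).  ``K`` defaults to ``params.K``.  Decreasing in a: the gain
    in protection of the loaded daughter cannot compensate the loss of the
    light one, because q is concave.
    """
    if K is None:
        K = params.K
    z1 = end_of_cycle_load(z0, params)
    f_plus, f_minus = daughter_fitnesses(z0, a, params)
    qp = protection_factor((1.0 + a) * z1 / 2.0, K)
    qm = protection_factor((1.0 - a) * z1 / 2.0, K)
    return 0.5 * (qp * f_plus + qm * f_minus)


def tabulate(
    params: ConceptualParams,
    z0_grid=None,
    a_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
):
    """Tabulate (z0, T, F, f0, fbar1(a), fbar2(a)) for plotting.

    Returns a pandas DataFrame with one row per z0 and one column per
    quantity; ``fbar1_a{a}`` uses the protection factor with params.K.
    """
    import pandas as pd

    if z0_grid is None:
        z0_grid = np.arange(0.0, params.z_hat, 1.0)
    rows = []
    for z0 in z0_grid:
        row = {
            "z0": z0,
            "f0": fitness_f0(z0, params),
            "T": division_time(z0, params) if z0 < params.z_hat else np.inf,
            "F": end_of_cycle_load(z0, params),
        }
        for a in a_grid:
            row[f"fbar1_a{a:g}"] = protected_gen1_fitness(z0, a, None, params)
            row[f"fbar2_a{a:g}"] = gen2_average_fitness(z0, a, params)
        rows.append(row)
    return pd.DataFrame(rows)
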
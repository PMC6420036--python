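"""Evolutionarily stable segregation strategies (ESSS).

Adaptive dynamics reduces the evolution of the segregation trait ``p_z`` to
maximising the long-term growth rate ``lambda1(p)`` of the plasmid-bearing
block over strategies in ``[0, 0.5]^z_hat``.  The maximiser cannot be found
analytically; the continuous steepest-ascent flow ``dp/ds = grad lambda1``
is followed numerically by projected gradient ascent with a backtracking
step, multi-start initialisation, and a local-maximum probe.

The gradient of a simple eigenvalue is computed from the left and right
dominant eigenvectors:  d lambda1 / d p_z = w^T (dA/dp_z) v / (w^T v),
where dA/dp_z only touches column z through the derivative of the binomial
segregation kernel.  A finite-difference route is kept as a cross-check and
fallback.

Two kinds of coordinate carry no information and are frozen at 0.5:
mothers that never divide (beta(z) = 0, e.g. z = z_hat at full burden) and
z = 1 (a single plasmid goes to one daughter either way; the kernel does not
depend on p_1).  ``lambda1`` is an even function of each ``p_z`` about 0.5,
so the uniform-0.5 strategy is always a stationary point; the ascent
therefore probes small perturbations before declaring a point converged,
which lets it leave that saddle.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable

import numpy as np

from .core import (
    ModelParameters,
    SegregationStrategy,
    _assemble,
    binomial_pmf_derivative,
)

__all__ = [
    "ESSResult",
    "flat_coordinates",
    "lyapunov_gradient",
    "steepest_ascent",
    "multi_start_ess",
    "verify_local_max",
    "onset_threshold",
    "sensitivity_sweep",
    "grid_search_ess",
]


@dataclasses.dataclass(frozen=True)
class ESSResult:
    """Optimised segregation strategy and diagnostics.

    ``trajectory`` samples (s, lambda1) along the ascent, where ``s`` is the
    accumulated artificial time (sum of accepted step sizes).
    """

    p_star: SegregationStrategy
    lambda1_star: float
    trajectory: list[tuple[float, float]]
    converged: bool
    gradient_norm_final: float
    flat_mask: np.ndarray
    n_starts_agreeing: int = 1

    def identifiable(self) -> np.ndarray:
        """Boolean mask over z = 1..z_hat of coordinates that affect lambda1."""
        return ~self.flat_mask


def flat_coordinates(params: ModelParameters) -> np.ndarray:
    """Mask of unidentifiable trait coordinates (z = 1..z_hat).

    True where the gradient of lambda1 w.r.t. p_z vanishes structurally:
    mothers with beta(z) = 0 never divide, and for z = 1 the kernel
    k(.; 1) = (1, 1) regardless of p.
    """
    beta = params.division_rates()
    mask = beta == 0.0
    mask[0] = True  # z = 1
    return mask


def _lambda1_raw(params: ModelParameters, p: np.ndarray) -> float:
    """lambda1 as a function of a raw p vector in [0, 1]^z_hat."""
    A, _ = _assemble(params, p)
    from scipy import linalg

    lam = linalg.eigvals(A)
    return float(lam.real.max())


def _eig_pair(params: ModelParameters, p: np.ndarray):
    A, _ = _assemble(params, p)
    from scipy import linalg

    lam, vl, vr = linalg.eig(A, left=True, right=True)
    idx = int(np.argmax(lam.real))
    v = vr[:, idx].real
    w = vl[:, idx].real
    if v.sum() < 0:
        v = -v
    if w @ v < 0:
        w = -w
    return float(lam[idx].real), w, v


def _adjoint_gradient(params: ModelParameters, p: np.ndarray) -> tuple[float, np.ndarray]:
    """(lambda1, gradient) via left/right dominant eigenvectors."""
    lam1, w, v = _eig_pair(params, p)
    beta = params.division_rates()
    zh = params.z_hat
    grad = np.zeros(zh)
    wv = float(w @ v)
    for z0 in range(1, zh + 1):
        col = z0 - 1
        if beta[col] == 0.0 or z0 == 1:
            continue
        dg = binomial_pmf_derivative(z0, p[col])
        dk = dg + dg[::-1]  # kernel derivative over daughter z = 0..z0
        # dA/dp_z0 touches rows 1..z0 of column z0 (daughter z = 0 exits via B)
        grad[col] = beta[col] * v[col] * float(w[0:z0] @ dk[1 : z0 + 1]) / wv
    return lam1, grad


def _fd_gradient(
    params: ModelParameters, p: np.ndarray, h: float = 1e-5
) -> tuple[float, np.ndarray]:
    """Central finite differences, one-sided at the [0, 1] box boundary."""
    lam0 = _lambda1_raw(params, p)
    flat = flat_coordinates(params)
    grad = np.zeros_like(p)
    for i in range(p.size):
        if flat[i]:
            continue
        lo = max(0.0, p[i] - h)
        hi = min(1.0, p[i] + h)
        f_lo = _lambda1_raw(params, _subst(p, i, lo)) if lo != p[i] else lam0
        f_hi = _lambda1_raw(params, _subst(p, i, hi)) if hi != p[i] else lam0
        grad[i] = (f_hi - f_lo) / (hi - lo)
    return lam0, grad


def _subst(p: np.ndarray, i: int, v: float) -> np.ndarray:
    q = p.copy()
    q[i] = v
    return q


def lyapunov_gradient(
    params: ModelParameters,
    strategy: SegregationStrategy,
    method: str = "adjoint",
    h: float = 1e-5,
) -> np.ndarray:
    """Gradient of lambda1 with respect to p_z, z = 1..z_hat.

    ``method`` is "adjoint" (exact eigenvalue perturbation, default) or "fd"
    (central finite differences with step ``h``).  On a degenerate eigengap
    the adjoint route falls back to finite differences with a warning.
    """
    p = np.asarray(strategy.p)
    if method == "adjoint":
        try:
            _, grad = _adjoint_gradient(params, p)
            return grad
        except (ArithmeticError, FloatingPointError) as exc:  # pragma: no cover
            warnings.warn(f"adjoint gradient failed ({exc}); falling back to fd")
            method = "fd"
    if method == "fd":
        _, grad = _fd_gradient(params, p, h=h)
        return grad
    raise ValueError(f"unknown method {method!r}")


def _project(p: np.ndarray, flat: np.ndarray) -> np.ndarray:
    q = np.clip(p, 0.0, 0.5)
    q[flat] = 0.5
    return q


def _projected_gradient(p: np.ndarray, grad: np.ndarray, flat: np.ndarray) -> np.ndarray:
    pg = grad.copy()
    pg[(p <= 0.0) & (grad < 0.0)] = 0.0
    pg[(p >= 0.5) & (grad > 0.0)] = 0.0
    pg[flat] = 0.0
    return pg


def steepest_ascent(
    params: ModelParameters,
    init: SegregationStrategy,
    step0: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 5000,
    saddle_probes: int = 30,
    saddle_delta: float = 0.01,
    seed: int = 0,
) -> ESSResult:
    """Maximise lambda1 by projected gradient ascent on [0, 0.5]^z_hat.

    Euler steps along the steepest-ascent flow with a backtracking step size:
    a step is accepted only if it improves lambda1, so the trajectory is
    monotone.  When the projected gradient drops below ``tol`` the point is
    probed with ``saddle_probes`` random perturbations of size
    ``saddle_delta``; if one improves lambda1 the ascent restarts from it
    (this matters because uniform p = 0.5 is always a stationary point).
    """
    rng = np.random.default_rng(seed)
    flat = flat_coordinates(params)
    p = _project(np.asarray(init.p, dtype=float).copy(), flat)
    lam, grad = _adjoint_gradient(params, p)
    s = 0.0
    step = step0
    trajectory = [(s, lam)]
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        pg = _projected_gradient(p, grad, flat)
        gnorm = float(np.abs(pg).max()) if pg.size else 0.0
        if gnorm < tol:
            # stationary point: probe for an ascent direction before
            # declaring convergence.  Coordinate probes come first — they
            # detect single-trait directions (e.g. the high-z directions at
            # the uniform-0.5 saddle) that random full-vector perturbations
            # miss because losses on the plateau coordinates dominate.
            escaped = False
            trials = [
                _subst(p, i, p[i] + sign * saddle_delta)
                for i in np.flatnonzero(~flat)
                for sign in (-1.0, +1.0)
            ]
            trials += [
                p + saddle_delta * rng.uniform(-1.0, 1.0, size=p.size)
                for _ in range(saddle_probes)
            ]
            for raw in trials:
                trial = _project(raw, flat)
                lam_t = _lambda1_raw(params, trial)
                if lam_t > lam + 1e-13:
                    p, lam = trial, lam_t
                    _, grad = _adjoint_gradient(params, p)
                    trajectory.append((s, lam))
                    escaped = True
                    break
            if escaped:
                continue
            converged = True
            break
        # backtracking line search along the projected-ascent direction
        accepted = False
        trial_step = step
        for _ in range(50):
            cand = _project(p + trial_step * grad, flat)
            lam_c = _lambda1_raw(params, cand)
            if lam_c > lam:
                p, lam = cand, lam_c
                s += trial_step
                step = min(trial_step * 1.5, 1e3)
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            # no improving step along the gradient: treat as stationary,
            # let the saddle probe decide on the next pass
            grad = np.zeros_like(grad)
            continue
        _, grad = _adjoint_gradient(params, p)
        trajectory.append((s, lam))
    pg = _projected_gradient(p, lyapunov_gradient(params, SegregationStrategy(p)), flat)
    return ESSResult(
        p_star=SegregationStrategy(p),
        lambda1_star=lam,
        trajectory=trajectory,
        converged=converged,
        gradient_norm_final=float(np.abs(pg).max()),
        flat_mask=flat,
    )


def multi_start_ess(
    params: ModelParameters,
    n_starts: int = 3,
    seed: int = 0,
    agreement_tol: float = 0.02,
    **ascent_kwargs,
) -> ESSResult:
    """Steepest ascent from several initial strategies; returns the best.

    Initials: uniform 0.5, uniform 0.25, then seeded uniform-random vectors
    in [0, 0.5].  ``n_starts_agreeing`` counts runs whose optimum matches the
    best one within ``agreement_tol`` sup-norm over identifiable coordinates.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    zh = params.z_hat
    inits = [
        SegregationStrategy.uniform(zh, 0.5),
        SegregationStrategy.uniform(zh, 0.25),
    ][:n_starts]
    while len(inits) < n_starts:
        inits.append(SegregationStrategy(rng.uniform(0.0, 0.5, size=zh)))
    results = [
        steepest_ascent(params, init, seed=seed + 1000 * i, **ascent_kwargs)
        for i, init in enumerate(inits)
    ]
    best = max(results, key=lambda r: r.lambda1_star)
    free = ~best.flat_mask
    agreeing = sum(
        1
        for r in results
        if np.max(np.abs(r.p_star.p[free] - best.p_star.p[free]), initial=0.0)
        < agreement_tol
    )
    return dataclasses.replace(best, n_starts_agreeing=agreeing)


def verify_local_max(
    params: ModelParameters,
    p_star: SegregationStrategy,
    delta: float = 0.02,
    n_probes: int = 100,
    seed: int = 0,
    tol: float = 1e-9,
) -> bool:
    """True iff no local in-bounds perturbation of size ``delta`` improves
    lambda1 beyond ``tol``.

    Probes every coordinate individually (p_z +/- delta, clipped to the
    box) and then ``n_probes`` random full-vector perturbations; the
    coordinate sweep is what detects single-trait ascent directions (e.g.
    the high-z directions at the uniform-0.5 saddle).
    """
    rng = np.random.default_rng(seed)
    flat = flat_coordinates(params)
    p = np.asarray(p_star.p)
    lam = _lambda1_raw(params, p)
    if delta > 0:
        for i in np.flatnonzero(~flat):
            for sign in (+1.0, -1.0):
                trial = _project(_subst(p, i, p[i] + sign * delta), flat)
                if _lambda1_raw(params, trial) > lam + tol:
                    return False
    for _ in range(n_probes):
        trial = _project(p + delta * rng.uniform(-1.0, 1.0, size=p.size), flat)
        if _lambda1_raw(params, trial) > lam + tol:
            return False
    return True


def onset_threshold(
    p_star: SegregationStrategy, deviation_tol: float = 0.05
) -> int | None:
    """Smallest mother copy number z (1 <= z < z_hat) at which the optimised
    strategy departs from equal segregation by more than ``deviation_tol``.
    Returns None if the strategy stays within the band everywhere."""
    p = np.asarray(p_star.p)
    for z in range(1, p.size):  # z = 1..z_hat-1
        if abs(p[z - 1] - 0.5) > deviation_tol:
            return z
    return None


def sensitivity_sweep(
    points: Iterable[ModelParameters],
    n_starts: int = 2,
    seed: int = 0,
    equal_tol: float = 0.05,
    **ascent_kwargs,
):
    """Optimise the strategy at each parameter point and summarise.

    Returns a pandas DataFrame with one row per point: the parameters, the
    optimal lambda1, the minimum optimised p over identifiable z, the onset
    copy number, and whether the ESSS is equal segregation everywhere
    (max |p - 0.5| < ``equal_tol`` over identifiable coordinates).  Failures
    at individual points are recorded and the sweep continues.
    """
    import pandas as pd

    rows = []
    for pt in points:
        row = {
            "z_hat": pt.z_hat,
            "b": pt.b,
            "beta0": pt.beta0,
            "burden_scale": pt.burden_scale,
        }
        try:
            res = multi_start_ess(pt, n_starts=n_starts, seed=seed, **ascent_kwargs)
            free = res.identifiable()
            p = res.p_star.p
            row.update(
                lambda1_star=res.lambda1_star,
                min_p=float(p[free].min()) if free.any() else np.nan,
                onset_z=onset_threshold(res.p_star, equal_tol),
                equal_everywhere=bool(
                    np.max(np.abs(p[free] - 0.5), initial=0.0) < equal_tol
                ),
                converged=res.converged,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - sweep robustness
            row.update(
                lambda1_star=np.nan,
                min_p=np.nan,
                onset_z=None,
                equal_everywhere=None,
                converged=False,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def grid_search_ess(
    params: ModelParameters, resolution: float = 0.025
) -> tuple[SegregationStrategy, float]:
    """Exhaustive grid search over [0, 0.5]^z_hat (identifiable coordinates
    only; flat ones fixed at 0.5).  Exponential cost — intended as an
    independent oracle for z_hat <= 3."""
    flat = flat_coordinates(params)
    free_idx = np.flatnonzero(~flat)
    if free_idx.size > 3:
        raise ValueError("grid search is only feasible for <= 3 free coordinates")
    grid = np.arange(0.0, 0.5 + 1e-12, resolution)
    best_p, best_lam = None, -np.inf
    base = np.full(params.z_hat, 0.5)
    for combo in itertools.product(grid, repeat=free_idx.size):
        p = base.copy()
        p[free_idx] = combo
        lam = _lambda1_raw(params, p)
        if lam > best_lam:
            best_lam, best_p = lam, p
    return SegregationStrategy(best_p), float(best_lam)
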
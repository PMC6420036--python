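"""Exact stochastic simulation of single-cell plasmid dynamics and the
analysis procedures used on mother/daughter fluorescence records.

Each cell carries an integer plasmid count ``z`` and experiences three
competing exponential clocks: plasmid replication at rate ``b*z*(1 -
z/z_hat)`` (copy number +1, capped at ``z_hat``), division at rate
``beta(z, alpha)`` and death at rate ``mu(z, alpha)``.  At division the
"selected" daughter draws Binomial(z, p_z) plasmids and her sister receives
the rest, so daughter counts always sum to the mother's.  The realisation
is exact (event-driven per cell); the population is kept bounded by uniform
subsampling with a carried weight, which preserves the composition in
expectation and lets growth rates be read off the weighted census.

The analysis half mirrors how time-lapse fluorescence data are processed:
a noisy linear fluorescence proxy per cell, share histograms of
``f1/(f1+f2)`` stratified by mother fluorescence, a rank plot of daughter
fluorescences over the mother's rank, and re-estimation of the segregation
strategy from division records.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .core import EnvironmentSchedule, ModelParameters, SegregationStrategy

__all__ = [
    "DivisionRecord",
    "FluorescenceRecord",
    "SimulationResult",
    "simulate_lineages",
    "fluorescence_proxy",
    "share_histograms",
    "rank_plot_table",
    "estimate_strategy",
    "records_to_frame",
]

RECORD_COLUMNS = ["time", "lineage", "mother_z", "daughter1_z", "daughter2_z"]


@dataclasses.dataclass(frozen=True)
class DivisionRecord:
    """One cell division: the mother's copy number at division and the two
    daughter counts (daughter1 is the binomially selected daughter; the
    counts sum to the mother's)."""

    mother_z: int
    daughter1_z: int
    daughter2_z: int
    time: float
    lineage: int = 0

    def __post_init__(self) -> None:
        if self.daughter1_z + self.daughter2_z != self.mother_z:
            raise ValueError("daughter copy numbers must sum to the mother's")
        if min(self.mother_z, self.daughter1_z, self.daughter2_z) < 0:
            raise ValueError("copy numbers must be non-negative")


@dataclasses.dataclass(frozen=True)
class FluorescenceRecord:
    """Fluorescence proxies (arbitrary units) for one division."""

    mother_f: float
    f1: float
    f2: float
    record: DivisionRecord


def records_to_frame(records) -> pd.DataFrame:
    """Normalise a list of DivisionRecord (or a DataFrame) to the tabular
    schema used by the analysis functions."""
    if isinstance(records, pd.DataFrame):
        missing = set(RECORD_COLUMNS[2:]) - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        return records
    rows = [
        (r.time, r.lineage, r.mother_z, r.daughter1_z, r.daughter2_z) for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclasses.dataclass
class SimulationResult:
    """Output of :func:`simulate_lineages`.

    ``records`` is a DataFrame of divisions (columns ``time, lineage,
    mother_z, daughter1_z, daughter2_z``); ``final_census`` counts surviving
    cells per copy number z = 0..z_hat at ``t_max``; ``population`` samples
    the weighted population size over time (columns ``t, cells, weight,
    weighted_size``), where the weight accumulates the uniform-subsampling
    factor so that ``weighted_size`` estimates the unbounded population.
    """

    records: pd.DataFrame
    final_census: np.ndarray
    population: pd.DataFrame
    n_subsamples: int
    params: ModelParameters
    strategy: SegregationStrategy
    seed: int

    def growth_rate(self, t_min: float = 0.0) -> float:
        """Per-capita growth rate: slope of log weighted size for t >= t_min."""
        pop = self.population[self.population["t"] >= t_min]
        pop = pop[pop["weighted_size"] > 0]
        if len(pop) < 2:
            raise ValueError("not enough census points to estimate a growth rate")
        slope = np.polyfit(pop["t"], np.log(pop["weighted_size"]), 1)[0]
        return float(slope)


def simulate_lineages(
    params: ModelParameters,
    strategy: SegregationStrategy,
    schedule: EnvironmentSchedule | None = None,
    t_max: float = 20.0,
    max_cells: int = 10_000,
    seed: int = 0,
    initial: list[int] | None = None,
    plasmid_bearing_only: bool = True,
    census_interval: float = 0.5,
) -> SimulationResult:
    """Exact event-driven simulation of the branching cell process.

    ``initial`` lists the founding cells' copy numbers (default: ten cells
    at z_hat//2).  With ``plasmid_bearing_only`` (default) daughters born
    with z = 0 are recorded but not followed — they can never regain
    plasmids, and dropping them makes the census directly comparable to the
    plasmid-bearing block of the deterministic model.  Whenever the live
    population exceeds ``max_cells`` it is uniformly subsampled back to
    ``max_cells`` and the carried weight is scaled up accordingly.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if strategy.z_hat != params.z_hat:
        raise ValueError("strategy length does not match z_hat")
    if schedule is None:
        schedule = EnvironmentSchedule.constant(0)
    rng = np.random.default_rng(seed)
    zh = params.z_hat
    p = np.asarray(strategy.p)
    beta = np.zeros(zh + 1)
    beta[1:] = params.division_rates()
    z_arr = np.arange(zh + 1, dtype=float)
    birth = params.b * z_arr * (1.0 - z_arr / zh)

    if initial is None:
        initial = [max(zh // 2, 1)] * 10
    cells = [int(z) for z in initial]
    for z in cells:
        if not 0 <= z <= zh:
            raise ValueError(f"initial copy number {z} outside [0, {zh}]")

    rec_time: list[float] = []
    rec_lineage: list[int] = []
    rec_mother: list[int] = []
    rec_d1: list[int] = []
    rec_d2: list[int] = []

    weight = 1.0
    n_subsamples = 0
    pop_rows = [(0.0, len(cells), weight, weight * len(cells))]
    lineages = list(range(len(cells)))
    next_lineage = len(cells)

    t = 0.0
    exp = rng.exponential
    unif = rng.random
    while t < t_max - 1e-12:
        # window bounded by the census interval and schedule segments
        alpha = schedule.alpha_at(t)
        tau = t % schedule.period
        rem = schedule.period - tau  # remaining time in the current segment
        acc = 0.0
        for d, _a in schedule.segments:
            if tau < acc + d:
                rem = acc + d - tau
                break
            acc += d
        w_end = min(t + census_interval, t + rem, t_max)
        mu0 = params.mu0 if alpha == 1 else 0.0
        beta0_free = params.beta0 if alpha == 0 else 0.0

        new_cells: list[int] = []
        new_lineages: list[int] = []
        stack = list(zip(cells, lineages, [t] * len(cells)))
        while stack:
            z, lin, tc = stack.pop()
            while True:
                r_birth = birth[z]
                if z == 0:
                    r_div = beta0_free
                    r_death = mu0
                else:
                    r_div = beta[z]
                    r_death = 0.0
                total = r_birth + r_div + r_death
                if total <= 0.0:
                    break
                tc = tc + exp(1.0 / total)
                if tc >= w_end:
                    break
                u = unif() * total
                if u < r_birth:
                    z += 1
                elif u < r_birth + r_div:
                    if z > 0:
                        d1 = int(rng.binomial(z, p[z - 1]))
                    else:
                        d1 = 0
                    d2 = z - d1
                    rec_time.append(tc)
                    rec_lineage.append(lin)
                    rec_mother.append(z)
                    rec_d1.append(d1)
                    rec_d2.append(d2)
                    # continue this loop as daughter 1, stack daughter 2
                    keep1 = not (plasmid_bearing_only and d1 == 0)
                    keep2 = not (plasmid_bearing_only and d2 == 0)
                    if keep2:
                        stack.append((d2, next_lineage, tc))
                        next_lineage += 1
                    if keep1:
                        z = d1
                    elif keep2:
                        z, lin, tc = stack.pop()
                    else:
                        z = -1
                        break
                else:
                    z = -1  # death
                    break
            if z >= 0:
                new_cells.append(z)
                new_lineages.append(lin)
        cells, lineages = new_cells, new_lineages
        t = w_end
        if len(cells) > max_cells:
            idx = rng.choice(len(cells), size=max_cells, replace=False)
            weight *= len(cells) / max_cells
            cells = [cells[i] for i in idx]
            lineages = [lineages[i] for i in idx]
            n_subsamples += 1
        pop_rows.append((t, len(cells), weight, weight * len(cells)))

    census = np.bincount(cells, minlength=zh + 1) if cells else np.zeros(zh + 1, int)
    records = pd.DataFrame(
        {
            "time": rec_time,
            "lineage": rec_lineage,
            "mother_z": rec_mother,
            "daughter1_z": rec_d1,
            "daughter2_z": rec_d2,
        }
    )
    population = pd.DataFrame(
        pop_rows, columns=["t", "cells", "weight", "weighted_size"]
    )
    return SimulationResult(
        records=records,
        final_census=census,
        population=population,
        n_subsamples=n_subsamples,
        params=params,
        strategy=strategy,
        seed=seed,
    )


def fluorescence_proxy(
    records, gain: float = 10.0, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Attach a GFP-like fluorescence proxy ``f = gain*z + N(0, noise_sd)``
    (truncated at 0) to mother and daughters of each division record."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    df = records_to_frame(records).copy()
    rng = np.random.default_rng(seed)
    n = len(df)
    noise = rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0 else np.zeros((n, 3))
    df["mother_f"] = np.clip(gain * df["mother_z"].to_numpy() + noise[:, 0], 0.0, None)
    df["f1"] = np.clip(gain * df["daughter1_z"].to_numpy() + noise[:, 1], 0.0, None)
    df["f2"] = np.clip(gain * df["daughter2_z"].to_numpy() + noise[:, 2], 0.0, None)
    return df


def _share_histogram_counts(shares: np.ndarray, n_bins: int) -> np.ndarray:
    """Histogram over uniform bins on [0, 1] with half-weight splitting of
    values that fall on an interior edge (within rounding), so that
    mirrored data give bin-exactly mirrored counts."""
    counts = np.zeros(n_bins)
    scaled = shares * n_bins
    nearest = np.rint(scaled)
    on_edge = (np.abs(scaled - nearest) < 1e-9) & (nearest > 0) & (nearest < n_bins)
    idx = np.clip(np.floor(scaled).astype(int), 0, n_bins - 1)
    for s, i, e, k in zip(shares, idx, on_edge, nearest.astype(int)):
        if e:
            counts[k] += 0.5
            counts[k - 1] += 0.5
        else:
            counts[i] += 1.0
    return counts


def share_histograms(
    fluor: pd.DataFrame,
    n_strata: int = 10,
    n_bins: int = 20,
    strata_mode: str = "max-relative",
) -> tuple[pd.DataFrame, int]:
    """Per-stratum histograms of the daughter fluorescence shares.

    Mothers are assigned to ``n_strata`` strata either by fluorescence
    relative to the observed maximum (``"max-relative"``: stratum j covers
    (j/n, (j+1)/n] of the maximum) or by empirical quantile
    (``"quantile"``).  Within each stratum both shares ``f1/(f1+f2)`` and
    ``f2/(f1+f2)`` of every division enter the histogram, which is
    therefore exactly symmetric about 0.5 (values on an interior bin edge
    are split half/half so the symmetry is bin-exact).

    Returns ``(table, n_dropped)`` where the long-format table has columns
    ``stratum, bin_left, bin_right, count`` and ``n_dropped`` counts
    divisions with ``f1 + f2 = 0``.
    """
    if fluor.empty:
        raise ValueError("no fluorescence records")
    if strata_mode not in ("max-relative", "quantile"):
        raise ValueError("strata_mode must be 'max-relative' or 'quantile'")
    tot = fluor["f1"].to_numpy() + fluor["f2"].to_numpy()
    keep = tot > 0
    n_dropped = int((~keep).sum())
    df = fluor[keep]
    tot = tot[keep]
    mf = df["mother_f"].to_numpy()
    if strata_mode == "max-relative":
        fmax = mf.max()
        if fmax <= 0:
            raise ValueError("all mother fluorescences are zero")
        stratum = np.minimum((mf / fmax * n_strata).astype(int), n_strata - 1)
    else:
        ranks = stats.rankdata(mf, method="ordinal") - 1
        stratum = (ranks * n_strata // len(mf)).astype(int)
    s1 = df["f1"].to_numpy() / tot
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for j in range(n_strata):
        sel = stratum == j
        shares = np.concatenate([s1[sel], 1.0 - s1[sel]])
        counts = _share_histogram_counts(shares, n_bins)
        for i in range(n_bins):
            rows.append((j, edges[i], edges[i + 1], counts[i]))
    table = pd.DataFrame(rows, columns=["stratum", "bin_left", "bin_right", "count"])
    return table, n_dropped


def rank_plot_table(fluor: pd.DataFrame) -> pd.DataFrame:
    """Order mothers by fluorescence (stable sort; rank 1 = dimmest) and
    report the two daughter fluorescences, ordered per division.

    Columns: ``rank, mother_f, f_low, f_high``.
    """
    if fluor.empty:
        raise ValueError("no fluorescence records")
    df = fluor.sort_values("mother_f", kind="stable").reset_index(drop=True)
    f1 = df["f1"].to_numpy()
    f2 = df["f2"].to_numpy()
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(df) + 1),
            "mother_f": df["mother_f"].to_numpy(),
            "f_low": np.minimum(f1, f2),
            "f_high": np.maximum(f1, f2),
        }
    )


def estimate_strategy(
    records, z_hat: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Re-estimate the segregation strategy from division records.

    For each mother copy number z the selected-daughter counts are pooled:
    p_hat = (sum of daughter1 plasmids) / (sum of mother plasmids), with a
    Clopper-Pearson interval at level ``1 - alpha``.  Estimate and interval
    are reflected into the canonical band [0, 0.5].  Copy numbers never
    observed as mothers are flagged (``observed = False``).
    """
    df = records_to_frame(records)
    if z_hat is None:
        z_hat = int(df["mother_z"].max()) if len(df) else 0
    rows = []
    grouped = df.groupby("mother_z")
    for z in range(1, z_hat + 1):
        if z in grouped.groups:
            g = grouped.get_group(z)
            trials = int(g["mother_z"].sum())
            successes = int(g["daughter1_z"].sum())
            p_hat = successes / trials
            lo = (
                stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
                if successes > 0
                else 0.0
            )
            hi = (
                stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
                if successes < trials
                else 1.0
            )
            if p_hat > 0.5:
                p_hat, lo, hi = 1.0 - p_hat, 1.0 - hi, 1.0 - lo
            rows.append((z, len(g), p_hat, lo, min(hi, 1.0), True))
        else:
            rows.append((z, 0, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["z", "n_divisions", "p_hat", "ci_low", "ci_high", "observed"]
    )
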
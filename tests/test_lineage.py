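"""Stochastic lineage simulation and the fluorescence-analysis pipeline."""

import numpy as np
import pandas as pd
import pytest

from plasmidseg import ModelParameters, SegregationStrategy, build_generator, spectral_bound
from plasmidseg.lineage import (
    DivisionRecord,
    estimate_strategy,
    fluorescence_proxy,
    rank_plot_table,
    records_to_frame,
    share_histograms,
    simulate_lineages,
)


def synthetic_records(z0_values, p_of_z, seed=0):
    """Division records drawn directly from the binomial segregation model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, z0 in enumerate(z0_values):
        d1 = int(rng.binomial(z0, p_of_z(z0)))
        rows.append((float(i), i, int(z0), d1, int(z0) - d1))
    return pd.DataFrame(
        rows, columns=["time", "lineage", "mother_z", "daughter1_z", "daughter2_z"]
    )


class TestRecords:
    def test_division_record_enforces_conservation(self):
        with pytest.raises(ValueError):
            DivisionRecord(mother_z=10, daughter1_z=4, daughter2_z=5, time=1.0)

    def test_records_to_frame_round_trip(self):
        recs = [DivisionRecord(10, 4, 6, 1.0, 0), DivisionRecord(3, 1, 2, 2.0, 1)]
        df = records_to_frame(recs)
        assert list(df["mother_z"]) == [10, 3]
        assert (df["daughter1_z"] + df["daughter2_z"] == df["mother_z"]).all()


class TestSimulation:
    def test_plasmids_conserved_at_every_division(self, sim_equal):
        rec = sim_equal.records
        assert (rec["daughter1_z"] + rec["daughter2_z"] == rec["mother_z"]).all()
        assert (rec["mother_z"] >= 0).all()

    def test_bit_reproducible_runs(self, default_params):
        st = SegregationStrategy.uniform(50, 0.5)
        kw = dict(t_max=5.0, max_cells=500, seed=11, initial=[25] * 5)
        r1 = simulate_lineages(default_params, st, **kw)
        r2 = simulate_lineages(default_params, st, **kw)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        assert np.array_equal(r1.final_census, r2.final_census)

    def test_no_replication_conserves_total_plasmids(self):
        # with b=0 plasmids are only diluted by division; tracking every cell
        # (including plasmid-free daughters) keeps the total count constant
        params = ModelParameters(b=0.0)
        st = SegregationStrategy.uniform(50, 0.5)
        res = simulate_lineages(
            params,
            st,
            t_max=6.0,
            max_cells=100_000,
            seed=4,
            initial=[32] * 10,
            plasmid_bearing_only=False,
        )
        assert res.n_subsamples == 0
        total = int(np.arange(res.final_census.size) @ res.final_census)
        assert total == 32 * 10

    def test_daughter_share_matches_binomial_sampling(self, default_params):
        p_true = 0.3
        st = SegregationStrategy.uniform(50, p_true)
        res = simulate_lineages(
            default_params, st, t_max=10.0, max_cells=3000, seed=5, initial=[25] * 20
        )
        rec = res.records[res.records["mother_z"] > 0]
        trials = int(rec["mother_z"].sum())
        p_hat = rec["daughter1_z"].sum() / trials
        se = np.sqrt(p_true * (1 - p_true) / trials)
        assert abs(p_hat - p_true) < 4 * se

    def test_growth_rate_tracks_spectral_bound(self, default_params, sim_equal):
        lam1 = spectral_bound(
            build_generator(default_params, SegregationStrategy.uniform(50, 0.5))
        ).lambda1
        assert sim_equal.growth_rate(t_min=8.0) == pytest.approx(lam1, abs=0.02)

    def test_rejects_bad_inputs(self, default_params):
        st = SegregationStrategy.uniform(50, 0.5)
        with pytest.raises(ValueError):
            simulate_lineages(default_params, st, t_max=-1.0)
        with pytest.raises(ValueError):
            simulate_lineages(default_params, st, t_max=1.0, initial=[99])


class TestFluorescence:
    def test_noiseless_proxy_is_proportional(self):
        df = synthetic_records([10, 20, 30], lambda z: 0.5, seed=1)
        fl = fluorescence_proxy(df, gain=7.0, noise_sd=0.0)
        assert np.allclose(fl["mother_f"], 7.0 * fl["mother_z"])
        assert np.allclose(fl["f1"], 7.0 * fl["daughter1_z"])

    def test_noise_attenuates_correlation_as_predicted(self):
        rng = np.random.default_rng(2)
        z0 = rng.integers(5, 50, size=1000)
        df = synthetic_records(z0, lambda z: 0.5, seed=2)
        gain, sd = 10.0, 5.0
        fl = fluorescence_proxy(df, gain=gain, noise_sd=sd, seed=3)
        z = fl["mother_z"].to_numpy(float)
        f = fl["mother_f"].to_numpy()
        expected = np.sqrt(
            gain**2 * z.var() / (gain**2 * z.var() + sd**2)
        )  # variance-ratio attenuation
        observed = np.corrcoef(f, z)[0, 1]
        assert observed == pytest.approx(expected, abs=0.02)

    def test_validation(self):
        df = synthetic_records([10], lambda z: 0.5)
        with pytest.raises(ValueError):
            fluorescence_proxy(df, gain=0.0)
        with pytest.raises(ValueError):
            fluorescence_proxy(df, noise_sd=-1.0)


class TestShareHistograms:
    def test_bin_exact_symmetry_about_half(self):
        rng = np.random.default_rng(6)
        z0 = rng.integers(2, 50, size=2000)
        df = synthetic_records(z0, lambda z: 0.5 if z < 25 else 0.25, seed=6)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=3.0, seed=7)
        table, _ = share_histograms(fl, n_strata=10, n_bins=20)
        for _, grp in table.groupby("stratum"):
            counts = grp.sort_values("bin_left")["count"].to_numpy()
            assert np.allclose(counts, counts[::-1])

    def test_equal_segregation_concentrates_near_half(self):
        z0 = np.full(3000, 40)
        df = synthetic_records(z0, lambda z: 0.5, seed=8)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=0.0)
        table, _ = share_histograms(fl, n_strata=1, n_bins=20)
        counts = table.sort_values("bin_left")["count"].to_numpy()
        # Binomial(40, 0.5) puts ~95% of shares within [0.35, 0.65]
        # (|Z - 20| <= 6 is a ~2-sigma event) and the mode at 0.5
        centre = counts[7:13].sum()
        assert centre > 0.9 * counts.sum()
        assert 7 <= np.argmax(counts) <= 12

    def test_unequal_high_copy_mothers_give_bimodal_top_stratum(self):
        rng = np.random.default_rng(9)
        z0 = rng.integers(2, 51, size=6000)
        df = synthetic_records(z0, lambda z: 0.5 if z < 30 else 0.2, seed=9)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=0.0)
        table, _ = share_histograms(fl, n_strata=10, n_bins=20)
        top = table[table["stratum"] == 9].sort_values("bin_left")
        counts = top["count"].to_numpy()
        mids = (top["bin_left"].to_numpy() + top["bin_right"].to_numpy()) / 2
        # two symmetric modes away from 0.5, a dip at the centre
        peak = mids[np.argmax(counts)]
        assert abs(peak - 0.5) > 0.15
        centre = counts[(mids > 0.45) & (mids < 0.55)].sum()
        assert centre < counts.max()

    def test_zero_total_divisions_are_dropped(self):
        df = pd.DataFrame(
            {
                "time": [0.0, 1.0],
                "lineage": [0, 1],
                "mother_z": [0, 10],
                "daughter1_z": [0, 5],
                "daughter2_z": [0, 5],
            }
        )
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=0.0)
        table, n_dropped = share_histograms(fl, n_strata=2, n_bins=4)
        assert n_dropped == 1
        assert table["count"].sum() == pytest.approx(2.0)  # both shares of one division

    def test_quantile_mode_balances_strata(self):
        rng = np.random.default_rng(10)
        z0 = rng.integers(2, 51, size=1000)
        df = synthetic_records(z0, lambda z: 0.5, seed=10)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=1.0, seed=11)
        table, _ = share_histograms(fl, n_strata=5, n_bins=10, strata_mode="quantile")
        per_stratum = table.groupby("stratum")["count"].sum()
        assert per_stratum.max() - per_stratum.min() <= 2.01  # two shares per division


class TestRankPlot:
    def test_single_record(self):
        df = synthetic_records([10], lambda z: 0.5)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=0.0)
        table = rank_plot_table(fl)
        assert list(table["rank"]) == [1]

    def test_mother_column_monotone_and_daughters_ordered(self):
        rng = np.random.default_rng(12)
        z0 = rng.integers(2, 51, size=500)
        df = synthetic_records(z0, lambda z: 0.4, seed=12)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=2.0, seed=13)
        table = rank_plot_table(fl)
        assert (np.diff(table["mother_f"]) >= 0).all()
        assert (table["f_low"] <= table["f_high"]).all()

    def test_branch_separation_appears_at_high_ranks(self):
        # equal segregation at low load, strongly unequal at high load:
        # the low/high daughter branches fuse at low ranks and split at high
        rng = np.random.default_rng(14)
        z0 = rng.integers(2, 51, size=4000)
        df = synthetic_records(z0, lambda z: 0.5 if z < 30 else 0.15, seed=14)
        fl = fluorescence_proxy(df, gain=10.0, noise_sd=0.0)
        table = rank_plot_table(fl)
        n = len(table)
        low = table.iloc[: n // 4]
        high = table.iloc[-n // 4 :]
        gap_low = (low["f_high"] - low["f_low"]).mean() / low["mother_f"].mean()
        gap_high = (high["f_high"] - high["f_low"]).mean() / high["mother_f"].mean()
        # high ranks split by ~(1 - 2p) = 0.7 of the mother's level, low
        # ranks only by binomial noise (~z^{-1/2} relative)
        assert gap_high > 0.6
        assert gap_low < 0.45
        assert gap_high > 2 * gap_low


class TestEstimateStrategy:
    def test_recovers_uniform_half(self):
        rng = np.random.default_rng(15)
        z0 = rng.integers(2, 51, size=5000)
        df = synthetic_records(z0, lambda z: 0.5, seed=15)
        est = estimate_strategy(df, z_hat=50)
        well = est[est["n_divisions"] >= 50]
        assert ((well["ci_low"] <= 0.5) & (0.5 <= well["ci_high"])).mean() > 0.85

    def test_unobserved_copy_numbers_flagged(self):
        df = synthetic_records([10, 10, 12], lambda z: 0.5, seed=16)
        est = estimate_strategy(df, z_hat=15)
        assert not est.loc[est["z"] == 11, "observed"].item()
        assert est.loc[est["z"] == 10, "observed"].item()

    def test_recovers_step_strategy_from_synthetic_records(self):
        rng = np.random.default_rng(17)
        z0 = rng.integers(2, 51, size=20_000)
        truth = lambda z: 0.5 if z < 25 else 0.3  # noqa: E731
        df = synthetic_records(z0, truth, seed=17)
        est = estimate_strategy(df, z_hat=50)
        well = est[est["n_divisions"] >= 200]
        for _, row in well.iterrows():
            assert abs(row["p_hat"] - truth(row["z"])) < 0.05
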
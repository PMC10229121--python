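import numpy as np
import pandas as pd
import pytest

from middledown.proteoforms import c4_targets
from middledown.quantify import (
    AveragedSpectrum,
    EmptyWindowError,
    UndefinedStoichiometryError,
    aggregate_replicates,
    bio_replicate_values,
    compare_conditions,
    default_windows,
    extract_stoichiometry,
    quantify_run,
    select_and_average,
    ttest_two_sample,
)
from middledown.simulate import (
    AcquisitionConfig,
    Run,
    Scan,
    simulate_run,
    simulate_timecourse,
)

from .oracles import oracle_pooled_t, oracle_sem


def _spectrum_with(intensities, bin_width=0.1):
    """AveragedSpectrum with given intensities at the four C4 targets."""
    grid = np.arange(470.0, 530.0, bin_width) + bin_width / 2
    inten = np.zeros_like(grid)
    for t, i in zip(c4_targets(), intensities):
        inten[np.argmin(np.abs(grid - t))] = i
    return AveragedSpectrum(degree=0, grid_mz=grid, mean_intensity=inten, n_scans=1)


class TestSelectAndAverage:
    def test_all_scans_in_matching_window_are_kept(self, single_degree_mixture):
        run, _ = simulate_run(single_degree_mixture, AcquisitionConfig(), seed=0)
        windows = default_windows()
        spec = select_and_average(run, windows[3])
        assert spec.n_scans == len(run.ms2_scans())

    def test_query_of_empty_window_raises_with_counts(self, single_degree_mixture):
        run, _ = simulate_run(single_degree_mixture, AcquisitionConfig(), seed=0)
        windows = default_windows()
        with pytest.raises(EmptyWindowError) as err:
            select_and_average(run, windows[5])
        assert err.value.degree == 5
        assert err.value.n_in_rt == 0

    def test_averaging_is_arithmetic_mean(self):
        targets = c4_targets()
        prec = 594.1258889
        mk = lambda scale: Scan(
            2, 36.0, np.array(targets), scale * np.array([10.0, 0, 0, 0]),
            precursor_mz=prec,
        )
        run = Run(scans=[mk(1.0), mk(3.0)])
        window = default_windows()[0]
        spec = select_and_average(run, window)
        got = spec.mean_intensity[np.argmin(np.abs(spec.grid_mz - targets[0]))]
        assert got == pytest.approx(20.0)  # mean of I and 3I

    def test_low_snr_scans_are_dropped(self, single_degree_mixture):
        run, _ = simulate_run(
            single_degree_mixture,
            AcquisitionConfig(baseline=1000.0, noise_cv=0.0),
            seed=0,
        )
        windows = default_windows()
        # with a huge baseline the on-target sum of edge-of-peak scans falls
        # below snr_min x median off-target intensity and they are curated out
        spec_loose = select_and_average(run, windows[3], snr_min=0.0)
        spec_tight = select_and_average(run, windows[3], snr_min=3.0)
        assert spec_tight.n_scans < spec_loose.n_scans


class TestExtractStoichiometry:
    def test_single_state_is_100_percent(self):
        pct = extract_stoichiometry(_spectrum_with([5.0, 0, 0, 0]))
        np.testing.assert_allclose(pct, [100, 0, 0, 0])

    def test_equal_intensities_split_evenly(self):
        pct = extract_stoichiometry(_spectrum_with([3.0, 3.0, 3.0, 3.0]))
        np.testing.assert_allclose(pct, [25, 25, 25, 25])

    def test_zero_signal_is_undefined(self):
        with pytest.raises(UndefinedStoichiometryError):
            extract_stoichiometry(_spectrum_with([0, 0, 0, 0]))

    def test_oversized_tolerance_rejected(self):
        with pytest.raises(ValueError):
            extract_stoichiometry(_spectrum_with([1, 1, 1, 1]), fragment_tol=8.0)

    def test_noise_free_round_trip_recovers_truth(self, single_degree_mixture):
        run, truth = simulate_run(single_degree_mixture, AcquisitionConfig(), seed=0)
        spec = select_and_average(run, default_windows()[3])
        pct = extract_stoichiometry(spec)
        np.testing.assert_allclose(
            pct / 100.0, truth.k4[3], atol=1e-9
        )


class TestAggregate:
    @staticmethod
    def _per_run(bio_values):
        rows = []
        for bio, me0 in enumerate(bio_values, start=1):
            for state, pct in zip(
                ("me0", "me1", "me2", "me3"), (me0, 100.0 - me0, 0.0, 0.0)
            ):
                rows.append(
                    {
                        "condition": "c", "time_min": 0.0, "bio_rep": bio,
                        "tech_rep": 1, "acetyl_degree": 5, "me_state": state,
                        "pct": pct,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_replicates_have_zero_sem(self):
        table = aggregate_replicates(self._per_run([20.0, 20.0, 20.0]))
        cell = table[table.me_state == "me0"].iloc[0]
        assert cell["mean_pct"] == pytest.approx(20.0)
        assert cell["sem"] == pytest.approx(0.0)
        assert cell["n"] == 3

    def test_sem_matches_closed_form_oracle(self):
        table = aggregate_replicates(self._per_run([10.0, 20.0, 30.0]))
        cell = table[table.me_state == "me0"].iloc[0]
        assert cell["mean_pct"] == pytest.approx(20.0)
        assert cell["sem"] == pytest.approx(oracle_sem([10.0, 20.0, 30.0]), abs=1e-10)
        assert cell["sem"] == pytest.approx(5.7735, abs=1e-4)

    def test_single_biological_replicate_sem_not_available(self):
        table = aggregate_replicates(self._per_run([20.0]))
        cell = table[table.me_state == "me0"].iloc[0]
        assert cell["n"] == 1
        assert np.isnan(cell["sem"])

    def test_rows_sum_to_100(self):
        table = aggregate_replicates(self._per_run([12.0, 34.0, 56.0]))
        total = table.groupby("acetyl_degree")["mean_pct"].sum()
        np.testing.assert_allclose(total.to_numpy(), 100.0, atol=1e-6)

    def test_technical_before_biological(self):
        # tech reps 10 and 30 within bio 1 average to 20 before crossing bios
        rows = []
        for bio, tech, me0 in [(1, 1, 10.0), (1, 2, 30.0), (2, 1, 40.0), (2, 2, 40.0)]:
            for state, pct in zip(
                ("me0", "me1", "me2", "me3"), (me0, 100 - me0, 0.0, 0.0)
            ):
                rows.append(
                    {"condition": "c", "time_min": 0.0, "bio_rep": bio,
                     "tech_rep": tech, "acetyl_degree": 0, "me_state": state,
                     "pct": pct}
                )
        table = aggregate_replicates(pd.DataFrame(rows))
        cell = table[table.me_state == "me0"].iloc[0]
        assert cell["mean_pct"] == pytest.approx(30.0)  # mean of 20 and 40
        assert cell["n"] == 2


class TestCompare:
    def test_identical_groups_p_is_one(self):
        t, df, p = ttest_two_sample([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_pooled_t_matches_textbook_oracle(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t, df, p = ttest_two_sample(a, b)
        to, dfo, po = oracle_pooled_t(a, b)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == dfo
        assert p == pytest.approx(po, abs=1e-10)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_sample([1.0], [1.0, 2.0])

    def test_zero_variance_unequal_means_degenerate(self):
        with pytest.raises(ValueError):
            ttest_two_sample([1.0, 1.0], [2.0, 2.0])

    def test_compare_conditions_table(self, single_degree_mixture):
        cfg = AcquisitionConfig(scan_interval_s=20, noise_cv=0.1)
        runs_a = simulate_timecourse(
            [(0.0, single_degree_mixture)], cfg, n_bio=3, n_tech=1, seed=1,
            condition="water",
        )
        runs_b = simulate_timecourse(
            [(0.0, single_degree_mixture)], cfg, n_bio=3, n_tech=1, seed=2,
            condition="butyrate",
        )
        per = pd.concat(
            [quantify_run(r) for r, _ in runs_a + runs_b], ignore_index=True
        )
        bio = bio_replicate_values(per)
        out = compare_conditions(
            bio[bio.condition == "water"], bio[bio.condition == "butyrate"]
        )
        assert len(out) == 4  # one cell per K4 state at the single degree
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


class TestPipelineProperties:
    def test_full_noise_free_recovery_all_degrees(self, noise_free_run):
        run, truth = noise_free_run
        per = quantify_run(run)
        piv = per.pivot_table(index="acetyl_degree", columns="me_state", values="pct")
        for a, pi in truth.k4.items():
            rec = piv.loc[a, ["me0", "me1", "me2", "me3"]].to_numpy() / 100.0
            np.testing.assert_allclose(rec, pi, atol=1e-9)

    def test_missing_degree_reported_as_nan_not_zero(self, single_degree_mixture):
        run, _ = simulate_run(single_degree_mixture, AcquisitionConfig(), seed=0)
        per = quantify_run(run)
        absent = per[per.acetyl_degree == 5]
        assert absent["pct"].isna().all()

    def test_extraction_targets_shared_across_degrees(self):
        # the K4 readout uses one fragment-target set; windows only carry
        # precursor targets, so extraction cannot vary by acetyl degree
        windows = default_windows()
        assert all(
            not hasattr(w, "fragment_targets") for w in windows.values()
        )
        assert len(set(c4_targets())) == 4

    def test_monotone_me3_trajectory_preserved(self):
        # me3-within-5ac rises monotonically along the noise-free time course
        from middledown.simulate import default_trajectory

        cfg = AcquisitionConfig(scan_interval_s=20)
        runs = simulate_timecourse(default_trajectory(), cfg, n_bio=1, n_tech=1, seed=0)
        series = []
        for run, truth in runs:
            per = quantify_run(run)
            cell = per[
                (per.acetyl_degree == 5) & (per.me_state == "me3")
            ]["pct"].iloc[0]
            series.append((run.metadata["time_min"], cell, truth.k4[5][3]))
        series.sort()
        recovered = [s[1] for s in series]
        truth_series = [s[2] * 100 for s in series]
        assert all(b > a for a, b in zip(recovered, recovered[1:]))
        np.testing.assert_allclose(recovered, truth_series, atol=1e-9)
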
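import json

import numpy as np
import pytest

from middledown.proteoforms import H3_1_50
from middledown.simulate import (
    DEFAULT_RT_WINDOWS,
    AcquisitionConfig,
    MixtureSpec,
    Run,
    SimulationError,
    default_mixture,
    default_trajectory,
    degree_precursors,
    four_pl,
    hill_velocity,
    read_mzml,
    read_run_json,
    read_truth_yaml,
    simulate_binding,
    simulate_kinetics,
    simulate_run,
    simulate_timecourse,
    write_mzml,
    write_run_json,
    write_truth_yaml,
)


class TestMixtureSpec:
    def test_all_zero_abundance_rejected(self):
        with pytest.raises(SimulationError):
            MixtureSpec({0: 0.0}, {0: (1.0, 0, 0, 0)})

    def test_stoichiometry_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            MixtureSpec({0: 1.0}, {0: (0.5, 0.2, 0.2, 0.2)})

    def test_yaml_round_trip(self, tmp_path):
        mix = default_mixture()
        write_truth_yaml(mix, tmp_path / "t.yaml")
        back = read_truth_yaml(tmp_path / "t.yaml")
        assert back == mix


class TestAcquisitionConfig:
    def test_malformed_window_rejected(self):
        with pytest.raises(SimulationError):
            AcquisitionConfig(rt_windows={0: (40.0, 35.0)})

    def test_malformed_scan_range_rejected(self):
        with pytest.raises(SimulationError):
            AcquisitionConfig(ms1_range=(640.0, 585.0))


class TestSimulateRun:
    def test_same_seed_bit_identical(self, tmp_path):
        cfg = AcquisitionConfig(noise_cv=0.2, baseline=1.0)
        r1, _ = simulate_run(default_mixture(), cfg, seed=5)
        r2, _ = simulate_run(default_mixture(), cfg, seed=5)
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())

    def test_different_seed_differs(self):
        cfg = AcquisitionConfig(noise_cv=0.2)
        r1, _ = simulate_run(default_mixture(), cfg, seed=5)
        r2, _ = simulate_run(default_mixture(), cfg, seed=6)
        assert json.dumps(r1.to_dict()) != json.dumps(r2.to_dict())

    def test_ms2_only_in_windows_of_present_degrees(self):
        mix = MixtureSpec(
            abundances={3: 5.0, 5: 0.0},
            k4={3: (0.7, 0.2, 0.08, 0.02), 5: (0.25, 0.25, 0.25, 0.25)},
        )
        run, _ = simulate_run(mix, AcquisitionConfig(), seed=0)
        lo3, hi3 = DEFAULT_RT_WINDOWS[3]
        lo5, hi5 = DEFAULT_RT_WINDOWS[5]
        rts = [s.rt_min for s in run.ms2_scans()]
        assert all(lo3 <= t < hi3 for t in rts)
        assert not any(lo5 <= t < hi5 for t in rts)

    def test_all_precursors_inside_ms1_window(self):
        for degree in range(6):
            for mz in degree_precursors(degree):
                assert 585 <= mz <= 640

    def test_ms2_precursor_target_is_theoretical(self):
        run, _ = simulate_run(default_mixture(), AcquisitionConfig(), seed=2)
        allowed = {
            round(mz, 6)
            for d in range(6)
            for mz in degree_precursors(d)
        }
        for s in run.ms2_scans():
            assert round(s.precursor_mz, 6) in allowed

    def test_run_json_round_trip_exact(self, tmp_path):
        run, _ = simulate_run(
            default_mixture(), AcquisitionConfig(noise_cv=0.1), seed=9
        )
        write_run_json(run, tmp_path / "r.json")
        back = read_run_json(tmp_path / "r.json")
        assert json.dumps(back.to_dict()) == json.dumps(run.to_dict())

    def test_mzml_round_trip(self, tmp_path):
        run, _ = simulate_run(
            default_mixture(), AcquisitionConfig(noise_cv=0.1, baseline=0.3), seed=9
        )
        write_mzml(run, tmp_path / "r.mzML")
        back = read_mzml(tmp_path / "r.mzML")
        assert len(back.scans) == len(run.scans)
        for a, b in zip(run.scans, back.scans):
            assert a.level == b.level
            assert b.rt_min == pytest.approx(a.rt_min, abs=0)
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)
            if a.level == 2:
                assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=0)


class TestTimecourse:
    def test_replicate_counts(self):
        runs = simulate_timecourse(
            default_trajectory(), AcquisitionConfig(scan_interval_s=30),
            n_bio=3, n_tech=2, seed=1,
        )
        assert len(runs) == 6 * 3 * 2
        labels = {
            (r.metadata["time_min"], r.metadata["bio_rep"], r.metadata["tech_rep"])
            for r, _ in runs
        }
        assert len(labels) == 36

    def test_zero_noise_replicate_stoichiometries_identical(self):
        # without biological or acquisition noise every replicate carries the
        # same ground truth and yields the same recovered stoichiometry
        from middledown.quantify import quantify_run

        mix = default_mixture()
        runs = simulate_timecourse(
            [(0.0, mix)], AcquisitionConfig(scan_interval_s=30),
            n_bio=2, n_tech=2, seed=3, bio_cv=0.0,
        )
        tables = []
        for run, truth in runs:
            assert truth == mix
            per = quantify_run(run)
            tables.append(per.sort_values(["acetyl_degree", "me_state"])["pct"].to_numpy())
        for t in tables[1:]:
            np.testing.assert_allclose(t, tables[0], atol=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(SimulationError):
            simulate_timecourse([], AcquisitionConfig(), seed=0)


class TestKineticsGenerator:
    def test_half_saturation_identity(self):
        # at S = K05 the Hill velocity is kcat*E/2 for any h
        for h in (0.7, 1.0, 2.5):
            v = hill_velocity(130.0, 130.0, 0.03, h, 4.0)
            assert v == pytest.approx(0.03 * 4.0 / 2.0, rel=1e-12)

    def test_h_equal_one_is_michaelis_menten(self):
        S = np.array([0.0, 10.0, 50.0, 200.0, 400.0])
        hill = hill_velocity(S, 130.0, 0.03, 1.0, 4.0)
        mm = 0.03 * 4.0 * S / (130.0 + S)
        np.testing.assert_allclose(hill, mm, rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            simulate_kinetics(-1.0, 0.03, 1.0, 4.0, [1.0, 2.0])
        with pytest.raises(SimulationError):
            simulate_kinetics(130.0, 0.03, 0.0, 4.0, [1.0, 2.0])

    def test_noise_free_table_matches_model(self):
        S = [0.0, 23.4, 79.0, 178.0, 400.0]
        tab = simulate_kinetics(130.0, 0.03, 1.7, 4.0, S, noise_sd=0, seed=0)
        np.testing.assert_allclose(
            tab["rate"].to_numpy(), hill_velocity(np.array(S), 130.0, 0.03, 1.7, 4.0)
        )


class TestBindingGenerator:
    def test_hookless_series_monotone(self):
        Q = np.geomspace(0.1, 1000, 12)
        tab = simulate_binding(100.0, 10100.0, 10.0, 1.2, Q, seed=0, n_rep=1)
        y = tab["counts"].to_numpy()
        assert np.all(np.diff(y) > 0)

    def test_hook_suppresses_high_concentrations(self):
        Q = np.geomspace(0.1, 1000, 12)
        tab = simulate_binding(
            100.0, 10100.0, 10.0, 1.2, Q, hook=(50.0, 2.0), seed=0, n_rep=1
        )
        y = tab["counts"].to_numpy()
        assert y[-1] < y.max()

    def test_four_pl_at_zero_is_bottom(self):
        assert four_pl(0.0, 7.0, 100.0, 10.0, 1.5) == 7.0
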
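import numpy as np
import pytest

from adipolipid.membrane import (BilayerTrajectory, LipidTopology,
                                 analyze_trajectory, apl_series,
                                 area_per_lipid, compare_systems,
                                 design_mixture, discard_equilibration,
                                 read_trajectory, smol_profile, thickness,
                                 write_trajectory)
from adipolipid.synthetic import TrajectorySpec, simulate_trajectory


class TestAreaPerLipid:
    def test_reference_box(self):
        # 6 x 6 nm lateral box, 64 lipids per leaflet
        assert area_per_lipid(np.array([6.0, 6.0, 8.0]), 64) == \
            pytest.approx(0.5625)

    def test_linear_in_lx(self):
        a1 = area_per_lipid(np.array([6.0, 6.0, 8.0]), 64)
        a2 = area_per_lipid(np.array([12.0, 6.0, 8.0]), 64)
        assert a2 == pytest.approx(2 * a1)

    def test_guards(self):
        with pytest.raises(ValueError):
            area_per_lipid(np.array([6.0, 6.0, 8.0]), 0)
        with pytest.raises(ValueError):
            area_per_lipid(np.array([-6.0, 6.0, 8.0]), 64)


def _tiny_trajectory(n_frames=10, thickness0=4.0):
    return simulate_trajectory(TrajectorySpec(
        n_lipids=16, n_chain_carbons=8, n_frames=n_frames,
        thickness0=thickness0, target_smol_profile=0.4, seed=5))


class TestSmol:
    def test_bounds_on_arbitrary_coordinates(self, rng):
        coords = rng.normal(size=(4, 30, 3))
        lipids = [LipidTopology("upper", 0, ((1, 2, 3, 4, 5),)),
                  LipidTopology("lower", 6, ((7, 8, 9, 10, 11),))]
        traj = BilayerTrajectory(boxes=np.tile([5.0, 5.0, 8.0], (4, 1)),
                                 coords=coords, times=np.arange(4.0),
                                 lipids=lipids)
        prof = smol_profile(traj)
        assert (prof["smol"] >= -0.5 - 1e-12).all()
        assert (prof["smol"] <= 1.0 + 1e-12).all()

    def test_segment_numbering_from_linkage(self):
        traj = _tiny_trajectory()
        prof = smol_profile(traj)
        assert list(prof["segment"]) == list(range(1, 7))

    def test_chain_selector(self):
        traj = _tiny_trajectory()
        p0 = smol_profile(traj, chain_selector=0)
        p_all = smol_profile(traj)
        assert len(p0) == len(p_all)
        with pytest.raises(ValueError, match="no chains"):
            smol_profile(traj, chain_selector=lambda li, ci: False)

    def test_short_chain_rejected(self):
        lipids = [LipidTopology("upper", 0, ((1, 2),))]
        traj = BilayerTrajectory(boxes=np.array([[5.0, 5.0, 8.0]]),
                                 coords=np.zeros((1, 3, 3)),
                                 times=np.array([0.0]), lipids=lipids)
        with pytest.raises(ValueError, match="fewer than 3"):
            smol_profile(traj)


class TestThickness:
    def test_head_plane_separation(self):
        traj = _tiny_trajectory(thickness0=4.0)
        assert np.allclose(thickness(traj), 4.0)

    def test_translation_invariance(self):
        traj = _tiny_trajectory()
        shifted = BilayerTrajectory(boxes=traj.boxes.copy(),
                                    coords=traj.coords + [0.0, 0.0, 13.7],
                                    times=traj.times.copy(),
                                    lipids=traj.lipids)
        assert np.allclose(thickness(traj), thickness(shifted))

    def test_volume_coupled_series_anticorrelated(self):
        """thickness = 2V/APL across a target-APL series."""
        means_apl, means_th = [], []
        for k, apl in enumerate([0.55, 0.58, 0.60, 0.62, 0.65]):
            traj = simulate_trajectory(TrajectorySpec(
                n_lipids=16, n_chain_carbons=6, n_frames=8, target_apl=apl,
                volume_coupling=True, frame_jitter_sd=0.02, seed=k))
            means_apl.append(apl_series(traj).mean())
            means_th.append(thickness(traj).mean())
        r = np.corrcoef(means_apl, means_th)[0, 1]
        assert r < -0.99


class TestEquilibrationDiscard:
    def test_window_arithmetic(self):
        traj = simulate_trajectory(TrajectorySpec(
            n_lipids=8, n_chain_carbons=5, n_frames=100,
            time_per_frame=1.0, seed=0))
        analyzed = discard_equilibration(traj, 40.0)
        assert analyzed.n_frames == 60
        assert analyzed.times[0] == 40.0 and analyzed.times[-1] == 99.0

    def test_zero_is_identity(self):
        traj = _tiny_trajectory()
        same = discard_equilibration(traj, 0.0)
        assert same.n_frames == traj.n_frames

    def test_frame_count_formula(self):
        traj = _tiny_trajectory(n_frames=25)
        for t_eq in (3.0, 7.0, 12.0):
            analyzed = discard_equilibration(traj, t_eq)
            assert analyzed.n_frames == 25 - int(t_eq / 1.0)

    def test_discarding_everything_rejected(self):
        traj = _tiny_trajectory(n_frames=5)
        with pytest.raises(ValueError, match="whole trajectory"):
            discard_equilibration(traj, 100.0)


class TestMixtureDesign:
    def test_largest_remainder_70_percent(self):
        design = design_mixture([("PE(P-16:0/20:4)", 0.70),
                                 ("PC(16:1/18:0)", 0.30)], 128)
        assert design.per_leaflet_counts == [45, 19]
        assert design.realized_fractions[0] == pytest.approx(45 / 64)

    def test_even_split(self):
        design = design_mixture([("PE(P-16:0/20:4)", 0.5),
                                 ("PC(16:1/18:0)", 0.5)], 128)
        assert design.per_leaflet_counts == [32, 32]

    def test_single_component(self):
        design = design_mixture([("PC(16:0/20:4)", 1.0)], 64)
        assert design.per_leaflet_counts == [32]

    def test_zero_count_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            design_mixture([("PC(16:1/18:0)", 0.999),
                            ("PE(P-16:0/20:4)", 0.001)], 16)

    def test_fraction_sum_and_parity_guards(self):
        with pytest.raises(ValueError, match="sum"):
            design_mixture([("PC(16:1/18:0)", 0.6)], 128)
        with pytest.raises(ValueError, match="even"):
            design_mixture([("PC(16:1/18:0)", 1.0)], 127)


class TestCompareSystems:
    def _props(self, apl, seed):
        traj = simulate_trajectory(TrajectorySpec(
            n_lipids=16, n_chain_carbons=6, n_frames=20, target_apl=apl,
            frame_jitter_sd=0.01, seed=seed))
        return analyze_trajectory(traj, t_equil=5.0)

    def test_known_difference_recovered(self):
        p1, p2 = self._props(0.60, 1), self._props(0.62, 2)
        table = compare_systems([p1, p2], labels=["a", "b"])
        assert list(table["label"]) == ["b", "a"]  # larger APL first
        diff = table.iloc[0]["apl_diff_to_next"]
        assert diff == pytest.approx(0.02, abs=0.01)

    def test_identical_systems(self):
        p = self._props(0.60, 3)
        table = compare_systems([p, p], labels=["x", "y"])
        assert table.iloc[0]["apl_diff_to_next"] == pytest.approx(0.0)

    def test_label_order_invariant_ranking(self):
        p1, p2, p3 = (self._props(a, s) for a, s in
                      [(0.55, 4), (0.65, 5), (0.60, 6)])
        t1 = compare_systems([p1, p2, p3], labels=["a", "b", "c"])
        t2 = compare_systems([p3, p1, p2], labels=["c", "a", "b"])
        assert list(t1["label"]) == list(t2["label"]) == ["b", "c", "a"]

    def test_mismatched_windows_rejected(self):
        traj = simulate_trajectory(TrajectorySpec(
            n_lipids=16, n_chain_carbons=6, n_frames=20, seed=7))
        p1 = analyze_trajectory(traj, t_equil=5.0)
        p2 = analyze_trajectory(traj, t_equil=10.0)
        with pytest.raises(ValueError, match="window"):
            compare_systems([p1, p2], labels=["a", "b"])


def test_trajectory_text_round_trip(tmp_path):
    traj = _tiny_trajectory(n_frames=3)
    path = tmp_path / "traj.txt"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.n_frames == traj.n_frames
    assert back.lipids == traj.lipids
    assert np.allclose(back.coords, traj.coords, atol=1e-8)
    assert np.allclose(back.boxes, traj.boxes, atol=1e-8)


def test_analyze_trajectory_summary():
    traj = simulate_trajectory(TrajectorySpec(
        n_lipids=32, n_chain_carbons=10, n_frames=30, target_apl=0.6,
        target_smol_profile=0.5, seed=9))
    props = analyze_trajectory(traj, t_equil=10.0, label="sys")
    assert props.analyzed_window == (10.0, 29.0)
    assert props.apl_mean == pytest.approx(0.6)
    assert abs(props.smol_saturated_mean - 0.5) < 0.05
    assert props.fluidity_index == pytest.approx(1 / props.smol_saturated_mean)
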
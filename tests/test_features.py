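"""Occupancy, coordination and cavity features; dwell-event detection."""

import numpy as np
import pandas as pd
import pytest

from sfstates import (
    FrameSet,
    SyntheticSpec,
    cavity_axis_profile,
    cavity_hydration,
    cavity_k_presence,
    compute_features,
    dwell_events,
    generate_ensemble,
    make_topology,
    plant_ion_dwell,
    read_features,
    site_k_occupancy,
    site_oxygen_coordination,
    write_features,
)
from sfstates.errors import ArgumentError, ConfigurationError
from sfstates.features import FEATURE_COLUMNS

from conftest import random_rotation


def _ensemble(**kwargs):
    spec = SyntheticSpec(noise_sigma=0.0, n_frames=1, **kwargs)
    frame_set, truth = generate_ensemble(spec)
    return frame_set, make_topology(frame_set), truth


class TestSiteOccupancy:
    def test_single_ion_at_s2_center(self):
        frame_set, topo, _ = _ensemble(ion_schedule=(2,))
        occ = site_k_occupancy(frame_set, topo)
        assert occ[2] == pytest.approx(1.0, abs=1e-9)
        # adjacent sites sit one site length (2.8 Å) away: 1/(1+2^6)
        assert occ[1] == pytest.approx(1.0 / 65.0, abs=1e-6)
        assert occ[3] == pytest.approx(1.0 / 65.0, abs=1e-6)
        # sites two lengths away (5.6 Å = 4 d_c) are essentially empty
        assert occ[0] < 0.02 and occ[4] < 0.02

    def test_no_ions_all_zero(self):
        frame_set, topo, _ = _ensemble(ion_schedule=())
        np.testing.assert_array_equal(site_k_occupancy(frame_set, topo),
                                      np.zeros(5))

    def test_ion_at_cutoff_gives_half(self):
        frame_set, topo, _ = _ensemble(ion_schedule=(0,))
        coords = frame_set.coordinates.copy()
        ion_row = topo.potassium_selection[0]
        coords[0, ion_row] += np.array([1.4, 0.0, 0.0])  # d_c off-center
        moved = FrameSet(coords, frame_set.atom_table)
        occ = site_k_occupancy(moved, topo)
        assert occ[0] == pytest.approx(0.5, abs=1e-9)

    def test_invariant_under_ion_relabeling(self):
        frame_set, topo, _ = _ensemble(ion_schedule=(0, 2, 4))
        occ = site_k_occupancy(frame_set, topo)
        coords = frame_set.coordinates.copy()
        ions = list(topo.potassium_selection)
        coords[0, ions] = coords[0, ions[::-1]]  # permute ion positions
        permuted = FrameSet(coords, frame_set.atom_table)
        np.testing.assert_allclose(site_k_occupancy(permuted, topo), occ,
                                   atol=1e-12)

    def test_ground_truth_agreement_across_seeds(self):
        # measured occupancy > 0.8 at planted sites, < 0.1 elsewhere
        for seed in range(10):
            spec = SyntheticSpec(n_frames=20, noise_sigma=0.2, seed=seed,
                                 ion_schedule=(1, 3))
            frame_set, truth = generate_ensemble(spec)
            topo = make_topology(frame_set)
            feats = compute_features(frame_set, topo)
            occ = feats[[f"s{i}_k" for i in range(5)]].to_numpy()
            assert (occ[truth.occupancies == 1] > 0.8).all()
            assert (occ[truth.occupancies == 0] < 0.1).all()


class TestOxygenCoordination:
    def test_conductive_all_sites_above_five(self, conductive_ideal):
        frame_set, topo, _ = conductive_ideal
        assert (site_oxygen_coordination(frame_set, topo) > 5).all()

    def test_widened_degrades_s0_s1_only(self, conductive_ideal,
                                         widened_ideal):
        base = site_oxygen_coordination(*conductive_ideal[:2])
        wide = site_oxygen_coordination(*widened_ideal[:2])
        assert wide[0] < 5 and wide[1] < 5
        np.testing.assert_allclose(wide[3:], base[3:], rtol=0.05)

    def test_oxygen_free_frame_zero(self, conductive_ideal):
        frame_set, topo, _ = conductive_ideal
        import dataclasses

        stripped = dataclasses.replace(
            topo, oxygen_selection=np.empty(0, dtype=int),
            potassium_selection=topo.potassium_selection)
        np.testing.assert_array_equal(
            site_oxygen_coordination(frame_set, stripped), np.zeros(5))


class TestCavityProfiles:
    def test_profile_spans_configured_segment(self, conductive_ideal):
        frame_set, topo, _ = conductive_ideal
        profile = cavity_axis_profile(frame_set, topo, "oxygen")
        assert len(profile.values) == topo.cavity_probe.n_points == 41
        z = profile.points[:, 2]
        # lower boundary of S4 is the ring plane at z=0; the segment starts
        # 2 Å below it and runs 20 Å intracellularly
        assert z[0] == pytest.approx(-2.0, abs=1e-9)
        assert z[-1] == pytest.approx(-22.0, abs=1e-9)

    def test_empty_cavity_zero_profile(self):
        frame_set, topo, _ = _ensemble(ion_schedule=(), water_column=False)
        profile = cavity_axis_profile(frame_set, topo, "potassium")
        np.testing.assert_array_equal(profile.values, 0.0)
        # only the far tail of the filter oxygens reaches the segment
        assert cavity_hydration(frame_set, topo) == pytest.approx(0.0,
                                                                  abs=1e-3)

    def test_single_cavity_ion_max_near_one(self):
        spec = plant_ion_dwell(SyntheticSpec(n_frames=1, noise_sigma=0.0,
                                             ion_schedule=()), 0.01)
        frame_set, truth = generate_ensemble(spec)
        topo = make_topology(frame_set)
        assert cavity_k_presence(frame_set, topo) == pytest.approx(1.0,
                                                                   abs=0.01)

    def test_max_independent_of_ion_z(self):
        # the paper-defined z-independence of the cavity maximum: one on-axis
        # ion moved along the probed segment keeps the estimate at ~1
        frame_set, topo, _ = _ensemble(ion_schedule=())
        table = frame_set.atom_table.copy()
        ion_row = len(table)
        table = pd.concat([table, pd.DataFrame({
            "atom_id": [ion_row], "atom_name": ["K"], "residue_name": ["K"],
            "residue_number": [999], "subunit_index": [-1], "element": ["K"],
        })], ignore_index=True)
        values = []
        for z in (-3.0, -7.5, -12.0, -16.5, -21.0):
            coords = np.concatenate(
                [frame_set.coordinates,
                 np.array([[[0.0, 0.0, z]]])], axis=1)
            fs = FrameSet(coords, table)
            topo_z = make_topology(fs)
            values.append(cavity_k_presence(fs, topo_z))
        np.testing.assert_allclose(values, 1.0, rtol=0.01)

    def test_ion_off_axis_by_cutoff_gives_half(self):
        frame_set, topo, _ = _ensemble(ion_schedule=())
        table = frame_set.atom_table.copy()
        table = pd.concat([table, pd.DataFrame({
            "atom_id": [len(table)], "atom_name": ["K"],
            "residue_name": ["K"], "residue_number": [999],
            "subunit_index": [-1], "element": ["K"],
        })], ignore_index=True)
        coords = np.concatenate(
            [frame_set.coordinates, np.array([[[1.4, 0.0, -12.0]]])], axis=1)
        fs = FrameSet(coords, table)
        assert cavity_k_presence(fs, make_topology(fs)) == pytest.approx(
            0.5, abs=1e-3)

    def test_continuous_column_hydration_above_one(self, conductive_ideal):
        frame_set, topo, _ = conductive_ideal
        assert cavity_hydration(frame_set, topo) > 1.0

    def test_hydration_gap_detected(self):
        continuous, topo_c, _ = _ensemble(ion_schedule=())
        base = cavity_hydration(continuous, topo_c)
        gap7, topo_7, _ = _ensemble(ion_schedule=(),
                                    water_gap=(-15.5, -8.5))
        assert cavity_hydration(gap7, topo_7) < min(base, 1.0)
        assert cavity_hydration(gap7, topo_7) < 4.0  # dehydrated-cluster flag
        # a gap wider than 2 d_c on each side of its midpoint -> near zero
        gap12, topo_12, _ = _ensemble(ion_schedule=(),
                                      water_gap=(-18.0, -6.0))
        assert cavity_hydration(gap12, topo_12) < 0.1


class TestFeaturePipeline:
    def test_stride_commutes_exactly(self, noisy_ensemble):
        frame_set, topo, _ = noisy_ensemble
        full = compute_features(frame_set, topo)
        strided_fs = frame_set.strided(5)
        strided = compute_features(strided_fs, make_topology(strided_fs))
        np.testing.assert_array_equal(
            full.iloc[::5][FEATURE_COLUMNS].to_numpy(),
            strided[FEATURE_COLUMNS].to_numpy())

    def test_rotation_invariance(self, noisy_ensemble):
        # features are invariant under a global rigid transform provided the
        # configured pore axis is transformed along with the coordinates
        from sfstates import build_topology

        frame_set, topo, _ = noisy_ensemble
        sub = frame_set.strided(20)
        base = compute_features(sub, make_topology(sub))
        rot = random_rotation(31)
        moved = sub.transformed(rotation=rot,
                                translation=np.array([4.0, -2.0, 6.0]))
        topo_moved = build_topology(moved, site_scheme="synthetic",
                                    pore_axis=rot @ np.array([0.0, 0.0, 1.0]))
        got = compute_features(moved, topo_moved)
        np.testing.assert_allclose(got[FEATURE_COLUMNS].to_numpy(),
                                   base[FEATURE_COLUMNS].to_numpy(),
                                   atol=1e-6)

    def test_fourfold_rotation_exact(self, conductive_ideal):
        frame_set, topo, _ = conductive_ideal
        quarter = np.array([[0.0, -1.0, 0.0],
                            [1.0, 0.0, 0.0],
                            [0.0, 0.0, 1.0]])
        base = compute_features(frame_set, topo)
        moved = frame_set.transformed(rotation=quarter)
        got = compute_features(moved, make_topology(moved))
        np.testing.assert_allclose(got[FEATURE_COLUMNS].to_numpy(),
                                   base[FEATURE_COLUMNS].to_numpy(),
                                   atol=1e-9)

    def test_all_features_non_negative(self, noisy_features):
        assert (noisy_features[FEATURE_COLUMNS].to_numpy() >= 0).all()

    def test_csv_round_trip(self, tmp_path, noisy_features):
        path = write_features(noisy_features, str(tmp_path / "f.csv"))
        back = read_features(path)
        np.testing.assert_allclose(back[FEATURE_COLUMNS].to_numpy(),
                                   noisy_features[FEATURE_COLUMNS
                                                  ].to_numpy(), atol=1e-12)

    def test_csv_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("frame,s0_k\n0,1.0\n")
        with pytest.raises(ArgumentError):
            read_features(str(bad))


class TestDwellEvents:
    def _planted(self, duration_ns, n_frames=1200, **kwargs):
        spec = SyntheticSpec(n_frames=n_frames, noise_sigma=0.0,
                             ion_schedule=(), **kwargs)
        if duration_ns > 0:
            spec = plant_ion_dwell(spec, duration_ns, start_frame=50)
        frame_set, truth = generate_ensemble(spec)
        return frame_set, make_topology(frame_set), truth

    def test_five_ns_not_stable(self):
        frame_set, topo, _ = self._planted(5.0)
        events, any_stable = dwell_events(frame_set, topo)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(5.0)
        assert events[0].exit_frame - events[0].entry_frame == 500
        assert not any_stable

    def test_ten_point_oh_one_ns_stable(self):
        frame_set, topo, _ = self._planted(10.01)
        events, any_stable = dwell_events(frame_set, topo)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(10.01)
        assert any_stable

    def test_no_ions_no_events(self):
        frame_set, topo, _ = self._planted(0.0)
        events, any_stable = dwell_events(frame_set, topo)
        assert events == [] and not any_stable

    def test_two_plants_two_events(self):
        spec = SyntheticSpec(n_frames=1200, noise_sigma=0.0,
                             ion_schedule=())
        spec = plant_ion_dwell(spec, 2.0, start_frame=100)
        spec = plant_ion_dwell(spec, 3.0, start_frame=700)
        frame_set, truth = generate_ensemble(spec)
        topo = make_topology(frame_set)
        events, any_stable = dwell_events(frame_set, topo)
        assert [e.duration for e in events] == pytest.approx([2.0, 3.0])
        assert [(e.entry_frame, e.exit_frame) for e in events] == \
            [(100, 300), (700, 1000)]
        assert not any_stable

    def test_short_gap_does_not_split(self):
        frame_set, topo, _ = self._planted(4.0)
        coords = frame_set.coordinates.copy()
        ion = topo.potassium_selection[0]
        coords[250:252, ion] = [50.0, 50.0, 50.0]  # 2-frame excursion
        fs = FrameSet(coords, frame_set.atom_table)
        events, _ = dwell_events(fs, topo)
        assert len(events) == 1

    def test_long_gap_splits(self):
        frame_set, topo, _ = self._planted(4.0)
        coords = frame_set.coordinates.copy()
        ion = topo.potassium_selection[0]
        coords[250:255, ion] = [50.0, 50.0, 50.0]  # 5-frame excursion
        fs = FrameSet(coords, frame_set.atom_table)
        events, _ = dwell_events(fs, topo)
        assert len(events) == 2

    def test_duration_consistent_with_interval(self):
        frame_set, topo, truth = self._planted(1.0, frame_interval=0.02,
                                               n_frames=300)
        events, _ = dwell_events(frame_set, topo)
        assert len(events) == 1
        n = events[0].exit_frame - events[0].entry_frame
        assert events[0].duration == pytest.approx(n * 0.02)

    def test_unknown_interval_rejected(self):
        frame_set, topo, _ = self._planted(1.0, n_frames=200)
        frame_set.frame_interval = 0.0  # deliberately corrupt
        with pytest.raises(ConfigurationError):
            dwell_events(frame_set, topo)
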
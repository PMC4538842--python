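"""Base-pair frames, step parameters, helical axis, bending and A/B form."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import topotraj as tt
from topotraj import basegeom
from topotraj.nucleic import _FLIP, BasePairFrame, compose_step
from conftest import random_rigid_motion


def frames_of(traj, pairing):
    return tt.assign_base_frames(traj.coords[0], traj.topology, pairing)


class TestBaseFrames:
    def test_reference_pose_gives_identity(self):
        top = tt.Topology.from_residue_table(
            [("I", "DG", 1, tt.NUCLEOTIDE, [(a, a[0]) for a in basegeom.ring_atom_names("G")])]
        )
        coords = basegeom.ring_coords("G")[None, :, :]
        traj = tt.Trajectory(top, coords)
        from topotraj.nucleic import _residue_base_frame

        R, t = _residue_base_frame(traj.coords[0], top, 0)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(t, 0.0, atol=1e-6)

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(3)
        top = tt.Topology.from_residue_table(
            [("I", "DA", 1, tt.NUCLEOTIDE, [(a, a[0]) for a in basegeom.ring_atom_names("A")])]
        )
        ref = basegeom.ring_coords("A")
        R, t = random_rigid_motion(rng)
        traj = tt.Trajectory(top, (ref @ R.T + t)[None])
        from topotraj.nucleic import _residue_base_frame

        Rf, tf = _residue_base_frame(traj.coords[0], top, 0)
        np.testing.assert_allclose(Rf, R, atol=1e-8)
        np.testing.assert_allclose(tf, t, atol=1e-8)

    def test_pair_origin_matches_builder(self):
        traj, pairing = tt.build_duplex(
            tt.DuplexRecipe.uniform(4, sequence="ATAT")
        )
        frames = frames_of(traj, pairing)
        # builder starts the first pair frame at the origin with identity triad
        np.testing.assert_allclose(frames[0].origin, 0.0, atol=1e-6)
        np.testing.assert_allclose(frames[0].triad, np.eye(3), atol=1e-6)

    def test_missing_ring_atom_named(self):
        top = tt.Topology.from_residue_table(
            [("I", "DG", 5, tt.NUCLEOTIDE, [("N9", "N"), ("C8", "C")])]
        )
        with pytest.raises(ValueError, match="N7"):
            tt.assign_base_frames(np.zeros((2, 3)), top, [(0, 0)])


class TestStepParameters:
    def test_pure_rise(self):
        f1 = BasePairFrame(np.zeros(3), np.eye(3))
        f2 = BasePairFrame(np.array([0.0, 0.0, 3.4]), np.eye(3))
        row = tt.step_parameters([f1, f2]).iloc[0]
        assert row["rise"] == pytest.approx(3.4, abs=1e-9)
        for p in ("shift", "slide", "tilt", "roll", "twist"):
            assert row[p] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_schedule_round_trip(self):
        rec = tt.DuplexRecipe.uniform(10, twist=32.7, rise=2.8, slide=-1.5)
        traj, pairing = tt.build_duplex(rec)
        table = tt.step_parameters(frames_of(traj, pairing))
        np.testing.assert_allclose(table["slide"], -1.5, atol=1e-6)
        np.testing.assert_allclose(table["twist"], 32.7, atol=1e-6)
        np.testing.assert_allclose(table["rise"], 2.8, atol=1e-6)

    @settings(derandomize=True, max_examples=20)
    @given(
        shift=st.floats(-2, 2), slide=st.floats(-3, 3), rise=st.floats(2.5, 4),
        tilt=st.floats(-15, 15), roll=st.floats(-15, 15), twist=st.floats(20, 45),
    )
    def test_compose_decompose_inverse(self, shift, slide, rise, tilt, roll, twist):
        """Builder/analyzer round trip over the physical parameter ranges."""
        params = dict(shift=shift, slide=slide, rise=rise, tilt=tilt, roll=roll, twist=twist)
        R1, o1 = np.eye(3), np.zeros(3)
        R2, o2 = compose_step(R1, o1, params)
        table = tt.step_parameters(
            [BasePairFrame(o1, R1), BasePairFrame(o2, R2)]
        )
        for key, want in params.items():
            assert table.iloc[0][key] == pytest.approx(want, abs=1e-6)

    def test_strand_reversal_symmetry(self):
        """Reading the duplex 3'→5': Slide/Rise/Roll/Twist invariant,
        Shift/Tilt change sign."""
        rng = np.random.default_rng(5)
        steps = [
            {"shift": rng.uniform(-1, 1), "slide": rng.uniform(-2, 1),
             "rise": rng.uniform(2.8, 3.6), "tilt": rng.uniform(-5, 5),
             "roll": rng.uniform(-8, 8), "twist": rng.uniform(25, 40)}
            for _ in range(6)
        ]
        traj, pairing = tt.build_duplex(tt.DuplexRecipe(7, steps))
        frames = frames_of(traj, pairing)
        fwd = tt.step_parameters(frames).reset_index(drop=True)
        rev_frames = [BasePairFrame(f.origin, f.triad @ _FLIP) for f in reversed(frames)]
        rev = tt.step_parameters(rev_frames).iloc[::-1].reset_index(drop=True)
        for col in ("slide", "rise", "roll", "twist"):
            np.testing.assert_allclose(rev[col], fwd[col], atol=1e-9)
        for col in ("shift", "tilt"):
            np.testing.assert_allclose(rev[col], -fwd[col], atol=1e-9)

    def test_non_orthonormal_triad_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            BasePairFrame(np.zeros(3), np.eye(3) * 1.1)


class TestHelicalAxis:
    def test_straight_duplex_parallel_tangents(self, straight_duplex):
        _, _, frames = straight_duplex
        axis = tt.fit_helical_axis(frames)
        dots = axis.tangents @ axis.tangents[0]
        assert np.degrees(np.arccos(np.clip(dots.min(), -1, 1))) < 0.5

    def test_uniform_roll_arc_constant_turn(self):
        traj, pairing = tt.build_bent_duplex(60.0, 20)
        axis = tt.fit_helical_axis(frames_of(traj, pairing))
        turns = [
            np.degrees(np.arccos(np.clip(axis.tangents[k] @ axis.tangents[k + 1], -1, 1)))
            for k in range(3, 16)
        ]
        assert (max(turns) - min(turns)) / np.mean(turns) < 0.05

    def test_minimal_three_bp(self):
        traj, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(3))
        axis = tt.fit_helical_axis(frames_of(traj, pairing))
        assert axis.n_points == 3

    def test_too_few_bp_rejected(self):
        traj, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(2))
        with pytest.raises(ValueError):
            tt.fit_helical_axis(frames_of(traj, pairing))


class TestXDisplacement:
    def test_on_axis_is_zero(self, straight_duplex):
        _, _, frames = straight_duplex
        axis = tt.fit_helical_axis(frames)
        xd = tt.x_displacement(frames, axis)["xdisp"].to_numpy()
        np.testing.assert_allclose(xd, 0.0, atol=1e-6)

    def test_constructed_offset_recovered(self):
        rec = tt.DuplexRecipe.uniform(12, x_offsets=[-4.0] * 12)
        traj, pairing = tt.build_duplex(rec)
        frames = frames_of(traj, pairing)
        axis = tt.fit_helical_axis(frames)
        xd = tt.x_displacement(frames, axis)["xdisp"].to_numpy()
        np.testing.assert_allclose(xd[2:-2], -4.0, atol=0.05)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(17)
        rec = tt.DuplexRecipe.uniform(10, x_offsets=[-2.0] * 10)
        traj, pairing = tt.build_duplex(rec)
        frames = frames_of(traj, pairing)
        xd = tt.x_displacement(frames, tt.fit_helical_axis(frames))["xdisp"].to_numpy()
        R, t = random_rigid_motion(rng)
        moved = tt.Trajectory(traj.topology, traj.coords @ R.T + t)
        f2 = frames_of(moved, pairing)
        xd2 = tt.x_displacement(f2, tt.fit_helical_axis(f2))["xdisp"].to_numpy()
        np.testing.assert_allclose(xd2, xd, atol=1e-6)


class TestBendingAngle:
    def test_straight_is_zero(self, straight_duplex):
        _, _, frames = straight_duplex
        assert tt.bending_angle(tt.fit_helical_axis(frames)) == pytest.approx(0.0, abs=1.0)

    def test_planar_ninety_degree_arc(self):
        traj, pairing = tt.build_bent_duplex(90.0, 20)
        axis = tt.fit_helical_axis(frames_of(traj, pairing))
        assert tt.bending_angle(axis) == pytest.approx(90.0, abs=3.0)

    def test_internal_window_of_synthetic_arc(self):
        # synthetic stand-in for the internal-28-bp curvilinear analysis:
        # a 30-bp duplex bent by the printed 140.3 degrees
        traj, pairing = tt.build_bent_duplex(140.3, 30)
        axis = tt.fit_helical_axis(frames_of(traj, pairing))
        assert tt.bending_angle(axis, (1, 28)) == pytest.approx(140.3, abs=4.0)

    def test_additive_for_concatenated_arcs(self):
        def arc_angle(total):
            traj, pairing = tt.build_bent_duplex(total, 22)
            return tt.bending_angle(tt.fit_helical_axis(frames_of(traj, pairing)))

        # one duplex carrying two consecutive coplanar arcs
        n_bp, a1, a2 = 24, 35.0, 50.0
        n_steps = n_bp - 1
        half = (n_steps - 2) // 2
        steps = []
        for i in range(n_steps):
            if i == 0 or i == n_steps - 1:
                roll = 0.0
            elif i <= half:
                roll = a1 / half
            else:
                roll = a2 / (n_steps - 2 - half)
            steps.append({"rise": 3.4, "twist": 0.0, "roll": roll})
        traj, pairing = tt.build_duplex(tt.DuplexRecipe(n_bp, steps))
        total = tt.bending_angle(tt.fit_helical_axis(frames_of(traj, pairing)))
        assert total == pytest.approx(a1 + a2, rel=0.05)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(23)
        traj, pairing = tt.build_bent_duplex(70.0, 18)
        base = tt.bending_angle(tt.fit_helical_axis(frames_of(traj, pairing)))
        R, t = random_rigid_motion(rng)
        moved = tt.Trajectory(traj.topology, traj.coords @ R.T + t)
        after = tt.bending_angle(tt.fit_helical_axis(frames_of(moved, pairing)))
        assert after == pytest.approx(base, abs=1e-6)

    def test_range_outside_axis_rejected(self):
        traj, pairing = tt.build_bent_duplex(30.0, 10)
        axis = tt.fit_helical_axis(frames_of(traj, pairing))
        with pytest.raises(ValueError):
            tt.bending_angle(axis, (2, 40))


class TestClassifyForm:
    @staticmethod
    def _tables(slides, xdisps):
        step = pd.DataFrame({"slide": slides})
        for col in ("shift", "rise", "tilt", "roll", "twist"):
            step[col] = 0.0 if col != "rise" else 3.4
        axis = pd.DataFrame({"xdisp": xdisps})
        return step, axis

    def test_fiber_parameter_sets(self):
        for want, kw in [
            ("A", dict(twist=32.7, rise=2.8, slide=-1.5, roll=10.0)),
            ("B", dict(twist=36.0, rise=3.4, slide=0.0)),
        ]:
            traj, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(12, **kw))
            frames = frames_of(traj, pairing)
            cls = tt.classify_form(
                tt.step_parameters(frames),
                tt.x_displacement(frames, tt.fit_helical_axis(frames)),
            )
            assert set(cls.labels) == {want}

    def test_planted_bab_partition(self):
        # 19 steps: B(4), A(8), B(7) with canonical descriptor values; the
        # transition base pairs sit at the ends of the A compartment
        slides = [0.0] * 4 + [-1.5] * 8 + [0.0] * 7
        xd_bp = [0.0] * 4 + [-4.2] * 8 + [0.0] * 8
        cls = tt.classify_form(*self._tables(slides, xd_bp))
        lengths = [(lab, end - start + 1) for lab, start, end in cls.runs]
        assert lengths == [("B", 4), ("A", 8), ("B", 7)]

    def test_depends_only_on_values_and_idempotent(self):
        slides = [0.0] * 3 + [-1.5] * 5
        xd = [0.0] * 3 + [-4.2] * 6
        step, axis = self._tables(slides, xd)
        first = tt.classify_form(step, axis)
        relabeled = step.copy()
        relabeled.index = [f"s{i}" for i in range(len(step))]
        second = tt.classify_form(relabeled, axis)
        assert first.labels == second.labels and first.runs == second.runs

    def test_short_runs_absorbed_into_earlier(self):
        slides = [0.0] * 5 + [-1.5] + [0.0] * 5
        xd = [0.0] * 5 + [-4.2] + [0.0] * 6
        cls = tt.classify_form(*self._tables(slides, xd), min_run_length=2)
        assert cls.runs == [("B", 0, 10)]


class TestParameterSeries:
    def test_constant_builder_trajectory(self):
        traj1, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(6, slide=-1.0))
        coords = np.repeat(traj1.coords, 4, axis=0)
        traj = tt.Trajectory(traj1.topology, coords)
        s = tt.parameter_series(traj, pairing, "slide", 2)
        np.testing.assert_allclose(s.values, -1.0, atol=1e-6)
        assert len(s) == 4

    def test_ramped_slide_schedule_recovered(self):
        ramp = np.linspace(-2.0, 0.5, 5)
        frames = []
        for v in ramp:
            t, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(6, slide=float(v)))
            frames.append(t.coords[0])
        traj = tt.Trajectory(t.topology, np.stack(frames))
        s = tt.parameter_series(traj, pairing, "slide", 3)
        np.testing.assert_allclose(s.values, ramp, atol=1e-6)

    def test_single_frame_and_label_locus(self):
        traj, pairing = tt.build_duplex(tt.DuplexRecipe.uniform(6))
        labels = ["-3", "-2", "-1", "+1", "+2", "+3"]
        s = tt.parameter_series(traj, pairing, "twist", "-1/+1", labels=labels)
        assert len(s) == 1
        assert s.values[0] == pytest.approx(36.0, abs=1e-6)
        xd = tt.parameter_series(traj, pairing, "xdisp", "+1", labels=labels)
        assert len(xd) == 1
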
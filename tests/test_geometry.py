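"""Collective-variable calculators: values, gradients, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metadrt as m
from metadrt.geometry import (
    DegenerateGeometryError,
    InvalidSelectionError,
    min_intergroup_distance,
)

from conftest import random_rigid_motion


def frame_of(points, masses=None):
    points = np.asarray(points, dtype=float)
    masses = np.ones(len(points)) if masses is None else np.asarray(masses, float)
    return m.Frame(points, masses)


class TestCenterOfMass:
    def test_single_particle_identity(self):
        f = frame_of([[1, 2, 3]])
        assert np.allclose(m.center_of_mass(f, m.AtomGroup([0])), [1, 2, 3])

    def test_equal_masses_midpoint(self):
        f = frame_of([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(m.center_of_mass(f, m.AtomGroup([0, 1])), [1, 0, 0])

    def test_mass_weighting(self):
        f = frame_of([[0, 0, 0], [4, 0, 0]], masses=[1, 3])
        assert np.allclose(m.center_of_mass(f, m.AtomGroup([0, 1])), [3, 0, 0])

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidSelectionError):
            m.AtomGroup([])

    def test_out_of_bounds_rejected(self):
        f = frame_of([[0, 0, 0]])
        with pytest.raises(InvalidSelectionError):
            m.center_of_mass(f, m.AtomGroup([0, 5]))


class TestDistanceAngleDihedral:
    def test_distance_345(self):
        f = frame_of([[0, 0, 0], [3, 4, 0]])
        assert m.cv_distance(f, m.AtomGroup([0]), m.AtomGroup([1])) == pytest.approx(5.0)

    def test_distance_identical_groups_zero(self):
        f = frame_of([[1, 1, 1], [2, 2, 2]])
        g = m.AtomGroup([0, 1])
        assert m.cv_distance(f, g, g) == pytest.approx(0.0)

    def test_distance_sqrt3(self):
        f = frame_of([[1, 1, 1], [2, 2, 2]])
        d = m.cv_distance(f, m.AtomGroup([0]), m.AtomGroup([1]))
        assert d == pytest.approx(np.sqrt(3.0))

    @pytest.mark.parametrize(
        "points, expected",
        [
            ([[1, 0, 0], [0, 0, 0], [0, 1, 0]], 90.0),
            ([[0, 0, 0], [1, 0, 0], [2, 0, 0]], 180.0),
            ([[1, 0, 0], [0, 0, 0], [1, 1, 0]], 45.0),
        ],
    )
    def test_angle_closed_forms(self, points, expected):
        f = frame_of(points)
        gs = [m.AtomGroup([i]) for i in range(3)]
        assert m.cv_angle(f, *gs) == pytest.approx(expected)

    def test_angle_degenerate_raises(self):
        f = frame_of([[0, 0, 0], [0, 0, 0], [1, 0, 0]], masses=[1, 1, 1])
        with pytest.raises(DegenerateGeometryError):
            m.cv_angle(f, m.AtomGroup([0]), m.AtomGroup([1]), m.AtomGroup([2]))

    @pytest.mark.parametrize(
        "fourth, expected",
        [([0, 1, 0], 0.0), ([2, 1, 0], 180.0), ([1, 1, 1], 90.0), ([1, 1, -1], -90.0)],
    )
    def test_dihedral_planar_and_twisted(self, fourth, expected):
        pts = [[0, 0, 0], [1, 0, 0], [1, 1, 0], fourth]
        f = frame_of(pts)
        gs = [m.AtomGroup([i]) for i in range(4)]
        assert m.cv_dihedral(f, *gs) == pytest.approx(expected)

    def test_dihedral_independent_sign_oracle(self):
        """Sign and magnitude agree with sign((n1×n2)·b2)·arccos(n̂1·n̂2)."""
        rng = np.random.default_rng(42)
        gs = [m.AtomGroup([i]) for i in range(4)]
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            cosphi = np.clip(
                np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2)), -1, 1
            )
            sign = np.sign(np.dot(np.cross(n1, n2), b2)) or 1.0
            expected = sign * np.degrees(np.arccos(cosphi))
            got = m.cv_dihedral(frame_of(pts), *gs)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_dihedral_mirror_flips_sign(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], float)
        gs = [m.AtomGroup([i]) for i in range(4)]
        phi = m.cv_dihedral(frame_of(pts), *gs)
        mirrored = pts * np.array([1, 1, -1])
        assert m.cv_dihedral(frame_of(mirrored), *gs) == pytest.approx(-phi)

    def test_dihedral_collinear_raises(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        gs = [m.AtomGroup([i]) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            m.cv_dihedral(frame_of(pts), *gs)


class TestRMSD:
    def test_identity_zero(self):
        f = frame_of([[0, 0, 0], [1, 1, 1]])
        assert m.cv_rmsd(f, f, m.AtomGroup([0, 1])) == pytest.approx(0.0)

    def test_uniform_displacement(self):
        ref = frame_of([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        shift = np.array([1.0, 2.0, 2.0])  # norm 3
        f = frame_of(ref.coords + shift)
        assert m.cv_rmsd(f, ref, m.AtomGroup([0, 1, 2])) == pytest.approx(3.0)

    def test_two_particle_closed_form(self):
        ref = frame_of([[0, 0, 0], [5, 0, 0]])
        f = frame_of([[1, 0, 0], [5, 2, 0]])  # displacements 1 and 2
        assert m.cv_rmsd(f, ref, m.AtomGroup([0, 1])) == pytest.approx(np.sqrt(2.5))

    def test_superposition_removes_rigid_motion(self):
        rng = np.random.default_rng(0)
        ref = frame_of(rng.normal(size=(6, 3)))
        rot, trans = random_rigid_motion(rng)
        moved = frame_of(ref.coords @ rot.T + trans)
        g = m.AtomGroup(range(6))
        assert m.cv_rmsd(moved, ref, g) > 1.0
        assert m.cv_rmsd(moved, ref, g, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_reference_index_mismatch(self):
        ref = frame_of([[0, 0, 0]])
        f = frame_of([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(InvalidSelectionError):
            m.cv_rmsd(f, ref, m.AtomGroup([0, 1]))


class TestEvaluateCVs:
    def test_empty_spec_list(self):
        f = frame_of([[0, 0, 0]])
        assert m.evaluate_cvs(f, []).shape == (0,)

    def test_single_distance_consistency(self):
        f = frame_of([[0, 0, 0], [3, 4, 0]])
        spec = m.CVSpec("distance", (m.AtomGroup([0]), m.AtomGroup([1])))
        assert m.evaluate_cvs(f, [spec])[0] == pytest.approx(5.0)

    def test_five_cv_set_matches_individual_calls(self, pseudo_complex):
        complex_, specs = pseudo_complex
        frame = complex_.frame(2.0)
        values = m.evaluate_cvs(frame, specs)
        expected = [
            m.cv_distance(frame, *specs[0].groups),
            m.cv_angle(frame, *specs[1].groups),
            m.cv_dihedral(frame, *specs[2].groups),
            m.cv_rmsd(frame, specs[3].reference, specs[3].groups[0]),
            m.cv_rmsd(frame, specs[4].reference, specs[4].groups[0]),
        ]
        assert np.allclose(values, expected)


class TestUnboundDetector:
    def two_groups(self, sep):
        coords = [[0, 0, 0], [sep, 0, 0]]
        return frame_of(coords), m.AtomGroup([0]), m.AtomGroup([1])

    @pytest.mark.parametrize("sep, expected", [(4.9, False), (5.1, True), (100.0, True)])
    def test_cutoff_boundary(self, sep, expected):
        f, lig, rec = self.two_groups(sep)
        assert m.is_unbound(f, lig, rec, cutoff=5.0) is expected

    def test_overlapping_groups_rejected(self):
        f = frame_of([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(InvalidSelectionError):
            m.is_unbound(f, m.AtomGroup([0, 1]), m.AtomGroup([1]))

    def test_monotone_in_cutoff(self):
        f, lig, rec = self.two_groups(7.0)
        assert m.is_unbound(f, lig, rec, cutoff=6.0)
        assert m.is_unbound(f, lig, rec, cutoff=3.0)  # smaller cutoff stays unbound

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_min_distance_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(1, 10, size=2)
        coords = rng.normal(scale=8.0, size=(n_a + n_b, 3))
        f = frame_of(coords)
        ga, gb = m.AtomGroup(range(n_a)), m.AtomGroup(range(n_a, n_a + n_b))
        brute = min(
            np.linalg.norm(coords[i] - coords[j])
            for i in range(n_a)
            for j in range(n_a, n_a + n_b)
        )
        assert min_intergroup_distance(f, ga, gb) == pytest.approx(brute)


class TestRigidMotionInvariance:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_all_cvs_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        complex_, specs = m.generate_pseudo_complex(seed=3)
        frame = complex_.frame(1.5)
        values = m.evaluate_cvs(frame, specs)
        rot, trans = random_rigid_motion(rng)
        moved = m.Frame(frame.coords @ rot.T + trans, frame.masses)
        moved_specs = [
            spec
            if spec.kind != "rmsd"
            else m.CVSpec(
                "rmsd",
                spec.groups,
                reference=m.Frame(
                    spec.reference.coords @ rot.T + trans, spec.reference.masses
                ),
                name=spec.name,
            )
            for spec in specs
        ]
        assert np.allclose(m.evaluate_cvs(moved, moved_specs), values, atol=1e-8)

    def test_triangle_inequality_of_com_distances(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=5.0, size=(9, 3))
        f = frame_of(coords)
        g = [m.AtomGroup(range(3 * i, 3 * i + 3)) for i in range(3)]
        ab = m.cv_distance(f, g[0], g[1])
        bc = m.cv_distance(f, g[1], g[2])
        ac = m.cv_distance(f, g[0], g[2])
        assert ac <= ab + bc + 1e-12


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, pseudo_complex):
        complex_, specs = pseudo_complex
        frame = complex_.frame(1.3)
        rng = np.random.default_rng(9)
        eps = 1e-6
        for spec in specs:
            _, grad = m.cv_value_and_gradient(frame, spec)
            for _ in range(6):
                i = int(rng.integers(frame.n_atoms))
                j = int(rng.integers(3))
                cp = frame.coords.copy()
                cp[i, j] += eps
                vp = m.evaluate_cvs(m.Frame(cp, frame.masses), [spec])[0]
                cp[i, j] -= 2 * eps
                vm = m.evaluate_cvs(m.Frame(cp, frame.masses), [spec])[0]
                fd = (vp - vm) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, abs=2e-6), spec.name
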
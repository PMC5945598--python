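"""Superposition, screw decomposition and inter-domain axes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filaxis.errors import GeometryError, NoRotationError
from filaxis.geometry import (RigidTransform, rotation_to_axis_angle,
                              screw_axis_between, screw_to_transform,
                              superpose, superpose_coords)
from filaxis.structio import ResidueSelection
from filaxis.synth import TwoDomainSpec, make_two_domain_ensemble

from conftest import model_from_points


def random_transform(rng) -> RigidTransform:
    return RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                          rng.normal(scale=10, size=3))


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self):
        rng = np.random.default_rng(0)
        t1, t2 = random_transform(rng), random_transform(rng)
        pts = rng.normal(size=(5, 3))
        assert np.allclose(t1.compose(t2).apply(pts),
                           t1.apply(t2.apply(pts)), atol=1e-12)
        assert np.allclose(t1.inverse().apply(t1.apply(pts)), pts,
                           atol=1e-9)


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(1)
        model = model_from_points(rng.normal(size=(12, 3)))
        t, rmsd = superpose(model, model, ResidueSelection.whole_chain("A"))
        assert rmsd < 1e-12
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(t.translation).max() < 1e-9

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        shift = np.array([1.0, 2.0, 3.0])
        moved = model_from_points(pts @ R.T + shift)
        ref = model_from_points(pts)
        t, rmsd = superpose(moved, ref, ResidueSelection.whole_chain("A"))
        assert rmsd < 1e-9
        assert np.abs(t.rotation - R.T).max() < 1e-9  # inverts the motion

    def test_rmsd_matches_random_search_oracle(self):
        """Fitted RMSD equals a stochastic search minimum over rotations.

        10,000 global random rotations followed by random local refinement
        at shrinking step sizes; wholly independent of the SVD solution.
        """
        rng = np.random.default_rng(3)
        P = rng.normal(size=(10, 3))
        true = random_transform(rng)
        Q = true.apply(P) + rng.normal(scale=0.1, size=P.shape)
        _, fitted = superpose_coords(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)

        def cost(R):
            d = Qc - Pc @ R.T
            return np.sqrt((d * d).sum(axis=1).mean())

        best_R, best = None, np.inf
        for R in Rotation.random(10_000, random_state=rng).as_matrix():
            c = cost(R)
            if c < best:
                best_R, best = R, c
        for step in (0.1, 0.03, 0.01, 0.003, 0.001):
            for _ in range(400):
                perturb = Rotation.from_rotvec(
                    rng.normal(scale=step, size=3)).as_matrix()
                R = perturb @ best_R
                c = cost(R)
                if c < best:
                    best_R, best = R, c
        assert fitted <= best + 1e-12
        assert abs(fitted - best) < 1e-3

    def test_too_few_or_collinear_pairs(self):
        two = model_from_points([[0, 0, 0], [1, 0, 0]])
        line = model_from_points([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        sel = ResidueSelection.whole_chain("A")
        with pytest.raises(GeometryError, match=">=3"):
            superpose(two, two, sel)
        with pytest.raises(GeometryError, match="collinear"):
            superpose(line, line, sel)

    def test_mismatched_atom_sets_reported(self):
        a = model_from_points(np.random.default_rng(4).normal(size=(6, 3)))
        b = model_from_points(np.random.default_rng(5).normal(size=(4, 3)))
        sel = ResidueSelection.whole_chain("A")
        with pytest.raises(GeometryError, match="unmatched residues"):
            superpose(a, b, sel)
        # intersect mode succeeds over the common residues
        t, _ = superpose(a, b, sel, on_mismatch="intersect")
        assert t is not None

    def test_optimality_against_random_transforms(self):
        """The fit never loses to a randomly sampled rigid transform."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            P = rng.normal(size=(8, 3))
            Q = random_transform(rng).apply(P) \
                + rng.normal(scale=0.2, size=P.shape)
            _, fitted = superpose_coords(P, Q)
            for _ in range(20):
                cand = random_transform(rng)
                d = Q - cand.apply(P)
                assert fitted <= np.sqrt((d * d).sum(1).mean()) + 1e-12


class TestScrewDecomposition:
    def test_pure_rotation_about_z(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        axis = rotation_to_axis_angle(RigidTransform(R, np.zeros(3)))
        assert axis.angle_deg == pytest.approx(90.0, abs=1e-9)
        assert np.allclose(axis.direction, [0, 0, 1], atol=1e-12)
        assert axis.translation_along_axis == pytest.approx(0.0, abs=1e-12)

    def test_identity_is_flagged(self):
        axis = rotation_to_axis_angle(RigidTransform.identity())
        assert axis.is_identity
        assert axis.angle_deg == 0.0
        with pytest.raises(NoRotationError):
            _ = axis.direction
        with pytest.raises(NoRotationError):
            _ = axis.point

    def test_round_trip_reproduces_transform(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = random_transform(rng)
            back = screw_to_transform(rotation_to_axis_angle(t))
            assert np.abs(back.rotation - t.rotation).max() < 1e-9
            assert np.abs(back.translation - t.translation).max() < 1e-9

    def test_axis_point_is_fixed_up_to_axial_slide(self):
        rng = np.random.default_rng(8)
        t = random_transform(rng)
        axis = rotation_to_axis_angle(t)
        moved = t.apply(axis.point[None])[0]
        expect = axis.point + axis.translation_along_axis * axis.direction
        assert np.abs(moved - expect).max() < 1e-8


class TestScrewAxisBetween:
    @pytest.mark.parametrize("angle", [6.0, 15.0])
    def test_planted_hinge_recovered_noise_free(self, angle):
        models, truth = make_two_domain_ensemble(TwoDomainSpec(
            seed=21, noise_sd=0.0, angles_deg=(0.0, angle)))
        fixed = ResidueSelection.from_ranges("A", [tuple(truth["body_a_residues"])])
        moving = ResidueSelection.from_ranges("A", [tuple(truth["body_b_residues"])])
        screw = screw_axis_between(models[0], models[1], fixed, moving)
        assert screw.angle_deg == pytest.approx(angle, abs=1e-6)
        cosang = abs(float(screw.direction @ np.array(truth["hinge_axis"])))
        assert np.arccos(min(cosang, 1.0)) < 1e-6

    def test_same_conformer_gives_no_rotation(self, hinge_ensemble):
        models, truth = hinge_ensemble
        fixed = ResidueSelection.from_ranges("A", [tuple(truth["body_a_residues"])])
        moving = ResidueSelection.from_ranges("A", [tuple(truth["body_b_residues"])])
        screw = screw_axis_between(models[0], models[0], fixed, moving)
        assert screw.is_identity or screw.angle_deg < 1e-9

    def test_direction_symmetry(self, hinge_ensemble):
        """Swapping the conformers preserves the angle exactly.

        The two fits are exact inverses, so the angle agrees to numerical
        precision; the reported direction is expressed in each conformer's
        own fixed-body frame, so on noisy data the two axes agree only up
        to the (noise-driven) frame rotation.
        """
        models, truth = hinge_ensemble
        fixed = ResidueSelection.from_ranges("A", [tuple(truth["body_a_residues"])])
        moving = ResidueSelection.from_ranges("A", [tuple(truth["body_b_residues"])])
        fwd = screw_axis_between(models[0], models[4], fixed, moving)
        rev = screw_axis_between(models[4], models[0], fixed, moving)
        assert fwd.angle_deg == pytest.approx(rev.angle_deg, abs=1e-6)
        assert abs(float(fwd.direction @ rev.direction)) > np.cos(
            np.radians(1.0))

    def test_direction_symmetry_exact_without_noise(self):
        models, truth = make_two_domain_ensemble(TwoDomainSpec(
            seed=22, noise_sd=0.0, angles_deg=(0.0, 9.0)))
        fixed = ResidueSelection.from_ranges("A", [tuple(truth["body_a_residues"])])
        moving = ResidueSelection.from_ranges("A", [tuple(truth["body_b_residues"])])
        fwd = screw_axis_between(models[0], models[1], fixed, moving)
        rev = screw_axis_between(models[1], models[0], fixed, moving)
        assert fwd.angle_deg == pytest.approx(rev.angle_deg, abs=1e-9)
        assert abs(float(fwd.direction @ rev.direction)) == pytest.approx(
            1.0, abs=1e-9)
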
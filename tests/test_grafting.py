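"""Site extraction, rigid-body grafting and hybrid two-strand filaments."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filaxis.errors import GraftError
from filaxis.grafting import (GraftRecipe, HybridSpec, annotate_filament,
                              build_hybrid_filament,
                              compare_collision_counts,
                              extract_site_complex, graft_by_rigid_body)
from filaxis.helical import fit_helical_axis, strand_rotation_from_genetic
from filaxis.structio import ResidueSelection
from filaxis.synth import (FilamentSpec, make_clash_fixture,
                           make_decorated_filament)

from conftest import model_from_points


def chain_coords(model, chain_id):
    return np.vstack([a.coord for r in model.chain(chain_id).residues
                      for a in r.atoms])


class TestAnnotation:
    def test_roles_and_pairing_match_ground_truth(self, decorated_filament):
        model, truth = decorated_filament
        ann = annotate_filament(model)
        assert ann.actin_chains == truth["actin_chains"]
        assert {k: list(v) for k, v in ann.cofilin_map.items()} == \
            truth["cofilin_map"]


class TestExtractSiteComplex:
    def test_f_site_takes_the_barbed_end_subunit(self, decorated_filament):
        model, truth = decorated_filament
        cof = next(iter(truth["cofilin_map"]))
        b_sub, p_sub = truth["cofilin_map"][cof]
        complex_model = extract_site_complex(model, "F", cofilin_chain=cof)
        assert [c.id for c in complex_model.chains] == [b_sub, cof]

    def test_g_site_takes_the_pointed_end_subunit(self, decorated_filament):
        model, truth = decorated_filament
        cof = next(iter(truth["cofilin_map"]))
        _, p_sub = truth["cofilin_map"][cof]
        complex_model = extract_site_complex(model, "G", cofilin_chain=cof)
        assert [c.id for c in complex_model.chains] == [p_sub, cof]

    def test_monomeric_input_rejected(self):
        mono = model_from_points(np.random.default_rng(0).normal(size=(8, 3)))
        with pytest.raises(GraftError, match="chains found"):
            extract_site_complex(mono, "F")


class TestGraftByRigidBody:
    def test_identity_graft_returns_cofilin_in_place(self, decorated_filament):
        model, truth = decorated_filament
        cof = next(iter(truth["cofilin_map"]))
        b_sub, _ = truth["cofilin_map"][cof]
        complex_model = extract_site_complex(model, "F", cofilin_chain=cof)
        recipe = GraftRecipe(complex_model,
                             ResidueSelection.whole_chain(b_sub),
                             b_sub, cof, b_sub, "F")
        result = graft_by_rigid_body(recipe, model)
        orig = chain_coords(model, cof)
        back = chain_coords(result.model, result.grafted_chain)
        assert np.abs(orig - back).max() < 1e-9
        assert result.alignment_rmsd < 1e-9

    def test_graft_is_equivariant(self, decorated_filament, bare_filament):
        model, truth = decorated_filament
        bare, _ = bare_filament
        cof = next(iter(truth["cofilin_map"]))
        b_sub, _ = truth["cofilin_map"][cof]
        complex_model = extract_site_complex(model, "F", cofilin_chain=cof)
        recipe = GraftRecipe(complex_model,
                             ResidueSelection.whole_chain(b_sub),
                             b_sub, cof, "D", "F")
        plain = graft_by_rigid_body(recipe, bare)
        rng = np.random.default_rng(1)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(scale=15, size=3)
        moved_target = bare.copy()
        moved_target.transform(R, t)
        moved = graft_by_rigid_body(recipe, moved_target)
        expect = chain_coords(plain.model, plain.grafted_chain) @ R.T + t
        got = chain_coords(moved.model, moved.grafted_chain)
        assert np.abs(expect - got).max() < 1e-9

    def test_internal_geometry_preserved(self, decorated_filament,
                                         bare_filament):
        model, truth = decorated_filament
        bare, _ = bare_filament
        cof = next(iter(truth["cofilin_map"]))
        b_sub, _ = truth["cofilin_map"][cof]
        complex_model = extract_site_complex(model, "F", cofilin_chain=cof)
        recipe = GraftRecipe(complex_model,
                             ResidueSelection.whole_chain(b_sub),
                             b_sub, cof, "B", "F")
        result = graft_by_rigid_body(recipe, bare)
        before = chain_coords(model, cof)
        after = chain_coords(result.model, result.grafted_chain)
        d_before = np.linalg.norm(before[:, None] - before[None], axis=-1)
        d_after = np.linalg.norm(after[:, None] - after[None], axis=-1)
        assert np.abs(d_before - d_after).max() < 1e-9


class TestHybridFilament:
    def test_self_replacement_is_identity(self):
        bare, truth = make_decorated_filament(FilamentSpec(
            seed=9, decorated=False, n_subunits=4))
        res = build_hybrid_filament(
            bare, bare, HybridSpec(span=2, center_subunit=2, strand="A"),
            ResidueSelection.whole_chain("A"))
        for cid in truth["actin_chains"]:
            assert np.abs(chain_coords(res.model, cid)
                          - chain_coords(bare, cid)).max() < 1e-9

    def test_replaced_strand_carries_donor_twist(self, decorated_filament,
                                                 bare_filament):
        cof_fil, cof_truth = decorated_filament
        bare, bare_truth = bare_filament
        res = build_hybrid_filament(
            cof_fil, bare, HybridSpec(span=3, center_subunit=2, strand="A"),
            ResidueSelection.whole_chain("A"))
        strand_a = [ResidueSelection.whole_chain(c) for c in "ACE"]
        strand_b = [ResidueSelection.whole_chain(c) for c in "BDF"]
        twist_a = fit_helical_axis(res.model, strand_a).symmetry
        twist_b = fit_helical_axis(res.model, strand_b).symmetry
        want_a = strand_rotation_from_genetic(
            cof_truth["genetic_twist_deg"]).delta_phi_deg
        want_b = strand_rotation_from_genetic(
            bare_truth["genetic_twist_deg"]).delta_phi_deg
        assert twist_a.genetic_twist_deg == pytest.approx(want_a, abs=1e-6)
        assert twist_b.genetic_twist_deg == pytest.approx(want_b, abs=1e-6)

    def test_opposite_strand_untouched_bitwise(self, decorated_filament,
                                               bare_filament):
        cof_fil, _ = decorated_filament
        bare, _ = bare_filament
        res = build_hybrid_filament(
            cof_fil, bare, HybridSpec(span=2, center_subunit=2, strand="A"),
            ResidueSelection.whole_chain("A"))
        for cid in "BDF":
            assert np.array_equal(chain_coords(res.model, cid),
                                  chain_coords(bare, cid))

    def test_bound_cofilins_travel_with_the_stretch(self, decorated_filament,
                                                    bare_filament):
        cof_fil, truth = decorated_filament
        bare, _ = bare_filament
        res = build_hybrid_filament(
            cof_fil, bare, HybridSpec(span=3, center_subunit=2, strand="A"),
            ResidueSelection.whole_chain("A"))
        # span A,C,E hosts the two strand-A cofilins (A-C and C-E bridges)
        assert sorted(res.donor_cofilin_chains) == ["a", "c"]

    def test_span_outside_two_to_five_rejected(self, decorated_filament,
                                               bare_filament):
        cof_fil, _ = decorated_filament
        bare, _ = bare_filament
        with pytest.raises(GraftError, match="span"):
            build_hybrid_filament(
                cof_fil, bare, HybridSpec(span=6, center_subunit=2),
                ResidueSelection.whole_chain("A"))
        res = build_hybrid_filament(
            cof_fil, bare, HybridSpec(span=1, center_subunit=2),
            ResidueSelection.whole_chain("A"), allow_any_span=True)
        assert res.replaced_chains == ["C"]


class TestCollisionComparison:
    def test_identical_models_zero_reduction(self):
        model, _ = make_clash_fixture(10, 4)
        assert compare_collision_counts(model, model, [("X", "Y")]) == \
            pytest.approx(0.0)

    def test_planted_counts_give_eighty_percent(self):
        few, _ = make_clash_fixture(10, 2)
        many, _ = make_clash_fixture(10, 10)
        out = compare_collision_counts(few, many, [("X", "Y")])
        assert out == pytest.approx(80.0)

    def test_zero_reference_is_undefined(self):
        none, _ = make_clash_fixture(5, 0)
        some, _ = make_clash_fixture(5, 3)
        with pytest.raises(GraftError, match="undefined"):
            compare_collision_counts(some, none, [("X", "Y")])
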
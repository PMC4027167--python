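import numpy as np
import pytest

from conftest import random_rotation
from napring.docking import (RestraintR3, TetramerModel, c2_transform,
                             clash_score, dock_symmetric_tetramer,
                             params_from_transform, predict_interface_contacts,
                             restraint_violation, soft_clash_penalty,
                             superpose_and_clash, tetramer_rmsd)
from napring.errors import AlignmentError, DockingFailure
from napring.labels import LabelEnsemble
from napring.structure import Atom, RigidTransform, Structure, apply_transform


class TestC2Transform:
    @pytest.mark.parametrize("params", [
        (0.3, 1.2, 10.0, -5.0),
        (1.5, -0.4, 0.0, 40.0),
        (np.pi / 2, 0.0, 25.0, 25.0),
    ])
    def test_is_involution(self, params):
        T = c2_transform(*params)
        TT = T.compose(T)
        assert np.allclose(TT.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(TT.translation, 0.0, atol=1e-10)

    @pytest.mark.parametrize("params", [
        (0.3, 1.2, 10.0, -5.0),
        (2.1, 2.8, -17.0, 3.0),
    ])
    def test_parameter_round_trip(self, params):
        origin = np.array([5.0, -2.0, 8.0])
        T = c2_transform(*params, origin=origin)
        x = params_from_transform(T, origin=origin)
        T2 = c2_transform(*x, origin=origin)
        assert np.allclose(T2.rotation, T.rotation, atol=1e-9)
        assert np.allclose(T2.translation, T.translation, atol=1e-7)


class TestScores:
    def test_restraint_violation_flat_bottom(self, toy_dimer, toy_ensembles,
                                             o_tetramer):
        _, T = o_tetramer
        from napring.labels import effective_r3_distance

        r_eff = effective_r3_distance(toy_ensembles["ear_A"],
                                      toy_ensembles["ear_A"].transformed(T))
        model = TetramerModel(dimer=toy_dimer, transform=T)
        at_target = RestraintR3(toy_ensembles["ear_A"], toy_ensembles["ear_A"],
                                r_eff, 0.0)
        at_edge = RestraintR3(toy_ensembles["ear_A"], toy_ensembles["ear_A"],
                              r_eff - 0.2, 0.2)
        beyond = RestraintR3(toy_ensembles["ear_A"], toy_ensembles["ear_A"],
                             r_eff - 0.7, 0.2)
        assert restraint_violation(model, at_target) == pytest.approx(0.0)
        assert restraint_violation(model, at_edge) == pytest.approx(0.0, abs=1e-9)
        assert restraint_violation(model, beyond) == pytest.approx(0.5, abs=1e-9)

    def test_clash_count_separated_and_superposed(self, toy_dimer):
        # a pure translation is not a C2; build the far copy via c2_transform
        T_far = c2_transform(0.1, 0.2, 250.0, 0.0)
        far = TetramerModel(dimer=toy_dimer, transform=T_far)
        assert clash_score(far) == 0
        n_ca = int(toy_dimer.mask(atom_name="CA").sum())
        # exact superposition: C2 with axis through the dimer's own symmetry
        identity_like = c2_transform(0.0, 0.0, 0.0, 0.0)
        count = clash_score(TetramerModel(dimer=toy_dimer,
                                          transform=identity_like), cutoff=4.0)
        assert count >= n_ca  # every atom has at least its own image nearby

    def test_clash_count_matches_brute_force(self, toy_dimer):
        T = c2_transform(0.7, 0.3, 20.0, 5.0)
        model = TetramerModel(dimer=toy_dimer, transform=T)
        ca = toy_dimer.positions[toy_dimer.mask(atom_name="CA")]
        ca2 = T.apply(ca)
        brute = sum(1 for p in ca for q in ca2
                    if np.linalg.norm(p - q) < 4.0)
        assert clash_score(model, 4.0) == brute

    def test_soft_penalty_zero_when_separated(self):
        a = np.zeros((5, 3))
        b = np.zeros((5, 3)) + np.array([100.0, 0, 0])
        assert soft_clash_penalty(a, b) == 0.0


class TestDockingRecovery:
    def test_truth_recovered_and_x_topology_scores_worse(
            self, toy_dimer, truth_restraints, o_tetramer):
        """Zero-noise restraints from the ring truth pull docking back to the
        truth; the four-helix-bundle arrangement violates them badly."""
        from napring.docking import _score_transform
        from napring.synthesis import make_tetramer_geometry

        _, T_true = o_tetramer
        result = dock_symmetric_tetramer(toy_dimer, truth_restraints,
                                         n_starts=16, seed=11,
                                         accept_viol=0.05,
                                         refilter_ensembles=False)
        best = result.best
        assert best.total_violation < 0.05
        assert tetramer_rmsd(best, T_true) < 3.0
        ca = toy_dimer.positions[toy_dimer.mask(atom_name="CA")]
        _, T_x = make_tetramer_geometry("X", toy_dimer)
        score_o = _score_transform(T_true, truth_restraints, ca, 4.0, 1.0)
        score_x = _score_transform(T_x, truth_restraints, ca, 4.0, 1.0)
        assert score_x > score_o + 1.0

    def test_empty_restraints_accept_any_separated_arrangement(self, toy_dimer):
        result = dock_symmetric_tetramer(toy_dimer, [], n_starts=4, seed=0,
                                         accept_viol=0.05,
                                         refilter_ensembles=False)
        assert result.best.score == pytest.approx(0.0, abs=1e-9)
        assert result.best.clash_count == 0

    def test_violations_idempotent_on_recompute(self, toy_dimer,
                                                truth_restraints):
        result = dock_symmetric_tetramer(toy_dimer, truth_restraints,
                                         n_starts=6, seed=2, accept_viol=0.3,
                                         refilter_ensembles=False)
        model = result.best
        recomputed = np.array([restraint_violation(model, r)
                               for r in truth_restraints])
        assert np.allclose(recomputed, model.violations, atol=1e-9)

    def test_score_invariant_under_global_rigid_motion(self, toy_dimer,
                                                       truth_restraints,
                                                       o_tetramer):
        """Moving the whole tetramer (dimer + transform conjugation + both
        ensembles) leaves every violation unchanged."""
        _, T = o_tetramer
        G = RigidTransform(random_rotation(21), np.array([30.0, -12.0, 7.0]))
        T_conj = G.compose(T).compose(G.inverse())
        moved_dimer = apply_transform(toy_dimer, G)
        for r in truth_restraints:
            moved = RestraintR3(r.ensemble_a.transformed(G),
                                r.ensemble_b.transformed(G),
                                r.target, r.tolerance)
            v0 = restraint_violation(
                TetramerModel(dimer=toy_dimer, transform=T), r)
            v1 = restraint_violation(
                TetramerModel(dimer=moved_dimer, transform=T_conj), moved)
            assert v1 == pytest.approx(v0, abs=1e-9)

    def test_impossible_restraints_fail_docking(self, toy_dimer, toy_ensembles):
        bad = [RestraintR3(toy_ensembles["ear_A"], toy_ensembles["ear_A"],
                           0.5, 0.0),
               RestraintR3(toy_ensembles["ear_A"], toy_ensembles["ear_A"],
                           11.5, 0.0)]
        result = dock_symmetric_tetramer(toy_dimer, bad, n_starts=3, seed=0,
                                         accept_viol=0.01,
                                         refilter_ensembles=False)
        with pytest.raises(DockingFailure):
            _ = result.best


class TestInterfacePredictions:
    def test_contacts_empty_when_separated(self, toy_dimer):
        model = TetramerModel(dimer=toy_dimer,
                              transform=c2_transform(0.1, 0.2, 300.0, 0.0))
        assert predict_interface_contacts(model, cutoff=5.0) == []

    def test_symmetric_self_pairs_flagged(self, toy_dimer, o_tetramer):
        _, T = o_tetramer
        model = TetramerModel(dimer=toy_dimer, transform=T)
        contacts = predict_interface_contacts(model, cutoff=8.0)
        assert contacts, "ring interface should produce contacts"
        assert contacts == sorted(contacts, key=lambda c: c[2])
        # the earmuff-earmuff ring interface contains i-i' self pairs
        assert any(sym for *_, sym in contacts)

    def test_superpose_self_gives_zero_clashes(self, toy_dimer, o_tetramer):
        _, T = o_tetramer
        model = TetramerModel(dimer=toy_dimer, transform=T)
        # align the dimer onto its own copy 1 via both chains: the "partner"
        # has no non-shared chains left, so no clashes are possible
        count = superpose_and_clash(model, toy_dimer,
                                    {"A": "A", "B": "B"}, cutoff=3.0)
        assert count == 0

    def test_partner_occupying_interface_clashes(self, toy_dimer, o_tetramer):
        """A partner complex whose extra chain sits where dimer copy 2 is
        must clash with the tetramer, matching a brute-force count."""
        _, T = o_tetramer
        model = TetramerModel(dimer=toy_dimer, transform=T)
        copy2 = toy_dimer.transformed(T)
        extra = [Atom("CA", "C", i + 1, "GLY", "Z", p, 12.0)
                 for i, p in enumerate(copy2.positions[::4])]
        partner = Structure(list(toy_dimer.atoms()) + extra)
        count = superpose_and_clash(model, partner, {"A": "A", "B": "B"},
                                    cutoff=3.0)
        zpos = np.array([a.position for a in extra])
        brute = sum(1 for p in zpos for q in copy2.positions
                    if np.linalg.norm(p - q) < 3.0)
        assert count == brute
        assert count > 0

    def test_alignment_needs_three_atoms(self, toy_dimer, o_tetramer):
        _, T = o_tetramer
        model = TetramerModel(dimer=toy_dimer, transform=T)
        stranger = Structure([Atom("CA", "C", 999, "GLY", "Q",
                                   np.zeros(3), 12.0)])
        with pytest.raises(AlignmentError):
            superpose_and_clash(model, stranger, {"Q": "A"})
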
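"""Superposition, RMSD statistics, distances and groove geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ptdna.duplex import AtomRecord, Ensemble, StructureModel
from ptdna.ensemble import (
    MAJOR_EDGE,
    average_pairwise_rmsd,
    cross_ensemble_rmsd,
    ensemble_distance,
    groove_assign,
    pucker_from_coords,
    superpose,
)
from ptdna.synth import SynthConfig, synth_ensemble


def toy_model(coords, names=None):
    names = names or [f"C{i+1}" for i in range(len(coords))]
    atoms = [
        AtomRecord(n, "C", 1, "DG", "A", c) for n, c in zip(names, coords)
    ]
    return StructureModel(atoms)


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 5, 3)
    return R, t


class TestSuperpose:
    def test_self_superposition_is_zero(self, free_template):
        _, rmsd = superpose(free_template, free_template)
        assert rmsd < 1e-12

    def test_rigid_motion_removed(self, free_template):
        rng = np.random.default_rng(0)
        R, t = random_rigid(rng)
        moved = free_template.with_coords(free_template.coords() @ R.T + t)
        back, rmsd = superpose(moved, free_template, selection="all")
        assert rmsd < 1e-9
        assert np.abs(back.coords() - free_template.coords()).max() < 1e-8

    def test_three_atom_single_displacement_oracle(self):
        # two atoms agree, the third is displaced by 1 A out of plane; an
        # independent numerical optimizer over rotation vectors (after
        # centroid alignment, which is jointly optimal) must agree with the
        # closed-form Kabsch result, and both must beat the no-rotation
        # bound 1/sqrt(3)
        from scipy.optimize import minimize

        ref = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
        mob = ref.copy()
        mob[2, 2] += 1.0
        _, rmsd = superpose(toy_model(mob), toy_model(ref), selection="all")

        c_ref, c_mob = ref.mean(0), mob.mean(0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            trial = (mob - c_mob) @ R.T + c_ref
            return np.sqrt(((trial - ref) ** 2).sum(1).mean())

        best = min(
            minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in (np.zeros(3), np.array([0.2, -0.1, 0.1]))
        )
        assert rmsd == pytest.approx(best, abs=1e-6)
        assert rmsd < 1.0 / np.sqrt(3.0)

    def test_mismatched_selection_rejected(self):
        a = toy_model(np.zeros((3, 3)), ["C1", "C2", "C3"])
        b = toy_model(np.zeros((3, 3)), ["N1", "N2", "N3"])
        with pytest.raises(ValueError):
            superpose(a, b, selection="all")


class TestPairwiseRmsd:
    def test_identical_models_zero(self, free_template):
        e = Ensemble([free_template.with_coords(free_template.coords(), i) for i in (1, 2, 3)])
        rep = average_pairwise_rmsd(e)
        assert rep.mean < 1e-12 and rep.sd < 1e-12

    def test_matrix_symmetric_zero_diagonal(self, free_template):
        e = synth_ensemble(free_template, SynthConfig(seed=3, ensemble_size=4))
        rep = average_pairwise_rmsd(e)
        assert np.allclose(rep.matrix, rep.matrix.T)
        assert np.all(np.diag(rep.matrix) == 0)
        triu = rep.matrix[np.triu_indices(4, 1)]
        assert rep.mean == pytest.approx(triu.mean())

    def test_brute_force_equivalence_small_ensemble(self, free_template):
        """Independent oracle: scipy Rotation.align_vectors per pair."""
        e = synth_ensemble(free_template, SynthConfig(seed=5, ensemble_size=5, jitter_sd=0.1))
        rep = average_pairwise_rmsd(e, "backbone")
        from ptdna.ensemble import resolve_selection

        sel = [i for _, i in resolve_selection(e[0], "backbone")]
        vals = []
        for i in range(5):
            for j in range(i + 1, 5):
                P = e[i].coords()[sel]
                Q = e[j].coords()[sel]
                rot, ssd = Rotation.align_vectors(
                    Q - Q.mean(0), P - P.mean(0)
                )
                moved = rot.apply(P - P.mean(0))
                vals.append(np.sqrt(((moved - (Q - Q.mean(0))) ** 2).sum(1).mean()))
        assert rep.mean == pytest.approx(np.mean(vals), abs=1e-9)

    def test_rigid_invariance(self, free_template):
        e = synth_ensemble(free_template, SynthConfig(seed=6, ensemble_size=4))
        rng = np.random.default_rng(2)
        moved = []
        for m in e:
            R, t = random_rigid(rng)
            moved.append(m.with_coords(m.coords() @ R.T + t, m.model_index))
        assert average_pairwise_rmsd(Ensemble(moved)).mean == pytest.approx(
            average_pairwise_rmsd(e).mean, abs=1e-9
        )

    def test_singleton_rejected(self, free_template):
        with pytest.raises(ValueError):
            average_pairwise_rmsd(Ensemble([free_template]))


class TestCrossEnsemble:
    def test_self_comparison_zero(self, free_template):
        e = synth_ensemble(free_template, SynthConfig(seed=1, ensemble_size=3))
        assert cross_ensemble_rmsd(e, e, mode="model1") < 1e-12
        assert cross_ensemble_rmsd(e, e, mode="mean-structure") < 1e-12

    def test_sulfur_oxygen_mapping(self, rp_template, free_template):
        e_rp = synth_ensemble(rp_template, SynthConfig(seed=2, ensemble_size=3))
        e_free = synth_ensemble(free_template, SynthConfig(seed=3, ensemble_size=3))
        r = cross_ensemble_rmsd(e_rp, e_free)
        assert 0 < r < 0.5  # same helix, jitter + P-S vs P-O offsets only

    def test_unknown_mode_rejected(self, free_template):
        e = synth_ensemble(free_template, SynthConfig(seed=1, ensemble_size=3))
        with pytest.raises(ValueError):
            cross_ensemble_rmsd(e, e, mode="median")


class TestEnsembleDistance:
    def test_three_four_five(self):
        m = toy_model(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]), ["P", "O5'"])
        st = ensemble_distance(Ensemble([m]), [(1, "P", 1, "O5'")])
        assert st.mean == pytest.approx(5.0)

    def test_same_atom_zero(self, free_template):
        st = ensemble_distance(
            Ensemble([free_template]), [(3, "P", 3, "P")]
        )
        assert st.mean == 0.0

    def test_pooling_and_model_order_invariance(self, free_template):
        e = synth_ensemble(free_template, SynthConfig(seed=4, ensemble_size=5))
        pairs = [(2, "H2''", 3, "O2P"), (16, "H2''", 17, "O2P")]
        st = ensemble_distance(e, pairs)
        assert st.per_model.shape == (5, 2)
        assert st.mean == pytest.approx(st.per_model.mean())
        assert min(st.per_model.min(), st.per_site_mean.min()) <= st.mean
        shuffled = Ensemble(list(reversed(e.models)))
        assert ensemble_distance(shuffled, pairs).mean == pytest.approx(st.mean)

    def test_missing_atom_rejected(self, free_template):
        with pytest.raises(KeyError):
            ensemble_distance(Ensemble([free_template]), [(3, "XX", 3, "P")])


class TestGroove:
    def test_rp_sulfur_in_major_groove(self, rp_template):
        for res in (3, 17):
            assert groove_assign(rp_template, res, "S2P").label == "major"

    def test_sp_sulfur_exterior(self, sp_template):
        for res in (3, 17):
            assert groove_assign(sp_template, res, "S1P").label == "exterior"

    def test_major_edge_sweep(self, free_template):
        for a in free_template.atoms:
            if a.name in MAJOR_EDGE.get(a.res_name, ()):
                g = groove_assign(free_template, a.res_num, a.name)
                assert g.label == "major", (a.res_num, a.name, g)

    def test_minor_edge_atom(self, free_template):
        assert groove_assign(free_template, 3, "N3").label == "minor"

    def test_absent_atom_rejected(self, free_template):
        with pytest.raises(KeyError):
            groove_assign(free_template, 3, "S2P")


class TestPuckerFromCoords:
    def test_template_sugars_s_type(self, free_template):
        pucker, label = pucker_from_coords(free_template, 5)
        assert label == "S" and 90 <= pucker.P < 270

    def test_mirrored_sugar_is_n_type(self, free_template):
        # reflecting the ring flips every endocyclic torsion: P -> P + 180
        atoms = [
            AtomRecord(a.name, a.element, a.res_num, a.res_name, a.chain,
                       a.coord * np.array([1.0, 1.0, -1.0]))
            for a in free_template.atoms
        ]
        mirrored = StructureModel(atoms)
        _, label = pucker_from_coords(mirrored, 5)
        assert label == "N"

    def test_planar_ring_degenerate(self):
        ring = ["C1'", "C2'", "C3'", "C4'", "O4'"]
        ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        coords = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], axis=1) * 1.2
        m = toy_model(coords, ring)
        with pytest.raises(ValueError):
            pucker_from_coords(m, 1)

    def test_missing_ring_atom_rejected(self, free_template):
        broken = StructureModel(
            [a for a in free_template.atoms if not (a.res_num == 5 and a.name == "O4'")]
        )
        with pytest.raises(KeyError):
            pucker_from_coords(broken, 5)
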
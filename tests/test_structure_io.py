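"""Geometry primitives and multi-model I/O."""

import logging
import math

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peprdc import (
    Ensemble,
    dihedral,
    ensemble_precision,
    find_cystines,
    read_ensemble,
    superpose,
)
from peprdc import synthetic as syn
from peprdc.structure_io import (
    Model,
    UndefinedDihedralError,
    write_ensemble_pdb,
)

finite = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite, finite, finite).map(np.array)


def gemmi_dihedral(p1, p2, p3, p4):
    """Independent oracle: gemmi's torsion routine."""
    pts = [gemmi.Position(*p) for p in (p1, p2, p3, p4)]
    return math.degrees(gemmi.calculate_dihedral(*pts))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [np.array(v, float) for v in
             [(1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)]]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        p = [np.array(v, float) for v in
             [(1, 1, 0), (0, 1, 0), (0, 0, 0), (-1, 0, 0)]]
        assert abs(dihedral(*p)) == pytest.approx(180.0, abs=1e-12)

    def test_against_gemmi_oracle_random_quadruples(self, rng):
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 5
            try:
                mine = dihedral(*pts)
            except UndefinedDihedralError:
                continue
            ref = gemmi_dihedral(*pts)
            diff = (mine - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p1=point, p2=point, p3=point, p4=point)
    def test_mirror_negates(self, p1, p2, p3, p4):
        mirror = np.array([-1.0, 1.0, 1.0])
        try:
            ang = dihedral(p1, p2, p3, p4)
        except UndefinedDihedralError:
            return
        mang = dihedral(p1 * mirror, p2 * mirror, p3 * mirror, p4 * mirror)
        assert abs(abs(ang) - abs(mang)) < 1e-9
        if abs(abs(ang) - 180.0) > 1e-9:  # ±180 are the same angle
            assert mang == pytest.approx(-ang, abs=1e-9)

    def test_collinear_raises(self):
        a, b, c = (np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                   np.array([2.0, 0, 0]))
        with pytest.raises(UndefinedDihedralError):
            dihedral(a, b, c, np.array([3.0, 1, 0]))


def quaternion_superpose(ref, mov):
    """Brute-force Horn quaternion superposition oracle."""
    rc, mc = ref.mean(0), mov.mean(0)
    a, b = ref - rc, mov - mc
    m = b.T @ a
    k = np.array([
        [m[0, 0] + m[1, 1] + m[2, 2], m[1, 2] - m[2, 1], m[2, 0] - m[0, 2], m[0, 1] - m[1, 0]],
        [m[1, 2] - m[2, 1], m[0, 0] - m[1, 1] - m[2, 2], m[0, 1] + m[1, 0], m[2, 0] + m[0, 2]],
        [m[2, 0] - m[0, 2], m[0, 1] + m[1, 0], m[1, 1] - m[0, 0] - m[2, 2], m[1, 2] + m[2, 1]],
        [m[0, 1] - m[1, 0], m[2, 0] + m[0, 2], m[1, 2] + m[2, 1], m[2, 2] - m[0, 0] - m[1, 1]],
    ])
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    moved = b @ rot.T
    return float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))


class TestSuperpose:
    def _selection(self, model):
        return [a.key for a in model.atoms if a.name in ("N", "CA", "C")]

    def test_self_identity(self, helical_peptide):
        sel = self._selection(helical_peptide)
        sp = superpose(helical_peptide, helical_peptide, sel)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-9)

    def test_translation_invariance(self, helical_peptide):
        sel = self._selection(helical_peptide)
        moved = helical_peptide.transformed(np.eye(3), np.array([5.0, -3.0, 2.0]))
        assert superpose(helical_peptide, moved, sel).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_vs_quaternion_oracle(self, helical_peptide):
        sel = self._selection(helical_peptide)
        atoms = list(helical_peptide.atoms)
        k = next(i for i, a in enumerate(atoms) if a.key == sel[10])
        from dataclasses import replace
        atoms[k] = replace(atoms[k], position=atoms[k].position + np.array([1.0, 0, 0]))
        other = Model(2, atoms)
        sp = superpose(helical_peptide, other, sel)
        ref = helical_peptide.coordinates(sel)
        mov = other.coordinates(sel)
        assert sp.rmsd == pytest.approx(quaternion_superpose(ref, mov), abs=1e-9)
        # a single 1 Å displacement leaves rmsd slightly under sqrt(1/n)
        assert sp.rmsd <= math.sqrt(1.0 / len(sel)) + 1e-9

    def test_rmsd_symmetric(self, helical_peptide, rng):
        sel = self._selection(helical_peptide)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=rng).as_matrix()
        ens = syn.perturb_ensemble(helical_peptide, 2, coord_jitter_sd=0.5, seed=4)
        a, b = ens.models
        b = b.transformed(rot, np.array([1.0, 2.0, 3.0]))
        assert superpose(a, b, sel).rmsd == pytest.approx(
            superpose(b, a, sel).rmsd, abs=1e-9)

    def test_too_few_atoms(self, helical_peptide):
        sel = self._selection(helical_peptide)[:2]
        with pytest.raises(ValueError):
            superpose(helical_peptide, helical_peptide, sel)


class TestEnsemblePrecision:
    def test_identical_models_zero(self, helical_peptide):
        ens = Ensemble(models=[helical_peptide, Model(2, helical_peptide.atoms)])
        assert ensemble_precision(ens) == pytest.approx(0.0, abs=1e-12)

    def test_jittered_matches_pairwise_oracle(self, helical_peptide):
        sigma = 0.3
        ens = syn.perturb_ensemble(helical_peptide, 10, coord_jitter_sd=sigma, seed=7)
        keys = sorted(a.key for a in helical_peptide.atoms
                      if a.name in ("N", "CA", "C"))
        # independent brute-force pairwise oracle via the quaternion fit
        vals = []
        for i in range(10):
            for j in range(i + 1, 10):
                vals.append(quaternion_superpose(ens.models[i].coordinates(keys),
                                                 ens.models[j].coordinates(keys)))
        oracle = float(np.mean(vals))
        got = ensemble_precision(ens, atoms=("N", "CA", "C"))
        assert got == pytest.approx(oracle, abs=1e-9)
        # expected scale: per-atom 3-D displacement difference has rms σ√6
        assert got == pytest.approx(sigma * math.sqrt(6.0), rel=0.15)

    def test_invariant_under_rigid_transform(self, helical_peptide, rng):
        from scipy.spatial.transform import Rotation
        ens = syn.perturb_ensemble(helical_peptide, 4, coord_jitter_sd=0.4, seed=8)
        base = ensemble_precision(ens)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = Ensemble(models=[ens.models[0].transformed(rot, np.array([9.0, 1, -4]))]
                         + ens.models[1:])
        assert ensemble_precision(moved) == pytest.approx(base, abs=1e-9)

    def test_empty_selection_errors(self, helical_peptide):
        ens = syn.perturb_ensemble(helical_peptide, 2, coord_jitter_sd=0.1, seed=9)
        with pytest.raises(ValueError):
            ensemble_precision(ens, atoms=("ZZ",))


class TestFindCystines:
    def test_constructed_cystine_found(self):
        model = syn.build_cystine((-60, -60, -85, -60, -60), residue_numbers=(7, 37))
        assert find_cystines(model) == [(7, 37)]

    def test_distant_free_cysteines_empty(self):
        m1 = syn.build_peptide("C", [(-57, -47)], [-60.0], start_residue=1)
        m2 = syn.build_peptide("C", [(-57, -47)], [-60.0], start_residue=9)
        shifted = m2.transformed(np.eye(3), np.array([20.0, 0, 0]))
        merged = Model(1, m1.atoms + shifted.atoms)
        assert find_cystines(merged) == []

    def test_cluster_pairing(self):
        model = syn.build_disulfide_cluster([(7, 37), (23, 33), (26, 46)])
        assert find_cystines(model) == [(7, 37), (23, 33), (26, 46)]

    def test_ssbond_fallback_when_no_sg(self, helical_peptide):
        assert find_cystines(helical_peptide, ssbond_fallback=[(3, 9)]) == [(3, 9)]


class TestReadWrite:
    def test_two_model_round_trip(self, tmp_path, helical_peptide):
        ens = syn.perturb_ensemble(helical_peptide, 2, coord_jitter_sd=0.2, seed=3)
        path = tmp_path / "two.pdb"
        write_ensemble_pdb(ens, path)
        back = read_ensemble(path)
        assert len(back) == 2
        keys = sorted(back.common_atom_keys)
        assert keys == sorted(ens.common_atom_keys)
        for orig, rb in zip(ens.models, back.models):
            assert np.abs(orig.coordinates(keys) - rb.coordinates(keys)).max() < 1e-3

    def test_mismatched_atom_sets_warn_and_intersect(self, tmp_path, caplog,
                                                     helical_peptide):
        ens = syn.perturb_ensemble(helical_peptide, 2, coord_jitter_sd=0.1, seed=5)
        pruned = Model(2, ens.models[1].atoms[:-3])
        path = tmp_path / "mismatch.pdb"
        write_ensemble_pdb(Ensemble(models=[ens.models[0], pruned]), path)
        with caplog.at_level(logging.WARNING):
            back = read_ensemble(path)
        assert "mismatched atom sets" in caplog.text
        assert len(back.common_atom_keys) == len(ens.models[0].atoms) - 3

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_ensemble(tmp_path / "nope.pdb")

    def test_zero_models(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(ValueError):
            read_ensemble(path)
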
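"""Saupe tensor fitting, Q statistics and cross-validation."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peprdc import (
    AlignmentTensor,
    DEFAULT_CONSTANTS,
    RDCRecord,
    RDCSet,
    back_calculate,
    design_row,
    fit_tensor,
    fit_tensor_ensemble,
    make_cv_plan,
    normalize,
    q_factor,
    q_free,
    read_rdc_tsv,
    read_xplor_dipo,
    write_rdc_tsv,
)
from peprdc import synthetic as syn
from peprdc.constants import GAMMA


class TestNormalization:
    def test_nh_identity(self):
        rec = RDCRecord(5, "N", 5, "H", "N-HN", "pf1", 12.0)
        assert normalize(rec) == pytest.approx(12.0)

    def test_caha_factor_from_constant_ratio(self):
        # oracle: γC·γH/r_CH³ over γN·γH/r_NH³ computed independently
        expect = (GAMMA["C"] * GAMMA["H"] / 1.117**3) / (
            GAMMA["N"] * GAMMA["H"] / 1.041**3)
        rec = RDCRecord(5, "CA", 5, "HA", "CA-HA", "pf1", 10.0)
        assert DEFAULT_CONSTANTS.factor("CA-HA") == pytest.approx(expect, rel=1e-12)
        assert normalize(rec) == pytest.approx(10.0 / expect, rel=1e-12)

    def test_cca_factor_from_constant_ratio(self):
        expect = (GAMMA["C"] * GAMMA["C"] / 1.526**3) / (
            GAMMA["N"] * GAMMA["H"] / 1.041**3)
        assert DEFAULT_CONSTANTS.factor("C-CA") == pytest.approx(expect, rel=1e-12)

    def test_sum_cbhb_uses_single_ch_factor(self):
        assert DEFAULT_CONSTANTS.factor("SUM-CBHB") == pytest.approx(
            DEFAULT_CONSTANTS.factor("CA-HA") * (1.117 / 1.117) ** 3)

    def test_unknown_type_errors(self):
        with pytest.raises(KeyError):
            DEFAULT_CONSTANTS.factor("H-H")


def saupe_contraction(tensor: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: explicit Σ_kl A_kl b_k b_l."""
    return float(sum(tensor[k, l] * b[k] * b[l] for k in range(3) for l in range(3)))


class TestDesignRow:
    def test_z_axis_vector_reads_azz(self, helical_peptide):
        tensor = syn.random_tensor(1, da=7.0, rhombicity=0.2)
        s = np.array([tensor.tensor[2, 2],
                      tensor.tensor[0, 0] - tensor.tensor[1, 1],
                      tensor.tensor[0, 1], tensor.tensor[0, 2],
                      tensor.tensor[1, 2]])
        from peprdc.rdc_core import _row_from_unit
        row = _row_from_unit(np.array([0.0, 0.0, 1.0]))
        assert row @ s == pytest.approx(tensor.tensor[2, 2], abs=1e-12)

    def test_matches_direct_contraction(self, rng):
        from peprdc.rdc_core import _row_from_unit
        tensor = syn.random_tensor(2, da=9.0, rhombicity=0.5)
        s = np.array([tensor.tensor[2, 2],
                      tensor.tensor[0, 0] - tensor.tensor[1, 1],
                      tensor.tensor[0, 1], tensor.tensor[0, 2],
                      tensor.tensor[1, 2]])
        for _ in range(200):
            b = rng.normal(size=3)
            b /= np.linalg.norm(b)
            assert _row_from_unit(b) @ s == pytest.approx(
                saupe_contraction(tensor.tensor, b), abs=1e-10)

    def test_antiparallel_vectors_identical(self):
        from peprdc.rdc_core import _row_from_unit
        b = np.array([0.3, -0.5, 0.81])
        b /= np.linalg.norm(b)
        assert np.allclose(_row_from_unit(b), _row_from_unit(-b), atol=1e-14)

    def test_sum_row_is_sum_of_proton_rows(self, mixed_peptide):
        from peprdc.rdc_core import _row_from_unit
        rec = RDCRecord(2, "CB", 2, "HB", "SUM-CBHB", "pf1", 0.0)
        row = design_row(mixed_peptide, rec)
        cb = mixed_peptide.position("A", 2, "CB")
        parts = []
        for hb in ("HB2", "HB3"):
            v = mixed_peptide.position("A", 2, hb) - cb
            parts.append(_row_from_unit(v / np.linalg.norm(v)))
        assert np.allclose(row, parts[0] + parts[1], atol=1e-12)

    def test_missing_atom_names_record(self, helical_peptide):
        rec = RDCRecord(99, "N", 99, "H", "N-HN", "pf1", 1.0)
        with pytest.raises(KeyError, match="residue 99"):
            design_row(helical_peptide, rec)


class TestFitTensor:
    def test_noiseless_exact_recovery(self, helical_peptide):
        truth = syn.random_tensor(3, da=10.0, rhombicity=0.4)
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")
        rdcs = syn.simulate_rdcs(helical_peptide, truth, recs, noise_sd=0.0)
        fitted, d_calc, rep = fit_tensor(helical_peptide, rdcs)
        assert np.abs(fitted.tensor - truth.tensor).max() < 1e-8
        assert rep.q < 1e-8
        obs = np.array([r.d_obs for r in rdcs])
        assert np.abs(d_calc - obs).max() < 1e-8

    def test_noisy_matches_normal_equations_oracle(self, mixed_peptide):
        recs = syn.backbone_rdc_records(mixed_peptide, "pf1")
        for trial in range(100):
            truth = syn.random_tensor(1000 + trial, da=10.0, rhombicity=0.3)
            rdcs = syn.simulate_rdcs(mixed_peptide, truth, recs[:100],
                                     noise_sd=1.0, seed=trial)
            fitted, _, rep = fit_tensor(mixed_peptide, rdcs)
            a = np.array([design_row(mixed_peptide, r) for r in rdcs])
            d = np.array([normalize(r) for r in rdcs])
            s = np.linalg.solve(a.T @ a, a.T @ d)  # independent solver path
            from peprdc.rdc_core import _params_from_tensor
            assert np.abs(_params_from_tensor(fitted.tensor) - s).max() < 1e-9
            resid = a @ s - d
            q_oracle = math.sqrt(np.mean(resid**2)) / math.sqrt(np.mean(d**2))
            assert rep.q == pytest.approx(q_oracle, abs=1e-9)

    def test_underdetermined_errors(self, helical_peptide):
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")[:4]
        rdcs = syn.simulate_rdcs(helical_peptide, syn.random_tensor(5), recs)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_tensor(helical_peptide, rdcs)

    def test_mixed_media_rejected(self, two_medium_rdcs, mixed_peptide):
        rdcs, _ = two_medium_rdcs
        with pytest.raises(ValueError, match="single alignment medium"):
            fit_tensor(mixed_peptide, rdcs)

    def test_q_invariant_under_rigid_rotation(self, helical_peptide, rng):
        truth = syn.random_tensor(6, da=10.0, rhombicity=0.3)
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")
        rdcs = syn.simulate_rdcs(helical_peptide, truth, recs, noise_sd=1.0, seed=6)
        _, _, base = fit_tensor(helical_peptide, rdcs)
        for _ in range(100):
            rot = Rotation.random(random_state=rng).as_matrix()
            moved = helical_peptide.transformed(rot, rng.normal(size=3))
            _, _, rep = fit_tensor(moved, rdcs)
            assert abs(rep.q - base.q) < 1e-9

    def test_q_invariant_under_observation_scaling(self, helical_peptide):
        truth = syn.random_tensor(7, da=10.0, rhombicity=0.3)
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")
        rdcs = syn.simulate_rdcs(helical_peptide, truth, recs, noise_sd=1.0, seed=7)
        _, _, base = fit_tensor(helical_peptide, rdcs)
        from dataclasses import replace
        scaled = RDCSet([replace(r, d_obs=r.d_obs * -3.7) for r in rdcs])
        _, _, rep = fit_tensor(helical_peptide, scaled)
        assert rep.q == pytest.approx(base.q, abs=1e-9)

    def test_fitted_tensor_symmetric_traceless_and_r_range(self, rng):
        for _ in range(1000):
            t = syn.random_tensor(rng, da=rng.uniform(2, 20),
                                  rhombicity=rng.uniform(0, 2 / 3))
            assert abs(np.trace(t.tensor)) < 1e-10
            assert np.allclose(t.tensor, t.tensor.T, atol=1e-12)
            assert -1e-12 <= t.rhombicity <= 2.0 / 3.0 + 1e-12

    def test_adding_exact_record_leaves_fit_unchanged(self, helical_peptide):
        truth = syn.random_tensor(8, da=10.0, rhombicity=0.3)
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")
        rdcs = syn.simulate_rdcs(helical_peptide, truth, recs, noise_sd=1.0, seed=8)
        fitted, _, _ = fit_tensor(helical_peptide, rdcs)
        extra = RDCRecord(10, "CA", 10, "HA", "CA-HA", "pf1", 0.0)
        d = back_calculate(helical_peptide, fitted, [extra], normalized=False)[0]
        from dataclasses import replace
        bigger = RDCSet(list(rdcs) + [replace(extra, d_obs=float(d))])
        refit, _, _ = fit_tensor(helical_peptide, bigger)
        assert np.abs(refit.tensor - fitted.tensor).max() < 1e-9

    def test_ensemble_fit_reports_spread(self, helical_peptide):
        truth = syn.random_tensor(9, da=10.0, rhombicity=0.3)
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")
        rdcs = syn.simulate_rdcs(helical_peptide, truth, recs, noise_sd=1.0, seed=9)
        ens = syn.perturb_ensemble(helical_peptide, 5, coord_jitter_sd=0.2, seed=10)
        res = fit_tensor_ensemble(ens, rdcs)
        assert res["q_best"] <= res["q_mean"]
        assert len(res["per_model"]) == 5


class TestQFactor:
    def test_exact_match_is_zero(self):
        assert q_factor([3.0, -2.0, 8.0], [3.0, -2.0, 8.0]).q == 0.0

    def test_all_zero_calc_is_one(self):
        assert q_factor([3.0, -2.0, 8.0], [0.0, 0.0, 0.0]).q == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # rms(resid) = sqrt(mean(4+1+1)) = sqrt(2); rms(obs) = sqrt(134/3)
        rep = q_factor([10.0, -5.0, 3.0], [8.0, -4.0, 2.0])
        assert rep.q == pytest.approx(math.sqrt(2.0) / math.sqrt(134.0 / 3.0), rel=1e-12)
        assert rep.n_rdc == 3

    def test_zero_observations_error(self):
        with pytest.raises(ZeroDivisionError):
            q_factor([0.0, 0.0], [1.0, 2.0])


class TestCvPlan:
    def test_each_record_held_out_once(self, two_medium_rdcs):
        rdcs, _ = two_medium_rdcs
        plan = make_cv_plan(rdcs, seed=1)
        assert len(rdcs.experiments) == 8
        everything = sorted(i for r in plan.rounds for i in r)
        assert everything == list(range(len(rdcs)))
        # each round holds ≈10% of every experiment
        for round_idx in plan.rounds:
            for exp in rdcs.experiments:
                n_exp = sum(1 for r in rdcs if r.experiment == exp)
                n_held = sum(1 for i in round_idx if rdcs[i].experiment == exp)
                assert abs(n_held - 0.1 * n_exp) <= 1.0

    def test_deterministic_for_fixed_seed(self, two_medium_rdcs):
        rdcs, _ = two_medium_rdcs
        assert make_cv_plan(rdcs, seed=42) == make_cv_plan(rdcs, seed=42)
        assert make_cv_plan(rdcs, seed=42) != make_cv_plan(rdcs, seed=43)

    def test_zero_fraction_rejected(self, two_medium_rdcs):
        rdcs, _ = two_medium_rdcs
        with pytest.raises(ValueError):
            make_cv_plan(rdcs, fraction=0.0)

    def test_small_experiment_named_in_error(self, helical_peptide):
        recs = syn.backbone_rdc_records(helical_peptide, "pf1")
        tiny = RDCSet([r for r in recs if r.rdc_type != "N-HN"]
                      + [r for r in recs if r.rdc_type == "N-HN"][:3])
        rdcs = RDCSet([r for r in syn.simulate_rdcs(
            helical_peptide, syn.random_tensor(2), list(tiny))])
        with pytest.raises(ValueError, match="N-HN"):
            make_cv_plan(rdcs, seed=0)


class TestQFree:
    def test_noiseless_qfree_vanishes(self, mixed_peptide):
        t = syn.random_tensor(11, da=10.0, rhombicity=0.3)
        recs = syn.backbone_rdc_records(mixed_peptide, "pf1")
        rdcs = syn.simulate_rdcs(mixed_peptide, t, recs, noise_sd=0.0)
        plan = make_cv_plan(rdcs, seed=2)
        mean, sd, rounds = q_free(plan, rdcs, mixed_peptide)
        assert all(q < 1e-8 for q in rounds)
        assert mean < 1e-8

    def test_noisy_qfree_matches_noise_floor(self, two_medium_rdcs, mixed_peptide):
        """With the identity refiner, held-out residuals carry one copy of
        the measurement noise plus a small tensor-estimation term, so
        Q_free ≈ rms(σ_norm)/rms(D̂_obs)."""
        rdcs, _ = two_medium_rdcs
        plan = make_cv_plan(rdcs, seed=3)
        mean, sd, _ = q_free(plan, rdcs, mixed_peptide)
        obs = np.array([normalize(r) for r in rdcs])
        sig = np.array([1.0 / abs(DEFAULT_CONSTANTS.factor(r.rdc_type))
                        for r in rdcs])
        floor = math.sqrt(np.mean(sig**2)) / math.sqrt(np.mean(obs**2))
        assert mean == pytest.approx(floor, rel=0.20)

    def test_refiner_failure_reports_round(self, two_medium_rdcs, mixed_peptide):
        rdcs, _ = two_medium_rdcs
        plan = make_cv_plan(rdcs, seed=4)

        def broken(structure, working):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="round 0"):
            q_free(plan, rdcs, mixed_peptide, refiner=broken)


class TestIO:
    def test_tsv_round_trip(self, tmp_path, two_medium_rdcs):
        rdcs, _ = two_medium_rdcs
        path = tmp_path / "rdc.tsv"
        write_rdc_tsv(rdcs, path)
        back = read_rdc_tsv(path)
        assert len(back) == len(rdcs)
        assert [r.d_obs for r in back] == pytest.approx([r.d_obs for r in rdcs])
        assert [r.experiment for r in back] == [r.experiment for r in rdcs]

    def test_xplor_dipo_reader(self, tmp_path):
        text = """
        assign ( resid 500 and name OO )( resid 500 and name Z )
               ( resid 500 and name X )( resid 500 and name Y )
               ( resid 7 and name N )( resid 7 and name HN )  -4.20 0.5
        assign ( resid 500 and name OO )( resid 500 and name Z )
               ( resid 500 and name X )( resid 500 and name Y )
               ( resid 8 and name CA )( resid 8 and name HA )  11.3 1.0
        """
        path = tmp_path / "dipo.tbl"
        path.write_text(text)
        rdcs = read_xplor_dipo(path, medium_id="pf1")
        assert len(rdcs) == 2
        assert rdcs[0].rdc_type == "N-HN" and rdcs[0].d_obs == pytest.approx(-4.2)
        assert rdcs[1].rdc_type == "CA-HA" and rdcs[1].residue_i == 8
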
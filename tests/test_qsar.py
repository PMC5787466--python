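"""Pharmacophore perception, hypothesis recovery and 3D-QSAR regression."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hopscreen.chemio import from_smiles
from hopscreen.fixtures import FixtureSpec, make_pharmacophore_fixture, make_qsar_fixture
from hopscreen.qsar import (
    ActivityRecord,
    PharmacophoreFeature,
    PharmacophoreHypothesis,
    align_to_hypothesis,
    classify_under_threshold,
    compute_descriptors,
    enumerate_hypotheses,
    fit_qsar,
    ic50_from_pic50,
    perceive_features,
    pic50_from_ic50,
    predict_activity,
    rank_hypotheses,
    update_with_experimental,
)
from hopscreen.qsar import _distance_assignment_exists
from hopscreen.shapefilter import generate_conformer_ensemble


def _ensemble(smiles: str, mol_id: str, n: int = 5, seed: int = 2):
    return generate_conformer_ensemble(from_smiles(smiles, mol_id), n, seed=seed)


class TestUnits:
    def test_pic50_of_1nm_is_9(self):
        assert pic50_from_ic50(1.0) == pytest.approx(9.0)

    def test_round_trip(self):
        for ic50 in (0.6, 7.0, 339.65, 10000.0):
            assert ic50_from_pic50(pic50_from_ic50(ic50)) == pytest.approx(ic50, rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pic50_from_ic50(0.0)


class TestPerceiveFeatures:
    def test_benzene_exactly_one_ring_feature(self):
        feats = perceive_features(_ensemble("c1ccccc1", "bz"))
        assert [f.kind for f in feats] == ["R"]

    def test_phenol_has_donor_acceptor_ring(self):
        kinds = {f.kind for f in perceive_features(_ensemble("Oc1ccccc1", "phenol"))}
        assert {"A", "D", "R"} <= kinds

    def test_acetate_anion_negative(self):
        kinds = {f.kind for f in perceive_features(_ensemble("CC(=O)[O-]", "acetate"))}
        assert "N" in kinds

    def test_amine_positive(self):
        kinds = {f.kind for f in perceive_features(_ensemble("NCCCC", "butylamine"))}
        assert "P" in kinds

    def test_ring_feature_at_centroid(self):
        mol = _ensemble("c1ccccc1", "bz")
        feat = perceive_features(mol)[0]
        coords = mol.mol.GetConformer(0).GetPositions()
        assert np.allclose(feat.xyz, coords.mean(axis=0), atol=1e-8)


class TestEnumerateHypotheses:
    def test_two_copies_give_all_k_subsets(self):
        mol = _ensemble("NC(=O)c1ccc(CCC)cc1", "m")
        feats = perceive_features(mol)
        pairs = [
            (mol, ActivityRecord.from_ic50("m1", 10.0)),
            (mol, ActivityRecord.from_ic50("m2", 20.0)),
        ]
        k = 3
        hyps = enumerate_hypotheses(pairs, (k, k), 10000, tolerance=2.0)
        assert len(hyps) == math.comb(len(feats), k)

    def test_no_common_arrangement_is_empty(self, caplog):
        a = _ensemble("c1ccccc1", "bz")  # only R
        b = _ensemble("c1ccncc1", "pyr")  # R + A
        pairs = [
            (b, ActivityRecord.from_ic50("pyr", 10.0)),
            (a, ActivityRecord.from_ic50("bz", 20.0)),
        ]
        with caplog.at_level("WARNING", logger="hopscreen"):
            hyps = enumerate_hypotheses(pairs, (2, 2), 100, tolerance=2.0)
        assert hyps == []

    def test_labels_sorted_kinds_plus_index(self):
        mol = _ensemble("NC(=O)c1ccc(CCC)cc1", "m")
        pairs = [
            (mol, ActivityRecord.from_ic50("m1", 10.0)),
            (mol, ActivityRecord.from_ic50("m2", 20.0)),
        ]
        for hyp in enumerate_hypotheses(pairs, (3, 3), 50, tolerance=2.0):
            prefix, idx = hyp.label.rsplit(".", 1)
            assert prefix == "".join(sorted(hyp.kinds))
            assert idx.isdigit()

    def test_planted_six_feature_recovery_ranks_top_five(self, spec):
        actives, planted = make_pharmacophore_fixture(spec)
        hyps = enumerate_hypotheses(actives, (6, 6), 5000, tolerance=2.0)
        assert hyps, "no hypotheses enumerated"
        ranked = rank_hypotheses(hyps, actives)

        def matches_planted(h: PharmacophoreHypothesis) -> bool:
            if sorted(h.kinds) != sorted(planted.kinds):
                return False
            feats = [
                PharmacophoreFeature(k, s, (i,))
                for i, (k, s) in enumerate(zip(planted.kinds, planted.sites))
            ]
            return _distance_assignment_exists(feats, h.kinds, h.distance_matrix, planted.tolerance)

        assert any(matches_planted(h) for _, h in ranked[:5])


class TestAlignment:
    def test_self_fit_is_zero(self):
        mol = _ensemble("NC(=O)c1ccc(CCC)cc1", "m")
        feats = perceive_features(mol)[:4]
        hyp = PharmacophoreHypothesis(
            "SELF", tuple(f.kind for f in feats), tuple(f.position for f in feats), 2.0
        )
        res = align_to_hypothesis(mol, hyp)
        assert res.matched
        assert res.fit_score == pytest.approx(0.0, abs=1e-6)

    def test_missing_kind_unmatched(self):
        mol = _ensemble("CCCCCC", "hexane")  # H only, no acceptor
        hyp = PharmacophoreHypothesis("AH", ("A", "H"), ((0.0, 0.0, 0.0), (4.0, 0.0, 0.0)), 2.0)
        res = align_to_hypothesis(mol, hyp)
        assert not res.matched
        assert res.fit_score == float("inf")

    def test_rigidly_rotated_copy_fits_to_zero(self):
        from scipy.spatial.transform import Rotation

        mol = _ensemble("NC(=O)c1ccc(OC)cc1", "m")
        feats = perceive_features(mol)
        hyp = PharmacophoreHypothesis(
            "SELF", tuple(f.kind for f in feats), tuple(f.position for f in feats), 2.0
        )
        rotated = mol.copy()
        conf = rotated.mol.GetConformer(0)
        rot = Rotation.from_euler("xyz", [0.4, -1.2, 2.2]).as_matrix()
        for i in range(rotated.mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (rot @ np.array([p.x, p.y, p.z]) + np.array([1.0, -2.0, 3.0])).tolist())
        res = align_to_hypothesis(rotated, hyp)
        assert res.matched
        assert res.fit_score == pytest.approx(0.0, abs=1e-3)


class TestFitAndPredict:
    def test_zero_noise_planted_recovery(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        assert model.fit_stats["r2"] > 0.999
        for mol, act in qsar_fixture.training:
            pred = predict_activity(model, mol)
            assert pred.pic50 == pytest.approx(act.pic50, abs=1e-6)

    def test_predictions_linear_in_planted_columns(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        for (mol, _), x in zip(qsar_fixture.training, qsar_fixture.descriptors):
            assert model.predict_pic50_from_descriptors(x) == pytest.approx(
                qsar_fixture.planted_pic50(x), abs=1e-6
            )

    def test_noise_degrades_rmse_into_band(self):
        rmses = []
        for seed in range(20):
            fixture = make_qsar_fixture(FixtureSpec(seed=100 + seed, qsar_noise_sigma=0.2))
            model = fit_qsar(fixture.training, fixture.hypothesis, grid=fixture.grid)
            rmses.append(model.fit_stats["rmse"])
        assert 0.1 <= float(np.mean(rmses)) <= 0.4

    def test_training_range_spans_published_spread(self, qsar_fixture):
        # activities span 2 nM to >10,000 nM territory and the worst
        # compound enters as a censored bound; the fit stays finite
        ic50s = [a.ic50 for _, a in qsar_fixture.training]
        assert max(ic50s) / min(ic50s) >= 5000
        assert any(a.censored for _, a in qsar_fixture.training)
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        for mol, _ in qsar_fixture.training:
            assert math.isfinite(predict_activity(model, mol).pic50)

    def test_too_few_matched_compounds_errors(self, qsar_fixture):
        with pytest.raises(ValueError, match="need 6"):
            fit_qsar(qsar_fixture.training[:3], qsar_fixture.hypothesis, grid=qsar_fixture.grid)

    def test_unmatched_molecule_gets_worst_tier_flag(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        alien = _ensemble("CCCCCCCC", "octane")
        pred = predict_activity(model, alien)
        assert not pred.matched
        worst = max(a.ic50 for _, a in qsar_fixture.training)
        assert pred.predicted_ic50 == pytest.approx(10.0 * worst)

    def test_monotone_in_positively_weighted_descriptor(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        j = int(np.argmax(model.coefficients))
        assert model.coefficients[j] > 0
        x = qsar_fixture.descriptors[0].copy()
        base = model.predict_pic50_from_descriptors(x)
        for delta in (0.1, 0.5, 1.0):
            bumped = x.copy()
            bumped[j] += delta
            assert model.predict_pic50_from_descriptors(bumped) >= base


class TestFeedbackUpdate:
    def test_duplicate_record_is_idempotent_bitwise(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        mol, act = qsar_fixture.training[0]
        updated = update_with_experimental(model, [(mol, act)])
        assert np.array_equal(updated.coefficients, model.coefficients)
        assert updated.intercept == model.intercept

    def test_consistent_augmentation_keeps_fit(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        mol, _ = qsar_fixture.training[0]
        x, _ = compute_descriptors(mol, qsar_fixture.hypothesis, qsar_fixture.grid)
        new_mol = mol.copy()
        new_mol.id = "new01"
        rec = ActivityRecord.from_ic50("new01", ic50_from_pic50(qsar_fixture.planted_pic50(x)))
        updated = update_with_experimental(model, [(new_mol, rec)])
        assert updated.fit_stats["r2"] > 0.999
        assert "new01" in updated.training_ids
        assert abs(updated.fit_stats["new_residuals"]["new01"]) < 1e-6

    def test_mislabeled_outlier_raises_rmse(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        mol, act = qsar_fixture.training[0]
        outlier_mol = mol.copy()
        outlier_mol.id = "outlier"
        outlier = ActivityRecord.from_ic50("outlier", act.ic50 * 1e4)  # contradicts its twin
        updated = update_with_experimental(model, [(outlier_mol, outlier)])
        assert updated.fit_stats["rmse"] > model.fit_stats["rmse"]

    def test_conflicting_duplicate_errors(self, qsar_fixture):
        model = fit_qsar(qsar_fixture.training, qsar_fixture.hypothesis, grid=qsar_fixture.grid)
        mol, act = qsar_fixture.training[0]
        conflict = ActivityRecord.from_ic50(act.compound_id, act.ic50 * 3.0)
        with pytest.raises(ValueError, match="conflicting"):
            update_with_experimental(model, [(mol, conflict)])


class TestThresholdGate:
    def test_published_rows_and_boundary(self):
        records = [
            ActivityRecord.from_ic50("SSI-4", 339.65, source="predicted"),
            ActivityRecord.from_ic50("SetB.61", 550.85, source="predicted"),
            ActivityRecord.from_ic50("edge", 500.0, source="predicted"),
        ]
        assert classify_under_threshold(records, 500.0) == [True, False, False]
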
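"""Feature computations: XOR penalties, SS assignment, SASA, contacts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poorqa.features import (
    FeatureFailure,
    PredictionSet,
    assign_secondary_structure,
    binary_xor_penalty,
    build_feature_vector,
    compute_sasa,
    contact_penalty,
    normalize_potential,
    sa_binarize,
    sa_penalty,
    ss_penalties,
)
from poorqa.structure_io import ContactPrediction, SAPrediction, SSPrediction
from poorqa.synthetic import build_backbone, derive_predictions, make_coil

from conftest import toy_model


class TestBinaryXorPenalty:
    @pytest.mark.parametrize("x, p, expected", [
        ("1100", "1100", 0.0),
        ("1100", "0011", 1.0),
        ("1111", "1110", 0.25),
    ])
    def test_examples(self, x, p, expected):
        assert binary_xor_penalty(x, p) == pytest.approx(expected)

    def test_length_mismatch_and_empty_error(self):
        with pytest.raises(ValueError):
            binary_xor_penalty("11", "1")
        with pytest.raises(ValueError):
            binary_xor_penalty("", "")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 100), st.randoms(use_true_random=False))
    def test_matches_bruteforce_and_symmetry(self, n, rnd):
        x = "".join(rnd.choice("01") for _ in range(n))
        p = "".join(rnd.choice("01") for _ in range(n))
        brute = sum(1 for a, b in zip(x, p) if a != b) / n
        assert binary_xor_penalty(x, p) == brute
        assert binary_xor_penalty(p, x) == brute
        assert binary_xor_penalty(x, x) == 0.0
        flipped = "".join("1" if c == "0" else "0" for c in x)
        assert binary_xor_penalty(x, flipped) == 1.0


class TestSsPenalties:
    @pytest.mark.parametrize("model_ss, pred, expected", [
        ("HHCC", "HHCC", (0.0, 0.0)),
        ("HHHH", "EEEE", (1.0, 1.0)),
        ("HECC", "HHCC", (0.25, 0.25)),  # each channel differs at one position
    ])
    def test_examples(self, model_ss, pred, expected):
        e_h, e_e = ss_penalties(model_ss, SSPrediction(pred))
        assert (e_h, e_e) == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ss_penalties("HH", SSPrediction("H"))


class TestSaPenalty:
    def test_identity_and_mapping(self):
        assert sa_penalty("1010", SAPrediction("ebeb")) == 0.0
        assert sa_penalty("1111", SAPrediction("bbbe")) == 0.75
        assert sa_penalty("0000", "bbbb") == 0.0


class TestSecondaryStructure:
    def test_ideal_helix_core_is_h(self, helix15):
        ss = assign_secondary_structure(helix15)
        core = ss[2:12]
        assert core.count("H") / len(core) >= 0.8

    def test_sheet_bridge_residues_are_e(self, sheet):
        ss = assign_secondary_structure(sheet)
        assert ss.count("E") >= 4
        assert "H" not in ss

    def test_two_residue_model_is_all_c(self):
        model = build_backbone([(-57.0, -47.0)] * 2)
        assert assign_secondary_structure(model) == "CC"

    def test_agrees_with_independent_dssp(self, helix15, sheet):
        mdtraj = pytest.importorskip("mdtraj")
        from poorqa.synthetic import write_pdb
        import tempfile, os
        for model in (helix15, sheet, make_coil(20, seed=3)):
            with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as f:
                path = f.name
            try:
                write_pdb(model, path)
                ref = "".join(mdtraj.compute_dssp(
                    mdtraj.load(path), simplified=True)[0])
                ref = ref.replace("NA", "C").replace(" ", "C")
                assert assign_secondary_structure(model) == ref
            finally:
                os.unlink(path)


class TestComputeSasa:
    def test_isolated_atom_matches_sphere(self):
        model = toy_model([{"C": (0, 0, 0)}])
        area = compute_sasa(model, n_points=960)[0]
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)

    def test_fully_buried_atom_is_zero(self):
        # central atom caged by neighbours on a 2 Å shell in 14 directions
        dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                (0, 0, -1)]
        dirs += [(s1 / math.sqrt(3), s2 / math.sqrt(3), s3 / math.sqrt(3))
                 for s1 in (-1, 1) for s2 in (-1, 1) for s3 in (-1, 1)]
        cage = {f"C{i+1}": tuple(2.0 * np.array(d)) for i, d in enumerate(dirs)}
        model = toy_model([{"C": (0, 0, 0)}, cage])
        per_atom_center = _center_atom_area(model)
        assert per_atom_center == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [1.5, 2.0, 3.0, 5.0])
    def test_two_atom_pair_matches_spherical_cap(self, d):
        model = toy_model([{"C": (0, 0, 0)}, {"C": (d, 0, 0)}])
        areas = compute_sasa(model, n_points=960)
        R = 1.70 + 1.4
        h = R - d / 2.0  # cap height of each sphere inside the other
        exact = 4 * math.pi * R ** 2 - 2 * math.pi * R * h
        np.testing.assert_allclose(areas, exact, rtol=0.02)

    def test_determinism(self, helix15):
        a = compute_sasa(helix15, n_points=240)
        b = compute_sasa(helix15, n_points=240)
        np.testing.assert_array_equal(a, b)


def _center_atom_area(model):
    """Area attributed to the first (single-atom) residue."""
    return compute_sasa(model, n_points=960)[0]


class TestSaBinarize:
    def test_threshold_semantics(self):
        model = toy_model([{"CA": (0, 0, 0)}] * 3, names=["ALA"] * 3)
        max_asa = 129.0  # ALA
        areas = np.array([0.10, 0.30, 0.25]) * max_asa
        assert sa_binarize(areas, model) == "011"

    def test_zero_areas_all_buried(self):
        model = toy_model([{"CA": (0, 0, 0)}] * 2)
        assert sa_binarize(np.zeros(2), model) == "00"

    def test_ratio_above_one_is_exposed(self):
        model = toy_model([{"CA": (0, 0, 0)}])
        assert sa_binarize(np.array([1.2 * 129.0]), model) == "1"


class TestContactPenalty:
    def test_self_consistent_contacts_score_zero(self, helix15):
        ref = helix15.reference_coordinates()
        pairs = []
        nums = helix15.residue_numbers
        for a in range(len(nums)):
            for b in range(a + 1, len(nums)):
                if np.linalg.norm(ref[a] - ref[b]) <= 8.0:
                    pairs.append((nums[a], nums[b], 1.0))
        assert contact_penalty(helix15, ContactPrediction(pairs)) == 0.0

    def test_distant_pairs_score_one(self):
        # 4 collinear residues, consecutive CB spacing 30 Å
        model = toy_model([{"CB": (30.0 * k, 0, 0), "CA": (30.0 * k, 1, 0)}
                           for k in range(4)])
        contacts = ContactPrediction([(1, 3, 0.9), (1, 4, 0.8), (2, 4, 0.7)])
        assert contact_penalty(model, contacts) == 1.0

    def test_collinear_example_half_matched(self):
        # consecutive CB spacing 5 Å; pairs (1,2) at 5 Å and (1,4) at 15 Å
        model = toy_model([{"CB": (5.0 * k, 0, 0), "CA": (5.0 * k, 1, 0)}
                           for k in range(4)])
        contacts = ContactPrediction([(1, 2, 0.9), (1, 4, 0.8)])
        # brute force on the stated coordinates: d(1,2)=5 <= 8, d(1,4)=15 > 8
        assert contact_penalty(model, contacts) == pytest.approx(0.5)

    def test_absent_residues_skipped_for_next_pairs(self):
        model = toy_model([{"CB": (5.0 * k, 0, 0), "CA": (5.0 * k, 1, 0)}
                           for k in range(3)])  # residues 1..3
        contacts = ContactPrediction([(1, 9, 0.95), (1, 2, 0.9), (2, 3, 0.8),
                                      (1, 3, 0.7)])
        # (1,9) unusable; top-3 usable: (1,2) 5 Å, (2,3) 5 Å, (1,3) 10 Å
        assert contact_penalty(model, contacts) == pytest.approx(1 / 3)

    def test_zero_usable_pairs_is_feature_failure(self):
        model = toy_model([{"CB": (0, 0, 0)}, {"CB": (5, 0, 0)}])
        with pytest.raises(FeatureFailure):
            contact_penalty(model, ContactPrediction([(7, 9, 0.9)]))


class TestNormalizePotential:
    @pytest.mark.parametrize("raw, n, expected", [
        (-12000.0, 120, -100.0),
        (0.0, 50, 0.0),
        (500.0, 1, 500.0),
    ])
    def test_examples(self, raw, n, expected):
        assert normalize_potential(raw, n) == expected

    def test_zero_residues_errors(self):
        with pytest.raises(ValueError):
            normalize_potential(1.0, 0)


class TestBuildFeatureVector:
    def test_self_consistent_inputs_give_zero_penalties(self, helix15):
        preds = derive_predictions(helix15, corruption_rate=0.0, seed=0,
                                   sasa_points=240)
        fv = build_feature_vector(helix15, preds, sasa_points=240)
        assert fv.fallback_mask == (False,) * 6
        assert (fv.e_ss_h, fv.e_ss_e, fv.e_sa, fv.e_contact) == (0, 0, 0, 0)
        n = len(helix15)
        assert fv.e_dope == pytest.approx(preds.dope[helix15.model_id] / n)
        assert fv.e_goap == pytest.approx(preds.goap[helix15.model_id] / n)

    def test_missing_contacts_fall_back_to_half(self, helix15):
        preds = derive_predictions(helix15, 0.0, seed=0, sasa_points=240)
        preds.contacts = None
        fv = build_feature_vector(helix15, preds, sasa_points=240)
        assert fv.e_contact == 0.5
        assert fv.fallback_mask[5] is True

    def test_missing_dope_falls_back_to_half(self, helix15):
        preds = derive_predictions(helix15, 0.0, seed=0, sasa_points=240)
        preds.dope = {}
        fv = build_feature_vector(helix15, preds, sasa_points=240)
        assert fv.e_dope == 0.5
        assert fv.fallback_mask[0] is True
        assert fv.fallback_mask[1] is False

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_penalty_components_always_in_unit_interval(self, seed):
        rnd = np.random.default_rng(seed)
        n = int(rnd.integers(3, 40))
        model_ss = "".join(rnd.choice(list("HEC"), n))
        pred_ss = "".join(rnd.choice(list("HEC"), n))
        e_h, e_e = ss_penalties(model_ss, SSPrediction(pred_ss))
        sa_model = "".join(rnd.choice(list("01"), n))
        sa_pred = "".join(rnd.choice(list("eb"), n))
        for value in (e_h, e_e, sa_penalty(sa_model, SAPrediction(sa_pred))):
            assert 0.0 <= value <= 1.0
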
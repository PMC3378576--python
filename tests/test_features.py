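"""The 440D feature extractor against brute-force oracles."""

import numpy as np
import pytest

from structclass.features import (
    N_FEATURES,
    PROPERTY_LAGS,
    PSSM_LAGS,
    SEGMENT_LENGTHS,
    extract_features,
    feature_labels,
    g1_composition,
    g2_mutation_means,
    g3_hydrophobicity_autocorr,
    g4_mass_autocorr,
    g5_pssm_autocorr,
    g6_segment_mean_square,
    g7_position_preference,
)
from structclass.io import PSSM
from structclass.scales import KYTE_DOOLITTLE, SIDE_CHAIN_MASS, scale_vector

from .conftest import random_pssm
from .oracles import (
    oracle_g1,
    oracle_g2,
    oracle_g5,
    oracle_g6,
    oracle_g7,
    oracle_property_autocorr,
)


class TestLabels:
    def test_registry_has_440_unique_group_prefixed_names(self):
        labels = feature_labels()
        assert len(labels) == N_FEATURES == 440
        assert len(set(labels)) == N_FEATURES
        assert all(lab.startswith("G") for lab in labels)

    def test_group_cardinalities(self):
        labels = feature_labels()
        counts = {f"G{i}": 0 for i in range(1, 8)}
        for lab in labels:
            counts[lab.split("_")[0]] += 1
        assert counts == {
            "G1": 20, "G2": 40, "G3": 20, "G4": 20,
            "G5": 140, "G6": 120, "G7": 80,
        }


class TestComposition:
    def test_single_type_sequence(self):
        feats = g1_composition("AAAA")
        assert feats[0] == 1.0
        assert np.all(feats[1:] == 0)

    def test_two_residue_hand_value(self):
        feats = g1_composition("AC")
        assert feats[0] == pytest.approx(np.sqrt(0.5))
        assert feats[4] == pytest.approx(np.sqrt(0.5))  # C is column 5

    def test_squares_sum_to_one_for_standard_sequences(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"),
                                     size=int(rng.integers(1, 60))))
            assert (g1_composition(seq) ** 2).sum() == pytest.approx(1.0)

    def test_nonstandard_letter_counts_toward_length_only(self):
        feats = g1_composition("AAXX")
        assert feats[0] == pytest.approx(np.sqrt(0.5))
        assert (feats ** 2).sum() == pytest.approx(0.5)


class TestMutationMeans:
    def test_all_zero_pssm(self):
        assert np.all(g2_mutation_means(np.zeros((6, 20))) == 0)

    def test_hand_value_two_rows(self):
        P = np.zeros((2, 20))
        P[:, 0] = (2, -1)  # column A
        feats = g2_mutation_means(P)
        assert feats[0] == pytest.approx(1.0)   # positive mean
        assert feats[20] == pytest.approx(-0.5)  # negative mean

    def test_sign_split(self, rng):
        feats = g2_mutation_means(random_pssm(rng, 30).scores)
        assert np.all(feats[:20] >= 0) and np.all(feats[20:] <= 0)


class TestPropertyAutocorrelations:
    def test_all_zero_pssm(self):
        assert np.all(g3_hydrophobicity_autocorr(np.zeros((30, 20))) == 0)
        assert np.all(g4_mass_autocorr(np.zeros((30, 20))) == 0)

    def test_constant_signal_gives_square(self):
        # a PSSM whose positive part projects to a constant c at every
        # position: put the same positive score in a single column
        P = np.zeros((40, 20))
        P[:, 0] = 2.0  # h+_i = 2 * H_A everywhere
        c = 2.0 * KYTE_DOOLITTLE["A"]
        feats = g3_hydrophobicity_autocorr(P)
        assert np.allclose(feats[:10], c ** 2)
        assert np.all(feats[10:] == 0)

    def test_matches_brute_force(self, rng):
        hydro = scale_vector(KYTE_DOOLITTLE)
        mass = scale_vector(SIDE_CHAIN_MASS)
        for _ in range(10):
            P = random_pssm(rng, int(rng.integers(12, 40))).scores
            np.testing.assert_allclose(
                g3_hydrophobicity_autocorr(P),
                oracle_property_autocorr(P, hydro, PROPERTY_LAGS), rtol=1e-10)
            np.testing.assert_allclose(
                g4_mass_autocorr(P),
                oracle_property_autocorr(P, mass, PROPERTY_LAGS), rtol=1e-10)

    def test_short_domain_emits_zero_lags(self):
        feats = g3_hydrophobicity_autocorr(np.ones((5, 20)))
        # lags 5..10 are undefined for L=5
        assert np.all(feats[4:10] == 0) and np.any(feats[:4] != 0)


class TestPssmAutocorrelation:
    def test_constant_column_gives_square(self):
        P = np.zeros((30, 20))
        P[:, 3] = 5.0
        feats = g5_pssm_autocorr(P).reshape(20, 7)
        assert np.allclose(feats[3], 25.0)
        assert np.all(feats[np.arange(20) != 3] == 0)

    def test_all_zero(self):
        assert np.all(g5_pssm_autocorr(np.zeros((30, 20))) == 0)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            P = random_pssm(rng, int(rng.integers(9, 40))).scores
            np.testing.assert_allclose(
                g5_pssm_autocorr(P), oracle_g5(P, PSSM_LAGS), rtol=1e-10)

    def test_column_shift_recomputes_square(self):
        # indexing spot-check: c -> c + d turns the c^2 plateau into (c+d)^2
        P = np.zeros((50, 20))
        P[:, 7] = 3.0
        base = g5_pssm_autocorr(P).reshape(20, 7)[7]
        P[:, 7] += 2.0
        shifted = g5_pssm_autocorr(P).reshape(20, 7)[7]
        assert np.allclose(base, 9.0) and np.allclose(shifted, 25.0)


class TestSegmentMeanSquare:
    def test_all_zero(self):
        assert np.all(g6_segment_mean_square(np.zeros((30, 20))) == 0)

    def test_constant_positive_column(self):
        P = np.zeros((40, 20))
        P[:, 2] = 4.0
        feats = g6_segment_mean_square(P).reshape(2, 3, 20)
        assert np.allclose(feats[0, :, 2], 16.0)  # positive part
        assert np.all(feats[1] == 0)  # negative part

    def test_matches_brute_force(self, rng):
        for _ in range(6):
            P = random_pssm(rng, int(rng.integers(17, 40))).scores
            np.testing.assert_allclose(
                g6_segment_mean_square(P), oracle_g6(P, SEGMENT_LENGTHS),
                rtol=1e-10)

    def test_short_domain_zeroes_long_segments(self):
        feats = g6_segment_mean_square(np.ones((6, 20))).reshape(2, 3, 20)
        assert np.all(feats[:, 1:, :] == 0)  # k=8 and k=16 blocks
        assert np.all(feats[0, 0, :] > 0)


class TestPositionPreference:
    def test_all_weight_on_first_position(self):
        P = np.zeros((10, 20))
        P[0, 0] = 7.0
        mean, spread, bias, edge = g7_position_preference(P)[:4]
        assert mean == pytest.approx(0.1)
        assert spread == pytest.approx(0.0)
        assert bias == pytest.approx(1.0)
        assert edge == pytest.approx(0.4)

    def test_weightless_column_default(self):
        feats = g7_position_preference(np.zeros((10, 20))).reshape(20, 4)
        assert np.allclose(feats, [0.5, 0.0, 0.0, 0.25])

    def test_uniform_column_symmetric_bias(self):
        P = np.zeros((31, 20))
        P[:, 0] = 1.0
        bias = g7_position_preference(P).reshape(20, 4)[0, 2]
        assert abs(bias) <= 1 / 31 + 1e-12

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            P = random_pssm(rng, int(rng.integers(5, 40))).scores
            np.testing.assert_allclose(
                g7_position_preference(P), oracle_g7(P), rtol=1e-10)


class TestExtractFeatures:
    def test_output_dimension_is_440(self, rng):
        pssm = random_pssm(rng, 35)
        assert extract_features(pssm.sequence, pssm).shape == (440,)

    def test_zero_pssm_leaves_only_composition(self):
        pssm = PSSM("A" * 30, np.zeros((30, 20), dtype=int))
        feats = extract_features(pssm.sequence, pssm)
        assert feats[0] == 1.0
        # G7 defaults are the only other non-zeros
        g7 = feats[360:]
        assert np.all(feats[20:360] == 0)
        assert np.allclose(g7.reshape(20, 4), [0.5, 0.0, 0.0, 0.25])

    def test_length_mismatch_rejected(self, rng):
        pssm = random_pssm(rng, 20)
        with pytest.raises(ValueError, match="length"):
            extract_features(pssm.sequence + "A", pssm)

    def test_equals_concatenated_oracles(self, rng):
        hydro = scale_vector(KYTE_DOOLITTLE)
        mass = scale_vector(SIDE_CHAIN_MASS)
        for _ in range(5):
            pssm = random_pssm(rng, int(rng.integers(18, 45)))
            P = pssm.scores
            expected = np.concatenate([
                oracle_g1(pssm.sequence),
                oracle_g2(P),
                oracle_property_autocorr(P, hydro, PROPERTY_LAGS),
                oracle_property_autocorr(P, mass, PROPERTY_LAGS),
                oracle_g5(P, PSSM_LAGS),
                oracle_g6(P, SEGMENT_LENGTHS),
                oracle_g7(P),
            ])
            np.testing.assert_allclose(
                extract_features(pssm.sequence, pssm), expected, rtol=1e-10)
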
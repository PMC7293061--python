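"""Entropy/MI identities and JMIM ranking against the brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stressecho as se
from stressecho.infotheory import JointCounts, _oracle_mi

from conftest import random_encoded_matrix


class TestEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([5, 5], 1.0),
            ([8, 0], 0.0),
            ([9, 1], -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))),  # 0.4690
        ],
    )
    def test_examples(self, counts, expected):
        assert se.entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            se.entropy([0, 0])

    def test_uniform_maximizes(self):
        assert se.entropy([1, 1, 1, 1]) == pytest.approx(2.0)


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = [0, 1] * 10
        assert se.mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_feature_carries_nothing(self):
        assert se.mutual_information([1] * 8, [0, 1] * 4) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            se.mutual_information([0, 1], [0, 1, 0])

    def test_dual_formula_agreement(self):
        """H-decomposition and direct-sum estimates agree to 1e-12 on [[2,1],[1,2]]."""
        f = [0, 0, 0, 1, 1, 1]
        c = [0, 0, 1, 0, 1, 1]  # joint counts [[2,1],[1,2]]
        direct = _oracle_mi(list(zip(f, c)))
        assert se.mutual_information(f, c) == pytest.approx(direct, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.integers(0, 3, 30)
        c = rng.integers(0, 2, 30)
        mi = se.mutual_information(f, c)
        assert mi >= 0.0
        assert mi == pytest.approx(se.mutual_information(c, f), abs=1e-12)
        assert mi <= se.entropy(np.bincount(c)) + 1e-12

    def test_i_x_x_equals_h_x(self):
        x = [0, 0, 1, 2, 2, 2]
        assert se.mutual_information(x, x) == pytest.approx(
            se.entropy(np.bincount(x)), abs=1e-12)


class TestJointMutualInformation:
    def test_constant_partner_reduces_to_plain_mi(self):
        f = [0, 1, 1, 0, 1, 0]
        c = [0, 1, 0, 0, 1, 1]
        assert se.joint_mutual_information(f, [3] * 6, c) == pytest.approx(
            se.mutual_information(f, c), abs=1e-12)

    def test_duplicate_partner_adds_nothing(self):
        f = [0, 1, 1, 0, 1, 0]
        c = [0, 1, 0, 0, 1, 1]
        assert se.joint_mutual_information(f, f, c) == pytest.approx(
            se.mutual_information(f, c), abs=1e-12)

    def test_xor_pair_is_jointly_but_not_individually_informative(self):
        """c = f1 XOR f2 on the exhaustive 4-row truth table."""
        f1 = [0, 0, 1, 1]
        f2 = [0, 1, 0, 1]
        c = [a ^ b for a, b in zip(f1, f2)]
        assert se.mutual_information(f1, c) == pytest.approx(0.0, abs=1e-12)
        assert se.mutual_information(f2, c) == pytest.approx(0.0, abs=1e-12)
        assert se.joint_mutual_information(f1, f2, c) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_pair_dominates_members(self, seed):
        """Plug-in joint MI of a pair >= each member's individual MI."""
        rng = np.random.default_rng(seed)
        fi = rng.integers(0, 3, 25)
        fs = rng.integers(0, 2, 25)
        c = rng.integers(0, 2, 25)
        jmi = se.joint_mutual_information(fi, fs, c)
        assert jmi + 1e-12 >= se.mutual_information(fi, c)
        assert jmi + 1e-12 >= se.mutual_information(fs, c)

    def test_joint_counts_validation(self):
        with pytest.raises(ValueError):
            JointCounts(np.array([[-1.0, 2.0]]))
        with pytest.raises(ValueError):
            JointCounts.from_vectors([0, 1], [0, 1], [0, 1], [0, 1])


def _matrix(columns: dict, y) -> se.EncodedMatrix:
    return se.EncodedMatrix(pd.DataFrame(columns), np.asarray(y, dtype=object))


class TestRanking:
    def test_label_copy_is_rank_one(self):
        y = ["positive", "negative"] * 10
        m = _matrix({"noise": [0] * 20, "copy": [1, 0] * 10, "other": [0, 1, 1, 0] * 5}, y)
        assert se.jmim_rank(m).features[0] == "copy"
        assert se.mim_rank(m).features[0] == "copy"

    def test_jmim_and_mim_share_rank_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = random_encoded_matrix(rng)
            assert se.jmim_rank(m).features[0] == se.mim_rank(m).features[0]

    def test_mim_sorts_by_individual_mi(self):
        rng = np.random.default_rng(4)
        m = random_encoded_matrix(rng, n_rows=30, n_features=5)
        ranking = se.mim_rank(m)
        assert sorted(ranking.criterion_bits, reverse=True) == ranking.criterion_bits

    def test_single_class_labels_rejected(self):
        m = _matrix({"f": [0, 1, 0]}, ["positive"] * 3)
        with pytest.raises(ValueError, match="class entropy"):
            se.jmim_rank(m)

    def test_ranking_is_permutation_of_features(self, planted):
        cohort, _ = planted
        m = se.encode_features(cohort)
        ranking = se.jmim_rank(m)
        assert sorted(ranking.features) == sorted(m.feature_names)
        assert all(v >= 0 for v in ranking.criterion_bits)

    def test_row_shuffle_leaves_ranking_unchanged(self, planted):
        cohort, _ = planted
        m = se.encode_features(cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m.y))
        shuffled = se.EncodedMatrix(m.X.iloc[perm].reset_index(drop=True), m.y[perm])
        assert se.jmim_rank(m).features == se.jmim_rank(shuffled).features

    def test_xor_contrast_between_mim_and_jmim(self):
        """JMIM recovers an XOR pair that individual MI cannot see.

        c = f1 XOR f2 on 8 truth-table replicates plus 3 extra (f1=1, f2=0,
        c=1) rows: the imbalance gives each member a sliver of marginal signal
        (~0.005 bits) that seeds the greedy search, after which the partner's
        joint MI with the seed is essentially the full class entropy.
        """
        f1 = [0, 0, 1, 1] * 8 + [1] * 3
        f2 = [0, 1, 0, 1] * 8 + [0] * 3
        c = [a ^ b for a, b in zip(f1, f2)]
        y = np.where(np.asarray(c) == 1, "positive", "negative")
        m = _matrix({"f1": f1, "f2": f2}, y)
        assert se.mutual_information(f1, c) < 0.05
        assert se.mutual_information(f2, c) < 0.05
        ranking = se.jmim_rank(m)
        assert ranking.features == ["f1", "f2"]
        assert ranking.criterion_bits[1] > 0.9  # ~H(C): the pair determines c

        # a weak but individually-visible feature outranks both XOR members
        # under plain MI (14/35 disagreement mask -> ~0.03 bits)
        mask = ([1] * 2 + [0] * 3) * 7
        f3 = [ci ^ mi for ci, mi in zip(c, mask)]
        m3 = _matrix({"f1": f1, "f2": f2, "f3": f3}, y)
        assert se.mim_rank(m3).features[0] == "f3"

    def test_selector_transform_keeps_top_k(self, planted):
        cohort, truth = planted
        m = se.encode_features(cohort)
        sel = se.JMIMSelector(n_features_to_select=2).fit(m)
        picked = sel.transform(m)
        assert picked.feature_names == sel.ranking_.features[:2]
        assert set(picked.feature_names) == set(truth.informative_features)
        assert sel.get_params()["n_features_to_select"] == 2

    def test_tsv_round_trip(self, planted):
        import io
        cohort, _ = planted
        ranking = se.jmim_rank(se.encode_features(cohort))
        buf = io.StringIO()
        ranking.to_tsv(buf, header_comment="seed=11")
        restored = se.RankingResult.from_tsv(io.StringIO(buf.getvalue()))
        assert restored.features == ranking.features
        assert restored.criterion_bits == pytest.approx(ranking.criterion_bits, abs=1e-6)


class TestOracle:
    def test_single_feature(self):
        y = ["positive", "negative"] * 5
        m = _matrix({"only": [0, 1, 0, 1, 1, 0, 0, 1, 0, 1]}, y)
        result = se.exhaustive_oracle_rank(m)
        assert result.features == ["only"]
        assert result.criterion_bits[0] == pytest.approx(
            se.mutual_information(m.X["only"], m.y), abs=1e-12)

    def test_duplicate_of_rank_one_is_deferred(self):
        """A copy of the top feature adds no joint information, so any feature
        with a positive min-criterion outranks the duplicate."""
        rng = np.random.default_rng(8)
        y01 = rng.integers(0, 2, 60)
        signal = np.where(rng.random(60) < 0.85, y01, 1 - y01)
        other = np.where(rng.random(60) < 0.7, y01, rng.integers(0, 2, 60))
        y = np.where(y01 == 1, "positive", "negative")
        m = _matrix({"sig": signal, "sig_copy": signal.copy(), "other": other}, y)
        result = se.exhaustive_oracle_rank(m)
        assert result.features[0] == "sig"
        assert result.features[1] == "other"  # duplicate relegated to last
        assert se.jmim_rank(m).features == result.features

    def test_too_many_features_rejected(self):
        rng = np.random.default_rng(0)
        m = random_encoded_matrix(rng, n_rows=12, n_features=9)
        with pytest.raises(ValueError, match="8 features"):
            se.exhaustive_oracle_rank(m)

    def test_fuzz_equivalence_with_jmim(self):
        """Greedy implementation matches brute-force enumeration, 100 matrices."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = random_encoded_matrix(rng)
            assert se.jmim_rank(m).features == se.exhaustive_oracle_rank(m).features
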
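"""Joint/channel data model and Shannon quantities."""

import numpy as np
import pytest

import chanpid as cp
from chanpid.distributions import ChanpidError


class TestJointFromTable:
    def test_copy_table(self, copy_joint):
        assert copy_joint.n_sources == 2
        assert copy_joint.p(((0, 1), 0, 1)) == pytest.approx(0.25)
        assert sum(copy_joint.prob.values()) == pytest.approx(1.0)

    def test_point_mass(self):
        j = cp.joint_from_table([((0, 0, 0), 1.0)])
        assert j.p((0, 0, 0)) == 1.0

    def test_near_one_sum_renormalized(self):
        j = cp.joint_from_table([((0, 0), 0.499999), ((1, 1), 0.5)])
        assert sum(j.prob.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "records, code",
        [
            ([((0, 0), -0.1), ((1, 1), 1.1)], "NEGATIVE_PROB"),
            ([((0, 0), 0.5), ((0, 0), 0.5)], "DUPLICATE_OUTCOME"),
            ([((0, 0), 0.5), ((1, 1), 0.4)], "SUM_FAR_FROM_ONE"),
            ([((0, 0), 0.5), ((1, 1, 1), 0.5)], "DIMENSION_MISMATCH"),
        ],
    )
    def test_invalid_tables(self, records, code):
        with pytest.raises(ChanpidError) as exc:
            cp.joint_from_table(records)
        assert exc.value.code == code


class TestChannelExtraction:
    def test_and_gate_channel(self, and_joint):
        p_t, K1 = cp.channel_from_joint(and_joint, 1)
        np.testing.assert_allclose(p_t.weights, [0.75, 0.25])
        np.testing.assert_allclose(K1.rows, [[2 / 3, 1 / 3], [0, 1]])

    def test_copy_channel_is_block_deterministic(self, copy_joint):
        _, K1 = cp.channel_from_joint(copy_joint, 1)
        np.testing.assert_allclose(K1.rows, [[1, 0], [1, 0], [0, 1], [0, 1]])

    def test_independent_source_gives_identical_rows(self):
        # Y2 independent of T: every row of K(2) is the Y2 marginal
        records = [((t, y), 0.25) for t in (0, 1) for y in (0, 1)]
        j = cp.joint_from_table(records)
        _, K = cp.channel_from_joint(j, 1)
        np.testing.assert_allclose(K.rows[0], K.rows[1])

    def test_zero_mass_target_outcome_dropped(self):
        records = [((0, 0), 0.5), ((1, 1), 0.5), ((2, 0), 0.0)]
        p_t, K = cp.joint_from_table(records), None
        p, K = cp.channel_from_joint(p_t, 1)
        assert p.support_labels == (0, 1)
        assert K.rows.shape == (2, 2)

    def test_tuple_channel_and_gate(self, and_joint):
        p_t, K12 = cp.tuple_channel(and_joint, [1, 2])
        assert K12.rows.shape == (2, 4)
        # T=0 is compatible with (0,0), (0,1), (1,0) equally
        np.testing.assert_allclose(K12.rows[0], [1 / 3, 1 / 3, 1 / 3, 0])
        np.testing.assert_allclose(K12.rows[1], [0, 0, 0, 1])

    def test_tuple_channel_single_index_consistency(self, and_joint):
        _, K1 = cp.channel_from_joint(and_joint, 1)
        _, K1b = cp.tuple_channel(and_joint, [1])
        np.testing.assert_allclose(K1.rows, K1b.rows)

    def test_copy_tuple_channel_is_identity(self, copy_joint):
        _, K12 = cp.tuple_channel(copy_joint, [1, 2])
        np.testing.assert_allclose(K12.rows, np.eye(4), atol=1e-12)

    def test_pairwise_marginal_reconstruction(self):
        j = cp.random_joint((3, 2), seed=7)
        p_t, K = cp.channel_from_joint(j, 1)
        marg = j.marginal([0, 1])
        for i, t in enumerate(p_t.support_labels):
            for k, y in enumerate(K.output_labels):
                assert p_t.weights[i] * K.rows[i, k] == pytest.approx(
                    marg.get((t, y), 0.0), abs=1e-12
                )


class TestInformationQuantities:
    def test_printed_mutual_informations(self, ce1_pair, ds_pair, p_46, p_334):
        _, K2 = ce1_pair
        _, K4 = ds_pair
        assert round(cp.mutual_information(p_46, K2), 3) == 0.004
        assert round(cp.mutual_information(p_334, K4), 3) == 0.322

    def test_noiseless_binary_channel(self):
        K = cp.ChannelMatrix.from_rows(np.eye(2))
        assert cp.mutual_information([0.5, 0.5], K) == pytest.approx(1.0)

    def test_identical_rows_give_zero(self):
        K = cp.ChannelMatrix.from_rows([[0.3, 0.7], [0.3, 0.7]])
        assert cp.mutual_information([0.2, 0.8], K) == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch(self):
        K = cp.ChannelMatrix.from_rows(np.eye(2))
        with pytest.raises(ChanpidError):
            cp.mutual_information([0.2, 0.3, 0.5], K)

    @pytest.mark.parametrize(
        "weights, expected",
        [((0.5, 0.5), 1.0), ((1.0, 0.0), 0.0), ((0.75, 0.25), 0.8113)],
    )
    def test_entropy(self, weights, expected):
        assert cp.entropy(cp.SimplexPoint.from_weights(weights)) == pytest.approx(
            expected, abs=5e-5
        )

    def test_specific_information_copy_case(self):
        p = cp.SimplexPoint.from_weights([0.5, 0.5])
        K = cp.ChannelMatrix.from_rows(np.eye(2))
        vals = cp.specific_information(p, K)
        assert [v.value for v in vals] == pytest.approx([1.0, 1.0])

    def test_specific_information_constant_channel(self):
        p = cp.SimplexPoint.from_weights([0.3, 0.7])
        K = cp.ChannelMatrix.from_rows([[0.5, 0.5], [0.5, 0.5]])
        assert [v.value for v in cp.specific_information(p, K)] == pytest.approx([0, 0])

    def test_specific_information_expectation_is_mi(self, and_joint):
        p_t, K1 = cp.channel_from_joint(and_joint, 1)
        vals = cp.specific_information(p_t, K1)
        expect = sum(w * v.value for w, v in zip(p_t.weights, vals))
        assert expect == pytest.approx(cp.mutual_information(p_t, K1), abs=1e-9)
        assert round(expect, 3) == 0.311

    def test_specific_information_expectation_random(self):
        # randomized identity check across many channels
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, k = rng.integers(2, 5), rng.integers(2, 5)
            K = cp.random_channel(int(n), int(k), seed)
            p = cp.SimplexPoint.from_weights(rng.dirichlet(np.ones(n)))
            vals = cp.specific_information(p, K)
            expect = sum(w * v.value for w, v in zip(p.weights, vals))
            assert expect == pytest.approx(cp.mutual_information(p, K), abs=1e-9)


class TestIO:
    def test_joint_tsv_roundtrip(self, tmp_path, and_joint):
        path = tmp_path / "and.tsv"
        cp.write_joint_tsv(and_joint, path)
        back = cp.read_joint_tsv(path)
        assert back.variable_names == and_joint.variable_names
        for o, p in and_joint.prob.items():
            assert back.p(o) == pytest.approx(p, abs=1e-12)

    def test_channel_csv_roundtrip(self, tmp_path, ce1_pair):
        K1, _ = ce1_pair
        path = tmp_path / "k1.csv"
        cp.write_channel_csv(K1, path)
        back = cp.read_channel_csv(path)
        np.testing.assert_allclose(back.rows, K1.rows)
        assert back.input_labels == K1.input_labels

    def test_malformed_tsv_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n", encoding="utf-8")
        with pytest.raises(ChanpidError):
            cp.read_joint_tsv(path)
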
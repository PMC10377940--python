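"""Intersection-information measures on the worked examples."""

import numpy as np
import pytest

import chanpid as cp
from chanpid.distributions import ChanpidError
from conftest import LIGHT_OPTS, source_channels


class TestMMI:
    def test_copy_target(self, copy_joint):
        p_t, chans = source_channels(copy_joint)
        assert cp.ii_mmi(p_t, chans).value == pytest.approx(1.0)

    def test_k3_k4(self, ds_pair, p_334):
        res = cp.ii_mmi(p_334, list(ds_pair))
        assert round(res.value, 3) == 0.322

    def test_independent_source_forces_zero(self):
        p_t, chans = source_channels(cp.gate_joint("IDENT_Y1"))
        assert cp.ii_mmi(p_t, chans).value == pytest.approx(0.0, abs=1e-12)


class TestDegradationMeasure:
    def test_and_gate(self, and_joint):
        p_t, chans = source_channels(and_joint)
        res = cp.ii_degradation(p_t, chans)
        assert res.bound_status == "EXACT"
        assert round(res.value, 3) == 0.311

    def test_sum_gate(self):
        p_t, chans = source_channels(cp.gate_joint("SUM"))
        assert round(cp.ii_degradation(p_t, chans).value, 1) == 0.5

    def test_counterexample1(self, ce1_pair, p_46):
        res = cp.ii_degradation(p_46, list(ce1_pair))
        assert round(res.value, 3) == 0.002

    def test_k3_k4_pair_zero(self, ds_pair, p_334):
        assert cp.ii_degradation(p_334, list(ds_pair)).value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_single_channel_self_redundancy(self, ce1_pair, p_46):
        K1, _ = ce1_pair
        res = cp.ii_degradation(p_46, [K1])
        assert res.value == pytest.approx(cp.mutual_information(p_46, K1), abs=1e-9)

    def test_argmax_channel_is_degradation_of_each_source(self, ce1_pair, p_46):
        res = cp.ii_degradation(p_46, list(ce1_pair))
        for K in ce1_pair:
            assert cp.degradation_check(res.argmax_channel, K, tol=1e-6).holds

    def test_specific_information_dominance_diagnostic(self, ce1_pair, p_46):
        res = cp.ii_degradation(p_46, list(ce1_pair))
        assert res.diagnostics["specific_info_dominance"]["max_excess"] <= 1e-6


class TestLessNoisyMeasure:
    def test_counterexample1_equals_weaker_source(self, ce1_pair, p_46):
        res = cp.ii_less_noisy(p_46, list(ce1_pair))
        assert res.bound_status == "EXACT"
        assert round(res.value, 3) == 0.004
        assert res.diagnostics["lower_bound_source"] == 1  # Q = Y2 is feasible

    def test_and_gate(self, and_joint):
        p_t, chans = source_channels(and_joint)
        assert round(cp.ii_less_noisy(p_t, chans).value, 3) == 0.311

    def test_k3_k4_bracket_contains_zero(self, ds_pair, p_334):
        res = cp.ii_less_noisy(p_334, list(ds_pair), LIGHT_OPTS)
        assert res.lower == pytest.approx(0.0, abs=1e-9)
        assert res.upper >= 0.0


class TestMoreCapableMeasure:
    def test_k3_k4(self, ds_pair, p_334):
        res = cp.ii_more_capable(p_334, list(ds_pair))
        assert round(res.value, 3) == 0.322

    def test_counterexample1(self, ce1_pair, p_46):
        res = cp.ii_more_capable(p_46, list(ce1_pair))
        assert round(res.value, 3) == 0.004

    def test_copy_with_independent_sources(self, copy_joint):
        p_t, chans = source_channels(copy_joint)
        res = cp.ii_more_capable(p_t, chans, LIGHT_OPTS)
        assert res.upper == pytest.approx(0.0, abs=1e-6)


class TestDsMeasure:
    def test_k3_k4_exact_via_joinmeet_certificate(self, ds_pair, p_334):
        res = cp.ii_ds(p_334, list(ds_pair))
        assert res.bound_status == "EXACT"
        assert round(res.value, 3) == 0.322
        assert res.diagnostics["ds_source"] == 1  # Q = Y4

    def test_and_gate(self, and_joint):
        p_t, chans = source_channels(and_joint)
        assert round(cp.ii_ds(p_t, chans).value, 3) == 0.311

    def test_counterexample1_unresolved_bracket(self, ce1_pair, p_46):
        res = cp.ii_ds(p_46, list(ce1_pair))
        assert res.bound_status == "BRACKET"
        assert round(res.lower, 3) == 0.002
        assert round(res.upper, 3) == 0.004


class TestCommonPart:
    def test_independent_full_support_single_component(self):
        j = cp.random_joint((2, 2, 2), seed=3)
        lab = cp.common_part_labeling(j)
        assert lab.n_components == 1

    def test_diagonal_support_one_component_per_symbol(self):
        records = [((a, a, a), 1 / 3) for a in range(3)]
        j = cp.joint_from_table(records)
        lab = cp.common_part_labeling(j)
        assert lab.n_components == 3

    def test_two_blocks(self):
        records = [
            (((0, 0), 0, 0), 0.2),
            (((0, 1), 0, 1), 0.2),
            (((1, 0), 1, 0), 0.1),
            (((2, 2), 2, 2), 0.5),
        ]
        j = cp.joint_from_table(records)
        lab = cp.common_part_labeling(j)
        assert lab.n_components == 2
        np.testing.assert_allclose(sorted(lab.component_probs.weights), [0.5, 0.5])

    def test_gacs_korner(self):
        ind = cp.random_joint((2, 2, 2), seed=5)
        assert cp.gacs_korner(ind) == pytest.approx(0.0, abs=1e-12)
        xy = cp.joint_from_table([((a, a, a), 0.5) for a in range(2)])
        assert cp.gacs_korner(xy) == pytest.approx(1.0)


class TestDeterministicMeasure:
    def test_and_gate_zero(self, and_joint):
        assert cp.ii_deterministic(and_joint).value == pytest.approx(0.0, abs=1e-12)

    def test_copy_independent_sources_zero(self, copy_joint):
        assert cp.ii_deterministic(copy_joint).value == pytest.approx(0.0, abs=1e-12)

    def test_block_structure_target(self):
        # T is the shared block index: redundancy = H(block distribution)
        records = [
            ((0, 0, 0), 0.2),
            ((0, 0, 1), 0.2),
            ((0, 1, 0), 0.2),
            ((1, 2, 2), 0.4),
        ]
        j = cp.joint_from_table(records)
        assert cp.ii_deterministic(j).value == pytest.approx(
            cp.entropy(cp.SimplexPoint.from_weights([0.6, 0.4]))
        )


class TestCopyTargetProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_independent_identity_property(self, seed):
        # copy target with independent sources: every order-based measure
        # vanishes even though MMI does not
        from conftest import random_copy_joint

        joint = random_copy_joint(seed)
        p_t, chans = source_channels(joint)
        assert cp.ii_deterministic(joint).value == pytest.approx(0.0, abs=1e-9)
        assert cp.ii_degradation(p_t, chans, LIGHT_OPTS).value == pytest.approx(
            0.0, abs=1e-6
        )
        for fn in (cp.ii_less_noisy, cp.ii_more_capable, cp.ii_ds):
            assert fn(p_t, chans, LIGHT_OPTS, joint=joint).upper <= 1e-6

    def test_copy_target_common_part_is_the_more_capable_value(self):
        # two-block dependent sources: the more-capable bracket contains the
        # Gács–Körner common information, and the common-part Q attains it
        records = []
        for y1 in (0, 1):
            for y2 in (0, 1):
                records.append((((y1, y2), y1, y2), 0.6 / 4))
        records.append((((2, 2), 2, 2), 0.4))
        joint = cp.joint_from_table(records)
        c = cp.gacs_korner(joint)
        assert c == pytest.approx(cp.entropy(cp.SimplexPoint.from_weights([0.6, 0.4])))
        res = cp.compute_measure(joint, "mc", LIGHT_OPTS)
        assert res.lower == pytest.approx(c, abs=1e-9)
        assert res.upper >= c - 1e-9


class TestBivariatePID:
    def test_and_gate_degradation(self, and_joint):
        pid = cp.pid_bivariate(and_joint, "d")
        assert pid.is_exact
        assert round(pid.redundancy.low, 3) == 0.311
        assert pid.unique1.low == pytest.approx(0.0, abs=1e-9)
        assert pid.unique2.low == pytest.approx(0.0, abs=1e-9)
        assert round(pid.synergy.low, 3) == 0.5

    def test_ident_y1_with_mmi(self):
        pid = cp.pid_bivariate(cp.gate_joint("IDENT_Y1"), "mmi")
        assert pid.redundancy.low == pytest.approx(0.0, abs=1e-9)
        assert pid.unique1.low == pytest.approx(1.0)
        assert pid.unique2.low == pytest.approx(0.0, abs=1e-9)
        assert pid.synergy.low == pytest.approx(0.0, abs=1e-9)

    def test_copy_with_more_capable(self, copy_joint):
        pid = cp.pid_bivariate(copy_joint, "mc", LIGHT_OPTS)
        assert pid.redundancy.high == pytest.approx(0.0, abs=1e-6)
        assert pid.unique1.low == pytest.approx(1.0, abs=1e-6)
        assert pid.unique2.low == pytest.approx(1.0, abs=1e-6)
        assert pid.synergy.high == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("measure", ["d", "mmi", "det"])
    def test_components_sum_to_total(self, measure, and_joint):
        pid = cp.pid_bivariate(and_joint, measure)
        total = (
            pid.redundancy.low + pid.unique1.low + pid.unique2.low + pid.synergy.low
        )
        assert total == pytest.approx(pid.total, abs=1e-6)

    def test_unsupported_measure(self, and_joint):
        with pytest.raises(ChanpidError):
            cp.pid_bivariate(and_joint, "nope")

    def test_bracket_propagates_to_components(self, ce1_pair, p_46):
        # counterexample-1 under ds: interval redundancy -> interval components
        records = []
        K1, K2 = ce1_pair
        for t, w in enumerate(p_46.weights):
            for y1 in (0, 1):
                for y2 in (0, 1):
                    records.append(((t, y1, y2), w * K1.rows[t, y1] * K2.rows[t, y2]))
        j = cp.joint_from_table(records)
        pid = cp.pid_bivariate(j, "ds")
        assert pid.bound_status == "BRACKET"
        assert pid.redundancy.width > 0
        assert pid.unique2.high - pid.unique2.low == pytest.approx(
            pid.redundancy.width, abs=1e-9
        )
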
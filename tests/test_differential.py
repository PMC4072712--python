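"""Replicate merging, list alignment and the DAve/DCI dual-threshold call."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from membranome import (
    AnalysisConfig,
    RunIdentification,
    align_lists,
    compute_dave,
    compute_dci,
    flag_differential,
    merge_replicates,
)
from membranome.differential import (
    DifferentialRecord,
    compare_conditions,
    consensus_from_scores,
)
from membranome.errors import ValidationError
from membranome.identification import ProteinEntry


def run_with(condition, scores, sample="s", bio=1, tech=1):
    return RunIdentification(
        sample_id=sample,
        condition=condition,
        bio_replicate=bio,
        tech_replicate=tech,
        entries=[
            ProteinEntry(accession=a, sc=s, hits=max(1, int(s // 6)))
            for a, s in scores.items()
        ],
    )


scores_st = st.dictionaries(
    st.sampled_from([f"P{i}" for i in range(12)]),
    st.floats(0.5, 120, allow_nan=False),
    max_size=12,
)


class TestMergeReplicates:
    def test_max_policy_takes_maximum(self):
        runs = [run_with("ref", {"A": 40}, "r1"), run_with("ref", {"A": 36}, "r2")]
        assert merge_replicates(runs, "max").scores["A"][0] == 40

    def test_union_presence_single_detection(self):
        runs = [
            run_with("ref", {"A": 20}, "r1"),
            run_with("ref", {}, "r2"),
            run_with("ref", {}, "r3"),
            run_with("ref", {}, "r4"),
        ]
        merged = merge_replicates(runs, "max")
        assert merged.scores["A"] == (20, 3)

    def test_mean_and_sum_policies(self):
        runs = [run_with("ref", {"A": 10}, "r1"), run_with("ref", {"A": 30}, "r2")]
        assert merge_replicates(runs, "mean").scores["A"][0] == pytest.approx(20)
        assert merge_replicates(runs, "sum").scores["A"][0] == pytest.approx(40)

    def test_zero_runs_error(self):
        with pytest.raises(ValidationError):
            merge_replicates([], "max")

    def test_mixed_conditions_error(self):
        with pytest.raises(ValidationError, match="mixed"):
            merge_replicates(
                [run_with("ref", {"A": 1}), run_with("test", {"A": 1})], "max"
            )


class TestAlignLists:
    def test_outer_join_with_zero_for_absent(self):
        ref = consensus_from_scores("ref", {"A": 30})
        test = consensus_from_scores("test", {"A": 10, "B": 25})
        records = {r.accession: r for r in align_lists(ref, test)}
        assert (records["A"].sc_ref, records["A"].sc_test) == (30, 10)
        assert (records["B"].sc_ref, records["B"].sc_test) == (0, 25)

    def test_identical_lists_align_symmetrically(self):
        a = consensus_from_scores("ref", {"A": 3, "B": 4})
        b = consensus_from_scores("test", {"A": 3, "B": 4})
        assert all(r.sc_ref == r.sc_test for r in align_lists(a, b))

    def test_disjoint_lists_concatenate(self):
        a = consensus_from_scores("ref", {f"R{i}": 10 for i in range(3)})
        b = consensus_from_scores("test", {f"T{i}": 10 for i in range(4)})
        assert len(align_lists(a, b)) == 7

    def test_same_condition_rejected(self):
        a = consensus_from_scores("ref", {"A": 3})
        with pytest.raises(ValidationError):
            align_lists(a, consensus_from_scores("ref", {"A": 3}))


class TestDaveDci:
    @pytest.mark.parametrize(
        "ref,test,dave",
        [(0, 45, -2.0), (45, 0, 2.0), (12, 12, 0.0), (30, 10, 1.0)],
    )
    def test_dave_values(self, ref, test, dave):
        assert compute_dave(ref, test) == pytest.approx(dave)

    @pytest.mark.parametrize("ref,test,dci", [(30, 10, 400.0), (7, 7, 0.0)])
    def test_dci_values(self, ref, test, dci):
        assert compute_dci(ref, test) == pytest.approx(dci)

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            compute_dave(0, 0)
        with pytest.raises(ValidationError):
            compute_dci(0, 0)

    @given(st.floats(0, 500, allow_subnormal=False), st.floats(0, 500, allow_subnormal=False))
    def test_antisymmetry(self, a, b):
        if a + b == 0:
            return
        assert compute_dave(a, b) == pytest.approx(-compute_dave(b, a))
        assert compute_dci(a, b) == pytest.approx(-compute_dci(b, a))

    @given(
        st.one_of(st.just(0.0), st.floats(0.01, 500)),
        st.one_of(st.just(0.0), st.floats(0.01, 500)),
    )
    def test_dave_extreme_iff_one_zero(self, a, b):
        if a + b == 0:
            return
        dave = compute_dave(a, b)
        assert -2.0 <= dave <= 2.0
        assert (abs(dave) == 2.0) == ((a == 0) != (b == 0))

    @given(
        st.floats(0.01, 500), st.floats(0.01, 500), st.floats(0.01, 50)
    )
    def test_dave_scale_invariant_dci_quadratic(self, a, b, c):
        assert compute_dave(a * c, b * c) == pytest.approx(
            compute_dave(a, b), rel=1e-9
        )
        assert compute_dci(a * c, b * c) == pytest.approx(
            compute_dci(a, b) * c * c, rel=1e-9
        )


class TestFlagDifferential:
    def record(self, ref, test):
        return DifferentialRecord(accession="A", sc_ref=ref, sc_test=test)

    def test_dci_at_threshold_not_significant(self, config):
        # scores 30 vs 10: DAve 1.0 but DCI exactly 400 fails the strict cut
        (r,) = flag_differential([self.record(30, 10)], config)
        assert r.dave == pytest.approx(1.0) and r.dci == pytest.approx(400.0)
        assert not r.significant

    def test_presence_absence_is_significant(self, config):
        # 50 vs 0: DAve 2.0, DCI 1250
        (r,) = flag_differential([self.record(50, 0)], config)
        assert r.dave == pytest.approx(2.0) and r.dci == pytest.approx(1250.0)
        assert r.significant

    def test_disagreeing_signs_not_significant(self, config):
        r = DifferentialRecord("A", 1, 1, dave=0.5, dci=-500.0)
        (out,) = flag_differential([r], config)
        assert not out.significant

    def test_grid_matches_literal_threshold_sentence(self, config):
        """Exhaustive oracle over integer score pairs {0..60}²\\{(0,0)}."""
        for ref in range(61):
            for test in range(61):
                if ref == test == 0:
                    continue
                (r,) = flag_differential([self.record(ref, test)], config)
                dave, dci = compute_dave(ref, test), compute_dci(ref, test)
                literal = (dave > 0.4 and dci > 400) or (dave < -0.4 and dci < -400)
                assert r.significant == literal, (ref, test)

    @given(scores_st, scores_st)
    def test_swapping_conditions_negates_and_preserves_flags(self, sa, sb):
        config = AnalysisConfig()
        if not sa and not sb:
            return
        a = consensus_from_scores("ref", sa)
        b = consensus_from_scores("test", sb)
        fwd = {r.accession: r for r in compare_conditions(a, b, config)}
        a2 = consensus_from_scores("x", sa)
        b2 = consensus_from_scores("y", sb)
        rev = {r.accession: r for r in compare_conditions(b2, a2, config)}
        assert set(fwd) == set(rev)
        for acc in fwd:
            assert fwd[acc].dave == pytest.approx(-rev[acc].dave)
            assert fwd[acc].dci == pytest.approx(-rev[acc].dci)
            assert fwd[acc].significant == rev[acc].significant
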
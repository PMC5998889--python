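"""Score function, per-gene activity selection, and the brute-force search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regushift as rs
from regushift.segmentation import CandidateActivitySet


def enumerate_best_row(m_row, tra):
    """Independent oracle: maximize the inner product over all candidates."""
    best_v, best_val = None, -np.inf
    for v in CandidateActivitySet(tra, len(m_row)).vectors:
        val = float(np.dot(m_row, v))
        if val > best_val:
            best_v, best_val = v, val
    return best_v, best_val


class TestDeriveTransitions:
    @pytest.mark.parametrize(
        "act, expected",
        [
            ([[1, 1, 1, 1], [0, 0, 0, 0]], ()),
            ([[1, 1, 0, 0], [1, 1, 1, 1]], (2,)),
            ([[1, 0, 1]], (1, 2)),
            ([[0, 0], [0, 0]], ()),
        ],
    )
    def test_definition(self, act, expected):
        assert rs.derive_transitions(act) == expected

    def test_rejects_non_binary(self):
        with pytest.raises(rs.ValidationError):
            rs.derive_transitions([[0.5, 1.0]])


class TestScoreModel:
    def test_hand_evaluated_score(self):
        raw, score = rs.score_model(
            [[1, 2], [-1, 3]], [[1, 1], [0, 1]],
            penalty_factor=1.0, penalty_mode="effective",
        )
        assert raw == 6.0
        assert score == pytest.approx(6.0 - math.log(4), abs=1e-12)

    def test_penalty_factor_two(self):
        _, score = rs.score_model(
            [[1, 2], [-1, 3]], [[1, 1], [0, 1]],
            penalty_factor=2.0, penalty_mode="effective",
        )
        assert score == pytest.approx(6.0 - 2 * math.log(4), abs=1e-12)

    def test_empty_model_scores_zero(self):
        raw, score = rs.score_model(
            [[3.0, -2.0], [1.0, 1.0]], [[0, 0], [0, 0]], penalty_factor=1.0
        )
        assert raw == 0.0 and score == 0.0

    def test_declared_mode_charges_unused_breaks(self):
        raw, score = rs.score_model(
            [[1, 1]], [[1, 1]], penalty_factor=1.0,
            penalty_mode="declared", tra=(1,),
        )
        assert raw == 2.0
        assert score == pytest.approx(2.0 - math.log(2))

    def test_shape_mismatch(self):
        with pytest.raises(rs.ValidationError):
            rs.score_model([[1, 2, 3]], [[1, 1]])


class TestBestRowActivity:
    @pytest.mark.parametrize(
        "m_row, tra, v_exp, raw_exp",
        [
            ([2, -1, -3, 4], (2,), [1, 1, 1, 1], 2.0),
            ([-1, -1], (), [0, 0], 0.0),
            ([1, -1], (1,), [1, 0], 1.0),
        ],
    )
    def test_examples(self, m_row, tra, v_exp, raw_exp):
        v, raw = rs.best_row_activity(m_row, tra)
        assert v.tolist() == v_exp
        assert raw == pytest.approx(raw_exp)
        # cross-check against full enumeration
        v_or, raw_or = enumerate_best_row(np.asarray(m_row, float), tra)
        assert raw == pytest.approx(max(raw_or, 0.0))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        n = data.draw(st.integers(2, 6))
        row = np.array(
            data.draw(
                st.lists(
                    st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n
                )
            )
        )
        k = data.draw(st.integers(0, n - 1))
        tra = tuple(
            sorted(
                data.draw(
                    st.lists(
                        st.integers(1, n - 1), min_size=k, max_size=k, unique=True
                    )
                )
            )
        )
        v, raw = rs.best_row_activity(row, tra)
        _, raw_or = enumerate_best_row(row, tra)
        assert raw == pytest.approx(max(raw_or, 0.0), abs=1e-9)


class TestEvaluateSegmentation:
    def test_alternating_sign_instance(self, micro_m):
        m = rs.evaluate_segmentation(
            micro_m, (1, 2), penalty_factor=1.0, penalty_mode="declared"
        )
        assert m.act.tolist() == [[1, 0, 1]]
        assert m.raw_score == 10.0
        assert m.score == pytest.approx(10.0 - 2 * math.log(3), abs=1e-12)

    def test_no_breaks_takes_positive_total(self, micro_m):
        m = rs.evaluate_segmentation(micro_m, (), penalty_factor=1.0)
        assert m.act.tolist() == [[1, 1, 1]]
        assert m.raw_score == 5.0 and m.score == 5.0

    def test_all_negative_canonicalizes_to_empty(self):
        m = rs.evaluate_segmentation(
            [[-1.0, -2.0], [-3.0, -0.5]], (1,),
            penalty_factor=1.0, penalty_mode="effective",
        )
        assert m.act.sum() == 0
        assert m.tra == () and m.score == 0.0
        m.validate()

    def test_break_out_of_range(self, micro_m):
        with pytest.raises(rs.ValidationError):
            rs.evaluate_segmentation(micro_m, (3,))

    def test_decomposability(self):
        rng = np.random.default_rng(11)
        M = rng.uniform(-1, 1, size=(4, 7))
        tra = (2, 5)
        m = rs.evaluate_segmentation(M, tra, penalty_factor=1.0)
        expected = sum(
            max(0.0, M[i, a : b + 1].sum())
            for i in range(4)
            for a, b in rs.periods_from_breaks(tra, 7)
        )
        assert m.raw_score == pytest.approx(expected, abs=1e-12)


class TestSearchExhaustive:
    def test_micro_instance_full_search(self, micro_m):
        res = rs.search_exhaustive(
            micro_m, penalty_factor=1.0, penalty_mode="declared", early_stop=False
        )
        assert res.best.tra == (1, 2)
        assert res.best.act.tolist() == [[1, 0, 1]]
        assert res.best.score == pytest.approx(10 - 2 * math.log(3), abs=1e-12)
        assert not res.stopped_early

    def test_early_stop_returns_flat_model(self, micro_m):
        res = rs.search_exhaustive(
            micro_m, penalty_factor=1.0, penalty_mode="declared", early_stop=True
        )
        # every 1-break model scores 5 - ln 3 < 5, so the k-loop quits
        assert res.stopped_early
        assert res.best.tra == () and res.best.score == 5.0
        assert [kb.k for kb in res.per_k] == [0, 1]
        # the k=2 row is still tabulated for reference, without changing best
        assert any(kb.k == 2 for kb in res.reference)

    def test_all_positive_needs_no_breaks(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(0.1, 2.0, size=(3, 5))
        res = rs.search_exhaustive(M, penalty_factor=1.0, early_stop=False)
        assert res.best.tra == ()
        assert res.best.act.all()
        assert res.best.score == pytest.approx(M.sum(), abs=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(rs.ValidationError):
            rs.search_exhaustive(np.empty((0, 3)))

    @pytest.mark.parametrize("seed", range(8))
    def test_raw_score_nondecreasing_in_k(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(-1, 1, size=(4, 6))
        res = rs.search_exhaustive(M, penalty_factor=0.5, early_stop=False)
        raws = [kb.raw_score for kb in res.per_k]
        assert all(b >= a - 1e-12 for a, b in zip(raws, raws[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_more_penalty_never_more_breaks(self, seed):
        rng = np.random.default_rng(100 + seed)
        M = rng.uniform(-1, 1, size=(4, 6))
        sizes = [
            len(
                rs.search_exhaustive(
                    M, penalty_factor=c, early_stop=False
                ).best.tra
            )
            for c in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_every_optimal_break_is_used(self, seed):
        """In the exhaustive optimum every declared break is realized by some
        gene, so the declared and effective optima coincide."""
        rng = np.random.default_rng(200 + seed)
        M = rng.uniform(-1, 1, size=(4, 6))
        res_d = rs.search_exhaustive(
            M, penalty_factor=1.0, penalty_mode="declared", early_stop=False
        )
        assert rs.derive_transitions(res_d.best.act) == res_d.best.tra
        res_e = rs.search_exhaustive(
            M, penalty_factor=1.0, penalty_mode="effective", early_stop=False
        )
        assert res_e.best.score == pytest.approx(res_d.best.score, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_sign_symmetry_at_k0(self, seed):
        rng = np.random.default_rng(300 + seed)
        M = rng.uniform(-1, 1, size=(3, 5))
        act_pos = rs.evaluate_segmentation(M, (), penalty_factor=1.0).act
        act_neg = rs.evaluate_segmentation(-M, (), penalty_factor=1.0).act
        assert ((act_pos + act_neg) == 1).all()
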
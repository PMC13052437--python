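"""Judgment-matrix math: validation, priorities, consistency, rounding, fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ahprank import (
    SAATY_SCALE,
    PairwiseMatrix,
    PriorityVector,
    StructuralError,
    consistency,
    consistent_matrix_from_weights,
    fit_saaty_matrix,
    priority_column_normalization,
    priority_eigenvector,
    round_to_saaty,
    validate_matrix,
)
from ahprank.synthetic import generate_judgments

# deliberately inconsistent 3x3 used across several checks
INCONSISTENT = [[1, 2, 0.5], [0.5, 1, 4], [2, 0.25, 1]]

positive_weights = st.lists(
    st.floats(min_value=0.05, max_value=20, allow_nan=False), min_size=2, max_size=6
)


def _dense_principal(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Independent oracle: dense eigendecomposition via numpy."""
    vals, vecs = np.linalg.eig(a)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    return v / v.sum(), float(vals[k].real)


class TestValidation:
    def test_reciprocal_2x2_is_valid(self):
        m = PairwiseMatrix(["a", "b"], [[1, 2], [0.5, 1]])
        assert validate_matrix(m) == []

    def test_broken_reciprocity_names_the_cell(self):
        m = PairwiseMatrix(["a", "b"], [[1, 3], [0.5, 1]])
        (v,) = validate_matrix(m)
        assert v.kind == "reciprocity" and v.cell == (1, 0)

    def test_strict_saaty_flags_off_scale_entry(self):
        m = PairwiseMatrix(["a", "b"], [[1, 1.4], [1 / 1.4, 1]])
        assert validate_matrix(m) == []  # fine as a general reciprocal matrix
        kinds = {v.kind for v in validate_matrix(m, strict_saaty=True)}
        assert kinds == {"saaty"}

    def test_nonsquare_is_a_structural_error(self):
        with pytest.raises(StructuralError):
            PairwiseMatrix(["a", "b"], [[1, 2, 3], [0.5, 1, 1]])

    def test_nonpositive_entry_is_positivity_violation(self):
        m = PairwiseMatrix(["a", "b"], [[1, -2], [-0.5, 1]])
        assert {v.kind for v in validate_matrix(m)} == {"positivity"}


class TestPriorities:
    def test_uniform_matrix_gives_uniform_weights(self):
        m = PairwiseMatrix(list("abc"), np.ones((3, 3)))
        pv, lam = priority_eigenvector(m)
        assert pv.weights == pytest.approx([1 / 3] * 3, abs=1e-12)
        assert lam == pytest.approx(3.0, abs=1e-9)
        assert priority_column_normalization(m).weights == pytest.approx([1 / 3] * 3)

    def test_consistent_matrix_recovers_generating_weights(self):
        m = PairwiseMatrix(list("abc"), [[1, 2, 6], [0.5, 1, 3], [1 / 6, 1 / 3, 1]])
        pv, lam = priority_eigenvector(m)
        assert pv.weights == pytest.approx([0.6, 0.3, 0.1], abs=1e-9)
        assert lam == pytest.approx(3.0, abs=1e-9)

    def test_extreme_judgment_matrix_gives_9_1_1_elevenths(self):
        """The 9/9/1 matrix yields 81.8 / 9.1 / 9.1 (%), by both methods."""
        m = PairwiseMatrix(["1:3", "1:2.5", "1:2"], [[1, 9, 9], [1 / 9, 1, 1], [1 / 9, 1, 1]])
        pv, _ = priority_eigenvector(m)
        assert pv.weights == pytest.approx([9 / 11, 1 / 11, 1 / 11], abs=1e-9)
        assert list(np.round(pv.weights * 100, 1)) == [81.8, 9.1, 9.1]
        cn = priority_column_normalization(m)
        assert cn.weights == pytest.approx(pv.weights, abs=1e-9)

    def test_inconsistent_matrix_methods_disagree(self):
        m = PairwiseMatrix(list("abc"), INCONSISTENT)
        pv, lam = priority_eigenvector(m)
        dense_w, dense_lam = _dense_principal(m.values)
        assert pv.weights == pytest.approx(dense_w, abs=1e-10)
        assert lam == pytest.approx(dense_lam, abs=1e-10)
        cn = priority_column_normalization(m)
        # frozen from the column-normalization definition applied by hand
        assert cn.weights == pytest.approx([0.33066933, 0.39260739, 0.27672328], abs=1e-8)
        assert np.max(np.abs(cn.weights - pv.weights)) > 1e-3

    @settings(derandomize=True, max_examples=60)
    @given(positive_weights)
    def test_power_iteration_matches_dense_solver(self, raw):
        m = generate_judgments(np.array(raw), noise_sd=0.4, seed=hash(tuple(raw)) % 2**31)
        pv, lam = priority_eigenvector(m)
        dense_w, dense_lam = _dense_principal(m.values)
        assert pv.weights == pytest.approx(dense_w, abs=1e-8)
        assert lam == pytest.approx(dense_lam, abs=1e-8)
        assert lam >= m.n - 1e-9  # lambda_max >= n always

    @settings(derandomize=True, max_examples=60)
    @given(positive_weights)
    def test_methods_agree_exactly_on_consistent_matrices(self, raw):
        pv = PriorityVector.from_raw([f"x{i}" for i in range(len(raw))], raw)
        m = consistent_matrix_from_weights(pv)
        eig, lam = priority_eigenvector(m)
        assert eig.weights == pytest.approx(pv.weights, abs=1e-9)
        assert priority_column_normalization(m).weights == pytest.approx(pv.weights, abs=1e-9)
        assert lam == pytest.approx(m.n, abs=1e-9)


class TestConsistency:
    def test_consistent_4x4_has_zero_cr(self):
        pv = PriorityVector.from_raw(list("abcd"), [4, 3, 2, 1])
        rep = consistency(consistent_matrix_from_weights(pv))
        assert rep.cr == pytest.approx(0.0, abs=1e-9)
        assert rep.consistent

    def test_any_2x2_is_consistent(self):
        rep = consistency(PairwiseMatrix(["a", "b"], [[1, 7], [1 / 7, 1]]))
        assert rep.cr == 0.0 and rep.consistent

    def test_inconsistent_3x3_cr_matches_dense_lambda(self):
        m = PairwiseMatrix(list("abc"), INCONSISTENT)
        _, dense_lam = _dense_principal(m.values)
        expected_cr = ((dense_lam - 3) / 2) / 0.58
        rep = consistency(m)
        assert rep.cr == pytest.approx(expected_cr, abs=1e-9)
        assert rep.cr == pytest.approx(0.79025204, abs=1e-6)  # frozen dense-eig value
        assert not rep.consistent

    def test_ri_table_bound(self):
        pv = PriorityVector.from_raw([f"x{i}" for i in range(11)], range(1, 12))
        with pytest.raises(ValueError, match="n <= 10"):
            consistency(consistent_matrix_from_weights(pv))


class TestConstructionAndRounding:
    def test_equal_weights_give_all_ones(self):
        m = consistent_matrix_from_weights(PriorityVector(["a", "b"], [0.5, 0.5]))
        assert np.allclose(m.values, 1.0)

    def test_ratio_matrix_from_printed_mole_priorities(self):
        pv = PriorityVector.from_raw(["1:3", "1:2.5", "1:2"], [0.818, 0.091, 0.091])
        m = consistent_matrix_from_weights(pv)
        assert m.values[0, 1] == pytest.approx(0.818 / 0.091)
        assert np.allclose(round_to_saaty(m).values[0, 1:], 9.0)

    def test_zero_weight_is_rejected(self):
        pv = PriorityVector(list("abc"), [0.5, 0.5, 0.0])
        with pytest.raises(ZeroDivisionError):
            consistent_matrix_from_weights(pv)

    @pytest.mark.parametrize(
        "entry,expected",
        [(8.99, 9.0), (1.4, 1.0), (0.35, 1 / 3), (1.5, 1.0), (0.3, 1 / 3)],
    )
    def test_rounding_to_nearest_saaty_value(self, entry, expected):
        # brute-force oracle over the 17-value admissible set, ties toward 1
        scale = sorted((float(s) for s in SAATY_SCALE), key=lambda s: (abs(s - entry), abs(s - 1)))
        assert scale[0] == pytest.approx(expected)
        m = PairwiseMatrix(["a", "b"], [[1, entry], [1 / entry, 1]])
        assert round_to_saaty(m).values[0, 1] == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(positive_weights)
    def test_rounded_matrices_stay_reciprocal_and_strict(self, raw):
        pv = PriorityVector.from_raw([f"x{i}" for i in range(len(raw))], raw)
        r = round_to_saaty(consistent_matrix_from_weights(pv))
        assert validate_matrix(r, strict_saaty=True) == []


class TestFitSaatyMatrix:
    def test_exhaustive_recovers_the_9_1_1_matrix(self):
        pv = PriorityVector.from_raw(["1:3", "1:2.5", "1:2"], [0.818, 0.091, 0.091])
        m, residual = fit_saaty_matrix(pv, budget=len(SAATY_SCALE) ** 3)
        assert np.allclose(m.values, [[1, 9, 9], [1 / 9, 1, 1], [1 / 9, 1, 1]])
        assert residual < 1e-3

    def test_uniform_target_is_exactly_representable(self):
        pv = PriorityVector(list("abc"), [1 / 3] * 3)
        m, residual = fit_saaty_matrix(pv)
        assert np.allclose(m.values, 1.0)
        assert residual == pytest.approx(0.0, abs=1e-9)

    def test_exhaustive_beats_random_strict_saaty_matrices(self):
        """The n=3 exhaustive search is a global optimum: no sampled matrix does better."""
        pv = PriorityVector.from_raw(list("abc"), [0.55, 0.3, 0.15])
        _, best = fit_saaty_matrix(pv, budget=len(SAATY_SCALE) ** 3)
        rng = np.random.default_rng(7)
        for _ in range(200):
            a12, a13, a23 = (float(SAATY_SCALE[i]) for i in rng.integers(0, 17, 3))
            cand = PairwiseMatrix(list("abc"), [[1, a12, a13],
                                                [1 / a12, 1, a23],
                                                [1 / a13, 1 / a23, 1]])
            r = float(np.linalg.norm(priority_eigenvector(cand)[0].weights - pv.weights))
            assert best <= r + 1e-12

    def test_four_criterion_target_has_irreducible_residual(self):
        """33.1/33.1/23.7/10.1 is not representable on the 1-9 scale; the
        best strict-Saaty fit leaves a small, pinned residual."""
        pv = PriorityVector(["metal_salt", "mole_ratio", "solvent", "duration"],
                            [0.331, 0.331, 0.237, 0.101])
        m, residual = fit_saaty_matrix(pv)
        assert validate_matrix(m, strict_saaty=True) == []
        assert residual == pytest.approx(0.0168180563, abs=1e-8)
        assert residual > 1e-3

    def test_size_cap(self):
        pv = PriorityVector.from_raw([f"x{i}" for i in range(7)], range(1, 8))
        with pytest.raises(ValueError, match="n <= 6"):
            fit_saaty_matrix(pv)
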
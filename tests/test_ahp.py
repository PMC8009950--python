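"""AHP engine: eigenvector priorities, consistency, aggregation, synthesis."""

import numpy as np
import pytest

from feedeval.ahp import (
    AHPModel,
    ExpertJudgments,
    InconsistentMatrixError,
    MatrixValidationError,
    PairwiseMatrix,
    PriorityVector,
    aggregate_experts,
    consistent_matrix,
    dump_model,
    geometric_matrix_mean,
    load_model,
    priorities,
    synthesize,
)
from feedeval.synth import gen_expert_matrices


def _vector(*weights, items=None):
    w = np.asarray(weights, float)
    items = tuple(items or (f"i{k}" for k in range(w.size)))
    return PriorityVector(items, w / w.sum())


class TestValidation:
    def test_non_reciprocal_rejected(self):
        A = np.array([[1.0, 2.0], [0.4, 1.0]])
        with pytest.raises(MatrixValidationError, match="reciprocal"):
            PairwiseMatrix(("a", "b"), A)

    def test_out_of_scale_rejected(self):
        A = np.array([[1.0, 12.0], [1 / 12.0, 1.0]])
        with pytest.raises(MatrixValidationError):
            PairwiseMatrix(("a", "b"), A)

    def test_upper_triangle_construction(self):
        M = PairwiseMatrix.from_upper_triangle(("a", "b", "c"),
                                               {("a", "b"): 3, ("a", "c"): 5, ("b", "c"): 3})
        assert M.values[1, 0] == pytest.approx(1 / 3)
        assert M.values[2, 0] == pytest.approx(1 / 5)


class TestPriorities:
    def test_consistent_matrix_exact_recovery(self):
        truth = _vector(0.5, 0.3, 0.2)
        vec, rep = priorities(consistent_matrix(truth))
        assert np.allclose(vec.weights, truth.weights, atol=1e-10)
        assert rep.CR == pytest.approx(0.0, abs=1e-10)
        assert rep.lambda_max == pytest.approx(3.0, abs=1e-9)

    def test_known_3x3_example(self):
        M = PairwiseMatrix(("a", "b", "c"),
                           np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1]]))
        vec, rep = priorities(M)
        assert np.allclose(vec.weights, [0.637, 0.258, 0.105], atol=0.001)
        assert rep.CR == pytest.approx(0.033, abs=0.001)

    def test_2x2_always_consistent(self):
        M = PairwiseMatrix(("a", "b"), np.array([[1.0, 7.0], [1 / 7.0, 1.0]]))
        _, rep = priorities(M)
        assert rep.CR == 0.0 and rep.acceptable

    def test_power_iteration_matches_dense_eigensolver(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(3, 8))
            truth = _vector(*rng.uniform(0.5, 3.0, n))
            mats = gen_expert_matrices(truth, jitter=0.3, n_experts=1,
                                       seed=int(rng.integers(2**31)))
            M = mats[0]
            vec, rep = priorities(M)
            vals, vecs = np.linalg.eig(M.values)
            lead = np.argmax(vals.real)
            ref = np.abs(vecs[:, lead].real)
            ref /= ref.sum()
            assert np.allclose(vec.weights, ref, atol=1e-8)
            assert rep.lambda_max == pytest.approx(float(vals[lead].real), abs=1e-8)

    def test_permutation_invariance(self):
        M = PairwiseMatrix(("a", "b", "c"),
                           np.array([[1, 2, 6], [0.5, 1, 4], [1 / 6, 0.25, 1]]))
        vec, _ = priorities(M)
        perm = [2, 0, 1]
        Mp = PairwiseMatrix(tuple(M.items[i] for i in perm),
                            M.values[np.ix_(perm, perm)])
        vp, _ = priorities(Mp)
        assert vp.as_dict() == pytest.approx(vec.as_dict(), abs=1e-10)

    def test_consistent_priorities_equal_normalized_column(self):
        truth = _vector(4, 2, 1, 1)
        M = consistent_matrix(truth)
        vec, _ = priorities(M)
        col = M.values[:, 2] / M.values[:, 2].sum()
        assert np.allclose(vec.weights, col, atol=1e-10)


class TestAggregation:
    def test_single_expert_identity(self):
        v = _vector(0.6, 0.4)
        assert aggregate_experts([v]).as_dict() == pytest.approx(v.as_dict())

    def test_two_expert_symmetry(self):
        a, b = _vector(0.6, 0.4), _vector(0.4, 0.6)
        assert aggregate_experts([a, b]).weights == pytest.approx([0.5, 0.5])

    def test_mismatched_items_error(self):
        a = _vector(0.5, 0.5, items=("x", "y"))
        b = _vector(0.5, 0.5, items=("x", "z"))
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_experts([a, b])

    def test_perturbed_vectors_mean_near_truth(self):
        truth = _vector(0.5, 0.3, 0.2)
        rng = np.random.default_rng(4)
        vecs = []
        for _ in range(3):
            w = truth.weights + rng.uniform(-0.03, 0.03, 3)
            vecs.append(PriorityVector(truth.items, w / w.sum()))
        agg = aggregate_experts(vecs)
        assert np.max(np.abs(agg.weights - truth.weights)) < 0.05

    def test_geometric_matrix_mean_preserves_reciprocity(self):
        truth = _vector(1, 2, 3)
        mats = gen_expert_matrices(truth, jitter=0.2, n_experts=3, seed=5)
        pooled = geometric_matrix_mean(mats)  # validates on construction
        assert np.allclose(pooled.values * pooled.values.T, 1.0)


def _model_from_truth(criteria_w, local_w):
    """Model whose matrices are exactly consistent with known weights."""
    experts = [ExpertJudgments(
        criteria_matrix=consistent_matrix(criteria_w),
        alternative_matrices={c: consistent_matrix(local_w[c]) for c in criteria_w.items},
    )]
    return AHPModel(goal="nutritional value", criteria=criteria_w.items,
                    alternatives=local_w[criteria_w.items[0]].items, experts=experts)


class TestSynthesis:
    CRITERIA = ("amino_acids", "fatty_acids", "vitamins", "minerals")
    ALTS = ("fish", "isopod", "krill")

    def test_uniform_criteria_identical_locals_global_equals_local(self):
        crit = _vector(1, 1, 1, 1, items=self.CRITERIA)
        local = _vector(0.5, 0.3, 0.2, items=self.ALTS)
        model = _model_from_truth(crit, {c: local for c in self.CRITERIA})
        rep = synthesize(model)
        assert rep.global_weights.as_dict() == pytest.approx(local.as_dict(), abs=1e-9)

    def test_construction_oracle_exact_recovery(self):
        crit = _vector(0.4, 0.3, 0.2, 0.1, items=self.CRITERIA)
        locals_ = {
            "amino_acids": _vector(0.6, 0.2, 0.2, items=self.ALTS),
            "fatty_acids": _vector(0.5, 0.1, 0.4, items=self.ALTS),
            "vitamins": _vector(0.2, 0.5, 0.3, items=self.ALTS),
            "minerals": _vector(0.2, 0.6, 0.2, items=self.ALTS),
        }
        expected = np.zeros(3)
        for c, lw in locals_.items():
            expected += crit[c] * lw.weights
        rep = synthesize(_model_from_truth(crit, locals_))
        assert np.allclose(rep.global_weights.weights, expected, atol=1e-9)
        assert rep.global_weights.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_forces_third_weight(self):
        # two published global weights pin the third by sum-to-one
        assert 1.0 - 0.5407 - 0.2015 == pytest.approx(0.2578, abs=1e-12)

    def test_monotone_in_local_weight(self):
        crit = _vector(0.4, 0.3, 0.2, 0.1, items=self.CRITERIA)
        base_local = _vector(0.34, 0.33, 0.33, items=self.ALTS)
        raised = _vector(0.60, 0.20, 0.20, items=self.ALTS)
        m1 = _model_from_truth(crit, {c: base_local for c in self.CRITERIA})
        m2 = _model_from_truth(
            crit, {**{c: base_local for c in self.CRITERIA}, "vitamins": raised})
        g1 = synthesize(m1).global_weights["fish"]
        g2 = synthesize(m2).global_weights["fish"]
        assert g2 > g1

    def test_inconsistent_matrix_refused_without_override(self):
        crit = _vector(1, 1, 1, items=("c1", "c2", "c3"))
        local = _vector(0.5, 0.3, 0.2, items=self.ALTS)
        bad = PairwiseMatrix(("c1", "c2", "c3"),
                             np.array([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]]))
        model = _model_from_truth(crit, {c: local for c in crit.items})
        model.experts[0].criteria_matrix = bad
        with pytest.raises(InconsistentMatrixError):
            synthesize(model)
        rep = synthesize(model, override_consistency=True)
        assert rep.global_weights.weights.sum() == pytest.approx(1.0)

    def test_model_yaml_round_trip(self, tmp_path):
        crit = _vector(0.4, 0.3, 0.2, 0.1, items=self.CRITERIA)
        local = _vector(0.5, 0.3, 0.2, items=self.ALTS)
        model = _model_from_truth(crit, {c: local for c in self.CRITERIA})
        path = tmp_path / "model.yaml"
        dump_model(model, path)
        again = load_model(path)
        rep1, rep2 = synthesize(model), synthesize(again)
        assert np.allclose(rep1.global_weights.weights, rep2.global_weights.weights)
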
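import numpy as np
import pandas as pd
import pytest

from esbalance.geodetector import (
    BIVARIATE_ENHANCE,
    INDEPENDENT,
    NONLINEAR_ENHANCE,
    NONLINEAR_WEAKEN,
    SINGLE_WEAKEN,
    FactorPartition,
    classify_interaction,
    discretize,
    factor_q,
    interaction_matrix,
    interaction_q,
    overlay,
)


def brute_force_q(y, labels):
    """Independent oracle: stratified variance decomposition by direct
    enumeration with population variances."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    within = 0.0
    for h in set(labels.tolist()):
        sel = y[labels == h]
        m = sel.sum() / sel.size
        within += ((sel - m) ** 2).sum()
    m = y.mean()
    total = ((y - m) ** 2).sum()
    return 1.0 - within / total


class TestDiscretize:
    def test_quantile_halves(self):
        part = discretize(np.arange(1, 11, dtype=float), "quantile", k=2)
        sizes = pd.Series(part.labels).value_counts()
        assert sorted(sizes) == [5, 5]

    def test_constant_vector_single_stratum(self):
        with pytest.warns(UserWarning):
            part = discretize(np.full(10, 2.0), k=3)
        assert part.n_strata == 1

    def test_equal_interval_breaks(self):
        part = discretize(np.linspace(0, 1, 20), "equal_interval", k=4)
        assert np.allclose(part.breaks, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_duplicate_quantile_edges_merge(self):
        values = np.array([0.0] * 8 + [1.0, 2.0])
        with pytest.warns(UserWarning):
            part = discretize(values, "quantile", k=5)
        assert part.n_strata < 5

    def test_natural_breaks_separates_clusters(self):
        x = np.concatenate([np.zeros(10), np.ones(10) * 5, np.ones(10) * 20])
        part = discretize(x, "natural_breaks", k=3)
        assert part.n_strata == 3
        assert factor_q(x + np.arange(30) * 1e-6, part).q > 0.99


class TestFactorQ:
    def test_perfect_stratification(self):
        y = np.array([1.0, 1.0, 2.0, 2.0])
        part = FactorPartition("f", np.array(["A", "A", "B", "B"]))
        assert factor_q(y, part).q == pytest.approx(1.0)

    def test_uninformative_stratification(self):
        y = np.array([1.0, 2.0, 1.0, 2.0])
        part = FactorPartition("f", np.array(["A", "A", "B", "B"]))
        assert factor_q(y, part).q == pytest.approx(0.0)

    def test_worked_example(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        part = FactorPartition("f", np.array(["A", "A", "B", "B"]))
        res = factor_q(y, part)
        assert res.q == pytest.approx(0.8)  # 1 - (4 * 0.25) / (4 * 1.25)
        assert res.stratum_sizes == {"A": 2, "B": 2}

    def test_constant_outcome_rejected(self):
        part = FactorPartition("f", np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            factor_q(np.ones(4), part)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = rng.integers(4, 31)
            y = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 6), size=n)
            part = FactorPartition("f", labels)
            q = factor_q(y, part).q
            assert q == pytest.approx(brute_force_q(y, labels), abs=1e-12)
            assert 0.0 <= q <= 1.0 + 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(23)
        y = rng.normal(size=40)
        part = discretize(rng.normal(size=40), k=4)
        q0 = factor_q(y, part).q
        q1 = factor_q(3.5 * y - 7.0, part).q
        assert q0 == pytest.approx(q1, abs=1e-12)

    def test_refinement_never_decreases_q(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            y = rng.normal(size=n)
            a = FactorPartition("a", rng.integers(0, 3, size=n))
            b = FactorPartition("b", rng.integers(0, 3, size=n))
            joint = overlay(a, b)
            q_joint = factor_q(y, joint).q
            assert q_joint >= factor_q(y, a).q - 1e-12
            assert q_joint >= factor_q(y, b).q - 1e-12

    def test_significance_decreases_with_separation(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 20)
        part = FactorPartition("f", labels)
        weak = rng.normal(size=40)
        strong = weak + 3.0 * labels
        assert factor_q(strong, part).p < factor_q(weak, part).p


class TestInteraction:
    @pytest.mark.parametrize(
        "q1,q2,q12,expected",
        [
            (0.3, 0.4, 0.8, NONLINEAR_ENHANCE),   # 0.8 > 0.7
            (0.3, 0.4, 0.65, BIVARIATE_ENHANCE),  # max < 0.65 < 0.7
            (0.3, 0.4, 0.7, INDEPENDENT),
            (0.3, 0.4, 0.35, SINGLE_WEAKEN),
            (0.3, 0.4, 0.2, NONLINEAR_WEAKEN),
        ],
    )
    def test_classification_rules(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected

    def test_overlay_idempotence(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        labels = rng.integers(0, 3, size=30)
        a = FactorPartition("a", labels)
        b = FactorPartition("b", labels.copy())
        res, cls = interaction_q(y, a, b)
        assert res.q == pytest.approx(factor_q(y, a).q, abs=1e-12)
        assert cls == SINGLE_WEAKEN  # q12 == max(q1, q2) boundary

    def test_xor_structure_is_nonlinear_enhancement(self):
        # y is determined by the overlay but by neither factor alone
        y = np.array([0.0, 1.0, 1.0, 0.0] * 2)
        a = FactorPartition("a", np.array(["a", "a", "b", "b"] * 2))
        b = FactorPartition("b", np.array(["c", "d", "c", "d"] * 2))
        assert factor_q(y, a).q == pytest.approx(0.0)
        assert factor_q(y, b).q == pytest.approx(0.0)
        res, cls = interaction_q(y, a, b)
        assert res.q == pytest.approx(1.0)
        assert cls == NONLINEAR_ENHANCE

    def test_singleton_overlay_warns(self):
        y = np.arange(4, dtype=float)
        a = FactorPartition("a", np.array([0, 0, 1, 1]))
        b = FactorPartition("b", np.array([0, 1, 0, 1]))
        with pytest.warns(UserWarning, match="singleton"):
            interaction_q(y, a, b)


class TestInteractionMatrix:
    def _partitions(self, n_factors, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        parts = [FactorPartition(f"f{i}", rng.integers(0, 4, size=n))
                 for i in range(n_factors)]
        return y, parts

    def test_two_factors_one_pair(self):
        y, parts = self._partitions(2)
        mat = interaction_matrix(y, parts)
        off = mat.attrs["classes"]
        assert len(off) == 1

    def test_ten_factors_forty_five_pairs(self):
        y, parts = self._partitions(10)
        mat = interaction_matrix(y, parts)
        assert len(mat.attrs["classes"]) == 45
        # lower triangular: upper entries stay NaN
        assert np.isnan(mat.to_numpy()[np.triu_indices(10, 1)]).all()

    def test_diagonal_is_single_factor_q(self):
        y, parts = self._partitions(3, seed=2)
        mat = interaction_matrix(y, parts)
        for p in parts:
            assert mat.loc[p.name, p.name] == pytest.approx(
                factor_q(y, p).q, abs=1e-12)

    def test_invariant_to_factor_order(self):
        y, parts = self._partitions(4, seed=3)
        mat = interaction_matrix(y, parts)
        rev = interaction_matrix(y, parts[::-1])
        for a in mat.index:
            for b in mat.index:
                v1 = mat.loc[a, b]
                v2 = rev.loc[b, a] if not np.isnan(rev.loc[b, a]) else rev.loc[a, b]
                if not np.isnan(v1):
                    assert v1 == pytest.approx(v2, abs=1e-12)

    def test_single_factor_rejected(self):
        y, parts = self._partitions(1)
        with pytest.raises(ValueError):
            interaction_matrix(y, parts)
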
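import numpy as np
import pytest

from mvbench import MethodSpec, ValidationError, impute, simulate_mask
from mvbench.impute import (
    METHOD_NAMES,
    knn_impute,
    llsi_impute,
    row_mean_impute,
    select_k_opt,
    sknn_impute,
)

from conftest import make_matrix, mask_entries

IMPLEMENTED = sorted(METHOD_NAMES - {"bpca"})


class TestDispatch:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            MethodSpec("magic")

    def test_bpca_is_a_plugin_hook(self, random_masked):
        with pytest.raises(NotImplementedError):
            impute(MethodSpec("bpca"), random_masked)

    @pytest.mark.parametrize("name", IMPLEMENTED)
    def test_empty_mask_is_identity(self, random_complete, name):
        data = mask_entries(random_complete, np.empty((0, 2)))
        res = impute(MethodSpec(name), data)
        assert res.completed == random_complete
        assert len(res.estimates) == 0

    @pytest.mark.parametrize("name", IMPLEMENTED)
    def test_off_mask_entries_untouched(self, random_masked, name):
        res = impute(MethodSpec(name), random_masked)
        ref = random_masked.reference.values.copy()
        got = res.completed.values.copy()
        for i, j in random_masked.mask:
            ref[i, j] = got[i, j] = 0.0
        assert np.array_equal(ref, got)  # bit-for-bit off the mask
        assert np.isfinite(res.estimates).all()

    @pytest.mark.parametrize("name", IMPLEMENTED)
    def test_deterministic_given_data(self, random_masked, name):
        a = impute(MethodSpec(name), random_masked)
        b = impute(MethodSpec(name), random_masked)
        assert np.array_equal(a.estimates, b.estimates)


class TestRowMean:
    @pytest.mark.parametrize(
        "row, expected",
        [([1.0, 2.0, 3.0], 2.0), ([0.1, -0.3, 0.8], 0.2), ([5.0, 5.0, 5.0], 5.0)],
    )
    def test_observed_mean(self, row, expected):
        values = np.vstack([row + [0.0], np.zeros(4)])
        m = make_matrix(values)
        data = mask_entries(m, [[0, 3]])
        res = row_mean_impute(data)
        assert res.estimates[0] == pytest.approx(expected, abs=1e-12)

    def test_fully_masked_gene_uses_condition_mean_fallback(self):
        m = make_matrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        data = mask_entries(m, [[0, 0], [0, 1]])
        res = row_mean_impute(data)
        assert res.estimates[0] == pytest.approx(4.0)  # mean of 3, 5
        assert res.estimates[1] == pytest.approx(5.0)  # mean of 4, 6
        assert res.params["fallbacks"]["condition_mean"] == 2
        assert res.params["n_fallback"] == 2


class TestKnn:
    def test_exact_duplicate_neighbour(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, (6, 4))
        values[1] = values[0]  # exact duplicate of the target gene
        m = make_matrix(values)
        data = mask_entries(m, [[0, 2]])
        res = knn_impute(data, k=1)
        assert res.estimates[0] == pytest.approx(values[1, 2], abs=1e-9)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, (10, 4))
        m = make_matrix(values)
        pos = [[0, 1], [4, 3], [7, 0]]
        data = mask_entries(m, pos)
        res = knn_impute(data, k=3)
        x = data.masked_values()
        n = 4
        for idx, (g, j) in enumerate(pos):
            cands = []
            for h in range(10):
                if h == g or np.isnan(x[h, j]):
                    continue
                both = np.isfinite(x[g]) & np.isfinite(x[h])
                if both.sum() == 0:
                    continue
                d = np.sqrt(n / both.sum() * np.sum((x[g, both] - x[h, both]) ** 2))
                cands.append((d, h))
            cands.sort()
            top = cands[:3]
            w = np.array([1.0 / (d + 1e-9) for d, _ in top])
            expect = np.dot(w, [x[h, j] for _, h in top]) / w.sum()
            assert res.estimates[idx] == pytest.approx(expect, abs=1e-10)

    def test_constant_candidates_give_constant(self):
        values = np.vstack([np.random.default_rng(2).normal(0, 1, 4),
                            np.tile([3.0, -1.0, 2.0, 7.0], (5, 1))])
        m = make_matrix(values)
        data = mask_entries(m, [[0, 3]])
        for k in (1, 3, 5):
            assert knn_impute(data, k=k).estimates[0] == pytest.approx(7.0, abs=1e-6)

    def test_k_must_be_positive(self, random_masked):
        with pytest.raises(ValidationError):
            knn_impute(random_masked, k=0)


class TestSelectKOpt:
    def make_duplicated_pairs(self):
        # every gene has two exact twins: the single nearest neighbour is
        # an exact estimator, larger k admits noise-gene contamination
        rng = np.random.default_rng(3)
        base = rng.normal(0, 2, (10, 8))
        values = np.vstack([base, base, base])
        return make_matrix(values)

    def test_exact_twins_select_k1(self):
        m = self.make_duplicated_pairs()
        data = simulate_mask(m, 5.0, seed=0)
        assert select_k_opt(data, [1, 5, 15], seed=1) == 1

    def test_single_candidate(self, random_masked):
        assert select_k_opt(random_masked, [15], cv_fraction=0.3, seed=0) == 15

    def test_seed_determinism(self):
        m = self.make_duplicated_pairs()
        data = simulate_mask(m, 5.0, seed=0)
        assert select_k_opt(data, [1, 5], seed=2) == select_k_opt(
            data, [1, 5], seed=2
        )

    def test_too_few_cv_entries(self, random_masked):
        with pytest.raises(ValidationError):
            select_k_opt(random_masked, [1], cv_fraction=0.01)


class TestSknn:
    def test_single_missing_gene_equals_knn(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(0, 1, (8, 5)))
        data = mask_entries(m, [[2, 3]])
        assert sknn_impute(data, k=3).estimates[0] == pytest.approx(
            knn_impute(data, k=3).estimates[0], abs=1e-12
        )

    def test_sequential_donation_oracle(self):
        # the second incomplete gene must be able to borrow from the first
        # once it has been imputed; verified against a step-by-step oracle
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, (6, 4))
        m = make_matrix(values)
        data = mask_entries(m, [[0, 1], [1, 2]])
        res = sknn_impute(data, k=2)

        x = data.masked_values()
        n = 4
        pool = [2, 3, 4, 5]
        for g in (0, 1):  # ascending missing count, ties by index
            obs = np.isfinite(x[g])
            dists = sorted(
                (np.sqrt(n / obs.sum() * np.sum((x[g, obs] - x[h, obs]) ** 2)), h)
                for h in pool
            )[:2]
            w = np.array([1.0 / (d + 1e-9) for d, _ in dists])
            for j in np.flatnonzero(~obs):
                x[g, j] = np.dot(w, [x[h, j] for _, h in dists]) / w.sum()
            pool.append(g)
        assert res.estimates == pytest.approx(
            [x[0, 1], x[1, 2]], abs=1e-10
        )

    def test_no_complete_gene_seeds_with_row_mean(self):
        values = np.array([
            [1.0, np.nan, 3.0],
            [np.nan, 2.0, 4.0],
        ])
        ref = make_matrix(np.nan_to_num(values, nan=0.0))
        data = mask_entries(ref, np.argwhere(np.isnan(values)))
        # overwrite the reference truths so masked_values() == values
        data.truth[:] = 0.0
        res = sknn_impute(data, k=1)
        assert res.params.get("seeded_by_row_mean") is True
        assert np.isfinite(res.estimates).all()


class TestLlsi:
    def test_exact_linear_combination_recovery(self):
        rng = np.random.default_rng(6)
        h1, h2 = rng.normal(0, 1, (2, 6))
        g = 0.5 * h1 + 2.0 * h2
        noise = rng.normal(0, 1, (4, 6)) + 10  # far-away decoys
        m = make_matrix(np.vstack([g, h1, h2, noise]))
        data = mask_entries(m, [[0, 4], [0, 5]])
        res = llsi_impute(data, k=2)
        assert res.estimates == pytest.approx(g[[4, 5]], abs=1e-8)

    def test_single_neighbour_rank_one(self):
        rng = np.random.default_rng(7)
        h = rng.normal(0, 1, 5)
        decoys = rng.normal(0, 1, (3, 5)) + 20
        m = make_matrix(np.vstack([3.0 * h, h, decoys]))
        data = mask_entries(m, [[0, 2]])
        res = llsi_impute(data, k=1)
        assert res.estimates[0] == pytest.approx(3.0 * h[2], abs=1e-8)

    def test_k_capped_at_available_neighbours(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(0, 1, (4, 5)))
        data = mask_entries(m, [[0, 1]])
        res = llsi_impute(data, k=50)  # only 3 qualified neighbours exist
        assert np.isfinite(res.estimates[0])
        assert res.params["n_fallback"] == 0

    def test_auto_k_runs(self, random_masked):
        res = llsi_impute(random_masked, k="auto", cv_fraction=0.3, seed=0)
        assert res.params["k"] in (5, 10, 15, 20)
        assert res.params["k_auto"] is True
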
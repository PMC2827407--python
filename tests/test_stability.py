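import numpy as np
import pytest
from sklearn.metrics import rand_score

from mvbench import (
    Partition,
    ValidationError,
    car,
    cpp,
    cpp_f,
    distance_matrix,
    hierarchical_cluster,
    kmeans_cluster,
    masked_euclidean_distance,
    within_cluster_dispersion,
)

from conftest import make_matrix


def partition(labels, source="GC"):
    labels = np.asarray(labels)
    return Partition(labels, K=int(labels.max()) + 1, source=source)


class TestMaskedDistance:
    def test_identical_profiles(self):
        v = np.array([1.0, -2.0, 0.5])
        assert masked_euclidean_distance(v, v) == 0.0

    def test_plain_euclidean_when_complete(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([1.0, 2.0, 3.0, 0.0])
        assert masked_euclidean_distance(v, w) == pytest.approx(4.0)

    def test_normalization_arithmetic(self):
        v = np.array([1.0, 2.0, np.nan, 4.0])
        w = np.array([1.0, 2.0, 3.0, 0.0])
        assert masked_euclidean_distance(v, w) == pytest.approx(
            np.sqrt(4.0 / 3.0 * 16.0)
        )

    def test_no_shared_coordinate_is_nan(self):
        v = np.array([1.0, np.nan])
        w = np.array([np.nan, 2.0])
        assert np.isnan(masked_euclidean_distance(v, w))

    def test_symmetry_on_random_masked_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(0, 1, 6)
            w = rng.normal(0, 1, 6)
            v[rng.random(6) < 0.3] = np.nan
            w[rng.random(6) < 0.3] = np.nan
            if not (np.isfinite(v) & np.isfinite(w)).any():
                continue
            assert masked_euclidean_distance(v, w) == pytest.approx(
                masked_euclidean_distance(w, v), abs=1e-12
            )


class TestDistanceMatrix:
    def test_complete_matrix_matches_brute_force(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(0, 1, (4, 3)))
        d = distance_matrix(m).values
        for i in range(4):
            for j in range(4):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(m.values[i] - m.values[j]), abs=1e-10
                )

    def test_masked_matrix_matches_definition(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, (8, 5))
        values[rng.random((8, 5)) < 0.2] = np.nan
        m = make_matrix(values)
        d = distance_matrix(m).values
        for i in range(8):
            for j in range(i):
                expect = masked_euclidean_distance(values[i], values[j])
                if np.isnan(expect):
                    continue
                assert d[i, j] == pytest.approx(expect, abs=1e-10)

    def test_duplicate_genes_zero_distance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (3, 4))
        m = make_matrix(np.vstack([values, values[0]]))
        assert distance_matrix(m).values[0, 3] == pytest.approx(0.0, abs=1e-9)

    def test_undefined_pair_substituted_with_max(self):
        values = np.array([
            [1.0, 2.0, np.nan, np.nan],
            [np.nan, np.nan, 3.0, 4.0],
            [0.0, 0.0, 0.0, 0.0],
            [5.0, 5.0, 5.0, 5.0],
        ])
        dm = distance_matrix(make_matrix(values))
        assert dm.n_undefined == 1
        finite_max = dm.values[2, 3]  # largest defined distance
        assert dm.values[0, 1] == pytest.approx(max(finite_max, dm.values[0, 1]))
        assert dm.values[0, 1] >= dm.values[0, 2]


class TestHierarchical:
    def test_closest_pair_merges_first(self):
        # three profiles on a line at positions 0, 1, 3 -> distances 1, 2, 3
        m = make_matrix(np.array([[0.0, 0], [1.0, 0], [3.0, 0]]))
        part = hierarchical_cluster(distance_matrix(m), "single", K=2)
        assert part.labels[0] == part.labels[1]
        assert part.labels[2] != part.labels[0]

    def test_k_equals_g_singletons(self, random_complete):
        part = hierarchical_cluster(
            distance_matrix(random_complete), "average", K=random_complete.n_genes
        )
        assert part.K == random_complete.n_genes
        assert len(set(part.labels.tolist())) == random_complete.n_genes

    def test_k_one_single_cluster(self, random_complete):
        part = hierarchical_cluster(distance_matrix(random_complete), "ward", K=1)
        assert part.K == 1
        assert (part.labels == 0).all()

    @pytest.mark.parametrize(
        "linkage",
        ["single", "complete", "average", "mcquitty", "median", "centroid", "ward"],
    )
    def test_all_linkages_produce_valid_partitions(self, random_complete, linkage):
        part = hierarchical_cluster(distance_matrix(random_complete), linkage, K=3)
        assert part.n_genes == random_complete.n_genes
        assert 1 <= part.K <= 3

    def test_unknown_linkage(self, random_complete):
        with pytest.raises(ValidationError):
            hierarchical_cluster(distance_matrix(random_complete), "best", K=2)


class TestKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        blob_a = rng.normal(0, 0.05, (10, 3))
        blob_b = rng.normal(5, 0.05, (10, 3))
        m = make_matrix(np.vstack([blob_a, blob_b]))
        part = kmeans_cluster(m, K=2, seed=0)
        truth = partition([0] * 10 + [1] * 10)
        assert car(truth, part) == 100.0

    def test_seed_determinism(self, random_complete):
        a = kmeans_cluster(random_complete, K=3, seed=5)
        b = kmeans_cluster(random_complete, K=3, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_k_one(self, random_complete):
        part = kmeans_cluster(random_complete, K=1, seed=0)
        assert part.K == 1


class TestCpp:
    def test_identical_partitions(self):
        p = partition([0, 0, 1, 1, 2])
        assert cpp(p, p) == 100.0

    def test_worked_overlap_example(self):
        rc = partition([0, 0, 0, 1, 1])  # {1,2,3}, {4,5}
        gc = partition([0, 0, 1, 0, 1])  # {1,2,4}, {3,5}
        assert cpp(rc, gc) == pytest.approx(60.0)

    def test_single_generated_cluster(self):
        rc = partition([0, 0, 1, 1, 2])
        gc = partition([0, 0, 0, 0, 0])
        assert cpp(rc, gc) == 100.0

    def test_mismatched_universe(self):
        with pytest.raises(ValidationError):
            cpp(partition([0, 1]), partition([0, 1, 1]))


class TestCppF:
    @pytest.fixture
    def fixture(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(0, 1, (12, 4)))
        rc = partition(rng.integers(0, 3, 12))
        gc = partition(rng.integers(0, 4, 12))
        return m, rc, gc

    def test_saturation(self, fixture):
        m, rc, gc = fixture
        assert cpp_f(rc, gc, m, f=gc.K) == 100.0

    def test_f_one_reduces_to_cpp(self, fixture):
        m, rc, gc = fixture
        assert cpp_f(rc, gc, m, f=1) == cpp(rc, gc)

    def test_monotone_in_f(self, fixture):
        m, rc, gc = fixture
        values = [cpp_f(rc, gc, m, f=f) for f in range(1, gc.K + 1)]
        assert values[0] == cpp(rc, gc)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_invalid_f(self, fixture):
        m, rc, gc = fixture
        with pytest.raises(ValidationError):
            cpp_f(rc, gc, m, f=0)


class TestCar:
    def test_identical_partitions(self):
        p = partition([0, 1, 0, 2, 1])
        assert car(p, p) == 100.0

    def test_worked_pair_example(self):
        rc = partition([0, 0, 1, 1])  # {1,2}, {3,4}
        gc = partition([0, 1, 0, 1])  # {1,3}, {2,4}
        assert car(rc, gc) == pytest.approx(100 * 2 / 6)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        rc = partition(rng.integers(0, 4, 30))
        labels = rng.integers(0, 4, 30)
        gc = partition(labels)
        remap = np.array([2, 3, 0, 1])
        gc2 = partition(remap[labels])
        assert car(rc, gc) == car(rc, gc2)

    def test_contingency_matches_pair_enumeration_and_sklearn(self):
        rng = np.random.default_rng(7)
        g = 200
        rc = partition(rng.integers(0, 8, g))
        gc = partition(rng.integers(0, 6, g))
        agree = 0
        for i in range(g):
            for j in range(i):
                same_rc = rc.labels[i] == rc.labels[j]
                same_gc = gc.labels[i] == gc.labels[j]
                agree += same_rc == same_gc
        brute = 100.0 * agree / (g * (g - 1) / 2)
        assert car(rc, gc) == pytest.approx(brute, abs=1e-10)
        assert car(rc, gc) == pytest.approx(
            100.0 * rand_score(rc.labels, gc.labels), abs=1e-10
        )


class TestDispersion:
    def test_singletons_are_zero(self, random_complete):
        g = random_complete.n_genes
        p = Partition(np.arange(g), K=g)
        assert within_cluster_dispersion(p, random_complete) == 0.0

    def test_two_point_cluster_geometry(self):
        m = make_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))  # distance 5
        p = Partition(np.zeros(2, dtype=int), K=1)
        assert within_cluster_dispersion(p, m) == pytest.approx(25.0 / 4.0)

    def test_decreases_with_k_on_structured_data(self):
        rng = np.random.default_rng(8)
        centers = rng.normal(0, 4, (6, 3))
        m = make_matrix(
            centers[np.repeat(np.arange(6), 10)] + rng.normal(0, 0.2, (60, 3))
        )
        disp = [
            within_cluster_dispersion(kmeans_cluster(m, K=k, seed=0), m)
            for k in (1, 2, 6, 12)
        ]
        assert all(b < a for a, b in zip(disp, disp[1:]))
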
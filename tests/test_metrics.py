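import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog

from chartmetrics import (
    MetricSpec,
    cross_support_emd,
    emd,
    emd_with_flow,
    euclidean_distance,
    pairwise_distance_matrix,
    pearson_similarity,
    quadratic_chi,
    rank_by_distance,
    similarity_matrix,
)
from chartmetrics.chart_space import GroundDistanceMatrix, LabTable, SimilarityMatrix
from chartmetrics.wcs_io import Chart

from conftest import random_chart_values


def line_metric(n):
    idx = np.arange(n)
    return GroundDistanceMatrix(np.abs(idx[:, None] - idx[None, :]).astype(float))


def emd_cdf_oracle(p, q):
    """Closed form for 1-D histograms under the |i-j| line metric."""
    p = p / p.sum()
    q = q / q.sum()
    return float(np.abs(np.cumsum(p - q)).sum())


def emd_lp_oracle(p, q, C):
    """Independent generic transportation LP: dense, all bins, equality
    constraints on both marginals (unit-mass form)."""
    p = p / p.sum()
    q = q / q.sum()
    n, m = len(p), len(q)
    A_eq, b_eq = [], []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1
        A_eq.append(row.ravel())
        b_eq.append(p[i])
    for j in range(m):
        row = np.zeros((n, m))
        row[:, j] = 1
        A_eq.append(row.ravel())
        b_eq.append(q[j])
    res = linprog(C.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def random_positive_histogram(rng, n):
    v = rng.uniform(0.0, 1.0, size=n)
    v[rng.integers(n)] += 0.5  # guarantee mass
    return v


class TestBaselines:
    def test_euclidean_examples(self):
        p = np.zeros(5)
        q = np.zeros(5)
        p[1] = q[3] = 1.0
        assert euclidean_distance(p, p) == 0.0
        assert euclidean_distance(p, q) == pytest.approx(np.sqrt(2))

    def test_euclidean_matches_brute_force(self):
        rng = np.random.default_rng(0)
        p, q = rng.uniform(size=20), rng.uniform(size=20)
        brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        assert euclidean_distance(p, q) == pytest.approx(brute, abs=1e-12)

    def test_pearson_extremes_and_brute_force(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        assert pearson_similarity(p, p) == pytest.approx(1.0)
        assert pearson_similarity(p, -p + 3.0) == pytest.approx(-1.0)
        q = rng.uniform(size=30)
        brute = (np.mean((p - p.mean()) * (q - q.mean())) / (p.std() * q.std()))
        assert pearson_similarity(p, q) == pytest.approx(brute, abs=1e-12)

    def test_pearson_rejects_constant_chart(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_similarity(np.ones(5), np.arange(5.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.ones(3), np.ones(4))


class TestEmd:
    def test_identical_charts_zero(self, ground):
        rng = np.random.default_rng(2)
        p = random_chart_values(rng, ground.n)
        assert emd(p, p, ground) == pytest.approx(0.0, abs=1e-9)

    def test_point_masses_give_ground_distance(self, ground):
        p = np.zeros(ground.n)
        q = np.zeros(ground.n)
        p[12], q[200] = 1.0, 1.0
        assert emd(p, q, ground) == pytest.approx(ground.D[12, 200], abs=1e-9)

    def test_cdf_closed_form_on_line_metric(self):
        rng = np.random.default_rng(3)
        D = line_metric(8)
        for _ in range(200):
            p = random_positive_histogram(rng, 8)
            q = random_positive_histogram(rng, 8)
            assert emd(p, q, D) == pytest.approx(emd_cdf_oracle(p, q), abs=1e-7)

    def test_against_independent_lp_formulation(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 50, size=(6, 3))
        lab = LabTable(np.arange(1, 7), coords)
        from chartmetrics import ground_distance_matrix

        D = ground_distance_matrix(lab)
        for _ in range(200):
            p = random_positive_histogram(rng, 6)
            q = random_positive_histogram(rng, 6)
            assert emd(p, q, D) == pytest.approx(
                emd_lp_oracle(p, q, D.D), abs=1e-7
            )

    def test_flow_plan_marginals(self, ground):
        rng = np.random.default_rng(5)
        p = random_chart_values(rng, ground.n)
        q = random_chart_values(rng, ground.n)
        value, plan = emd_with_flow(p, q, ground)
        assert plan.total_flow == pytest.approx(1.0, abs=1e-9)
        assert np.all(plan.f.sum(axis=1) <= plan.source_mass + 1e-9)
        assert np.all(plan.f.sum(axis=0) <= plan.target_mass + 1e-9)
        work = float((plan.f * ground.D).sum())
        assert value == pytest.approx(work / plan.total_flow, abs=1e-9)

    def test_metric_axioms_on_random_triples(self, ground):
        rng = np.random.default_rng(6)
        for _ in range(100):
            charts = [random_chart_values(rng, ground.n) for _ in range(3)]
            d01 = emd(charts[0], charts[1], ground)
            d10 = emd(charts[1], charts[0], ground)
            d12 = emd(charts[1], charts[2], ground)
            d02 = emd(charts[0], charts[2], ground)
            assert d01 == pytest.approx(d10, abs=1e-7)
            assert d02 <= d01 + d12 + 1e-6

    def test_bounded_by_chart_diameter(self, ground):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_chart_values(rng, ground.n)
            q = random_chart_values(rng, ground.n)
            assert emd(p, q, ground) <= ground.D.max() + 1e-9

    def test_zero_mass_rejected(self, ground):
        with pytest.raises(ValueError):
            emd(np.zeros(ground.n), np.ones(ground.n), ground)


class TestPermutationBehavior:
    """The central pitfall: entrywise metrics cannot see chip geometry."""

    @staticmethod
    def random_pair(rng, n):
        return random_chart_values(rng, n), random_chart_values(rng, n)

    def test_baselines_invariant_under_any_permutation(self, ground):
        rng = np.random.default_rng(8)
        p, q = self.random_pair(rng, ground.n)
        pi = rng.permutation(ground.n)
        assert abs(
            euclidean_distance(p, q) - euclidean_distance(p[pi], q[pi])
        ) < 1e-12
        assert abs(
            pearson_similarity(p, q) - pearson_similarity(p[pi], q[pi])
        ) < 1e-12

    def test_emd_changes_under_non_isometric_permutation(self, ground):
        rng = np.random.default_rng(9)
        p, q = self.random_pair(rng, ground.n)
        pi = rng.permutation(ground.n)
        before = emd(p, q, ground)
        after = emd(p[np.argsort(pi)], q[np.argsort(pi)], ground)
        assert abs(before - after) > 1e-3

    def test_emd_invariant_under_hue_rotation_isometry(self, grid, ground):
        # rotating every chromatic row by one hue column is a dE isometry
        perm = np.arange(330)
        for chip in grid.chips:
            if not chip.is_achromatic:
                new_col = chip.column % 40 + 1
                target = 10 + (ord(chip.row) - ord("B")) * 40 + (new_col - 1)
                perm[chip.chip_id - 1] = target
        Dp = ground.D[np.ix_(perm, perm)]
        assert np.allclose(Dp, ground.D, atol=1e-9)  # isometry indeed
        rng = np.random.default_rng(10)
        p, q = self.random_pair(rng, 330)
        pp, qp = np.zeros(330), np.zeros(330)
        pp[perm], qp[perm] = p, q
        assert emd(p, q, ground) == pytest.approx(emd(pp, qp, ground), abs=1e-7)


class TestQuadraticChi:
    def test_identity_and_symmetry(self, kernel):
        rng = np.random.default_rng(11)
        p = random_chart_values(rng, kernel.n)
        q = random_chart_values(rng, kernel.n)
        assert quadratic_chi(p, p, kernel) == pytest.approx(0.0, abs=1e-9)
        assert quadratic_chi(p, q, kernel) == pytest.approx(
            quadratic_chi(q, p, kernel), abs=1e-12
        )

    def test_identity_similarity_m_zero_reduces_to_euclidean(self):
        rng = np.random.default_rng(12)
        A = SimilarityMatrix(K=np.eye(20), sigma=1.0)
        for _ in range(20):
            p = random_positive_histogram(rng, 20)
            q = random_positive_histogram(rng, 20)
            assert quadratic_chi(p, q, A, m=0.0, normalize=False) == pytest.approx(
                euclidean_distance(p, q), abs=1e-9
            )

    def test_stronger_similarity_shrinks_distance(self, ground):
        rng = np.random.default_rng(13)
        p = random_chart_values(rng, ground.n)
        q = random_chart_values(rng, ground.n)
        tight = similarity_matrix(ground, sigma=10.0)
        loose = similarity_matrix(ground, sigma=200.0)
        assert quadratic_chi(p, q, loose) < quadratic_chi(p, q, tight)

    def test_invalid_exponent(self, kernel):
        rng = np.random.default_rng(14)
        p = random_chart_values(rng, kernel.n)
        with pytest.raises(ValueError):
            quadratic_chi(p, p, kernel, m=1.0)


class TestCrossSupportEmd:
    def test_same_grid_reduces_to_emd(self, ground):
        rng = np.random.default_rng(15)
        p = random_chart_values(rng, ground.n)
        q = random_chart_values(rng, ground.n)
        assert cross_support_emd(p, q, ground.D) == pytest.approx(
            emd(p, q, ground), abs=1e-9
        )

    def test_point_masses_forced_flow(self):
        D12 = np.array([[17.2, 30.0], [5.0, 40.0]])
        assert cross_support_emd([1.0, 0.0], [1.0, 0.0], D12) == pytest.approx(17.2)

    def test_refinement_invariance(self):
        # splitting a chip into two co-located half-mass chips changes nothing
        rng = np.random.default_rng(16)
        coords = rng.uniform(0, 50, size=(5, 3))
        lab1 = LabTable(np.arange(1, 6), coords)
        split = np.vstack([coords, coords[2]])  # duplicate chip 3's position
        lab2 = LabTable(np.arange(1, 7), split)
        from scipy.spatial.distance import cdist

        q = random_positive_histogram(rng, 5)
        p1 = rng.uniform(0.1, 1.0, size=5)
        p2 = np.concatenate([p1, [p1[2] / 2]])
        p2[2] /= 2
        D_a = cdist(lab1.coords, lab1.coords)
        D_b = cdist(lab2.coords, lab1.coords)
        assert cross_support_emd(p2, q, D_b) == pytest.approx(
            cross_support_emd(p1, q, D_a), abs=1e-9
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_support_emd([1.0, 0.0], [1.0], np.zeros((3, 2)))


class TestPairwiseAndRanking:
    def make_charts(self, grid, chips_list):
        charts = []
        for i, chips in enumerate(chips_list):
            v = np.zeros(len(grid))
            v[[c - 1 for c in chips]] = 1.0
            charts.append(Chart(v, "L1", f"t{i}", "language"))
        return charts

    def test_identical_charts_zero_matrix(self, grid, ground):
        charts = self.make_charts(grid, [[20, 21]] * 3)
        dm = pairwise_distance_matrix(charts, MetricSpec("emd", ground=ground))
        assert np.allclose(dm.matrix, 0.0, atol=1e-9)

    def test_entry_matches_direct_call(self, grid, ground):
        charts = self.make_charts(grid, [[20], [150], [300]])
        spec = MetricSpec("emd", ground=ground)
        dm = pairwise_distance_matrix(charts, spec)
        assert dm.matrix[1, 2] == pytest.approx(
            emd(charts[1], charts[2], ground), abs=1e-9
        )
        assert np.allclose(dm.matrix, dm.matrix.T, atol=1e-9)

    def test_reference_ranks_first_with_zero(self, grid, ground):
        charts = self.make_charts(grid, [[20], [150], [300]])
        ranking = rank_by_distance(
            charts[0], charts, MetricSpec("emd", ground=ground)
        )
        assert ranking[0] == ("L1:t0", pytest.approx(0.0, abs=1e-9))
        values = [v for _, v in ranking]
        assert values == sorted(values)

    def test_pearson_ranking_uses_one_minus_r(self, grid):
        charts = self.make_charts(grid, [[20, 21], [20, 21], [300]])
        ranking = rank_by_distance(charts[0], charts[1:], MetricSpec("pearson"))
        assert ranking[0][0] == "L1:t1"
        assert ranking[0][1] == pytest.approx(0.0, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.data())
def test_permutation_invariance_property(data):
    """Entrywise baselines ignore any chip reordering (property form)."""
    n = data.draw(st.integers(4, 16))
    floats = st.floats(0, 5, allow_nan=False, width=32)
    p = np.array(data.draw(st.lists(floats, min_size=n, max_size=n)))
    q = np.array(data.draw(st.lists(floats, min_size=n, max_size=n)))
    pi = np.array(data.draw(st.permutations(range(n))))
    assert euclidean_distance(p, q) == pytest.approx(
        euclidean_distance(p[pi], q[pi]), abs=1e-9
    )
    if p.std() > 1e-6 and q.std() > 1e-6:
        assert pearson_similarity(p, q) == pytest.approx(
            pearson_similarity(p[pi], q[pi]), abs=1e-9
        )


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_emd_symmetry_property(seed):
    """EMD on unit-mass charts is symmetric for arbitrary ground geometry."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 50, size=(7, 3))
    from chartmetrics import ground_distance_matrix

    D = ground_distance_matrix(LabTable(np.arange(1, 8), coords))
    p = random_positive_histogram(rng, 7)
    q = random_positive_histogram(rng, 7)
    assert emd(p, q, D) == pytest.approx(emd(q, p, D), abs=1e-7)
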
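import numpy as np
import pytest

from ldafold.lda import (
    ClassLimitError,
    ClassPartition,
    InsufficientTemplatesError,
    PartitionError,
    RegularizationRequiredError,
    TemplateEnsemble,
    append_hf_term,
    compute_scatter,
    kmeans_energy_partition,
    lda_basis,
    partition_cost,
    project,
    reconstruct,
    scatter_samples,
    search_bounds,
    shrink_scatter,
)
from oracles import dp_kmeans_1d_cost, naive_shrinkage


def make_ensemble(rng, n=30, l=12, energies=None):
    X = rng.normal(0, 2, (n, l))
    if energies is None:
        energies = rng.normal(0, 1, l)
    return TemplateEnsemble(X=X, labels=[f"t{i}" for i in range(l)], energies=energies)


class TestKmeansPartition:
    def test_well_separated_groups(self):
        part = kmeans_energy_partition([-10, -9, -8, 0, 1, 2], k=2)
        assert part.labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert part.class_sizes.tolist() == [3, 3]

    def test_four_classes_on_decoy_like_energies(self, rng):
        energies = rng.normal(-300, 40, 199)
        part = kmeans_energy_partition(energies, k=4)
        assert part.k == 4
        assert np.all(part.class_sizes > 0)
        # labels ordered by increasing class centroid energy
        centroids = [energies[part.labels == c].mean() for c in range(4)]
        assert centroids == sorted(centroids)

    def test_matches_dp_optimum_on_small_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, min(4, n) + 1))
            energies = rng.normal(0, 3, n)
            part = kmeans_energy_partition(energies, k)
            assert partition_cost(energies, part.labels) == pytest.approx(
                dp_kmeans_1d_cost(energies, k), rel=1e-10, abs=1e-10
            )

    def test_duplicate_energies_keep_all_classes_nonempty(self):
        part = kmeans_energy_partition([1.0, 1.0, 1.0, 1.0, 2.0], k=3)
        assert np.all(part.class_sizes > 0)

    def test_errors(self):
        with pytest.raises(InsufficientTemplatesError):
            kmeans_energy_partition([1.0, 2.0], k=3)
        with pytest.raises(ClassLimitError):
            kmeans_energy_partition(np.arange(30.0), k=11)


class TestScatter:
    def test_identical_templates_give_zero_scatter(self):
        X = np.tile(np.arange(30.0)[:, None], (1, 6))
        ens = TemplateEnsemble(X=X, labels=list("abcdef"), energies=np.zeros(6))
        part = ClassPartition(k=2, labels=np.array([0, 0, 0, 1, 1, 1]), class_sizes=np.array([3, 3]))
        sc = compute_scatter(ens, part)
        assert np.allclose(sc.SB, 0) and np.allclose(sc.SW, 0)

    def test_singleton_classes_have_zero_within_scatter(self, rng):
        ens = make_ensemble(rng, l=3)
        part = ClassPartition(k=3, labels=np.array([0, 1, 2]), class_sizes=np.ones(3, int))
        sc = compute_scatter(ens, part)
        assert np.allclose(sc.SW, 0)
        mu = ens.X.mean(axis=1)
        expected = sum(np.outer(ens.X[:, j] - mu, ens.X[:, j] - mu) for j in range(3))
        assert np.allclose(sc.SB, expected, atol=1e-9)

    def test_decomposition_equals_total_scatter(self, rng):
        for _ in range(5):
            ens = make_ensemble(rng, n=24, l=10)
            labels = rng.integers(0, 2, 10)
            labels[:2] = [0, 1]  # both classes non-empty
            sizes = np.bincount(labels, minlength=2)
            part = ClassPartition(k=2, labels=labels, class_sizes=sizes)
            sc = compute_scatter(ens, part)
            mu = ens.X.mean(axis=1)
            centered = ens.X - mu[:, None]
            total = centered @ centered.T
            assert np.allclose(sc.SB + sc.SW, total, rtol=1e-9, atol=1e-9)

    def test_scatter_samples_rebuild_matrices(self, rng):
        ens = make_ensemble(rng, n=15, l=8)
        part = kmeans_energy_partition(ens.energies, 3)
        sc = compute_scatter(ens, part)
        B, W = scatter_samples(ens, part)
        assert np.allclose(B.T @ B, sc.SB, atol=1e-9)
        assert np.allclose(W.T @ W, sc.SW, atol=1e-9)

    def test_partition_mismatch_rejected(self, rng):
        ens = make_ensemble(rng, l=6)
        part = ClassPartition(k=2, labels=np.array([0, 0, 1, 1]), class_sizes=np.array([2, 2]))
        with pytest.raises(PartitionError):
            compute_scatter(ens, part)


class TestShrinkage:
    def test_lambda_one_gives_scaled_identity(self, rng):
        Y = rng.normal(0, 1, (6, 5))
        S = Y.T @ Y
        res = shrink_scatter(S, Y)
        s = np.trace(S) / 5
        forced = (1 - 1.0) * S + 1.0 * s * np.eye(5)
        assert np.allclose(forced, s * np.eye(5))
        if res.lambda_ == 1.0:
            assert np.allclose(res.S_reg, s * np.eye(5), atol=1e-10)

    def test_target_scale_is_mean_diagonal(self):
        S = np.diag([2.0, 4.0])
        res = shrink_scatter(S, np.array([[np.sqrt(2.0), 0.0], [0.0, 2.0]]))
        assert res.s == pytest.approx(3.0)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(10):
            p = int(rng.integers(4, 8))
            N = int(rng.integers(5, 12))
            Y = rng.normal(0, 1, (N, p))
            S = Y.T @ Y
            res = shrink_scatter(S, Y)
            lam, s = naive_shrinkage(S, Y)
            assert res.lambda_ == pytest.approx(lam, abs=1e-12)
            assert res.s == pytest.approx(s, abs=1e-12)

    def test_positive_definite_after_shrinkage(self, rng):
        # singular scatter: more variables than samples
        Y = rng.normal(0, 1, (4, 12))
        S = Y.T @ Y
        res = shrink_scatter(S, Y)
        assert res.lambda_ > 0
        eigvals = np.linalg.eigvalsh(res.S_reg)
        assert eigvals.min() > 0

    def test_zero_denominator_defined_as_zero(self):
        # S = I with all off-diagonals zero -> denominator exactly 0
        Y = np.eye(3)
        res = shrink_scatter(np.eye(3), Y)
        assert res.lambda_ == 0.0


class TestLdaBasis:
    @staticmethod
    def _reduced(rng, means, per, d):
        p = means.shape[1]
        cols, labels = [], []
        for c, m in enumerate(means):
            cols.append(m[:, None] + rng.normal(0, 1, (p, per)))
            labels += [c] * per
        X = np.hstack(cols)
        ens = TemplateEnsemble(X=X, labels=[str(i) for i in range(X.shape[1])],
                               energies=np.zeros(X.shape[1]))
        part = ClassPartition(k=len(means), labels=np.array(labels),
                              class_sizes=np.full(len(means), per))
        sc = compute_scatter(ens, part)
        B, W = scatter_samples(ens, part)
        V = lda_basis(shrink_scatter(sc.SB, B), shrink_scatter(sc.SW, W), d)
        return V, ens, part

    def test_two_spherical_classes_give_axis_discriminant(self, rng):
        # exact inputs: spherical within-class scatter, separation along e1
        # -> symmetry forces the discriminant onto e1
        n = 10
        SB = np.zeros((n, n))
        SB[0, 0] = 64.0
        V = lda_basis(SB, np.eye(n), d=1)
        angle = np.arccos(min(1.0, abs(V[0, 0])))
        assert angle < 1e-3
        # sampled data: the tilt is a finite-sample effect, O(1/sqrt(n))
        means = np.zeros((2, 9))
        means[0, 0], means[1, 0] = -8.0, 8.0
        Vs, *_ = self._reduced(rng, means, per=40, d=1)
        assert np.arccos(min(1.0, abs(Vs[0, 0]))) < 0.15

    def test_spectrum_respects_between_class_rank(self, rng):
        means = rng.normal(0, 6, (3, 12))
        _, ens, part = self._reduced(rng, means, per=10, d=1)
        sc = compute_scatter(ens, part)
        B, W = scatter_samples(ens, part)
        sw = shrink_scatter(sc.SW, W)
        import scipy.linalg
        eigvals = np.sort(scipy.linalg.eigh(sc.SB, sw.S_reg, eigvals_only=True))[::-1]
        # rank(SB) <= k-1 = 2: eigenvalues beyond the 2nd are (numerically) zero
        assert eigvals[2] <= 1e-6 * max(eigvals[0], 1.0)

    def test_returns_requested_dimension_and_unit_columns(self, rng):
        means = rng.normal(0, 5, (4, 15))
        V, *_ = self._reduced(rng, means, per=8, d=4)
        assert V.shape == (15, 4)
        assert np.allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-9)

    def test_singular_within_scatter_requires_regularization(self, rng):
        SB = np.eye(4)
        SW = np.zeros((4, 4))
        with pytest.raises(RegularizationRequiredError):
            lda_basis(SB, SW, 2)


class TestReducedBasis:
    @staticmethod
    def _basis(rng, n=30, d=3, m_best=None):
        Vd = np.linalg.qr(rng.normal(0, 1, (n, d)))[0] @ np.diag(rng.uniform(0.5, 2, d))
        mu = rng.normal(0, 1, n)
        if m_best is None:
            m_best = mu + rng.normal(0, 2, n)
        return append_hf_term(Vd, mu, m_best), mu, m_best

    def test_hf_degenerate_when_best_equals_mean(self, rng):
        Vd = np.linalg.qr(rng.normal(0, 1, (20, 3)))[0]
        mu = rng.normal(0, 1, 20)
        basis = append_hf_term(Vd, mu, mu.copy())
        assert basis.hf_degenerate
        assert np.allclose(basis.V[:, -1], 0)
        assert basis.column_norms[-1] == pytest.approx(0, abs=1e-9)

    def test_hf_degenerate_when_best_in_span(self, rng):
        Vd = np.linalg.qr(rng.normal(0, 1, (20, 3)))[0]
        mu = rng.normal(0, 1, 20)
        basis = append_hf_term(Vd, mu, mu + 2.0 * Vd[:, 0])
        assert basis.hf_degenerate

    def test_hf_column_orthogonal_and_round_trip(self, rng):
        basis, mu, m_best = self._basis(rng)
        G = basis.V.T @ basis.V
        assert np.allclose(G, np.eye(basis.n_columns), atol=1e-8)
        recon = reconstruct(basis, project(basis, m_best))
        assert np.linalg.norm(recon - m_best) <= 1e-6 * np.linalg.norm(m_best)

    def test_projection_of_mean_is_zero(self, rng):
        basis, mu, _ = self._basis(rng)
        assert np.allclose(project(basis, basis.mu), 0, atol=1e-10)

    def test_project_reconstruct_round_trip_and_isometry(self, rng):
        basis, *_ = self._basis(rng)
        for _ in range(5):
            a = rng.normal(0, 3, basis.n_columns)
            assert np.allclose(project(basis, reconstruct(basis, a)), a, atol=1e-9)
            assert np.linalg.norm(reconstruct(basis, a) - basis.mu) == pytest.approx(
                np.linalg.norm(a), rel=1e-9
            )

    def test_projection_is_affine_linear(self, rng):
        basis, *_ = self._basis(rng)
        m1, m2 = rng.normal(0, 2, (2, 30))
        mid = project(basis, 0.5 * (m1 + m2))
        assert np.allclose(mid, 0.5 * (project(basis, m1) + project(basis, m2)), atol=1e-9)

    def test_reconstruction_is_nearest_point_in_subspace(self, rng):
        basis, *_ = self._basis(rng)
        x = rng.normal(0, 2, 30)
        best = np.linalg.norm(x - reconstruct(basis, project(basis, x)))
        for _ in range(100):
            a = rng.normal(0, 3, basis.n_columns)
            assert best <= np.linalg.norm(x - reconstruct(basis, a)) + 1e-12

    def test_serialization_round_trip(self, rng, tmp_path):
        basis, *_ = self._basis(rng)
        path = tmp_path / "basis.json"
        basis.to_json(path)
        from ldafold.lda import ReducedBasis
        back = ReducedBasis.from_json(path)
        assert np.allclose(back.V, basis.V)
        assert np.allclose(back.mu, basis.mu)
        assert back.d == basis.d


class TestSearchBounds:
    @staticmethod
    def _setup(rng, l=8, n=30, d=2):
        Vd = np.linalg.qr(rng.normal(0, 1, (n, d)))[0]
        mu = rng.normal(0, 1, n)
        basis = append_hf_term(Vd, mu, mu + rng.normal(0, 2, n))
        X = mu[:, None] + rng.normal(0, 2, (n, l))
        ens = TemplateEnsemble(X=X, labels=[str(i) for i in range(l)], energies=np.zeros(l))
        return basis, ens

    def test_zero_margin_bounds_are_min_max(self, rng):
        basis, ens = self._setup(rng)
        space = search_bounds(basis, ens, margin=0.0)
        A = basis.V.T @ (ens.X - basis.mu[:, None])
        assert np.allclose(space.lower, A.min(axis=1))
        assert np.allclose(space.upper, A.max(axis=1))

    def test_margin_arithmetic(self, rng):
        basis, ens = self._setup(rng)
        tight = search_bounds(basis, ens, margin=0.0)
        padded = search_bounds(basis, ens, margin=0.1)
        rng_width = tight.upper - tight.lower
        assert np.allclose(padded.lower, tight.lower - 0.1 * rng_width)
        assert np.allclose(padded.upper, tight.upper + 0.1 * rng_width)

    def test_all_templates_contained(self, rng):
        for _ in range(5):
            basis, ens = self._setup(rng, l=12)
            space = search_bounds(basis, ens, margin=0.05)
            A = basis.V.T @ (ens.X - basis.mu[:, None])
            for j in range(ens.l):
                assert space.contains(A[:, j], atol=1e-10)

    def test_degenerate_coordinate_still_has_width(self, rng):
        basis, ens = self._setup(rng, l=2)
        ens.X[:, 1] = ens.X[:, 0]  # identical templates: zero range everywhere
        space = search_bounds(basis, ens, margin=0.1)
        assert np.all(space.upper > space.lower)
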
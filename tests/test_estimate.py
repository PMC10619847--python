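import numpy as np
import pytest

from spinlm import (
    CovarianceSpec,
    PartitionIndex,
    SpatialDataset,
    build_cov_matrix,
    fit_fixed_effects,
    fit_reml,
    partition_compact,
    partition_random,
    reml_objective_blocked,
    var_beta_empirical,
    var_beta_exact,
    var_beta_pooled,
    wald_table,
)
from spinlm.estimate import FixedEffectsResult

from conftest import make_gaussian_dataset


def single_block(n):
    return PartitionIndex(np.zeros(n, dtype=int), 1, "rand", n)


def dense_reml(theta, dataset, family="exponential"):
    """Independent dense REML criterion (constant dropped)."""
    spec = CovarianceSpec(family, *theta)
    v = build_cov_matrix(dataset.coords, spec, check=False)
    vi = np.linalg.inv(v)
    x, y = dataset.X, dataset.y
    a = x.T @ vi @ x
    beta = np.linalg.solve(a, x.T @ vi @ y)
    r = y - x @ beta
    return (
        np.linalg.slogdet(v)[1] + r @ vi @ r + np.linalg.slogdet(a)[1]
    )


def dense_gls(dataset, spec):
    v = build_cov_matrix(dataset.coords, spec, check=False)
    vi = np.linalg.inv(v)
    a = dataset.X.T @ vi @ dataset.X
    beta = np.linalg.solve(a, dataset.X.T @ vi @ dataset.y)
    return beta, np.linalg.inv(a)


class TestBlockedObjective:
    def test_single_partition_equals_dense_reml(self, exp_spec):
        dataset, _ = make_gaussian_dataset(60, exp_spec, seed=10)
        theta = (1.5, 0.2, 0.3)
        blocked = reml_objective_blocked(theta, dataset, single_block(60))
        dense = dense_reml(theta, dataset)
        assert blocked == pytest.approx(dense, rel=1e-8)

    def test_invariant_to_block_relabeling(self, exp_spec):
        dataset, _ = make_gaussian_dataset(90, exp_spec, seed=11)
        part = partition_compact(dataset.coords, 30, seed=0)
        relabel = np.array([2, 0, 1])[part.labels]
        part2 = PartitionIndex(relabel, 3, "comp", 30)
        theta = (2.0, 0.3, 0.4)
        assert reml_objective_blocked(theta, dataset, part) == pytest.approx(
            reml_objective_blocked(theta, dataset, part2), rel=1e-12
        )

    def test_finite_with_categorical_level_missing_from_a_block(self):
        """The pooled log-determinant term tolerates an all-zero design
        column inside one block (composite likelihood would not)."""
        rng = np.random.default_rng(12)
        n = 60
        coords = rng.uniform(size=(n, 2))
        indicator = np.zeros(n)
        indicator[: n // 2] = 1.0  # level present only in the first half
        x = np.column_stack([np.ones(n), indicator])
        y = x @ [1.0, 0.5] + rng.standard_normal(n)
        dataset = SpatialDataset(coords, x, y)
        labels = np.repeat([0, 1], n // 2)
        part = PartitionIndex(labels, 2, "rand", n // 2)
        value = reml_objective_blocked((1.0, 0.1, 0.3), dataset, part)
        assert np.isfinite(value)

    def test_nonpd_parameters_return_penalty_not_exception(self):
        rng = np.random.default_rng(13)
        coords = np.repeat(rng.uniform(size=(5, 2)), 8, axis=0)
        x = np.ones((40, 1))
        dataset = SpatialDataset(coords, x, rng.standard_normal(40))
        # zero nugget with heavily duplicated sites: singular blocks
        value = reml_objective_blocked((1.0, 1e-15, 1e5), dataset, single_block(40))
        assert value > 1e9


class TestFitREML:
    def test_deterministic(self, exp_spec):
        dataset, _ = make_gaussian_dataset(150, exp_spec, seed=14)
        part = partition_compact(dataset.coords, 50, seed=1)
        f1 = fit_reml(dataset, part)
        f2 = fit_reml(dataset, part)
        assert f1.spec.theta == f2.spec.theta
        assert f1.objective == f2.objective

    def test_parameter_recovery_smoke(self):
        """Correct-model recovery on one seeded draw, generous bands."""
        spec = CovarianceSpec("exponential", 10.0, 0.1, 0.5)
        dataset, _ = make_gaussian_dataset(800, spec, seed=15)
        part = partition_compact(dataset.coords, 50, seed=2)
        fit = fit_reml(dataset, part)
        assert fit.converged
        tau2, eta2, rho = fit.spec.theta
        assert 4.0 < tau2 < 25.0
        assert eta2 < 1.0
        assert 0.1 < rho < 2.0

    def test_pure_nugget_data_predicts_the_mean(self):
        from spinlm import point_predict_global

        rng = np.random.default_rng(16)
        n = 300
        coords = rng.uniform(size=(n, 2))
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ [1.0, 2.0] + rng.standard_normal(n)  # no spatial structure
        dataset = SpatialDataset(coords, x, y)
        part = partition_compact(coords, 50, seed=3)
        fit = fit_reml(dataset, part)
        res = var_beta_exact(fit)
        sites = rng.uniform(size=(20, 2))
        sx = np.column_stack([np.ones(20), rng.standard_normal(20)])
        pred = point_predict_global(dataset, fit, sites, sx, 50, res)
        trend = sx @ fit.beta_bd
        # kriging weights near zero: predictions revert to the fitted trend
        assert np.abs(pred.predictions - trend).max() < 0.25 * y.std()

    def test_bad_init_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            fit_reml(small_dataset, single_block(80), init=(1.0, -1.0, 0.5))


class TestFixedEffects:
    def test_single_partition_equals_dense_gls(self, exp_spec):
        dataset, _ = make_gaussian_dataset(80, exp_spec, seed=17)
        fit = fit_fixed_effects(dataset, single_block(80), exp_spec)
        beta, cov = dense_gls(dataset, exp_spec)
        assert np.allclose(fit.beta_bd, beta, rtol=1e-8)
        res = var_beta_exact(fit)
        assert np.allclose(res.cov, cov, rtol=1e-8)

    def test_iid_limit_equals_ols_for_any_partition(self, rng):
        n = 120
        coords = rng.uniform(size=(n, 2))
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ [0.5, -1.0] + rng.standard_normal(n)
        dataset = SpatialDataset(coords, x, y)
        spec = CovarianceSpec("exponential", 1.0, 0.5, 1e-8)  # V ~ sigma2 I
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        for part in (
            single_block(n),
            partition_random(coords, 30, seed=1),
            partition_compact(coords, 40, seed=1),
        ):
            fit = fit_fixed_effects(dataset, part, spec)
            assert np.allclose(fit.beta_bd, ols, atol=1e-6)

    def test_q_matrix_identities(self, exp_spec):
        dataset, v = make_gaussian_dataset(100, exp_spec, seed=18)
        part = partition_compact(dataset.coords, 25, seed=4)
        fit = fit_fixed_effects(dataset, part, exp_spec)
        qt = fit.q_transpose()
        assert np.allclose(qt.T @ dataset.X, np.eye(2), atol=1e-8)
        assert np.allclose(qt.T @ dataset.y, fit.beta_bd, atol=1e-10)

    def test_reuses_reml_fit_for_same_partition(self, exp_spec):
        dataset, _ = make_gaussian_dataset(100, exp_spec, seed=19)
        part = partition_compact(dataset.coords, 25, seed=5)
        fit = fit_reml(dataset, part)
        assert fit_fixed_effects(dataset, part, fit) is fit


class TestVarianceEstimators:
    def test_exact_equals_qvq_oracle(self, exp_spec):
        """The module's central correctness identity: var(Q y) = Q V Q'."""
        dataset, v = make_gaussian_dataset(150, exp_spec, seed=20)
        part = partition_compact(dataset.coords, 50, seed=6)
        fit = fit_fixed_effects(dataset, part, exp_spec)
        res = var_beta_exact(fit)
        qt = fit.q_transpose()
        assert np.allclose(res.cov, qt.T @ v @ qt, rtol=1e-8, atol=1e-12)

    def test_cross_terms_vanish_for_truly_blockdiagonal_covariance(self):
        """Spherical model with clusters farther apart than the range:
        W_xx = 0 so the exact variance collapses to T_xx^{-1}."""
        rng = np.random.default_rng(21)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        coords = np.vstack([c + rng.uniform(0, 0.5, size=(20, 2)) for c in centers])
        n = coords.shape[0]
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        spec = CovarianceSpec("spherical", 2.0, 0.3, 1.0)
        y = x @ [1.0, 1.0] + rng.standard_normal(n)
        dataset = SpatialDataset(coords, x, y)
        part = PartitionIndex(np.repeat([0, 1, 2], 20), 3, "comp", 20)
        fit = fit_fixed_effects(dataset, part, spec)
        res = var_beta_exact(fit)
        assert np.allclose(res.cov, fit.Txx_inv, atol=1e-12)

    def test_empirical_two_block_scalar_formula(self):
        rng = np.random.default_rng(22)
        n = 40
        coords = rng.uniform(size=(n, 2))
        x = np.ones((n, 1))
        y = rng.standard_normal(n)
        dataset = SpatialDataset(coords, x, y)
        spec = CovarianceSpec("exponential", 1.0, 0.5, 0.2)
        part = PartitionIndex(np.repeat([0, 1], 20), 2, "rand", 20)
        fit = fit_fixed_effects(dataset, part, spec)
        betas, valid = fit.per_block_betas()
        assert valid.all()
        a, b = betas[:, 0]
        m = fit.beta_bd[0]
        expected = ((a - m) ** 2 + (b - m) ** 2) / 2.0
        res = var_beta_empirical(fit)
        assert res.cov[0, 0] == pytest.approx(expected)

    def test_empirical_requires_two_blocks(self, exp_spec, small_dataset):
        fit = fit_fixed_effects(small_dataset, single_block(80), exp_spec)
        with pytest.raises(ValueError):
            var_beta_empirical(fit)

    def test_pooled_single_block_equals_dense(self, exp_spec):
        dataset, _ = make_gaussian_dataset(70, exp_spec, seed=23)
        fit = fit_fixed_effects(dataset, single_block(70), exp_spec)
        _, cov = dense_gls(dataset, exp_spec)
        assert np.allclose(var_beta_pooled(fit).cov, cov, rtol=1e-8)

    def test_pooled_identical_blocks_averaging_identity(self):
        # four copies of the same block geometry: pooled variance is the
        # single-block variance divided by the number of blocks
        rng = np.random.default_rng(24)
        base = rng.uniform(size=(15, 2))
        coords = np.vstack([base + [offset, 0.0] for offset in (0.0, 100.0, 200.0, 300.0)])
        n = coords.shape[0]
        xcol = np.tile(rng.standard_normal(15), 4)
        x = np.column_stack([np.ones(n), xcol])
        dataset = SpatialDataset(coords, x, rng.standard_normal(n))
        spec = CovarianceSpec("exponential", 1.0, 0.2, 0.1)
        part = PartitionIndex(np.repeat(np.arange(4), 15), 4, "comp", 15)
        fit = fit_fixed_effects(dataset, part, spec)
        info = fit.block_information()
        single = np.linalg.inv(info[0])
        assert np.allclose(var_beta_pooled(fit).cov, single / 4.0, rtol=1e-8)

    def test_pooled_is_symmetric_psd(self, exp_spec):
        dataset, _ = make_gaussian_dataset(120, exp_spec, seed=25)
        part = partition_random(dataset.coords, 30, seed=7)
        fit = fit_fixed_effects(dataset, part, exp_spec)
        for res in (var_beta_pooled(fit), var_beta_empirical(fit), var_beta_exact(fit)):
            assert np.allclose(res.cov, res.cov.T)
            assert np.all(np.linalg.eigvalsh(res.cov) > -1e-12)


class TestWaldTable:
    def test_normal_reference_values(self):
        res = FixedEffectsResult(
            beta=np.array([1.645, 0.0]),
            cov=np.diag([1.0, 1.0]),
            estimator="exact",
            n_blocks_used=3,
        )
        table = wald_table(res, names=["a", "b"])
        assert table.loc["a", "p"] == pytest.approx(0.0999, abs=1e-3)
        assert table.loc["b", "z"] == 0.0
        assert table.loc["b", "p"] == pytest.approx(1.0)
        assert table.loc["a", "se"] == pytest.approx(1.0)

    def test_zero_se_reported_as_missing(self):
        res = FixedEffectsResult(
            beta=np.array([2.0]), cov=np.zeros((1, 1)), estimator="pooled", n_blocks_used=1
        )
        table = wald_table(res)
        assert np.isnan(table["p"].iloc[0])
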
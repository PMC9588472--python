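"""Variational inference: initializers, ELBO estimator, fitting, checkpoints."""

import numpy as np
import pytest

from ntfa.exceptions import ValidationError
from ntfa.grids import make_brain_grid
from ntfa.inference import (
    FitConfig,
    VariationalPosterior,
    elbo,
    fit,
    hotspot_init,
    init_variational,
    kmeans_center_init,
    load_checkpoint,
    ols_weight_init,
    reconstruct,
    save_checkpoint,
)
from ntfa.model import standardize_dataset
from ntfa.nets import SIGMA_FLOOR, GenerativeNets
from ntfa.simulate import make_scenario, render_template, simulate_dataset


def manual_forward(mlp, x):
    h = np.tanh(x @ mlp.W1.data + mlp.b1.data)
    return h @ mlp.W2.data + mlp.b2.data


def manual_positive(x):
    return np.logaddexp(0.0, x) + SIGMA_FLOOR


@pytest.fixture(scope="module")
def tiny_dataset(tiny_grid):
    ds = simulate_dataset(make_scenario("by_condition", T=5, seed=4,
                                        grid=tiny_grid))
    ds, _ = standardize_dataset(ds)
    return ds


class TestKMeansInit:
    def test_saturated_clustering_returns_voxel_coordinates(self):
        grid = make_brain_grid((4, 4, 4), 8.0)
        centers, rhos = kmeans_center_init(grid, K=grid.n_voxels, seed=0)
        got = {tuple(np.round(c, 6)) for c in centers}
        want = {tuple(c) for c in grid.coords}
        assert got == want
        # zero cluster variance is floored at (voxel/2)^2
        np.testing.assert_allclose(np.exp(rhos), 2 * (8.0 / 2) ** 2)

    def test_two_separated_blocks_recover_block_centroids(self, small_grid):
        # brute-force Lloyd fixed point: two well-separated halves
        left = small_grid.coords[small_grid.coords[:, 1] < -20]
        right = small_grid.coords[small_grid.coords[:, 1] > 20]
        pts = np.vstack([left, right])

        class FakeGrid:
            coords = pts
            n_voxels = len(pts)
            voxel_size_mm = 8.0

        centers, _ = kmeans_center_init(FakeGrid(), K=2, seed=0)
        expected = {tuple(np.round(left.mean(0), 4)),
                    tuple(np.round(right.mean(0), 4))}
        got = {tuple(np.round(c, 4)) for c in centers}
        assert got == expected

    def test_k_exceeding_v_rejected(self, tiny_grid):
        with pytest.raises(ValidationError):
            kmeans_center_init(tiny_grid, K=tiny_grid.n_voxels + 1)


class TestHotspotInit:
    def test_single_bump_peak_recovered(self, small_grid):
        t = render_template([[4.0, 12.0, -4.0]], [12.0], [1.0], small_grid)
        centers, rhos = hotspot_init(t.rendered, small_grid, K=1)
        np.testing.assert_allclose(centers[0], [4.0, 12.0, -4.0])
        # recovered squared-width scale close to the rendered 2*w^2
        assert np.exp(rhos[0]) == pytest.approx(2 * 12.0**2, rel=0.2)

    def test_second_center_lands_on_second_bump_after_subtraction(self, small_grid):
        img = render_template([[-28.0, -28.0, 4.0], [28.0, 28.0, 4.0]],
                              [10.0, 10.0], [1.0, 0.8], small_grid).rendered
        centers, _ = hotspot_init(img, small_grid, K=2)
        np.testing.assert_allclose(centers[0], [-28.0, -28.0, 4.0])
        np.testing.assert_allclose(centers[1], [28.0, 28.0, 4.0])

    def test_all_zero_image_falls_back_to_kmeans(self, tiny_grid):
        centers, _ = hotspot_init(np.zeros(tiny_grid.n_voxels), tiny_grid, K=3)
        ref, _ = kmeans_center_init(tiny_grid, K=3)
        np.testing.assert_allclose(np.sort(centers, axis=0),
                                   np.sort(ref, axis=0))


class TestOLSInit:
    def test_zero_target_gives_zero_weights(self, rng):
        F = rng.normal(size=(3, 20))
        np.testing.assert_allclose(ols_weight_init(F, np.zeros(20)), 0.0,
                                   atol=1e-12)

    def test_orthogonal_projection(self):
        F = np.eye(3, 12)
        w = ols_weight_init(F, 3.0 * F[1])
        np.testing.assert_allclose(w, [0.0, 3.0, 0.0], atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        F = rng.normal(size=(3, 20))
        y = rng.normal(size=20)
        expected = np.linalg.inv(F @ F.T) @ F @ y
        np.testing.assert_allclose(ols_weight_init(F, y), expected)

    def test_rank_deficient_falls_back_to_ridge_with_warning(self, rng):
        row = rng.normal(size=20)
        F = np.vstack([row, row])
        with pytest.warns(RuntimeWarning):
            w = ols_weight_init(F, row)
        assert np.all(np.isfinite(w))


class TestInitVariational:
    def test_embedding_blocks_start_at_standard_normal(self, tiny_dataset):
        config = FitConfig(K=3, seed=0)
        q, _ = init_variational(tiny_dataset, config)
        for block in ("z_P", "z_S", "z_PF"):
            np.testing.assert_array_equal(q.mean[block].data, 0.0)
            np.testing.assert_array_equal(q.std(block), 1.0)
        assert np.all(q.std("x_F") == 1.0)

    def test_weight_means_solve_ols_against_dataset_mean_image(self, tiny_dataset):
        config = FitConfig(K=3, seed=0)
        q, _ = init_variational(tiny_dataset, config)
        mean_image = tiny_dataset.mean_image()
        for p in range(tiny_dataset.P):
            centers = q.mean["x_F"].data[p]
            rhos = q.mean["rho_F"].data[p]
            d2 = ((tiny_dataset.grid.coords[None] - centers[:, None]) ** 2).sum(-1)
            F0 = np.exp(-d2 / np.exp(rhos)[:, None])
            w0 = ols_weight_init(F0, mean_image)
            n = next(i for i, s in enumerate(tiny_dataset.segments)
                     if s.participant_id == p + 1)
            np.testing.assert_allclose(q.mean["W"].data[n],
                                       np.tile(w0, (tiny_dataset.T, 1)))

    def test_init_is_deterministic(self, tiny_dataset):
        config = FitConfig(K=3, seed=5)
        q1, n1 = init_variational(tiny_dataset, config)
        q2, n2 = init_variational(tiny_dataset, config)
        for b in q1.BLOCKS:
            np.testing.assert_array_equal(q1.mean[b].data, q2.mean[b].data)
        np.testing.assert_array_equal(n1.theta_F.b2.data, n2.theta_F.b2.data)


def _toy_problem(sigma_Y=0.5):
    grid = make_brain_grid((1, 1, 1), 8.0)
    from ntfa.simulate import Dataset, Segment
    ds = Dataset(grid=grid, segments=(Segment(1, 1, "A", np.array([[0.6]])),))
    config = FitConfig(K=1, D=1, sigma_Y=sigma_Y, seed=0)
    nets = GenerativeNets(K=1, D=1, seed=2)
    q = VariationalPosterior(N=1, T=1, P=1, S=1, K=1, D=1)
    rng = np.random.default_rng(8)
    for b in q.BLOCKS:
        q.mean[b].data[:] = rng.normal(0, 0.5, size=q.mean[b].shape)
        q.log_std[b].data[:] = rng.normal(-0.5, 0.2, size=q.mean[b].shape)
    return ds, config, nets, q


def _gh_nodes(n):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()


def _gauss_kl(mu_q, sd_q, mu_p, sd_p):
    return (np.log(sd_p / sd_q)
            + (sd_q**2 + (mu_q - mu_p) ** 2) / (2 * sd_p**2) - 0.5)


def _toy_elbo_quadrature(ds, config, nets, q, n_nodes=15):
    """Deterministic oracle for the toy ELBO via Gauss-Hermite quadrature."""
    x, w = _gh_nodes(n_nodes)
    out = 0.0
    # embedding KL terms: closed form
    for b in ("z_P", "z_S", "z_PF"):
        mu, sd = q.mean[b].data.ravel()[0], q.std(b).ravel()[0]
        out -= _gauss_kl(mu, sd, 0.0, 1.0)
    # E over z_PF of the factor KL
    mu_pf, sd_pf = q.mean["z_PF"].data.ravel()[0], q.std("z_PF").ravel()[0]
    kl_f = 0.0
    for xi, wi in zip(x, w):
        z = mu_pf + sd_pf * xi
        raw = manual_forward(nets.theta_F, np.array([z]))
        mu_x, sd_x = raw[:3], manual_positive(raw[3:6])
        mu_r, sd_r = raw[6], manual_positive(raw[7:8])[0]
        kl_f += wi * (_gauss_kl(q.mean["x_F"].data[0, 0], q.std("x_F")[0, 0],
                                mu_x, sd_x).sum()
                      + _gauss_kl(q.mean["rho_F"].data[0, 0],
                                  q.std("rho_F")[0, 0], mu_r, sd_r))
    out -= kl_f
    # E over (z_P, z_S) of the weight KL
    mu_p, sd_p = q.mean["z_P"].data.ravel()[0], q.std("z_P").ravel()[0]
    mu_s, sd_s = q.mean["z_S"].data.ravel()[0], q.std("z_S").ravel()[0]
    kl_w = 0.0
    for xi, wi in zip(x, w):
        for xj, wj in zip(x, w):
            zc = manual_forward(nets.theta_C,
                                np.array([mu_p + sd_p * xi, mu_s + sd_s * xj]))
            raw = manual_forward(nets.theta_W, zc)
            kl_w += wi * wj * _gauss_kl(q.mean["W"].data[0, 0, 0],
                                        q.std("W")[0, 0, 0],
                                        raw[0], manual_positive(raw[1:2])[0])
    out -= kl_w
    # E over (W, x1..x3, rho) of the data log-likelihood (5-D quadrature)
    y = ds.segments[0].data[0, 0]
    coord = ds.grid.coords[0]
    grids = np.meshgrid(*([x] * 5), indexing="ij")
    weights = np.ones_like(grids[0])
    for gw in np.meshgrid(*([w] * 5), indexing="ij"):
        weights = weights * gw
    W = q.mean["W"].data[0, 0, 0] + q.std("W")[0, 0, 0] * grids[0]
    xs = [q.mean["x_F"].data[0, 0, i] + q.std("x_F")[0, 0, i] * grids[1 + i]
          for i in range(3)]
    rho = q.mean["rho_F"].data[0, 0] + q.std("rho_F")[0, 0] * grids[4]
    d2 = sum((xi - ci) ** 2 for xi, ci in zip(xs, coord))
    f = np.exp(-d2 / np.exp(rho))
    loglik = (-0.5 * np.log(2 * np.pi * config.sigma_Y**2)
              - (y - W * f) ** 2 / (2 * config.sigma_Y**2))
    out += (weights * loglik).sum()
    return out


class TestELBO:
    def test_total_equals_reconstruction_minus_kl(self, tiny_dataset):
        config = FitConfig(K=3, seed=0)
        q, nets = init_variational(tiny_dataset, config)
        _, est = elbo(q, nets, tiny_dataset, config, rng=0)
        assert est.total == pytest.approx(est.reconstruction - est.kl,
                                          rel=1e-6)
        assert est.kl >= 0.0

    def test_embedding_block_at_prior_contributes_zero_kl(self):
        from ntfa.inference import _std_normal_kl
        from ntfa.autodiff import Tensor
        kl = _std_normal_kl(Tensor(np.zeros((4, 2))), Tensor(np.zeros((4, 2))))
        np.testing.assert_allclose(kl.data, 0.0, atol=1e-14)

    def test_monte_carlo_matches_quadrature_oracle(self):
        ds, config, nets, q = _toy_problem()
        oracle = _toy_elbo_quadrature(ds, config, nets, q)
        totals = [elbo(q, nets, ds, config, rng=seed, mc_samples=500)[1].total
                  for seed in range(60)]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - oracle) < 3 * se

    def test_estimator_spread_shrinks_with_sample_count(self):
        ds, config, nets, q = _toy_problem()
        lo = [elbo(q, nets, ds, config, rng=s, mc_samples=100)[1].total
              for s in range(40)]
        hi = [elbo(q, nets, ds, config, rng=1000 + s, mc_samples=10_000)[1].total
              for s in range(10)]
        ratio = np.std(lo) / np.std(hi)
        assert 3.0 < ratio < 33.0  # expect ~ sqrt(10000/100) = 10

    def test_nonpositive_std_rejected(self, tiny_dataset):
        config = FitConfig(K=3, seed=0)
        q, nets = init_variational(tiny_dataset, config)
        q.log_std["W"].data[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            elbo(q, nets, tiny_dataset, config, rng=0)


@pytest.fixture(scope="module")
def short_fit(tiny_dataset):
    config = FitConfig(K=3, seed=0, max_epochs=300)
    return fit(tiny_dataset, config), config


class TestFit:
    def test_trace_length_and_reconstruct_contract(self, short_fit, tiny_dataset):
        result, _ = short_fit
        assert len(result.loss_trace) == result.epochs_run
        rec = reconstruct(result, 0)
        assert rec.shape == (tiny_dataset.T, tiny_dataset.grid.n_voxels)
        with pytest.raises(IndexError):
            reconstruct(result, tiny_dataset.N)

    def test_reconstruction_error_improves_over_initialization(
            self, short_fit, tiny_dataset):
        result, config = short_fit
        q0, _ = init_variational(tiny_dataset, config)
        import copy
        init_result = copy.copy(result)
        init_result.posterior = q0
        err0 = sum(np.linalg.norm(reconstruct(init_result, n)
                                  - tiny_dataset.segments[n].data)
                   for n in range(tiny_dataset.N))
        err1 = sum(np.linalg.norm(reconstruct(result, n)
                                  - tiny_dataset.segments[n].data)
                   for n in range(tiny_dataset.N))
        assert err1 <= err0

    def test_converged_run_has_flat_final_window(self, tiny_dataset):
        config = FitConfig(K=2, seed=1, convergence_window=20, max_epochs=2000)
        result = fit(tiny_dataset, config)
        assert result.converged
        w = config.convergence_window
        recent = np.mean(result.loss_trace[-w:])
        previous = np.mean(result.loss_trace[-2 * w:-w])
        assert abs(recent - previous) / max(abs(previous), 1.0) \
            < config.convergence_tol

    def test_same_seed_reproduces_trace(self, tiny_dataset):
        config = FitConfig(K=2, seed=3, max_epochs=40)
        r1 = fit(tiny_dataset, config)
        r2 = fit(tiny_dataset, config)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)

    def test_kl_nonnegative_and_identity_every_epoch(self, tiny_dataset):
        records = []
        config = FitConfig(K=2, seed=0, max_epochs=60)
        fit(tiny_dataset, config,
            callback=lambda e, est: records.append(est))
        assert len(records) == 60
        for est in records:
            assert est.kl >= 0.0
            assert est.total == pytest.approx(est.reconstruction - est.kl,
                                              rel=1e-6)

    def test_vanilla_sgd_path_runs(self, tiny_dataset):
        config = FitConfig(K=2, seed=0, optimizer="sgd", learning_rate=1e-6,
                           max_epochs=10)
        result = fit(tiny_dataset, config)
        assert result.epochs_run == 10
        assert np.isfinite(result.loss_trace).all()


class TestCheckpoint:
    def test_resume_continues_trace_without_jump(self, tiny_dataset, tmp_path):
        path = tmp_path / "ckpt.npz"
        config = FitConfig(K=2, seed=0, max_epochs=80)
        first = fit(tiny_dataset, config, checkpoint_path=path)
        config2 = FitConfig(K=2, seed=0, max_epochs=160)
        resumed = fit(tiny_dataset, config2, resume_from=path)
        np.testing.assert_array_equal(resumed.loss_trace[:80], first.loss_trace)
        # no discontinuity at the seam beyond typical epoch-to-epoch jitter
        steps = np.abs(np.diff(first.loss_trace[-20:]))
        seam = abs(resumed.loss_trace[80] - resumed.loss_trace[79])
        assert seam < 10 * max(steps.max(), 1.0)

    def test_load_checkpoint_restores_posterior(self, tiny_dataset, tmp_path):
        path = tmp_path / "ckpt.npz"
        config = FitConfig(K=2, seed=0, max_epochs=30)
        result = fit(tiny_dataset, config)
        save_checkpoint(result, path)
        back = load_checkpoint(path, tiny_dataset)
        np.testing.assert_array_equal(back.posterior.mean["x_F"].data,
                                      result.posterior.mean["x_F"].data)
        np.testing.assert_array_equal(reconstruct(back, 0),
                                      reconstruct(result, 0))

    def test_malformed_checkpoint_rejected(self, tiny_dataset, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, junk=np.zeros(3))
        with pytest.raises(ValidationError):
            load_checkpoint(path, tiny_dataset)
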
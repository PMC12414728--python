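import numpy as np
import pytest

from bagmove import bagging
from bagmove.learners import LearnerSpec
from bagmove.telemetry import Telemetry, TimeGrid, make_grid


def _grid(tel, step=5.0):
    return make_grid(tel, step)


class TestFit:
    def test_single_member_equals_its_own_fit(self, noisy_telemetry):
        model = bagging.fit(
            noisy_telemetry, LearnerSpec("knn", 5), B=1, rng=np.random.default_rng(0)
        )
        grid = _grid(noisy_telemetry)
        mean = bagging.predict_mean(model, grid)
        member = model.member_paths(grid)[0]
        np.testing.assert_array_equal(mean.coord1, member.coord1)
        np.testing.assert_array_equal(mean.coord2, member.coord2)

    def test_constant_location_recovered_exactly(self, constant_telemetry):
        model = bagging.fit(
            constant_telemetry, LearnerSpec("knn", 3), B=20, rng=np.random.default_rng(1)
        )
        path = bagging.predict_mean(model, _grid(constant_telemetry))
        np.testing.assert_allclose(path.coord1, 12.0)
        np.testing.assert_allclose(path.coord2, -7.0)

    def test_same_seed_identical_different_seed_differs(self, noisy_telemetry):
        a = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=10, rng=np.random.default_rng(5))
        b = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=10, rng=np.random.default_rng(5))
        c = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=10, rng=np.random.default_rng(6))
        for sa, sb in zip(a.samples, b.samples):
            assert sa.indices.tolist() == sb.indices.tolist()
        assert any(
            sa.indices.tolist() != sc.indices.tolist() for sa, sc in zip(a.samples, c.samples)
        )

    def test_invalid_arguments(self, noisy_telemetry, rng):
        with pytest.raises(ValueError):
            bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=0, rng=rng)
        with pytest.raises(ValueError):
            bagging.fit(noisy_telemetry, LearnerSpec("knn", 1000), rng=rng)
        with pytest.raises(ValueError):
            bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), scheme="moving", rng=rng)


class TestPredictMean:
    def test_bounded_by_observed_range(self, noisy_telemetry, rng):
        model = bagging.fit(noisy_telemetry, LearnerSpec("knn", 7), B=30, rng=rng)
        path = bagging.predict_mean(model, _grid(noisy_telemetry))
        assert path.coord1.min() >= noisy_telemetry.coord1.min()
        assert path.coord1.max() <= noisy_telemetry.coord1.max()

    def test_translation_equivariance(self, noisy_telemetry):
        shifted = Telemetry(
            noisy_telemetry.times,
            noisy_telemetry.coord1 + 1000.0,
            noisy_telemetry.coord2 - 250.0,
        )
        m1 = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=15, rng=np.random.default_rng(2))
        m2 = bagging.fit(shifted, LearnerSpec("knn", 5), B=15, rng=np.random.default_rng(2))
        g = _grid(noisy_telemetry)
        p1 = bagging.predict_mean(m1, g)
        p2 = bagging.predict_mean(m2, g)
        np.testing.assert_allclose(p2.coord1, p1.coord1 + 1000.0, atol=1e-9)
        np.testing.assert_allclose(p2.coord2, p1.coord2 - 250.0, atol=1e-9)

    def test_grid_outside_range_rejected_unless_allowed(self, noisy_telemetry, rng):
        model = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=5, rng=rng)
        t1 = noisy_telemetry.times[-1]
        outside = TimeGrid(np.array([t1 + 1.0, t1 + 2.0]), 1.0)
        with pytest.raises(ValueError):
            bagging.predict_mean(model, outside)
        path = bagging.predict_mean(model, outside, allow_extrapolation=True)
        assert np.isfinite(path.coord1).all()

    def test_converges_to_single_fit_as_B_grows(self, linear_telemetry):
        spec = LearnerSpec("knn", 3)
        grid = _grid(linear_telemetry, 2.0)
        single = spec.fit(linear_telemetry.times, linear_telemetry.coords())
        target = single.predict(grid.points)
        devs = []
        for B in (5, 400):
            model = bagging.fit(linear_telemetry, spec, B=B, rng=np.random.default_rng(0))
            mean = bagging.predict_mean(model, grid)
            devs.append(np.max(np.abs(mean.coord1 - target[:, 0])))
        assert devs[1] < devs[0]


class TestOobResiduals:
    def test_constant_noiseless_residuals_are_zero(self, constant_telemetry, rng):
        model = bagging.fit(constant_telemetry, LearnerSpec("knn", 3), B=20, rng=rng)
        pool = bagging.oob_residual_pool(model)
        np.testing.assert_allclose(pool.residuals1, 0.0, atol=1e-12)
        assert pool.size <= constant_telemetry.n

    def test_no_oob_coverage_raises(self, rng):
        tel = Telemetry([0.0], [1.0], [1.0])  # n=1: the only row is always in-bag
        model = bagging.fit(tel, LearnerSpec("knn", 1), B=5, rng=rng)
        with pytest.raises(ValueError, match="increase"):
            bagging.oob_residual_pool(model)

    def test_residual_sd_tracks_noise_sd(self):
        """Smooth path + iid Normal(0, 10^2) noise at n=500: the OOB residual
        spread recovers the noise scale within 15%."""
        rng = np.random.default_rng(42)
        n, sigma = 500, 10.0
        t = np.sort(rng.uniform(0, 1000, n))
        x = 100 * np.sin(2 * np.pi * t / 300) + rng.normal(0, sigma, n)
        y = 100 * np.cos(2 * np.pi * t / 300) + rng.normal(0, sigma, n)
        model = bagging.fit(Telemetry(t, x, y), LearnerSpec("knn", 5), B=60, rng=rng)
        pool = bagging.oob_residual_pool(model)
        sd = np.std(np.concatenate([pool.residuals1, pool.residuals2]))
        assert sd == pytest.approx(sigma, rel=0.15)


class TestPredictionInterval:
    def test_zero_residuals_zero_width(self, constant_telemetry, rng):
        model = bagging.fit(constant_telemetry, LearnerSpec("knn", 3), B=20, rng=rng)
        ip = bagging.prediction_interval(model, _grid(constant_telemetry), 0.95)
        np.testing.assert_allclose(ip.upper1 - ip.lower1, 0.0, atol=1e-12)

    def test_bounded_support_half_width(self, rng):
        """A residual pool of -1/+1 entries bounds the half-width by 1."""
        model = bagging.fit(
            Telemetry(np.arange(60.0), rng.normal(size=60), rng.normal(size=60)),
            LearnerSpec("knn", 5),
            B=40,
            rng=rng,
        )
        pool = bagging.ResidualPool(
            np.tile([-1.0, 1.0], 50), np.tile([-1.0, 1.0], 50), np.arange(100)
        )
        grid = TimeGrid(np.array([10.0, 20.0]), 10.0)
        ip = bagging.prediction_interval(model, grid, 0.999, pool=pool)
        np.testing.assert_allclose(ip.upper1 - ip.center.coord1, 1.0, atol=1e-9)

    def test_ordering_invariant_and_level_validation(self, noisy_telemetry, rng):
        model = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=30, rng=rng)
        ip = bagging.prediction_interval(model, _grid(noisy_telemetry), 0.9)
        assert np.all(ip.lower1 <= ip.center.coord1) and np.all(ip.center.coord1 <= ip.upper1)
        assert np.all(ip.lower2 <= ip.center.coord2) and np.all(ip.center.coord2 <= ip.upper2)
        with pytest.raises(ValueError):
            bagging.prediction_interval(model, _grid(noisy_telemetry), 1.5)


class TestRealizations:
    def test_ensemble_mode_returns_member_paths(self, noisy_telemetry, rng):
        model = bagging.fit(noisy_telemetry, LearnerSpec("knn", 5), B=3, rng=rng)
        grid = _grid(noisy_telemetry)
        reals = bagging.sample_realizations(model, grid, mode="ensemble", M=3)
        members = model.member_paths(grid)
        for r, m in zip(reals, members):
            np.testing.assert_array_equal(r.coord1, m.coord1)
        with pytest.raises(ValueError):
            bagging.sample_realizations(model, grid, mode="ensemble", M=4)

    def test_zero_pool_returns_copies_of_mean(self, constant_telemetry, rng):
        model = bagging.fit(constant_telemetry, LearnerSpec("knn", 3), B=20, rng=rng)
        grid = _grid(constant_telemetry)
        reals = bagging.sample_realizations(model, grid, mode="oob_perturbed", M=4, rng=rng)
        mean = bagging.predict_mean(model, grid)
        for r in reals:
            np.testing.assert_allclose(r.coord1, mean.coord1, atol=1e-12)

    def test_perturbed_spread_reproduces_pool_quantiles(self, rng):
        n = 300
        t = np.sort(rng.uniform(0, 500, n))
        tel = Telemetry(t, rng.normal(0, 20, n), rng.normal(0, 20, n))
        model = bagging.fit(tel, LearnerSpec("knn", 5), B=50, rng=rng)
        pool = bagging.oob_residual_pool(model)
        grid = TimeGrid(np.array([100.0, 200.0, 300.0]), 100.0)
        reals = bagging.sample_realizations(
            model, grid, mode="oob_perturbed", M=1000, rng=rng
        )
        center = bagging.predict_mean(model, grid)
        spread = np.array([r.coord1 - center.coord1 for r in reals]).ravel()
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(spread, q) == pytest.approx(
                np.quantile(pool.residuals1, q), abs=3.0
            )
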
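import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclesync import (
    ASFSeries,
    NoiseSpec,
    SimulationConfig,
    asf_matrix,
    asf_successive,
    ecdf,
    emulate_asynchronous_experiment,
    emulate_synchronized_experiment,
    estimate_sigma_tau,
    fit_logistic_decay,
    kuiper_statistic,
    normalize_series,
)
from cyclesync.asf import logistic_curve
from cyclesync.errors import InvalidInputError

from conftest import kuiper_brute_force

finite_samples = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False).map(lambda v: round(v, 6)),
    min_size=1,
    max_size=30,
)


class TestEcdf:
    def test_simple_values(self):
        f = ecdf([1.0, 2.0, 2.0, 4.0])
        assert f(2.0) == pytest.approx(0.75)
        assert f(4.0) == 1.0
        assert f(0.999) == 0.0

    def test_degenerate_sample(self):
        f = ecdf([5.0])
        assert f(4.999) == 0.0
        assert f(5.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            ecdf([])

    @given(finite_samples)
    def test_step_function_semantics(self, sample):
        f = ecdf(sample)
        assert np.all(np.diff(f.cum_frac) > 0)
        assert f.cum_frac[-1] == pytest.approx(1.0)
        assert f(max(sample)) == pytest.approx(1.0)


class TestKuiperStatistic:
    def test_identical_samples_are_zero(self, rng):
        x = rng.normal(size=500)
        assert kuiper_statistic(x, x.copy()) == 0.0

    def test_fully_separated_samples_are_one(self):
        assert kuiper_statistic([1, 2, 3], [10, 11, 12]) == 1.0

    def test_known_shifted_sample(self):
        # brute-force derivation over pooled points {1,2,3,4} gives 1/3
        assert kuiper_statistic([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0 / 3.0)
        assert kuiper_brute_force([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0 / 3.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            kuiper_statistic([], [1.0])

    def test_oracle_equivalence_fuzz(self, rng):
        for _ in range(500):
            n1, n2 = rng.integers(1, 31, size=2)
            # mixture of continuous values and ties across samples
            pool = rng.integers(0, 10, size=40).astype(float)
            x1 = rng.choice(pool, size=n1)
            x2 = np.concatenate([
                rng.choice(pool, size=n2 // 2 + 1),
                rng.normal(5, 3, size=n2 // 2),
            ])[:n2]
            expected = kuiper_brute_force(x1, x2)
            assert kuiper_statistic(x1, x2) == pytest.approx(expected, abs=1e-12)

    @given(finite_samples, finite_samples)
    def test_bounds_and_symmetry(self, x1, x2):
        v = kuiper_statistic(x1, x2)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(kuiper_statistic(x2, x1))

    @given(finite_samples, finite_samples)
    @settings(max_examples=50)
    def test_monotone_transform_invariance(self, x1, x2):
        v = kuiper_statistic(x1, x2)

        def transform(x):
            # affine map: strictly increasing and exact in floating point
            return np.asarray(x) * 2.0 + 10.0

        assert kuiper_statistic(transform(x1), transform(x2)) == pytest.approx(v, abs=1e-12)


class TestASFSeries:
    def test_successive_length(self, small_sync_timecourse):
        series = asf_successive(small_sync_timecourse)
        assert len(series) == 11
        assert series.pair_labels[0] == (0.0, 8.0)
        assert np.array_equal(series.times, small_sync_timecourse.times[1:])

    def test_identical_columns_give_zero(self, small_sync_timecourse):
        tc = small_sync_timecourse
        tc.measurements[:, :] = tc.measurements[:, [0]]
        series = asf_successive(tc)
        assert np.all(series.values == 0.0)

    def test_zero_noise_synchronized_pinned_at_one(self, zero_noise):
        tc = emulate_synchronized_experiment(zero_noise, n_cells=10, seed=1)
        series = asf_successive(tc)
        changed = np.diff(tc.measurements[0]) != 0
        assert np.all(series.values[changed] == 1.0)

    def test_convergence_tail_below_head(self, default_noise):
        tc = emulate_synchronized_experiment(
            default_noise, n_cells=1000, seed=7, init_age_fraction=0.5,
            parent_corr=0.9, measurement_cv=0.05,
        )
        values = asf_successive(tc).values
        assert values[-3:].mean() < values[:3].mean()

    def test_async_below_sync_initial(self, default_noise):
        sync = emulate_synchronized_experiment(
            default_noise, n_cells=1000, seed=3, init_age_fraction=0.5
        )
        asyn = emulate_asynchronous_experiment(default_noise, n_cells=1000, seed=3)
        sync_initial = asf_successive(sync).values[0]
        assert np.all(asf_successive(asyn).values < sync_initial)


class TestASFMatrix:
    def test_shape_symmetry_diagonal(self, small_sync_timecourse):
        mat = asf_matrix(small_sync_timecourse)
        n = small_sync_timecourse.n_timepoints
        assert mat.shape == (n, n)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0.0)

    def test_consistent_with_successive(self, small_sync_timecourse):
        mat = asf_matrix(small_sync_timecourse)
        series = asf_successive(small_sync_timecourse)
        off_diag = np.array([mat[j, j + 1] for j in range(len(series))])
        assert np.allclose(off_diag, series.values)


class TestNormalizeSeries:
    def test_definition(self):
        series = ASFSeries(pair_labels=((0, 8), (8, 16), (16, 24)), values=[0.8, 0.4, 0.2])
        norm = normalize_series(series)
        assert norm.values[0] == 1.0
        assert np.allclose(norm.values, [1.0, 0.5, 0.25])
        assert norm.normalized

    def test_idempotent(self):
        series = ASFSeries(pair_labels=((0, 8), (8, 16)), values=[1.0, 0.5], normalized=True)
        assert np.allclose(normalize_series(series).values, series.values)

    def test_zero_first_value_rejected(self):
        series = ASFSeries(pair_labels=((0, 8), (8, 16)), values=[0.0, 0.5])
        with pytest.raises(InvalidInputError):
            normalize_series(series)


class TestLogisticFit:
    def _series_from(self, upper, lower, rate, t_half):
        t = np.arange(8.0, 89.0, 8.0)
        values = logistic_curve(t, upper, lower, rate, t_half)
        labels = tuple((ti - 8.0, ti) for ti in t)
        return ASFSeries(pair_labels=labels, values=values)

    def test_noise_free_recovery(self):
        # generator values echo the published experimental endpoints
        series = self._series_from(0.869, 0.127, 0.15, 40.0)
        fit = fit_logistic_decay(series)
        assert fit.rss < 1e-10
        assert fit.upper == pytest.approx(0.869, abs=1e-3)
        assert fit.lower == pytest.approx(0.127, abs=1e-3)
        assert fit.rate == pytest.approx(0.15, rel=0.02)
        assert fit.t_half == pytest.approx(40.0, abs=0.5)

    def test_constant_series_rate_near_zero(self):
        t = np.arange(8.0, 89.0, 8.0)
        series = ASFSeries(
            pair_labels=tuple((ti - 8.0, ti) for ti in t), values=np.full(len(t), 0.6)
        )
        fit = fit_logistic_decay(series)
        assert fit.rss < 1e-12
        assert fit.predict(50.0) == pytest.approx(0.6, abs=1e-5)
        assert fit.rate < 0.05

    def test_simulated_experiment_positive_rate(self, default_noise):
        tc = emulate_synchronized_experiment(
            default_noise, n_cells=1000, seed=13, init_age_fraction=0.5,
            parent_corr=0.9, measurement_cv=0.05,
        )
        fit = fit_logistic_decay(asf_successive(tc))
        assert fit.rate > 0.0
        assert fit.upper > fit.lower

    def test_too_short_series_rejected(self):
        series = ASFSeries(pair_labels=((0, 8), (8, 16), (16, 24)), values=[0.9, 0.5, 0.2])
        with pytest.raises(InvalidInputError):
            fit_logistic_decay(series)


class TestFamilyContrast:
    def test_poisson_family_differs_from_normal(self):
        # matched mean and variance: Poisson(24) has variance 24 -> sd = sqrt(24)
        normal = NoiseSpec(mean_tau=24.0, sigma_tau=float(np.sqrt(24.0)), sigma_dna0=0.05)
        poisson = NoiseSpec(mean_tau=24.0, family_tau="poisson", family_dna="poisson",
                            sigma_dna0=0.05)
        discrepancies = []
        for seed in (1, 2, 3):
            a = emulate_synchronized_experiment(normal, n_cells=800, seed=seed)
            b = emulate_synchronized_experiment(poisson, n_cells=800, seed=seed)
            diff = asf_successive(a).values - asf_successive(b).values
            discrepancies.append(float(np.sum(diff**2)))
        assert min(discrepancies) > 0.01  # a reproducible, nonzero contrast

    def test_family_contrast_reproducible(self):
        poisson = NoiseSpec(mean_tau=24.0, family_tau="poisson", sigma_dna0=0.05)
        a = emulate_synchronized_experiment(poisson, n_cells=300, seed=9)
        b = emulate_synchronized_experiment(poisson, n_cells=300, seed=9)
        assert np.array_equal(a.measurements, b.measurements)


class TestEstimateSigmaTau:
    def test_degenerate_grid_returns_candidate(self, default_noise):
        tc = emulate_synchronized_experiment(default_noise, n_cells=200, seed=2)
        observed = asf_successive(tc)
        base = SimulationConfig(n_cells=200, noise=default_noise, seed=5)
        est = estimate_sigma_tau(observed, [3.0], reps=2, base=base)
        assert est.sigma_hat == 3.0
        assert est.discrepancy.shape == (1,)

    def test_empty_grid_rejected(self, default_noise):
        tc = emulate_synchronized_experiment(default_noise, n_cells=50, seed=2)
        base = SimulationConfig(n_cells=50, noise=default_noise, seed=5)
        with pytest.raises(InvalidInputError):
            estimate_sigma_tau(asf_successive(tc), [], reps=1, base=base)

    def test_mismatched_grid_rejected(self, default_noise):
        tc = emulate_synchronized_experiment(default_noise, n_cells=50, seed=2)
        observed = asf_successive(tc)
        base = SimulationConfig(
            n_cells=50, t_grid=np.arange(0.0, 49.0, 8.0), noise=default_noise, seed=5
        )
        with pytest.raises(InvalidInputError):
            estimate_sigma_tau(observed, [3.0], reps=1, base=base)

    def test_small_scale_recovery(self, default_noise):
        # cheap version of the full recovery criterion: coarse grid, 1 rep
        tc = emulate_synchronized_experiment(
            default_noise, n_cells=600, seed=31, init_age_fraction=0.5
        )
        base = SimulationConfig(
            n_cells=600, noise=default_noise, seed=101, init_age_fraction=0.5
        )
        est = estimate_sigma_tau(asf_successive(tc), [1.0, 3.0, 5.0], reps=2, base=base)
        assert est.sigma_hat == 3.0
        assert est.discrepancy[1] < est.discrepancy[0]
        assert est.discrepancy[1] < est.discrepancy[2]
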
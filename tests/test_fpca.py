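import numpy as np
import pytest

from funsurf import SimulationConfig, simulate_cohort
from funsurf.fpca import FpcaError, UnivariateFPCA, trapezoid_weights
from funsurf.simulate import eigenfunction_basis

GRID = np.linspace(0.0, 12.0, 51)
W = trapezoid_weights(GRID)


def _sparse_data(n=200, seed=0, times_per=6):
    rng = np.random.default_rng(seed)
    times = [np.sort(rng.uniform(0, 12, times_per)) for _ in range(n)]
    return rng, times


class TestMeanEstimation:
    def test_constant_data_gives_constant_mean(self):
        rng, times = _sparse_data(seed=1)
        values = [np.full_like(t, 3.25) for t in times]
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        mean_raw = fit.mean_ * fit.transform_scale_ + fit.transform_center_
        np.testing.assert_allclose(mean_raw, 3.25, atol=1e-8)

    def test_dense_noiseless_linear_data_recovers_line(self):
        rng, times = _sparse_data(n=300, seed=2, times_per=10)
        values = [0.5 + 0.25 * t for t in times]
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        np.testing.assert_allclose(fit.mean_, 0.5 + 0.25 * GRID, atol=1e-3)

    def test_too_few_distinct_times_rejected(self):
        times = [np.array([0.0, 6.0])] * 30
        values = [np.array([1.0, 2.0])] * 30
        with pytest.raises(FpcaError, match="distinct times"):
            UnivariateFPCA(pre_transform="none").fit(times, values)

    def test_fixed_penalty_and_gcv_both_accepted(self):
        rng, times = _sparse_data(seed=3)
        values = [np.sin(t / 2) + rng.normal(0, 0.1, t.size) for t in times]
        for lam in (None, 1.0):
            fit = UnivariateFPCA(pre_transform="none", mean_lambda=lam).fit(
                times, values
            )
            assert np.all(np.isfinite(fit.mean_))


class TestCovariance:
    def test_rank_one_noiseless_surface(self):
        rng, times = _sparse_data(n=500, seed=4, times_per=30)
        phi = lambda t: np.sqrt(2.0 / 12.0) * np.cos(np.pi * t / 12.0)
        values = [rng.normal(0, np.sqrt(2.0)) * phi(t) for t in times]
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        assert fit.eigenvalues_[0] > 0
        ratio = (
            fit.eigenvalues_[1] / fit.eigenvalues_[0]
            if fit.eigenvalues_.size > 1
            else 0.0
        )
        assert ratio < 0.01

    def test_surface_is_symmetric(self, marker_arrays):
        times, values = marker_arrays
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        assert np.max(np.abs(fit.covariance_ - fit.covariance_.T)) == 0.0

    def test_noise_variance_recovered(self):
        cfg = SimulationConfig(
            n_subjects=500, n_markers=1, eigenvalues=(2.0, 0.8),
            alpha=(0.0, 0.0), loadings=np.array([[1.0, 1.0]]),
            noise_sd=0.5, visit_rate=8.0, seed=5,
        )
        cohort, _ = simulate_cohort(cfg)
        times, values = zip(
            *(s.marker_observations("marker_01") for s in cohort.subjects)
        )
        fit = UnivariateFPCA(pre_transform="none").fit(list(times), list(values))
        assert fit.noise_variance_ == pytest.approx(0.25, rel=0.2)

    def test_no_repeated_measures_is_error(self):
        times = [np.array([float(i % 12)]) for i in range(30)]
        values = [np.array([1.0])] * 30
        with pytest.raises(FpcaError, match="unidentifiable"):
            UnivariateFPCA(pre_transform="none").fit(times, values)


class TestEigendecomposition:
    def test_constructed_rank_one_oracle(self):
        phi = eigenfunction_basis(GRID, 2)[:, 1]
        surface = 3.0 * np.outer(phi, phi)
        fit = UnivariateFPCA(pre_transform="none")
        fit.grid_ = GRID
        funcs, evals = fit._eigendecompose(surface)
        assert evals[0] == pytest.approx(3.0, abs=1e-6)
        align = abs(np.sum(W * funcs[:, 0] * phi))
        assert align == pytest.approx(1.0, abs=1e-6)
        assert evals[1] < 1e-8

    def test_quadrature_orthonormality(self, marker_arrays):
        times, values = marker_arrays
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        phi = fit.eigenfunctions_
        gram = phi.T @ (W[:, None] * phi)
        np.testing.assert_allclose(gram, np.eye(phi.shape[1]), atol=1e-6)

    def test_eigenvalues_nonnegative_decreasing(self, marker_arrays):
        times, values = marker_arrays
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        assert np.all(fit.eigenvalues_ >= 0)
        assert np.all(np.diff(fit.eigenvalues_) <= 1e-12)

    def test_sign_convention_max_abs_positive(self, marker_arrays):
        times, values = marker_arrays
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        for k in range(fit.eigenfunctions_.shape[1]):
            col = fit.eigenfunctions_[:, k]
            assert col[np.argmax(np.abs(col))] > 0


@pytest.fixture(scope="module")
def dense_fit():
    cfg = SimulationConfig(
        n_subjects=300, n_markers=1, eigenvalues=(2.0, 0.8),
        alpha=(0.0, 0.0), loadings=np.array([[1.0, 1.0]]),
        noise_sd=1e-6, visit_rate=25.0, seed=6,
    )
    cohort, truth = simulate_cohort(cfg)
    times, values = zip(
        *(s.marker_observations("marker_01") for s in cohort.subjects)
    )
    fit = UnivariateFPCA(pre_transform="none").fit(list(times), list(values))
    return fit, list(times), list(values), truth


def _clone_fit(fit, noise_variance):
    out = UnivariateFPCA(pre_transform="none")
    for attr in ("grid_", "mean_", "eigenfunctions_", "eigenvalues_",
                 "transform_center_", "transform_scale_", "n_components_"):
        setattr(out, attr, getattr(fit, attr))
    out.noise_variance_ = noise_variance
    return out


class TestScores:
    def test_dense_noiseless_scores_match_projection(self, dense_fit):
        """For curves in the fitted span, BLUP equals the quadrature projection."""
        fit = _clone_fit(dense_fit[0], 0.0)  # identity holds in noiseless limit
        rng = np.random.default_rng(0)
        for _ in range(10):
            xi_true = rng.normal(size=fit.n_components_) * np.sqrt(fit.eigenvalues_)
            v = fit.mean_ + fit.eigenfunctions_ @ xi_true
            xi, _ = fit.conditional_scores(GRID, v)
            resid = v - fit.mean_
            proj = (W[:, None] * fit.eigenfunctions_).T @ resid
            np.testing.assert_allclose(xi, proj, atol=1e-4)
            np.testing.assert_allclose(xi, xi_true, atol=1e-4)

    def test_single_observation_scores_are_shrunken(self, dense_fit):
        fit, times, values, _ = dense_fit
        dense_norms, sparse_norms = [], []
        for i in range(50):
            xi_dense, _ = fit.conditional_scores(times[i], values[i])
            xi_sparse, _ = fit.conditional_scores(times[i][:1], values[i][:1])
            dense_norms.append(np.linalg.norm(xi_dense))
            sparse_norms.append(np.linalg.norm(xi_sparse))
        assert np.mean(sparse_norms) < np.mean(dense_norms)

    def test_infinite_noise_shrinks_scores_to_zero(self, dense_fit):
        fit, times, values, _ = dense_fit
        noisy = _clone_fit(fit, 1e12)
        xi, _ = noisy.conditional_scores(times[0], values[0])
        np.testing.assert_allclose(xi, 0.0, atol=1e-6)

    def test_empty_subject_gets_prior_mean_and_flag(self, dense_fit):
        fit, *_ = dense_fit
        xi, observed = fit.conditional_scores(np.array([]), np.array([]))
        assert not observed
        np.testing.assert_array_equal(xi, 0.0)

    def test_times_outside_window_rejected(self, dense_fit):
        fit, *_ = dense_fit
        with pytest.raises(FpcaError, match="outside"):
            fit.conditional_scores(np.array([13.0]), np.array([1.0]))


class TestFullFit:
    def test_pve_monotone_bounded(self, marker_arrays):
        times, values = marker_arrays
        fit = UnivariateFPCA(pre_transform="none").fit(times, values)
        assert np.all(np.diff(fit.pve_) >= -1e-12)
        assert fit.pve_[-1] <= 1 + 1e-12

    def test_refit_is_deterministic(self, marker_arrays):
        times, values = marker_arrays
        a = UnivariateFPCA(pre_transform="none").fit(times, values)
        b = UnivariateFPCA(pre_transform="none").fit(times, values)
        np.testing.assert_array_equal(a.eigenfunctions_, b.eigenfunctions_)
        np.testing.assert_array_equal(a.eigenvalues_, b.eigenvalues_)

    def test_log1p_transform_roundtrips_in_scores(self):
        rng, times = _sparse_data(n=150, seed=7)
        values = [np.exp(rng.normal(1.0, 0.3, t.size)) for t in times]
        fit = UnivariateFPCA(pre_transform="log1p-z").fit(times, values)
        xi, flags = fit.transform(times, values)
        assert np.all(np.isfinite(xi))
        assert flags.all()


def test_dense_common_grid_matches_matrix_pca():
    """Unsmoothed FPCA on a dense common grid equals weighted matrix PCA."""
    rng = np.random.default_rng(8)
    n = 120
    phi = eigenfunction_basis(GRID, 3)
    scores = rng.normal(size=(n, 3)) * np.sqrt([3.0, 1.5, 0.5])
    data = scores @ phi.T  # (n, G), sigma = 0, zero mean
    times = [GRID.copy() for _ in range(n)]
    values = [row for row in data]
    fit = UnivariateFPCA(pre_transform="none", bandwidth=0.0).fit(times, values)

    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / n
    sw = np.sqrt(W)
    evals, evecs = np.linalg.eigh(sw[:, None] * cov * sw[None, :])
    order = np.argsort(evals)[::-1]
    pca_funcs = (evecs / sw[:, None])[:, order[:3]]
    for k in range(3):
        align = abs(np.sum(W * fit.eigenfunctions_[:, k] * pca_funcs[:, k]))
        assert align == pytest.approx(1.0, abs=1e-6)
        assert fit.eigenvalues_[k] == pytest.approx(evals[order[k]], rel=1e-6)
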
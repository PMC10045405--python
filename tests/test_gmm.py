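import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from pcgpipe import GmmModel, e_step, em_fit, hard_assign, m_step
from pcgpipe.gmm import log_likelihood


def _model(weights, means, variances):
    return GmmModel(weights=np.array(weights), means=np.array(means), variances=np.array(variances))


class TestEStep:
    def test_single_component_gives_unit_responsibility(self):
        model = _model([1.0], [[0.0]], [[1.0]])
        resp = e_step(model, np.array([[-3.0], [0.0], [5.0]]))
        assert np.allclose(resp, 1.0)

    def test_symmetric_two_component_at_origin(self):
        model = _model([0.5, 0.5], [[-2.0], [2.0]], [[1.0], [1.0]])
        resp = e_step(model, np.array([[0.0]]))
        assert np.allclose(resp, [[0.5, 0.5]], atol=1e-12)

    def test_matches_unlogged_formula(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 2, size=(10, 1))
        model = _model([0.3, 0.7], [[-1.0], [2.5]], [[0.8], [1.6]])
        resp = e_step(model, X)
        # direct (unstable) formula
        dens = np.empty((10, 2))
        for k in range(2):
            v = model.variances[k, 0]
            dens[:, k] = model.weights[k] * np.exp(
                -0.5 * (X[:, 0] - model.means[k, 0]) ** 2 / v
            ) / np.sqrt(2 * np.pi * v)
        direct = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(resp, direct, atol=1e-10)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 2))
        model = _model([0.2, 0.8], [[0, 0], [1, 1]], [[1, 2], [0.5, 0.5]])
        resp = e_step(model, X)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-12)


class TestMStep:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(10)
        X = rng.normal(3, 2, size=(40, 1))
        weights, means, variances = m_step(X, np.ones((40, 1)))
        assert weights[0] == pytest.approx(1.0)
        assert means[0, 0] == pytest.approx(X.mean(), abs=1e-12)
        assert variances[0, 0] == pytest.approx(X.var(), abs=1e-12)  # biased

    def test_hard_responsibilities_equal_group_statistics(self):
        rng = np.random.default_rng(11)
        X = np.concatenate([rng.normal(0, 1, (30, 1)), rng.normal(8, 2, (20, 1))])
        resp = np.zeros((50, 2))
        resp[:30, 0] = 1.0
        resp[30:, 1] = 1.0
        weights, means, variances = m_step(X, resp)
        assert means[0, 0] == pytest.approx(X[:30].mean(), abs=1e-12)
        assert means[1, 0] == pytest.approx(X[30:].mean(), abs=1e-12)
        assert variances[0, 0] == pytest.approx(X[:30].var(), abs=1e-12)
        assert weights == pytest.approx([0.6, 0.4])

    def test_uniform_responsibilities_give_global_statistics(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 2))
        weights, means, variances = m_step(X, np.full((25, 2), 0.5))
        assert weights == pytest.approx([0.5, 0.5])
        for k in range(2):
            assert np.allclose(means[k], X.mean(axis=0))
            assert np.allclose(variances[k], X.var(axis=0))


class TestEmFit:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(0)
        data = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        model, resp = em_fit(data, n_components=2, seed=42)
        means = np.sort(model.means.ravel())
        assert abs(means[0] - 0.0) <= 0.3
        assert abs(means[1] - 10.0) <= 0.3
        assert np.all(np.abs(model.weights - 0.5) <= 0.05)
        assert resp.shape == (400, 2)

    def test_single_component_closed_form_immediately(self):
        rng = np.random.default_rng(13)
        data = rng.normal(5, 3, 100)
        model, _ = em_fit(data, n_components=1, seed=0)
        assert model.converged
        assert len(model.log_likelihood_trace) <= 4
        assert model.means[0, 0] == pytest.approx(data.mean(), abs=1e-10)
        assert model.variances[0, 0] == pytest.approx(data.var(), abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_log_likelihood_monotone(self, seed):
        rng = np.random.default_rng(seed)
        data = np.concatenate(
            [rng.normal(rng.uniform(-5, 0), 1, 60), rng.normal(rng.uniform(2, 8), 2, 60)]
        )
        model, _ = em_fit(data, n_components=2, seed=seed)
        trace = np.asarray(model.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_component_permutation_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(14)
        data = rng.normal(size=(80, 1))
        model, _ = em_fit(data, n_components=2, seed=1)
        swapped = GmmModel(
            weights=model.weights[::-1].copy(),
            means=model.means[::-1].copy(),
            variances=model.variances[::-1].copy(),
        )
        assert log_likelihood(model, data) == pytest.approx(
            log_likelihood(swapped, data), abs=1e-9
        )

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            em_fit(np.array([1.0]), n_components=2)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        data = rng.normal(size=(60, 2))
        a, ra = em_fit(data, n_components=2, seed=7)
        b, rb = em_fit(data, n_components=2, seed=7)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(ra, rb)

    def test_likelihood_comparable_to_sklearn(self):
        # independent cross-check: our EM should find a fit whose mean
        # log-likelihood is close to sklearn's on a well-separated mixture
        rng = np.random.default_rng(16)
        data = np.concatenate([rng.normal(0, 1, 150), rng.normal(12, 1.5, 150)])[:, None]
        ours, _ = em_fit(data, n_components=2, seed=42)
        sk = GaussianMixture(2, covariance_type="diag", random_state=0).fit(data)
        ours_ll = log_likelihood(ours, data) / len(data)
        assert ours_ll == pytest.approx(sk.score(data), abs=0.05)


def test_hard_assign_argmax():
    resp = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
    assert hard_assign(resp).tolist() == [0, 1, 0]
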
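"""Tests for the self-organizing map: initialization, BMU search, kernels,
batch/sequential training, quantization error, serialization."""

import math
from itertools import product

import numpy as np
import pytest

from wearmap import (LearningRateSchedule, RadiusSchedule, SelfOrganizingMap,
                     find_bmu, init_model, kernel_weights,
                     neighborhood_weights, quantization_error, train)
from wearmap.som import _grid_coordinates, _grid_distances, _quantization_error


def batch_epoch_oracle(codebook, X, n_rows, n_cols, radius, kernel):
    """Brute-force one batch epoch: per-sample BMU by explicit distance
    scan (ties -> lowest index), then per-neuron neighborhood-weighted
    mean with explicit loops."""
    grid = _grid_coordinates(n_rows, n_cols)
    bmus = []
    for x in X:
        d = [float(np.sum((x - w) ** 2)) for w in codebook]
        bmus.append(int(np.argmin(d)))
    new = codebook.copy()
    for j in range(len(codebook)):
        num = np.zeros(codebook.shape[1])
        den = 0.0
        for i, x in enumerate(X):
            gd = float(np.linalg.norm(grid[j] - grid[bmus[i]]))
            if kernel == "gaussian":
                h = math.exp(-gd ** 2 / (2 * radius ** 2))
            else:
                h = 1.0 if gd <= radius else 0.0
            num += h * x
            den += h
        if den > 0:
            new[j] = num / den
    return new


class TestInit:
    def test_fixed_seed_reproduces_codebook(self):
        rng_data = np.random.default_rng(0).normal(size=(8, 4))
        a = init_model(3, 2, 4, mode="sample", data=rng_data, seed=5)
        b = init_model(3, 2, 4, mode="sample", data=rng_data, seed=5)
        assert np.array_equal(a.codebook_, b.codebook_)

    def test_sample_init_from_single_vector_dataset(self):
        data = np.array([[2.0, 3.0, 4.0]])
        m = init_model(2, 2, 3, mode="sample", data=data, seed=0)
        assert np.allclose(m.codebook_, data[0])

    def test_study_map_has_120_codebook_vectors(self):
        m = init_model(12, 10, 6, seed=0)
        assert m.codebook_.shape == (120, 6)

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError):
            init_model(2, 2, 5, mode="sample",
                       data=np.zeros((4, 3)), seed=0)

    def test_bad_grid_raises(self):
        with pytest.raises(ValueError):
            init_model(0, 3, 2)


class TestBMU:
    def test_exact_codebook_vector_wins(self):
        m = init_model(2, 2, 3, seed=1)
        m.codebook_ = np.arange(12.0).reshape(4, 3)
        assert find_bmu(m, m.codebook_[2]) == 2

    def test_all_identical_codebooks_tie_to_neuron_zero(self):
        m = init_model(2, 2, 2, seed=0)
        m.codebook_ = np.ones((4, 2))
        assert find_bmu(m, np.array([5.0, 5.0])) == 0

    def test_one_dimensional_nearest(self):
        m = init_model(2, 1, 1, seed=0)
        m.codebook_ = np.array([[0.0], [10.0]])
        assert find_bmu(m, np.array([4.0])) == 0
        assert find_bmu(m, np.array([6.0])) == 1

    def test_dimension_mismatch_raises(self):
        m = init_model(2, 2, 3, seed=0)
        with pytest.raises(ValueError):
            find_bmu(m, np.zeros(4))


class TestKernels:
    def test_gaussian_closed_form(self):
        m = init_model(3, 3, 1, seed=0)
        w = neighborhood_weights(m, bmu=0, radius=2.0)
        assert w[0] == 1.0
        # neuron at grid distance 2 from neuron 0 is (0,2) = index 2
        assert w[2] == pytest.approx(math.exp(-0.5))
        d = m.grid_distances()[0]
        assert (np.diff(w[np.argsort(d)]) <= 1e-12).all()

    def test_bubble_cuts_off_beyond_radius(self):
        w = kernel_weights(np.array([0.0, 1.0, 1.5, 2.0]), 1.5, "bubble")
        assert w.tolist() == [1.0, 1.0, 1.0, 0.0]

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            kernel_weights(np.array([1.0]), 0.0)


class TestSchedules:
    def test_linear_radius_interpolation_endpoints(self):
        s = RadiusSchedule(4.0, 1.0, 4)
        assert s.radii().tolist() == [4.0, 3.0, 2.0, 1.0]
        assert RadiusSchedule(2.0, 2.0, 1).radius_at(0) == 2.0

    @pytest.mark.parametrize("bad", [dict(initial=1.0, final=2.0, n_epochs=3),
                                     dict(initial=2.0, final=0.0, n_epochs=3),
                                     dict(initial=2.0, final=1.0, n_epochs=0)])
    def test_invalid_radius_schedule_raises(self, bad):
        with pytest.raises(ValueError):
            RadiusSchedule(**bad)

    def test_learning_rate_bounds(self):
        with pytest.raises(ValueError):
            LearningRateSchedule(initial=1.5)


class TestBatchTraining:
    @pytest.mark.parametrize("grid", [(1, 1), (1, 2), (2, 1), (1, 3), (3, 1),
                                      (2, 2), (1, 4), (4, 1), (1, 5), (5, 1)])
    @pytest.mark.parametrize("n_samples", [1, 3, 10])
    @pytest.mark.parametrize("kernel", ["gaussian", "bubble"])
    def test_one_batch_epoch_equals_brute_force_oracle(self, grid, n_samples,
                                                       kernel):
        """Exhaustive oracle equivalence on every lattice with <= 5 neurons
        and <= 10 samples."""
        rows, cols = grid
        rng = np.random.default_rng(rows * 100 + cols * 10 + n_samples)
        X = rng.normal(size=(n_samples, 3))
        m = SelfOrganizingMap(rows, cols, kernel=kernel, dtype=np.float64)
        codebook = rng.normal(size=(rows * cols, 3))
        for radius in (0.5, 1.0, 2.0):
            got = m._batch_epoch(codebook.copy(), X, m.grid_distances(),
                                 radius)
            want = batch_epoch_oracle(codebook.copy(), X, rows, cols, radius,
                                      kernel)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_single_data_vector_is_a_fixed_point(self):
        X = np.array([[1.0, 2.0, 3.0]])
        m = SelfOrganizingMap(3, 3, dtype=np.float64, random_state=0).fit(X)
        assert np.allclose(m.codebook_, X[0])

    def test_two_well_separated_groups_reach_kmeans_fixed_point(self):
        """2 x 1 map on 1-D data {0,0,0,10,10,10} with a shrinking radius
        ends near the k-means solution {0, 10}."""
        X = np.array([[0.0]] * 3 + [[10.0]] * 3)
        m = SelfOrganizingMap(2, 1, radius_initial=1.0, radius_final=0.2,
                              n_epochs_rough=10, n_epochs_fine=20,
                              dtype=np.float64, random_state=0).fit(X)
        assert np.allclose(sorted(m.codebook_.ravel()), [0.0, 10.0], atol=0.01)

    def test_training_is_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        a = SelfOrganizingMap(3, 3, random_state=7, dtype=np.float64).fit(X)
        b = SelfOrganizingMap(3, 3, random_state=7, dtype=np.float64).fit(X)
        assert np.array_equal(a.codebook_, b.codebook_)

    def test_zero_mass_neurons_keep_weights_under_bubble(self):
        # two far-apart neurons, bubble radius < grid distance: the neuron
        # matching no sample keeps its initial weights
        X = np.array([[0.0]])
        m = SelfOrganizingMap(1, 2, kernel="bubble", radius_initial=0.5,
                              radius_final=0.5, n_epochs_rough=1,
                              n_epochs_fine=0, dtype=np.float64)
        codebook = np.array([[0.0], [99.0]])
        out = m._batch_epoch(codebook, X, m.grid_distances(), 0.5)
        assert out[1, 0] == 99.0

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            SelfOrganizingMap(2, 2).fit(np.empty((0, 3)))

    def test_quantization_error_not_above_random_init(self):
        """Over 10 seeds, batch training from random initial codebooks never
        leaves the data worse-quantized than at initialization (at most one
        seed may violate; batch SOM is not strictly monotone)."""
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.3, (15, 4)),
                       rng.normal(3, 0.3, (15, 4))])
        violations = 0
        for seed in range(10):
            m = SelfOrganizingMap(4, 3, init="uniform_random",
                                  dtype=np.float64, random_state=seed).fit(X)
            q0 = _quantization_error(m.initial_codebook_, X)
            violations += m.quantization_error(X) > q0
        assert violations <= 1


class TestSequentialTraining:
    def test_sequential_mode_converges_and_is_seeded(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.2, (10, 2)),
                       rng.normal(4, 0.2, (10, 2))])
        kw = dict(mode="sequential", radius_initial=1.5, radius_final=0.5,
                  n_epochs_rough=5, n_epochs_fine=15, dtype=np.float64)
        a = SelfOrganizingMap(2, 2, random_state=3, **kw).fit(X)
        b = SelfOrganizingMap(2, 2, random_state=3, **kw).fit(X)
        assert np.array_equal(a.codebook_, b.codebook_)
        assert a.quantization_errors_[-1] < 1.0

    def test_train_wrapper_respects_schedules(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        base = SelfOrganizingMap(2, 2, dtype=np.float64)
        fitted = train(base, X, RadiusSchedule(2.0, 1.0, 5), mode="sequential",
                       lr_schedule=LearningRateSchedule(0.4, 0.05), seed=1)
        assert fitted.trained
        assert len(fitted.quantization_errors_) == 5
        assert not base.trained  # wrapper trains a clone


class TestQuantizationError:
    def test_zero_when_every_sample_is_a_codebook_vector(self):
        m = init_model(2, 2, 2, seed=0)
        m.codebook_ = np.arange(8.0).reshape(4, 2)
        assert quantization_error(m, m.codebook_.copy()) == 0.0

    def test_hand_computed_mean_distance(self):
        m = init_model(1, 1, 1, seed=0)
        m.codebook_ = np.array([[1.0]])
        assert quantization_error(m, np.array([[0.0], [2.0]])) == 1.0

    def test_duplicated_sample_contributes_identically(self):
        m = init_model(2, 1, 1, seed=0)
        m.codebook_ = np.array([[0.0], [4.0]])
        base = quantization_error(m, np.array([[1.0]]))
        dup = quantization_error(m, np.array([[1.0], [1.0]]))
        assert dup == pytest.approx(base)

    def test_empty_data_raises(self):
        m = init_model(1, 1, 1, seed=0)
        with pytest.raises(ValueError):
            m.quantization_error(np.empty((0, 1)))


class TestTopology:
    def test_grid_neighbors_have_nearby_codebooks_on_ring_data(self):
        """Topology preservation: lattice-adjacent neurons map to nearby
        codebook vectors on noisy 2-D ring data."""
        rng = np.random.default_rng(2)
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ring = np.c_[np.cos(t), np.sin(t)] + rng.normal(0, 0.05, (200, 2))
        m = SelfOrganizingMap(5, 5, radius_initial=2.0, radius_final=0.7,
                              dtype=np.float64, random_state=2).fit(ring)
        W = m.codebook_
        gd = m.grid_distances()
        iu = np.triu_indices(m.n_neurons, 1)
        cd = np.linalg.norm(W[:, None, :] - W[None, :, :], axis=-1)[iu]
        adjacent = gd[iu] == 1
        assert cd[adjacent].mean() < cd.mean()


class TestSerialization:
    def test_save_load_round_trip_is_exact(self, tmp_path):
        X = np.random.default_rng(5).normal(size=(10, 4))
        m = SelfOrganizingMap(3, 2, dtype=np.float64, random_state=1).fit(X)
        path = m.save(tmp_path / "model.npz")
        back = SelfOrganizingMap.load(path)
        assert np.array_equal(back.codebook_, m.codebook_)
        assert back.get_params() == m.get_params()
        assert back.quantization_errors_ == m.quantization_errors_

    def test_sklearn_get_set_params_round_trip(self):
        m = SelfOrganizingMap(7, 7, radius_initial=3.0)
        clone = SelfOrganizingMap(**m.get_params())
        assert clone.get_params() == m.get_params()
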
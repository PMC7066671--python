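import numpy as np
import pytest

import voxdelta as vd
from voxdelta.errors import InsufficientDataError
from voxdelta.pair_network import (
    PairSample,
    TwinVoxelRegressor,
    build_pairs,
    build_test_pairs,
    predict_absolute,
)

from conftest import FAST_GRID, FAST_MODEL
from _oracles import naive_spearman


def _tiny_model(**over):
    params = dict(conv_channels=(2, 3), latent_dim=6, dropout=0.0,
                  learning_rate=3e-3, epochs=2, augment=False, random_state=0)
    params.update(over)
    return TwinVoxelRegressor(**params)


def _random_grids(n, seed, channels=18, size=8):
    rng = np.random.default_rng(seed)
    return rng.random((n, channels, size, size, size), dtype=np.float32)


class TestBuildPairs:
    def test_training_pair_count(self, small_series, small_grids):
        pairs = build_pairs(small_series.ligands[:4], small_grids)
        assert len(pairs) == 6  # n(n-1)/2

    def test_test_pair_count(self, small_series, small_grids):
        pairs = build_test_pairs(small_series.ligands[3:5],
                                 small_series.ligands[:3], small_grids)
        assert len(pairs) == 6  # n_test * n_train

    def test_label_is_delta_pic50(self, small_series, small_grids):
        a, b = small_series.ligands[0], small_series.ligands[1]
        a.affinity, b.affinity = 6.0, 8.0
        try:
            (pair,) = build_pairs([a, b], small_grids)
            assert pair.label == pytest.approx(-2.0)
            assert pair.swapped().label == pytest.approx(2.0)
        finally:
            # restore the session-scoped fixture
            spec = vd.ToySeriesSpec(n_ligands=8, noise_sigma=0.0, seed=11)
            a.affinity = vd.oracle_affinity(a, spec, small_series.protein)
            b.affinity = vd.oracle_affinity(b, spec, small_series.protein)

    def test_insufficient_ligands_rejected(self, small_series, small_grids):
        with pytest.raises(InsufficientDataError):
            build_pairs(small_series.ligands[:1], small_grids)


class TestZeroSymmetry:
    def test_forward_self_is_exactly_zero(self):
        model = _tiny_model()
        g = _random_grids(2, 0)
        model.fit([PairSample(g[0], g[1], 1.0)])
        assert model.forward_pair(g[0], g[0]) == 0.0

    def test_antisymmetry_random_weights(self):
        for seed in range(5):
            model = _tiny_model(random_state=seed)
            g = _random_grids(4, seed)
            model.fit([PairSample(g[0], g[1], 0.5)])
            f_ab = model.forward_pair(g[2], g[3])
            f_ba = model.forward_pair(g[3], g[2])
            assert abs(f_ab + f_ba) <= 1e-6

    def test_zero_head_predicts_zero(self):
        model = _tiny_model()
        g = _random_grids(2, 1)
        model.fit([PairSample(g[0], g[1], 1.0)])
        model.head_w_ = np.zeros_like(model.head_w_)
        assert model.forward_pair(g[0], g[1]) == 0.0


class TestEncode:
    def test_default_latent_dimension_is_192(self, small_series):
        grid = vd.voxelize(small_series, small_series.ligands[1])
        model = TwinVoxelRegressor(random_state=0)  # paper-default architecture
        rng = np.random.default_rng(0)
        model._init_state(in_channels=18, rng=rng)
        latent = model.encode(grid.values[None])
        assert latent.shape == (1, 192)

    def test_identical_grids_identical_latents(self, fitted_fast_model, small_grids):
        g = next(iter(small_grids.values()))
        l1 = fitted_fast_model.encode(g[None])
        l2 = fitted_fast_model.encode(g[None])
        np.testing.assert_array_equal(l1, l2)

    def test_zero_grid_finite_latent(self, fitted_fast_model):
        g = np.zeros((1, 18, 12, 12, 12), dtype=np.float32)
        latent = fitted_fast_model.encode(g)
        assert np.all(np.isfinite(latent))


class TestTraining:
    def test_loss_decreases_and_overfits_small_set(self, small_series, small_grids):
        pairs = build_pairs(small_series.ligands[:5], small_grids)  # 10 pairs
        model = TwinVoxelRegressor(**{**FAST_MODEL, "epochs": 40},
                                   random_state=3)
        model.fit(pairs)
        assert model.loss_curve_[-1] < model.loss_curve_[0]
        assert model.loss_curve_[-1] < 0.01  # pIC50^2

    def test_seeded_reruns_identical(self, small_series, small_grids):
        pairs = build_pairs(small_series.ligands[:4], small_grids)
        m1 = TwinVoxelRegressor(**FAST_MODEL, random_state=7).fit(pairs)
        m2 = TwinVoxelRegressor(**FAST_MODEL, random_state=7).fit(pairs)
        for k in m1.encoder_.params:
            np.testing.assert_array_equal(m1.encoder_.params[k],
                                          m2.encoder_.params[k])
        np.testing.assert_array_equal(m1.head_w_, m2.head_w_)

    def test_augmented_training_runs_and_differs(self, small_series, small_grids):
        pairs = build_pairs(small_series.ligands[:3], small_grids)
        base = dict(FAST_MODEL, epochs=2)
        plain = TwinVoxelRegressor(**base, random_state=1).fit(pairs)
        aug = TwinVoxelRegressor(**{**base, "augment": True},
                                 grid_spec=FAST_GRID, random_state=1)
        aug.fit(pairs, protein=small_series.protein,
                center=small_series.pocket_center)
        assert not np.array_equal(plain.head_w_, aug.head_w_)

    def test_nan_labels_rejected(self, small_grids):
        g = list(small_grids.values())
        with pytest.raises(ValueError):
            _tiny_model().fit([PairSample(g[0], g[1], float("nan"))])


class TestFineTune:
    def test_default_is_three_epochs(self, fitted_fast_model, small_series,
                                     small_grids):
        import copy

        model = copy.deepcopy(fitted_fast_model)
        n_before = len(model.loss_curve_)
        pairs = build_pairs(small_series.ligands[:3], small_grids)
        model.fine_tune(pairs)
        assert len(model.loss_curve_) == n_before + 3

    def test_empty_background_reduces_to_training_on_new(self, fitted_fast_model,
                                                         small_series, small_grids):
        import copy

        model = copy.deepcopy(fitted_fast_model)
        pairs = build_pairs(small_series.ligands[:3], small_grids)
        model.fine_tune(pairs, background_pairs=(), epochs=2)
        assert len(model.loss_curve_) == len(fitted_fast_model.loss_curve_) + 2

    def test_antisymmetry_preserved_after_fine_tuning(self, fitted_fast_model,
                                                      small_series, small_grids):
        import copy

        model = copy.deepcopy(fitted_fast_model)
        pairs = build_pairs(small_series.ligands[:4], small_grids)
        model.fine_tune(pairs, epochs=1)
        g = list(small_grids.values())
        assert abs(model.forward_pair(g[0], g[1])
                   + model.forward_pair(g[1], g[0])) <= 1e-6

    def test_requires_fitted_model(self):
        with pytest.raises(RuntimeError):
            _tiny_model().fine_tune([], epochs=1)


class TestPredictAbsolute:
    def test_single_reference(self):
        est = predict_absolute("x", [(7.0, 1.0)])
        assert est.mu == 8.0 and est.sigma == 0.0 and est.n_references == 1

    def test_consistent_references_zero_sigma(self):
        est = predict_absolute("x", [(6.0, 2.0), (8.0, 0.0)])
        assert est.mu == 8.0 and est.sigma == 0.0

    def test_spread_references(self):
        est = predict_absolute("x", [(6.0, 1.0), (8.0, 1.0)])
        assert est.mu == 8.0 and est.sigma == 1.0

    def test_zero_references_error(self):
        with pytest.raises(InsufficientDataError):
            predict_absolute("x", [])

    def test_perfect_deltas_recover_truth(self, small_series):
        truth = {l.id: l.affinity for l in small_series.ligands}
        test = small_series.ligands[5]
        refs = [(truth[r.id], truth[test.id] - truth[r.id])
                for r in small_series.ligands[:4]]
        est = predict_absolute(test.id, refs)
        assert est.mu == pytest.approx(truth[test.id], abs=1e-12)
        assert est.sigma == pytest.approx(0.0, abs=1e-12)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, fitted_fast_model, small_grids):
        path = tmp_path / "model.npz"
        fitted_fast_model.save(path)
        loaded = TwinVoxelRegressor.load(path)
        g = list(small_grids.values())
        assert loaded.forward_pair(g[0], g[1]) == pytest.approx(
            fitted_fast_model.forward_pair(g[0], g[1]), abs=1e-7)


class TestRankingRecovery:
    def test_held_out_delta_spearman(self):
        """Trained on half of a noisy 40-ligand series, the network should
        rank held-out deltas (Spearman >= 0.5) in at least 8 of 10 seeds."""
        pocket = vd.make_toy_pocket(21)
        series = vd.make_series(
            vd.ToySeriesSpec(n_ligands=40, noise_sigma=0.3, seed=21), pocket)
        grids = {l.id: vd.voxelize(pocket, l, center=series.pocket_center,
                                   spec=FAST_GRID).values.astype(np.float32)
                 for l in series.ligands}
        train, test = series.ligands[:20], series.ligands[20:]
        pairs = build_pairs(train, grids)
        exp = [t.affinity - r.affinity for t in test for r in train]
        hits = 0
        for seed in range(10):
            model = TwinVoxelRegressor(**FAST_MODEL, random_state=seed).fit(pairs)
            delta = model.predict_delta_matrix(
                [grids[t.id] for t in test], [grids[r.id] for r in train])
            rho = naive_spearman(list(delta.ravel()), exp)
            hits += rho >= 0.5
        assert hits >= 8
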
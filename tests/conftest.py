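import numpy as np
import pytest

import voxdelta as vd

# Desk-scale model configuration used wherever a network must actually be
# trained in the suite: coarser 2 A grid, small filter counts, dropout off,
# higher learning rate, few epochs.  Architecture-constant checks use the
# full default configuration instead.
FAST_MODEL = dict(
    conv_channels=(8, 16),
    latent_dim=48,
    dropout=0.0,
    learning_rate=3e-3,
    batch_size=32,
    epochs=8,
    augment=False,
)

FAST_GRID = vd.GridSpec(edge=24.0, resolution=2.0)


@pytest.fixture(scope="session")
def pocket():
    return vd.make_toy_pocket(seed=0)


@pytest.fixture(scope="session")
def small_series(pocket):
    """8 noise-free ligands: quick to voxelize, deterministic affinities."""
    spec = vd.ToySeriesSpec(n_ligands=8, noise_sigma=0.0, seed=11)
    return vd.make_series(spec, pocket)


@pytest.fixture(scope="session")
def small_grids(small_series):
    return {
        lig.id: vd.voxelize(
            small_series.protein, lig, center=small_series.pocket_center,
            spec=FAST_GRID).values.astype(np.float32)
        for lig in small_series.ligands
    }


@pytest.fixture(scope="session")
def fitted_fast_model(small_series, small_grids):
    pairs = vd.build_pairs(small_series.ligands, small_grids)
    model = vd.TwinVoxelRegressor(random_state=0, **FAST_MODEL)
    return model.fit(pairs)
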
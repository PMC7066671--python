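"""The zero-symmetric twin 3D-CNN for relative potency prediction.

Both legs share one convolutional encoder; each input grid is reduced to a
192-dimensional latent vector and the prediction is a bias-free linear map of
the latent *difference*,

    f(a, b) = w . (enc(a) - enc(b)),

so f(a, b) = -f(b, a) and f(a, a) = 0 hold exactly by construction, matching
the antisymmetry of relative binding affinity.  Training minimizes the mean
squared error of predicted vs. labelled delta-pIC50 over ligand pairs with
Adam, optionally re-voxelizing each pair under a fresh random rotation every
epoch (data augmentation).

The estimator follows scikit-learn conventions (``get_params``/``set_params``,
``fit``/``predict``, fitted attributes with a trailing underscore).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nnet
from .errors import InsufficientDataError
from .voxelizer import GridSpec, VoxelGrid, random_rotation, voxelize

logger = logging.getLogger(__name__)


@dataclass
class PairSample:
    """An ordered ligand pair with label delta-pIC50 = pIC50(a) - pIC50(b).

    ``grid_a``/``grid_b`` are channel-first occupancy tensors; ``lig_a``/
    ``lig_b`` optionally keep the underlying poses so training can re-voxelize
    under random rotations.
    """

    grid_a: np.ndarray
    grid_b: np.ndarray
    label: float
    id_a: str = "a"
    id_b: str = "b"
    lig_a: object = field(default=None, repr=False)
    lig_b: object = field(default=None, repr=False)

    def swapped(self) -> "PairSample":
        return PairSample(self.grid_b, self.grid_a, -self.label,
                          self.id_b, self.id_a, self.lig_b, self.lig_a)


@dataclass
class AbsoluteEstimate:
    """MAP absolute-affinity estimate for one ligand against known references."""

    ligand_id: str
    mu: float
    sigma: float
    n_references: int


def _grid_values(grid) -> np.ndarray:
    return grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid)


def build_pairs(ligands: Sequence, grids: dict) -> list:
    """All unordered pairs among affinity-labelled ligands, canonical order.

    Pair (i, j) with i earlier in the series carries label
    pIC50(i) - pIC50(j); n labelled ligands yield n(n-1)/2 samples.  The
    mirrored pair is redundant because the network is exactly antisymmetric.
    """
    known = [l for l in ligands if l.affinity is not None]
    if len(known) < 2:
        raise InsufficientDataError(
            f"need >=2 ligands with known affinity, got {len(known)}"
        )
    pairs = []
    for i in range(len(known)):
        for j in range(i + 1, len(known)):
            a, b = known[i], known[j]
            pairs.append(
                PairSample(_grid_values(grids[a.id]), _grid_values(grids[b.id]),
                           a.affinity - b.affinity, a.id, b.id, a, b)
            )
    return pairs


def build_test_pairs(test_ligands: Sequence, train_ligands: Sequence,
                     grids: dict) -> list:
    """Every ordered (test, train) pair: n_test * n_train samples."""
    pairs = []
    for t in test_ligands:
        for r in train_ligands:
            label = (t.affinity - r.affinity
                     if t.affinity is not None and r.affinity is not None
                     else np.nan)
            pairs.append(
                PairSample(_grid_values(grids[t.id]), _grid_values(grids[r.id]),
                           label, t.id, r.id, t, r)
            )
    return pairs


def predict_absolute(ligand_id: str, references: Sequence) -> AbsoluteEstimate:
    """Reconstruct an absolute affinity from per-reference delta predictions.

    ``references`` holds (reference pIC50, predicted delta(test - ref)) tuples.
    The per-reference estimates ref + delta form a distribution whose mean is
    the MAP absolute estimate and whose population standard deviation is its
    uncertainty (zero with a single reference).
    """
    if len(references) == 0:
        raise InsufficientDataError("predict_absolute requires >=1 reference")
    estimates = np.array([p + d for p, d in references], dtype=float)
    return AbsoluteEstimate(
        ligand_id=ligand_id,
        mu=float(estimates.mean()),
        sigma=float(estimates.std(ddof=0)),
        n_references=len(estimates),
    )


class TwinVoxelRegressor(BaseEstimator, RegressorMixin):
    """Twin 3D-CNN regressor for delta-pIC50 between posed ligand pairs.

    Parameters
    ----------
    conv_channels : tuple of int
        Filter counts of the first two convolutions (the third equals
        ``latent_dim``).
    latent_dim : int
        Size of the flattened per-leg latent representation.
    dropout : float
        Dropout rate applied to each leg's latent during training
        (independent masks per leg).
    learning_rate, beta1, beta2, eps : float
        Adam hyperparameters (``eps`` is the Adam epsilon).
    batch_size, epochs : int
        Mini-batch size (in pairs) and number of passes over the pairs.
    augment : bool
        Re-voxelize each pair under a fresh uniform random rotation every
        epoch (applied identically to both grids of a pair).  Requires pairs
        carrying ligand poses and a fitted ``grid_spec``/protein context.
    random_state : int or None
        Seed for weight initialization, shuffling, rotations and dropout.

    Attributes
    ----------
    encoder_ : nnet.Encoder
        The shared-weight convolutional leg (tied across both inputs).
    head_w_ : ndarray of shape (latent_dim,)
        Bias-free linear head applied to the latent difference.
    loss_curve_ : list of float
        Mean training MSE per epoch.
    """

    def __init__(self, conv_channels=(32, 64), latent_dim=192, dropout=0.5,
                 learning_rate=1e-4, batch_size=32, epochs=50,
                 beta1=0.9, beta2=0.999, eps=1e-4, augment=True,
                 grid_spec=None, random_state=None, dtype="float32", verbose=0):
        self.conv_channels = conv_channels
        self.latent_dim = latent_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.augment = augment
        self.grid_spec = grid_spec
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # ------------------------------------------------------------------ setup

    def _init_state(self, in_channels: int, rng) -> None:
        self.encoder_ = nnet.Encoder(
            in_channels=in_channels, conv_channels=self.conv_channels,
            latent_dim=self.latent_dim, rng=rng, dtype=np.dtype(self.dtype))
        self.head_w_ = nnet.xavier_uniform(
            (self.latent_dim,), self.latent_dim, 1, rng, np.dtype(self.dtype))
        self.optimizer_ = nnet.Adam(lr=self.learning_rate, beta1=self.beta1,
                                    beta2=self.beta2, eps=self.eps)
        self.loss_curve_: list = []

    @staticmethod
    def _as_pairs(X, y=None) -> list:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], PairSample):
            return list(X)
        arr = np.asarray(X)
        if arr.ndim == 6 and arr.shape[1] == 2:  # [n, 2, C, D, H, W]
            if y is None:
                y = np.full(arr.shape[0], np.nan)
            return [PairSample(arr[i, 0], arr[i, 1], float(y[i]), f"a{i}", f"b{i}")
                    for i in range(arr.shape[0])]
        raise ValueError(
            "X must be a list of PairSample or an array [n, 2, C, D, H, W]")

    # --------------------------------------------------------------- training

    def _epoch_grids(self, pairs, protein, center, rng):
        """Per-epoch grid tensors with optional rotation augmentation.

        Returns (unique_grids [U, C, D, H, W], idx_a, idx_b): pairs sharing a
        grid object map to the same row, so each unique grid is encoded once
        per mini-batch.
        """
        augmenting = (self.augment and protein is not None
                      and all(p.lig_a is not None and p.lig_b is not None
                              for p in pairs))
        if augmenting:
            spec = self.grid_spec or GridSpec()
            grids, idx_a, idx_b = [], [], []
            for p in pairs:
                rot = random_rotation(rng)
                for lig, idx in ((p.lig_a, idx_a), (p.lig_b, idx_b)):
                    g = voxelize(protein, lig, center=center, rotation=rot,
                                 spec=spec).values
                    idx.append(len(grids))
                    grids.append(g)
            return np.asarray(grids, dtype=self.dtype), np.array(idx_a), np.array(idx_b)
        # Deduplicate by underlying array identity (grids reused across pairs).
        uniq: dict = {}
        grids = []
        idx_a, idx_b = [], []
        for p in pairs:
            for g, idx in ((p.grid_a, idx_a), (p.grid_b, idx_b)):
                key = id(g)
                if key not in uniq:
                    uniq[key] = len(grids)
                    grids.append(np.asarray(g, dtype=self.dtype))
                idx.append(uniq[key])
        return np.asarray(grids), np.array(idx_a), np.array(idx_b)

    def fit(self, X, y=None, protein=None, center=None, epochs=None):
        """Train on delta-pIC50-labelled pairs.

        ``X`` is a list of :class:`PairSample` (or an array
        ``[n, 2, C, D, H, W]`` with labels ``y``).  ``protein``/``center``
        enable rotation augmentation by re-voxelization.
        """
        pairs = self._as_pairs(X, y)
        if not pairs:
            raise InsufficientDataError("no training pairs")
        rng = np.random.default_rng(self.random_state)
        in_channels = np.asarray(pairs[0].grid_a).shape[0]
        self._init_state(in_channels, rng)
        self._run_epochs(pairs, epochs or self.epochs, rng, protein, center)
        self.n_pairs_ = len(pairs)
        return self

    def fine_tune(self, new_pairs, background_pairs=(), epochs: int = 3,
                  protein=None, center=None):
        """Continue optimization on new + background pairs for ``epochs``
        passes (default 3), from the current weights and optimizer state."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("fine_tune requires a fitted model")
        pairs = list(new_pairs) + list(background_pairs)
        if not pairs:
            raise InsufficientDataError("no pairs to fine-tune on")
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1)
        self._run_epochs(pairs, epochs, rng, protein, center)
        return self

    def _run_epochs(self, pairs, epochs, rng, protein, center):
        labels_all = np.array([p.label for p in pairs], dtype=self.dtype)
        if not np.all(np.isfinite(labels_all)):
            raise ValueError("pair labels must be finite for training")
        for epoch in range(epochs):
            grids, idx_a, idx_b = self._epoch_grids(pairs, protein, center, rng)
            order = rng.permutation(len(pairs))
            losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                loss = self._step(grids, idx_a[batch], idx_b[batch],
                                  labels_all[batch], rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch {start // self.batch_size}: {loss}")
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
            if self.verbose:
                logger.info("epoch %d: MSE %.5f", epoch, self.loss_curve_[-1])

    def _step(self, grids, idx_a, idx_b, labels, rng) -> float:
        """One Adam step on a mini-batch of pairs; unique grids encoded once."""
        used = np.unique(np.concatenate([idx_a, idx_b]))
        remap = {g: i for i, g in enumerate(used)}
        ia = np.array([remap[g] for g in idx_a])
        ib = np.array([remap[g] for g in idx_b])
        latents, cache = self.encoder_.forward(grids[used], want_cache=True)

        mask_a = nnet.dropout_mask((len(ia), self.latent_dim), self.dropout,
                                   rng, latents.dtype)
        mask_b = nnet.dropout_mask((len(ib), self.latent_dim), self.dropout,
                                   rng, latents.dtype)
        la = latents[ia] * mask_a
        lb = latents[ib] * mask_b
        diff = la - lb
        pred = diff @ self.head_w_
        err = pred - labels
        loss = float(np.mean(err**2))

        dpred = (2.0 / len(labels)) * err
        dhead = diff.T @ dpred
        ddiff = dpred[:, None] * self.head_w_[None, :]
        dlat = np.zeros_like(latents)
        np.add.at(dlat, ia, ddiff * mask_a)
        np.add.at(dlat, ib, -ddiff * mask_b)
        grads = self.encoder_.backward(dlat, cache)
        grads["head_w"] = dhead.astype(latents.dtype)

        params = dict(self.encoder_.params)
        params["head_w"] = self.head_w_
        self.optimizer_.step(params, grads)
        self.head_w_ = params["head_w"]
        return loss

    # -------------------------------------------------------------- inference

    def encode(self, grids, batch_size: int = 16) -> np.ndarray:
        """Deterministic (dropout-off) latents for grids [n, C, D, H, W]."""
        grids = np.asarray(grids, dtype=self.dtype)
        if grids.ndim == 4:
            grids = grids[None]
        out = [self.encoder_.forward(grids[sl])
               for sl in nnet._chunks(len(grids), batch_size)]
        return np.concatenate(out, axis=0)

    def forward_pair(self, grid_a, grid_b) -> float:
        """Predicted delta-pIC50 for one ordered pair (eval mode)."""
        latents = self.encode(np.stack([np.asarray(grid_a, dtype=self.dtype),
                                        np.asarray(grid_b, dtype=self.dtype)]))
        return float((latents[0] - latents[1]) @ self.head_w_)

    def predict(self, X) -> np.ndarray:
        """Predicted delta-pIC50 for each pair in ``X``."""
        pairs = self._as_pairs(X)
        grids, idx_a, idx_b = self._epoch_grids(pairs, None, None, None)
        latents = self.encode(grids)
        return np.asarray((latents[idx_a] - latents[idx_b]) @ self.head_w_,
                          dtype=float)

    def predict_delta_matrix(self, grids_test, grids_ref) -> np.ndarray:
        """Delta predictions for every (test, ref) combination, shape (t, r).

        Encodes each grid exactly once; equivalent to predicting all t*r
        ordered pairs.
        """
        lt = self.encode(np.asarray(grids_test, dtype=self.dtype))
        lr = self.encode(np.asarray(grids_ref, dtype=self.dtype))
        return np.asarray((lt @ self.head_w_)[:, None] - (lr @ self.head_w_)[None, :],
                          dtype=float)

    # ------------------------------------------------------------- checkpoint

    def save(self, path) -> None:
        """Write weights + configuration to an .npz checkpoint."""
        arrays = {f"enc_{k}": v for k, v in self.encoder_.params.items()}
        arrays["head_w"] = self.head_w_
        config = json.dumps({"params": self.get_params(deep=False),
                             "in_channels": self.encoder_.in_channels},
                            default=str)
        np.savez(path, __config__=np.frombuffer(config.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TwinVoxelRegressor":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            params = config["params"]
            for key in ("conv_channels",):
                if isinstance(params.get(key), str):
                    params[key] = tuple(
                        int(x) for x in params[key].strip("()").split(",") if x.strip())
            if isinstance(params.get("grid_spec"), str) and params["grid_spec"] != "None":
                params["grid_spec"] = None
            if params.get("grid_spec") == "None":
                params["grid_spec"] = None
            if isinstance(params.get("random_state"), str):
                params["random_state"] = (None if params["random_state"] == "None"
                                          else int(params["random_state"]))
            model = cls(**params)
            rng = np.random.default_rng(0)
            model._init_state(config["in_channels"], rng)
            for k in model.encoder_.params:
                model.encoder_.params[k] = data[f"enc_{k}"]
            model.head_w_ = data["head_w"]
        return model


def train(pairs, seed=None, epochs=50, augment=True, protein=None, center=None,
          **model_params) -> TwinVoxelRegressor:
    """Functional wrapper: fit a :class:`TwinVoxelRegressor` on pairs."""
    model = TwinVoxelRegressor(epochs=epochs, augment=augment,
                               random_state=seed, **model_params)
    return model.fit(pairs, protein=protein, center=center)


def fine_tune(model: TwinVoxelRegressor, new_pairs, background_pairs=(),
              epochs: int = 3, **kwargs) -> TwinVoxelRegressor:
    """Functional wrapper around :meth:`TwinVoxelRegressor.fine_tune`."""
    return model.fine_tune(new_pairs, background_pairs, epochs=epochs, **kwargs)
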
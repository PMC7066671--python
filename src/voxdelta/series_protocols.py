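"""Series preprocessing, evaluation splits, metrics, continuous learning.

Covers affinity unit conversion to pIC50, reference-ligand selection and
de-duplication via maximum common substructure (MCS), the three train/test
split schemes (random, temporal, ECFP4-similarity), delta-pIC50 metrics, and
the incremental train/predict loop that emulates a live lead-optimization
campaign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UnitError

logger = logging.getLogger(__name__)

#: Gas constant in kcal mol^-1 K^-1 and reference temperature in K used for
#: the Gibbs-energy -> pIC50 conversion (assumes IC50 ~ Kd, i.e.
#: non-competitive binding).
GAS_CONSTANT_KCAL = 1.9872e-3
TEMPERATURE_K = 298.15

AFFINITY_UNITS = ("pIC50", "IC50_molar", "IC50_uM", "IC50_nM", "dG_kcal_per_mol")


def convert_affinity(value: float, unit: str = "pIC50") -> float:
    """Convert an affinity reading to pIC50 (= -log10 IC50 [M]).

    Gibbs energies (kcal/mol) convert via pIC50 = -dG / (ln10 * R * T) at
    T = 298.15 K.  IC50 values must be positive.
    """
    if unit == "pIC50":
        return float(value)
    if unit in ("IC50_molar", "IC50_uM", "IC50_nM"):
        scale = {"IC50_molar": 1.0, "IC50_uM": 1e-6, "IC50_nM": 1e-9}[unit]
        molar = value * scale
        if molar <= 0:
            raise UnitError(f"IC50 must be positive, got {value} {unit}")
        return float(-math.log10(molar))
    if unit == "dG_kcal_per_mol":
        return float(-value / (math.log(10) * GAS_CONSTANT_KCAL * TEMPERATURE_K))
    raise UnitError(f"unknown affinity unit {unit!r}; expected one of {AFFINITY_UNITS}")


# ---------------------------------------------------------------------- MCS


def _heavy_mol(lig):
    from rdkit import Chem

    if lig.mol is None:
        raise ValueError(f"ligand {lig.id} carries no rdkit Mol (needed for MCS)")
    return Chem.RemoveHs(lig.mol, sanitize=False)


def mcs_size(lig_a, lig_b, timeout: int = 10) -> int:
    """Heavy-atom count of the maximum common substructure of two ligands."""
    from rdkit.Chem import rdFMCS

    res = rdFMCS.FindMCS([_heavy_mol(lig_a), _heavy_mol(lig_b)], timeout=timeout)
    return int(res.numAtoms)


def mcs_distance(lig_a, lig_b) -> float:
    """1 - |MCS| / max(heavy atom counts): symmetric, bounded in [0, 1]."""
    na = _heavy_mol(lig_a).GetNumAtoms()
    nb = _heavy_mol(lig_b).GetNumAtoms()
    return 1.0 - mcs_size(lig_a, lig_b) / max(na, nb)


def select_reference(series):
    """The series' reference ligand for delta anchoring.

    The crystal-structure ligand when flagged; otherwise the ligand with the
    lowest mean MCS distance to the rest (ties broken by series order).
    """
    ligands = series.ligands if hasattr(series, "ligands") else list(series)
    if not ligands:
        raise InsufficientDataError("empty series")
    for lig in ligands:
        if lig.is_crystal_reference:
            return lig
    if len(ligands) == 1:
        return ligands[0]
    best, best_mean = ligands[0], np.inf
    for lig in ligands:
        dists = [mcs_distance(lig, other) for other in ligands if other is not lig]
        mean = float(np.mean(dists))
        if mean < best_mean - 1e-12:
            best, best_mean = lig, mean
    return best


def dedup_ligands(series_group: Sequence):
    """Drop repeated ligands across series sharing one target cluster.

    A ligand is a repeat when its MCS with an already-kept ligand covers all
    heavy atoms of both molecules; the first occurrence is kept.  Returns new
    series objects with filtered ligand lists.
    """
    from .chem_io import CongenericSeries

    kept: list = []
    out = []
    for series in series_group:
        filtered = []
        for lig in series.ligands:
            n_lig = _heavy_mol(lig).GetNumAtoms()
            duplicate = False
            for ref in kept:
                n_ref = _heavy_mol(ref).GetNumAtoms()
                if n_lig == n_ref and mcs_size(lig, ref) == n_lig:
                    duplicate = True
                    break
            if duplicate:
                logger.info("dropping duplicate ligand %s", lig.id)
            else:
                kept.append(lig)
                filtered.append(lig)
        out.append(CongenericSeries(protein=series.protein, ligands=filtered,
                                    pocket_center=series.pocket_center))
    return out


# -------------------------------------------------------------------- splits


@dataclass(frozen=True)
class SplitScheme:
    """Train/test split scheme: random, temporal, or ECFP4-similarity."""

    kind: str = "random"
    seed: int = 0
    n_initial: int = 1

    def __post_init__(self):
        if self.kind not in ("random", "temporal", "similarity"):
            raise ValueError(f"unknown split kind {self.kind!r}")


def ecfp4_fingerprint(lig):
    """ECFP4 (Morgan radius 2, 2048 bits) fingerprint of a ligand."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = _heavy_mol(lig)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return gen.GetFingerprint(mol)


def split_series(series, scheme: SplitScheme, n: int):
    """Partition a series into (train ids, test ids) with |train| = n.

    random: seeded shuffle; temporal: n earliest timestamps train; similarity:
    greedy growth from the reference by highest ECFP4 Tanimoto similarity to
    any train member (ties broken by series order).
    """
    ligands = series.ligands
    size = len(ligands)
    if not 1 <= n < size:
        raise ValueError(f"need 1 <= n < series size ({size}), got n={n}")
    ids = [l.id for l in ligands]

    if scheme.kind == "random":
        rng = np.random.default_rng(scheme.seed)
        order = rng.permutation(size)
        train = [ids[i] for i in order[:n]]
    elif scheme.kind == "temporal":
        if any(l.timestamp is None for l in ligands):
            raise ValueError("temporal split requires timestamps on all ligands")
        order = sorted(range(size), key=lambda i: (ligands[i].timestamp, i))
        train = [ids[i] for i in order[:n]]
    else:  # similarity
        from rdkit import DataStructs

        fps = [ecfp4_fingerprint(l) for l in ligands]
        ref = select_reference(series)
        train_idx = [ids.index(ref.id)]
        remaining = [i for i in range(size) if i != train_idx[0]]
        while len(train_idx) < n:
            best_i, best_sim = None, -1.0
            for i in remaining:
                sim = max(DataStructs.TanimotoSimilarity(fps[i], fps[j])
                          for j in train_idx)
                if sim > best_sim + 1e-12:
                    best_i, best_sim = i, sim
            train_idx.append(best_i)
            remaining.remove(best_i)
        train = [ids[i] for i in train_idx]

    train_set = set(train)
    test = [i for i in ids if i not in train_set]
    return train, test


# ------------------------------------------------------------------- metrics


def evaluate_step(predicted, experimental):
    """(RMSE, Pearson R, Spearman rho) between delta-pIC50 vectors.

    Correlations are NaN (not silently zero) when either vector is constant
    or shorter than 2.
    """
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise ValueError("prediction/experiment length mismatch")
    if predicted.size < 1:
        raise ValueError("need at least one value for RMSE")
    rmse = float(np.sqrt(np.mean((predicted - experimental) ** 2)))
    if (predicted.size < 2 or np.ptp(predicted) == 0 or np.ptp(experimental) == 0):
        return rmse, float("nan"), float("nan")
    pearson = float(stats.pearsonr(experimental, predicted).statistic)
    spearman = float(stats.spearmanr(experimental, predicted).statistic)
    return rmse, pearson, spearman


# ------------------------------------------------- continuous-learning loop


@dataclass
class MetricTrajectory:
    """Per-step metric records of a continuous-learning run."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean +/- std of each metric over seeds, per training-set size."""
        return (self.records
                .groupby("n_train")[["rmse", "pearson_r", "spearman_rho"]]
                .agg(["mean", "std"]))


def continuous_learning_run(
    series,
    scheme_kind: str = "temporal",
    schedule: Sequence[int] = (1, 2, 5, 10, 20),
    seeds: Sequence[int] = (0,),
    model_params: Optional[dict] = None,
    grid_spec=None,
    pretrained=None,
    fine_tune_epochs: int = 3,
    pair_mode: str = "all",
) -> MetricTrajectory:
    """Incremental train/test over a growing known set, per the campaign loop.

    For each seed and each n in ``schedule``: split the series, train on all
    delta pairs among the n known ligands (or fine-tune a pretrained
    checkpoint for ``fine_tune_epochs`` passes), predict test-vs-train deltas
    and score them.  ``pair_mode`` "all" scores every (test, train) pair
    (n_test * n_train predictions); "reference" scores test ligands against
    the first train ligand only.
    """
    from .pair_network import TwinVoxelRegressor, build_pairs
    from .voxelizer import GridSpec, voxelize

    if len(series.ligands) < 3:
        raise InsufficientDataError("continuous learning needs >=3 ligands")
    model_params = dict(model_params or {})
    spec = grid_spec or GridSpec()
    grids = {lig.id: voxelize(series.protein, lig, center=series.pocket_center,
                              spec=spec).values.astype(np.float32)
             for lig in series.ligands}
    affinities = {lig.id: lig.affinity for lig in series.ligands}
    ligand_by_id = {lig.id: lig for lig in series.ligands}

    rows = []
    for seed in seeds:
        child = np.random.SeedSequence(seed).generate_state(2)
        for n in schedule:
            if n >= len(series.ligands):
                logger.warning("schedule step n=%d >= series size; skipped", n)
                continue
            scheme = SplitScheme(kind=scheme_kind, seed=int(child[0]) % (2**31))
            train_ids, test_ids = split_series(series, scheme, n)
            train_ligs = [ligand_by_id[i] for i in train_ids]
            test_ligs = [ligand_by_id[i] for i in test_ids]

            model_seed = int(child[1]) % (2**31)
            if pretrained is not None:
                import copy
                model = copy.deepcopy(pretrained)
                if n >= 2:
                    pairs = build_pairs(train_ligs, grids)
                    model.fine_tune(pairs, epochs=fine_tune_epochs)
            else:
                if n < 2:
                    logger.warning(
                        "n=%d gives no training pairs and no pretrained model; "
                        "skipped", n)
                    continue
                pairs = build_pairs(train_ligs, grids)
                model = TwinVoxelRegressor(random_state=model_seed,
                                           grid_spec=spec, **model_params)
                model.fit(pairs, protein=series.protein,
                          center=series.pocket_center)

            ref_ids = train_ids if pair_mode == "all" else train_ids[:1]
            delta = model.predict_delta_matrix(
                [grids[i] for i in test_ids], [grids[i] for i in ref_ids])
            exp = np.array([[affinities[t] - affinities[r] for r in ref_ids]
                            for t in test_ids])
            rmse, pearson, spearman = evaluate_step(delta.ravel(), exp.ravel())
            rows.append(dict(seed=seed, n_train=n, n_test=len(test_ids),
                             rmse=rmse, pearson_r=pearson, spearman_rho=spearman))
    return MetricTrajectory(records=pd.DataFrame(rows))
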
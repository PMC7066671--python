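import math

import numpy as np
import pytest

import voxdelta as vd
from voxdelta.chem_io import CongenericSeries, LigandPose
from voxdelta.errors import UnitError
from voxdelta.series_protocols import SplitScheme, mcs_size

from conftest import FAST_GRID, FAST_MODEL
from _oracles import naive_pearson, naive_rmse, naive_spearman


def _pose_from_smiles(smiles, lig_id, crystal=False, timestamp=None):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=4)
    mol = Chem.RemoveHs(mol)
    mol.SetProp("_Name", lig_id)
    conf = mol.GetConformer()
    return LigandPose(
        id=lig_id,
        elements=np.array([a.GetSymbol() for a in mol.GetAtoms()], dtype=object),
        coords=np.asarray(conf.GetPositions()),
        affinity=5.0,
        timestamp=timestamp,
        is_crystal_reference=crystal,
        mol=mol,
    )


class TestConvertAffinity:
    @pytest.mark.parametrize("ic50,expected", [(1e-6, 6.0), (1e-8, 8.0), (1.0, 0.0)])
    def test_ic50_molar(self, ic50, expected):
        assert vd.convert_affinity(ic50, "IC50_molar") == pytest.approx(expected)

    def test_pic50_passthrough(self):
        assert vd.convert_affinity(7.3, "pIC50") == 7.3

    def test_gibbs_energy(self):
        # ln10 * R * T = 1.3637 kcal/mol at 298.15 K
        assert vd.convert_affinity(-1.3637, "dG_kcal_per_mol") == pytest.approx(
            1.000, abs=5e-4)

    def test_strictly_monotone_and_invertible(self):
        ic50 = np.logspace(-12, 0, 50)
        p = [vd.convert_affinity(v, "IC50_molar") for v in ic50]
        assert all(a > b for a, b in zip(p, p[1:]))
        back = 10 ** (-np.array(p))
        np.testing.assert_allclose(back, ic50, rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(UnitError):
            vd.convert_affinity(-1.0, "IC50_molar")
        with pytest.raises(UnitError):
            vd.convert_affinity(1.0, "parsecs")


class TestSelectReference:
    def test_crystal_flag_wins(self, small_series):
        assert vd.select_reference(small_series).is_crystal_reference

    def test_identical_ligands_tie_break_first(self):
        ligs = [_pose_from_smiles("CCO", f"l{i}") for i in range(3)]
        assert vd.select_reference(ligs) is ligs[0]

    def test_three_ligand_mcs_tie(self):
        # CCO/CCN/CCC: every pair shares the 2-atom C-C substructure, so all
        # mean MCS distances are equal and the first ligand wins the tie.
        ligs = [_pose_from_smiles(s, f"l{i}")
                for i, s in enumerate(["CCO", "CCN", "CCC"])]
        for a in range(3):
            for b in range(a + 1, 3):
                assert mcs_size(ligs[a], ligs[b]) == 2
        assert vd.select_reference(ligs) is ligs[0]


class TestDedup:
    def _series(self, smiles_list, tag):
        pocket = vd.make_toy_pocket(0, n_atoms=30)
        ligs = [_pose_from_smiles(s, f"{tag}{i}") for i, s in enumerate(smiles_list)]
        return CongenericSeries(protein=pocket, ligands=ligs,
                                pocket_center=np.zeros(3))

    def test_repeat_across_series_removed(self):
        s1 = self._series(["CCO", "CCN"], "a")
        s2 = self._series(["CCO", "CCCC"], "b")
        out = vd.dedup_ligands([s1, s2])
        assert [l.id for l in out[0].ligands] == ["a0", "a1"]
        assert [l.id for l in out[1].ligands] == ["b1"]

    def test_disjoint_sets_unchanged(self):
        s1 = self._series(["CCO"], "a")
        s2 = self._series(["CCCl"], "b")
        out = vd.dedup_ligands([s1, s2])
        assert len(out[0].ligands) == 1 and len(out[1].ligands) == 1

    def test_three_copies_two_uniques(self):
        s = self._series(["CCO", "CCO", "CCO", "CCN", "CCCC"], "x")
        (out,) = vd.dedup_ligands([s])
        assert len(out.ligands) == 3


class TestSplitSeries:
    @pytest.mark.parametrize("kind", ["random", "temporal", "similarity"])
    @pytest.mark.parametrize("n", [1, 3, 7])
    def test_partition_property(self, small_series, kind, n):
        train, test = vd.split_series(small_series, SplitScheme(kind=kind, seed=1), n)
        all_ids = {l.id for l in small_series.ligands}
        assert len(train) == n
        assert set(train) | set(test) == all_ids
        assert set(train) & set(test) == set()

    def test_temporal_takes_earliest(self, small_series):
        train, _ = vd.split_series(small_series, SplitScheme(kind="temporal"), 3)
        stamps = {l.id: l.timestamp for l in small_series.ligands}
        assert sorted(stamps[t] for t in train) == [0, 1, 2]

    def test_temporal_without_timestamps_errors(self, pocket):
        ligs = [_pose_from_smiles("CCO", "a"), _pose_from_smiles("CCN", "b"),
                _pose_from_smiles("CCC", "c")]
        series = CongenericSeries(protein=pocket, ligands=ligs,
                                  pocket_center=np.zeros(3))
        with pytest.raises(ValueError):
            vd.split_series(series, SplitScheme(kind="temporal"), 1)

    def test_random_split_seed_determinism(self, small_series):
        s = SplitScheme(kind="random", seed=9)
        assert vd.split_series(small_series, s, 4) == vd.split_series(small_series, s, 4)
        other = vd.split_series(small_series, SplitScheme(kind="random", seed=10), 4)
        assert vd.split_series(small_series, s, 4) != other

    def test_similarity_grows_from_reference_deterministically(self, small_series):
        s = SplitScheme(kind="similarity")
        train1, _ = vd.split_series(small_series, s, 4)
        train2, _ = vd.split_series(small_series, s, 4)
        assert train1 == train2
        ref = vd.select_reference(small_series)
        assert train1[0] == ref.id

    def test_out_of_range_n_rejected(self, small_series):
        with pytest.raises(ValueError):
            vd.split_series(small_series, SplitScheme(), 0)
        with pytest.raises(ValueError):
            vd.split_series(small_series, SplitScheme(), len(small_series.ligands))


class TestEvaluateStep:
    def test_perfect_predictions(self):
        rmse, r, rho = vd.evaluate_step([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0
        assert r == pytest.approx(1.0, abs=1e-12)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated(self):
        exp = [1.0, 2.0, 4.0]
        rmse, r, rho = vd.evaluate_step([-1.0, -2.0, -4.0], exp)
        assert r == pytest.approx(-1.0) and rho == pytest.approx(-1.0)

    def test_constant_offset(self):
        exp = [0.0, 1.0, 2.0, 3.0]
        pred = [v + 0.5 for v in exp]
        rmse, r, _ = vd.evaluate_step(pred, exp)
        assert rmse == pytest.approx(0.5) and r == pytest.approx(1.0)

    def test_constant_vector_flagged_not_zero(self):
        rmse, r, rho = vd.evaluate_step([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert rmse > 0 and math.isnan(r) and math.isnan(rho)

    def test_matches_naive_reference_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            pred = list(rng.normal(size=n))
            exp = list(rng.normal(size=n))
            rmse, r, rho = vd.evaluate_step(pred, exp)
            assert rmse == pytest.approx(naive_rmse(pred, exp), abs=1e-10)
            assert r == pytest.approx(naive_pearson(exp, pred), abs=1e-10)
            assert rho == pytest.approx(naive_spearman(exp, pred), abs=1e-10)


class TestContinuousLearning:
    def test_deterministic_given_seeds(self, small_series):
        kwargs = dict(scheme_kind="temporal", schedule=(3, 5), seeds=(1,),
                      model_params=dict(FAST_MODEL, epochs=2),
                      grid_spec=FAST_GRID)
        t1 = vd.continuous_learning_run(small_series, **kwargs)
        t2 = vd.continuous_learning_run(small_series, **kwargs)
        assert t1.records.equals(t2.records)
        assert list(t1.records["n_train"]) == [3, 5]
        assert (t1.records["n_test"] == [5, 3]).all()

    def test_oversized_step_skipped(self, small_series):
        traj = vd.continuous_learning_run(
            small_series, schedule=(3, 99), seeds=(0,),
            model_params=dict(FAST_MODEL, epochs=1), grid_spec=FAST_GRID)
        assert list(traj.records["n_train"]) == [3]

    def test_summary_aggregates_over_seeds(self, small_series):
        traj = vd.continuous_learning_run(
            small_series, schedule=(4,), seeds=(0, 1),
            model_params=dict(FAST_MODEL, epochs=1), grid_spec=FAST_GRID)
        summary = traj.summary()
        assert summary.shape[0] == 1
        assert ("rmse", "mean") in summary.columns
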
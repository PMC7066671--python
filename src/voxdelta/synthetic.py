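"""Self-contained toy congeneric series for testing and benchmarking.

A pocket of typed pseudo-atoms sits on a hemispherical shell above a linear
carbon scaffold threaded through the pocket centre.  Each ligand decorates
fixed attachment points on the scaffold with substituents drawn from a small
element palette; its pIC50 is a stated deterministic function of substituent
composition and geometry,

    pIC50 = base + sum_over_substituents w(element) * exp(-(d / s)^2) + noise,

where d is the distance from the substituent atom to the nearest H-bond
donor/acceptor pocket atom.  Polar substituents close to the pocket are
rewarded, so the voxel descriptor (which sees pocket and ligand jointly)
carries signal a composition-only model lacks.  Everything is reproducible
from the seed and writable as standard PDB/SDF plus a manifest, so the
fixtures double as format round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .chem_io import (
    CongenericSeries,
    LigandPose,
    PROTEIN_CHANNELS,
    ProteinStructure,
    assign_protein_channels,
)

_HBOND_MASK = (1 << PROTEIN_CHANNELS.index("hbond_acceptor")) | (
    1 << PROTEIN_CHANNELS.index("hbond_donor")
)

#: Pseudo-residue templates the pocket is built from: (residue, atom, element).
_POCKET_TEMPLATES = (
    ("ALA", "CB", "C"),
    ("PHE", "CZ", "C"),
    ("SER", "OG", "O"),
    ("ASN", "ND2", "N"),
    ("ASP", "OD1", "O"),
    ("LYS", "NZ", "N"),
)

# Scaffold geometry: carbon chain along x, 1.54 A spacing, through the origin.
_BOND_LENGTH = 1.54
_MIN_CLASH = 0.8


@dataclass
class ToySeriesSpec:
    """Recipe for a reproducible toy congeneric series."""

    n_ligands: int = 50
    scaffold_size: int = 6
    n_sites: int = 4
    palette: tuple = ("C", "N", "O", "F", "Cl")
    weights: dict = field(default_factory=lambda: {
        "C": 0.1, "N": 0.8, "O": 0.6, "F": 0.3, "Cl": -0.4})
    base_affinity: float = 5.0
    proximity_scale: float = 6.0
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        bad = set(self.palette) - {"C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "H"}
        if bad:
            raise ValueError(f"palette elements outside ligand set: {bad}")


def make_toy_pocket(seed: int, n_atoms: Optional[int] = None,
                    radius: float = 8.0) -> ProteinStructure:
    """A pocket of 30-60 typed pseudo-atoms on a hemispherical shell.

    Atoms sit at ``radius`` (+/- 0.5 A jitter) from the origin in the z >= 0
    hemisphere; the origin is the pocket centre.  Channel flags come from the
    standard residue/atom-name typing table.
    """
    rng = np.random.default_rng(seed)
    if n_atoms is None:
        n_atoms = int(rng.integers(30, 61))
    coords = np.empty((0, 3))
    while len(coords) < n_atoms:
        # Uniform directions on the upper hemisphere.
        vec = rng.normal(size=(n_atoms, 3))
        vec[:, 2] = np.abs(vec[:, 2])
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        cand = vec * (radius + rng.uniform(-0.5, 0.5, size=(n_atoms, 1)))
        for c in cand:
            if len(coords) >= n_atoms:
                break
            if len(coords) == 0 or np.min(
                    np.linalg.norm(coords - c, axis=1)) >= 1.5:
                coords = np.vstack([coords, c])
    picks = rng.integers(0, len(_POCKET_TEMPLATES), size=n_atoms)
    res_names = np.array([_POCKET_TEMPLATES[p][0] for p in picks], dtype=object)
    atom_names = np.array([_POCKET_TEMPLATES[p][1] for p in picks], dtype=object)
    elements = np.array([_POCKET_TEMPLATES[p][2] for p in picks], dtype=object)
    flags = assign_protein_channels(elements, res_names, atom_names)
    return ProteinStructure(elements=elements, res_names=res_names,
                            atom_names=atom_names, coords=coords,
                            channel_flags=flags)


def _scaffold_coords(size: int) -> np.ndarray:
    xs = (np.arange(size) - (size - 1) / 2.0) * _BOND_LENGTH
    return np.column_stack([xs, np.zeros(size), np.zeros(size)])


def _site_positions(spec: ToySeriesSpec) -> tuple:
    """Attachment sites: (scaffold atom index, substituent xyz) per site.

    Sites alternate between pointing toward the pocket hemisphere (+z) and
    sideways (+y), so proximity factors differ across sites.
    """
    scaffold = _scaffold_coords(spec.scaffold_size)
    carbon_idx = np.linspace(0, spec.scaffold_size - 1, spec.n_sites).round().astype(int)
    sites = []
    for k, ci in enumerate(carbon_idx):
        direction = np.array([0.0, 0.0, 1.0]) if k % 2 == 0 else np.array([0.0, 1.0, 0.0])
        sites.append((int(ci), scaffold[ci] + direction * _BOND_LENGTH))
    return scaffold, sites


def _polar_pocket_coords(pocket: ProteinStructure) -> np.ndarray:
    mask = (pocket.channel_flags & _HBOND_MASK) != 0
    return pocket.coords[mask]


def proximity_factor(position, pocket: ProteinStructure, scale: float) -> float:
    """exp(-(d/scale)^2) with d the distance to the nearest donor/acceptor."""
    polar = _polar_pocket_coords(pocket)
    if len(polar) == 0:
        return 0.0
    d = float(np.min(np.linalg.norm(polar - np.asarray(position), axis=1)))
    return float(np.exp(-((d / scale) ** 2)))


def oracle_affinity(ligand: LigandPose, spec: ToySeriesSpec,
                    pocket: ProteinStructure) -> float:
    """Deterministic part of the toy affinity for an arbitrary ligand.

    Scaffold atoms (those on the y = z = 0 axis) contribute nothing; every
    other atom contributes weight(element) * proximity_factor.
    """
    value = spec.base_affinity
    for elem, xyz in zip(ligand.elements, ligand.coords):
        if abs(xyz[1]) < 0.1 and abs(xyz[2]) < 0.1:
            continue  # scaffold atom
        value += spec.weights.get(str(elem), 0.0) * proximity_factor(
            xyz, pocket, spec.proximity_scale)
    return float(value)


def _build_mol(elements, coords, bonds):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for elem in elements:
        rw.AddAtom(Chem.Atom(str(elem)))
    for i, j in bonds:
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(len(elements))
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    return mol


def make_series(spec: ToySeriesSpec,
                pocket: Optional[ProteinStructure] = None) -> CongenericSeries:
    """Generate a toy congeneric series with oracle affinities plus noise.

    Ligand 0 is the bare scaffold and is flagged as the crystal reference;
    timestamps equal generation order.
    """
    rng = np.random.default_rng(spec.seed)
    if pocket is None:
        pocket = make_toy_pocket(spec.seed)
    scaffold, sites = _site_positions(spec)

    ligands = []
    for i in range(spec.n_ligands):
        elements = ["C"] * spec.scaffold_size
        coords = [row for row in scaffold]
        bonds = [(k, k + 1) for k in range(spec.scaffold_size - 1)]
        if i > 0:
            for ci, pos in sites:
                choice = rng.choice(len(spec.palette) + 1)
                if choice == len(spec.palette):
                    continue  # site left bare
                elements.append(spec.palette[choice])
                coords.append(pos)
                bonds.append((ci, len(elements) - 1))
        coords = np.asarray(coords, dtype=float)
        lig = LigandPose(
            id=f"lig{i:03d}",
            elements=np.array(elements, dtype=object),
            coords=coords,
            timestamp=i,
            is_crystal_reference=(i == 0),
            mol=_build_mol(elements, coords, bonds),
        )
        noise = rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma > 0 else 0.0
        lig.affinity = oracle_affinity(lig, spec, pocket) + noise
        _assert_no_clash(lig)
        ligands.append(lig)
    return CongenericSeries(protein=pocket, ligands=ligands,
                            pocket_center=np.zeros(3))


def _assert_no_clash(lig: LigandPose) -> None:
    d = np.linalg.norm(lig.coords[:, None] - lig.coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < _MIN_CLASH:
        raise ValueError(f"ligand {lig.id} has atoms closer than {_MIN_CLASH} A")


def write_fixture_dir(path, series: CongenericSeries,
                      affinity_tag: str = "pIC50") -> dict:
    """Write the series as pocket.pdb + ligands.sdf + manifest.csv.

    Emits exactly the input formats the readers consume; returns the paths.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    import pandas as pd

    from .chem_io import write_ligands

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prot = series.protein
    atoms = struc.AtomArray(prot.n_atoms)
    atoms.coord = prot.coords.astype(np.float32)
    atoms.res_name = np.asarray(prot.res_names, dtype="U5")
    atoms.atom_name = np.asarray(prot.atom_names, dtype="U6")
    atoms.element = np.asarray([e.upper() for e in prot.elements], dtype="U2")
    atoms.res_id = np.arange(1, prot.n_atoms + 1)
    atoms.chain_id = np.full(prot.n_atoms, "A", dtype="U4")
    pdb_path = path / "pocket.pdb"
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(pdb_path))

    sdf_path = path / "ligands.sdf"
    write_ligands(sdf_path, series.ligands, affinity_tag=affinity_tag)

    manifest = pd.DataFrame(
        [dict(ligand_id=l.id, sdf_index=i, affinity=l.affinity, unit="pIC50",
              timestamp=l.timestamp, crystal=int(l.is_crystal_reference))
         for i, l in enumerate(series.ligands)])
    manifest_path = path / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return {"pdb": pdb_path, "sdf": sdf_path, "manifest": manifest_path}
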
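"""Reading protein/ligand structures and assigning voxel channel types.

Proteins are read from PDB and typed with eight pharmacophore-like channels
(hydrophobic, aromatic, H-bond acceptor/donor, positive/negative ionizable,
metallic, total excluded volume) via a residue/atom-name lookup table shipped
as package data.  Ligands are read from SDF (V2000, explicit hydrogens
allowed) and typed with a one-hot over the ten supported elements
{C, N, O, F, P, S, Cl, Br, I, H}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import EmptyStructureError, ParseError, UnsupportedElementError
from .series_protocols import convert_affinity

logger = logging.getLogger(__name__)

#: Names of the eight protein pharmacophore channels, in channel order.
PROTEIN_CHANNELS = (
    "hydrophobic",
    "aromatic",
    "hbond_acceptor",
    "hbond_donor",
    "positive_ionizable",
    "negative_ionizable",
    "metallic",
    "excluded_volume",
)

#: Ligand element channels, in channel order (appended after the protein's 8).
LIGAND_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "H")

EXCLUDED_VOLUME = PROTEIN_CHANNELS.index("excluded_volume")

_WATER_RESIDUES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "DOD"})
_METAL_ELEMENTS = frozenset({"Zn", "Mg", "Mn", "Fe", "Na", "K", "Ca", "Cu", "Ni", "Co"})


@dataclass
class ProteinStructure:
    """Protein atoms with per-atom pharmacophore channel flags.

    ``channel_flags`` is an 8-bit mask over :data:`PROTEIN_CHANNELS`;
    hydrogens carry no flags, every heavy atom carries at least the
    excluded-volume flag.
    """

    elements: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    channel_flags: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("protein coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e != "H" for e in self.elements])


@dataclass
class LigandPose:
    """One 3D ligand pose in the protein frame, with an optional pIC50 label."""

    id: str
    elements: np.ndarray
    coords: np.ndarray
    affinity: Optional[float] = None
    timestamp: Optional[int] = None
    is_crystal_reference: bool = False
    mol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        bad = [e for e in self.elements if e not in LIGAND_ELEMENTS]
        if bad:
            raise UnsupportedElementError(
                f"ligand {self.id!r}: unsupported element(s) {sorted(set(bad))}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_coords(self) -> np.ndarray:
        mask = np.asarray([e != "H" for e in self.elements])
        return self.coords[mask]


@dataclass
class CongenericSeries:
    """A protein plus an ordered congeneric ligand series posed in its pocket."""

    protein: ProteinStructure
    ligands: list
    pocket_center: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ids = [lig.id for lig in self.ligands]
        if len(set(ids)) != len(ids):
            raise ValueError("ligand ids must be unique within a series")
        if sum(lig.is_crystal_reference for lig in self.ligands) > 1:
            raise ValueError("at most one crystal-reference ligand per series")
        if self.pocket_center is None and self.ligands:
            ref = next(
                (l for l in self.ligands if l.is_crystal_reference), self.ligands[0]
            )
            self.pocket_center = ref.heavy_coords.mean(axis=0)
        if self.pocket_center is not None:
            self.pocket_center = np.asarray(self.pocket_center, dtype=float)

    def __len__(self) -> int:
        return len(self.ligands)

    def ligand(self, lig_id: str) -> LigandPose:
        for lig in self.ligands:
            if lig.id == lig_id:
                return lig
        raise KeyError(lig_id)


def _load_channel_table() -> tuple[dict, set]:
    """Parse the packaged residue/atom-name -> channels table.

    Returns (rules, known_residues) where rules maps (residue, atom_name) to a
    channel bitmask and residue may be "*" for backbone wildcards.
    """
    rules: dict = {}
    known: set = set()
    text = resources.files("voxdelta.data").joinpath("protein_channels.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, channels = line.split("\t")
        known.add(res)
        mask = 0
        if channels != "-":
            for name in channels.split(","):
                mask |= 1 << PROTEIN_CHANNELS.index(name)
        if atom != "-":
            rules[(res, atom)] = mask
    known.discard("*")
    return rules, known


_CHANNEL_RULES, _KNOWN_RESIDUES = _load_channel_table()

# Standard amino acids are "known" even if they contribute only generic flags.
_KNOWN_RESIDUES |= {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def assign_protein_channels(
    elements, res_names, atom_names, rules: Optional[dict] = None
) -> np.ndarray:
    """Assign the 8-bit pharmacophore mask to each protein atom.

    Hydrogens get an empty mask.  Heavy atoms always carry the excluded-volume
    flag; atoms of residues absent from the typing table carry only it (with a
    logged warning).  Element-level rules: carbon -> hydrophobic, metal
    elements -> metallic.
    """
    if rules is None:
        rules = _CHANNEL_RULES
    flags = np.zeros(len(elements), dtype=np.uint8)
    warned: set = set()
    for i, (elem, res, atom) in enumerate(zip(elements, res_names, atom_names)):
        if elem == "H":
            continue
        mask = 1 << EXCLUDED_VOLUME
        if res in _KNOWN_RESIDUES:
            if elem == "C":
                mask |= 1 << PROTEIN_CHANNELS.index("hydrophobic")
            if elem in _METAL_ELEMENTS:
                mask |= 1 << PROTEIN_CHANNELS.index("metallic")
            if (res, atom) in rules:
                mask |= rules[(res, atom)]
            elif ("*", atom) in rules:
                mask |= rules[("*", atom)]
        elif res not in warned:
            warned.add(res)
            logger.warning(
                "residue %s not in channel table; excluded-volume only", res
            )
        flags[i] = mask
    return flags


def assign_ligand_channels(elements) -> np.ndarray:
    """One-hot element typing over :data:`LIGAND_ELEMENTS`, shape (n, 10)."""
    onehot = np.zeros((len(elements), len(LIGAND_ELEMENTS)), dtype=bool)
    for i, elem in enumerate(elements):
        try:
            onehot[i, LIGAND_ELEMENTS.index(elem)] = True
        except ValueError:
            raise UnsupportedElementError(f"element {elem!r} not in ligand set")
    return onehot


def read_protein(
    path,
    include_waters: bool = False,
    include_hetero: bool = False,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Waters and hetero records (ions, cofactors) are excluded by default.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"could not parse PDB file {path}: {exc}") from exc

    keep = np.ones(atoms.array_length(), dtype=bool)
    water = np.isin(atoms.res_name, list(_WATER_RESIDUES))
    if not include_waters:
        keep &= ~water
    if not include_hetero:
        keep &= ~(atoms.hetero & ~water)
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"no protein atoms in {path}")

    elements = np.array([e.capitalize() for e in atoms.element], dtype=object)
    res_names = np.array(atoms.res_name, dtype=object)
    atom_names = np.array(atoms.atom_name, dtype=object)
    flags = assign_protein_channels(elements, res_names, atom_names)
    return ProteinStructure(elements, res_names, atom_names, atoms.coord, flags)


def _mol_to_pose(mol, index: int, affinity_tag: str, affinity_unit: str) -> LigandPose:
    from rdkit import Chem

    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    lig_id = name.strip() or f"lig{index:03d}"
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = conf.GetPositions()
    affinity = None
    if mol.HasProp(affinity_tag):
        affinity = convert_affinity(float(mol.GetProp(affinity_tag)), affinity_unit)
    timestamp = int(mol.GetProp("timestamp")) if mol.HasProp("timestamp") else None
    crystal = mol.HasProp("crystal_reference") and mol.GetProp(
        "crystal_reference"
    ).strip() in {"1", "true", "True"}
    return LigandPose(
        id=lig_id,
        elements=np.array(elements, dtype=object),
        coords=np.asarray(coords, dtype=float),
        affinity=affinity,
        timestamp=timestamp,
        is_crystal_reference=crystal,
        mol=mol,
    )


def read_ligands(
    path,
    affinity_tag: str = "pIC50",
    affinity_unit: str = "pIC50",
) -> list:
    """Read an SDF file into a list of :class:`LigandPose`, in file order.

    Molecules rdkit cannot read, or containing elements outside the supported
    ten-element set, are skipped with a logged warning.  Affinities are read
    from the SD tag ``affinity_tag`` and converted to pIC50 from
    ``affinity_unit``.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise ParseError(f"SDF file {path} does not exist")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    poses = []
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("molecule block %d in %s unreadable; skipped", i, path)
            continue
        try:
            poses.append(_mol_to_pose(mol, i, affinity_tag, affinity_unit))
        except UnsupportedElementError as exc:
            logger.warning("%s; skipped", exc)
    return poses


def write_ligands(path, ligands, affinity_tag: str = "pIC50") -> None:
    """Write ligand poses to SDF (V2000), with pIC50/timestamp/crystal SD tags."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for lig in ligands:
            mol = lig.mol
            if mol is None:
                mol = _pose_to_mol(lig)
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", lig.id)
            if lig.affinity is not None:
                mol.SetProp(affinity_tag, f"{lig.affinity:.6f}")
            if lig.timestamp is not None:
                mol.SetProp("timestamp", str(lig.timestamp))
            if lig.is_crystal_reference:
                mol.SetProp("crystal_reference", "1")
            writer.write(mol)
    finally:
        writer.close()


def _pose_to_mol(lig: LigandPose):
    """Build a bond-less rdkit Mol carrying only elements and coordinates."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for elem in lig.elements:
        atom = Chem.Atom(str(elem))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    conf = Chem.Conformer(lig.n_atoms)
    for i, (x, y, z) in enumerate(lig.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    return mol
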
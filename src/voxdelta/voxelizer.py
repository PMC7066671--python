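"""Voxelization of protein-ligand complexes onto channelled occupancy grids.

A complex is discretized onto a cubic, pocket-centred box (default 24 A edge,
1 A voxels).  Each atom contributes to nearby voxel centres through a pair
correlation function of its van der Waals radius,

    n(r) = 1 - exp(-(r_vdw / r)^12),

saturating to 1 at the atom position.  Protein atoms populate the eight
pharmacophore channels their flags select; ligand atoms populate one of ten
element channels; together 18 stacked channels.  Overlapping contributions to
the same channel are combined with a per-voxel maximum, so occupancies stay
in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import (
    LIGAND_ELEMENTS,
    PROTEIN_CHANNELS,
    CongenericSeries,
    LigandPose,
    ProteinStructure,
)

logger = logging.getLogger(__name__)

N_PROTEIN_CHANNELS = len(PROTEIN_CHANNELS)
N_LIGAND_CHANNELS = len(LIGAND_ELEMENTS)
N_CHANNELS = N_PROTEIN_CHANNELS + N_LIGAND_CHANNELS


def _load_vdw_table() -> dict:
    table = {}
    text = resources.files("voxdelta.data").joinpath("vdw_radii.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        elem, radius = line.split("\t")
        table[elem] = float(radius)
    return table


#: Default element -> van der Waals radius table (Angstrom), from package data.
VDW_RADII = _load_vdw_table()


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the voxelization box.

    ``edge`` is the physical box edge in Angstrom, ``resolution`` the voxel
    edge; atoms farther than ``cutoff`` from a voxel centre are skipped
    (their contribution is below 1e-4 for typical radii).
    """

    edge: float = 24.0
    resolution: float = 1.0
    cutoff: float = 5.0

    @property
    def n_voxels(self) -> int:
        n = self.edge / self.resolution
        if abs(n - round(n)) > 1e-9:
            raise ValueError("edge must be an integer multiple of resolution")
        return int(round(n))

    @property
    def shape(self) -> tuple:
        n = self.n_voxels
        return (N_CHANNELS, n, n, n)


@dataclass
class VoxelGrid:
    """An 18-channel occupancy tensor for one protein-ligand complex."""

    values: np.ndarray
    box_center: np.ndarray
    spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.box_center = np.asarray(self.box_center, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"grid shape {self.values.shape} != spec shape {self.spec.shape}"
            )

    @property
    def shape(self) -> tuple:
        return self.values.shape


def atom_contribution(r, r_vdw) -> np.ndarray:
    """Occupancy contribution of an atom at distance ``r`` from a voxel centre.

    Evaluates 1 - exp(-(r_vdw/r)^12) with the r -> 0 limit defined as 1.
    Vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    r_vdw = np.asarray(r_vdw, dtype=float)
    if np.any(r_vdw <= 0):
        raise ValueError("van der Waals radius must be positive")
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio12 = (r_vdw / r) ** 12
    return np.where(r == 0, 1.0, -np.expm1(-ratio12))


def random_rotation(seed) -> np.ndarray:
    """A uniformly distributed proper rotation matrix (det +1), seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Rotation.random(rng=rng).as_matrix()


def _paint_atoms(
    grid: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
    channel_lists: list,
    center: np.ndarray,
    spec: GridSpec,
) -> int:
    """Max-combine atom contributions into ``grid``; returns #atoms painted."""
    n = spec.n_voxels
    res = spec.resolution
    corner = center - spec.edge / 2.0
    painted = 0
    for pos, r_vdw, channels in zip(coords, radii, channel_lists):
        if not channels:
            continue
        rel = (pos - corner) / res - 0.5  # position in voxel-centre units
        lo = np.maximum(np.ceil(rel - spec.cutoff / res), 0).astype(int)
        hi = np.minimum(np.floor(rel + spec.cutoff / res), n - 1).astype(int)
        if np.any(lo > hi):
            continue
        axes = [
            (np.arange(l, h + 1) + 0.5) * res + c - p
            for l, h, c, p in zip(lo, hi, corner, pos)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        within = d2 <= spec.cutoff**2
        if not within.any():
            continue
        occ = atom_contribution(np.sqrt(d2), r_vdw)
        occ[~within] = 0.0
        window = (
            slice(lo[0], hi[0] + 1),
            slice(lo[1], hi[1] + 1),
            slice(lo[2], hi[2] + 1),
        )
        for ch in channels:
            np.maximum(grid[ch][window], occ, out=grid[ch][window])
        painted += 1
    return painted


def voxelize(
    protein: ProteinStructure | CongenericSeries,
    ligand: Optional[LigandPose] = None,
    center=None,
    rotation: Optional[np.ndarray] = None,
    spec: Optional[GridSpec] = None,
    radii: Optional[dict] = None,
) -> VoxelGrid:
    """Voxelize a protein-ligand complex into an 18-channel grid.

    ``rotation``, if given, is applied to all atom coordinates about
    ``center`` before gridding (used for training-time augmentation).
    Either a :class:`ProteinStructure` plus explicit ``center`` or a
    :class:`CongenericSeries` (whose pocket centre is used) may be passed.
    """
    if isinstance(protein, CongenericSeries):
        if center is None:
            center = protein.pocket_center
        protein = protein.protein
    if center is None:
        raise ValueError("a box center is required")
    center = np.asarray(center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValueError("box center must be finite")
    spec = spec or GridSpec()
    radii = radii or VDW_RADII

    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def _transform(xyz: np.ndarray) -> np.ndarray:
        if rotation is None:
            return xyz
        return (xyz - center) @ rotation.T + center

    grid = np.zeros(spec.shape, dtype=np.float64)
    painted = 0

    # Protein channels 0-7 from the pharmacophore bitmask (hydrogens carry none).
    pcoords = _transform(protein.coords)
    pradii = np.array([radii[e] for e in protein.elements])
    pchannels = [
        [c for c in range(N_PROTEIN_CHANNELS) if flags & (1 << c)]
        for flags in protein.channel_flags
    ]
    painted += _paint_atoms(grid, pcoords, pradii, pchannels, center, spec)

    # Ligand channels 8-17, one element channel per atom.
    if ligand is not None and ligand.n_atoms > 0:
        lcoords = _transform(ligand.coords)
        lradii = np.array([radii[e] for e in ligand.elements])
        lchannels = [
            [N_PROTEIN_CHANNELS + LIGAND_ELEMENTS.index(e)] for e in ligand.elements
        ]
        painted += _paint_atoms(grid, lcoords, lradii, lchannels, center, spec)

    if painted == 0:
        logger.warning("no atoms within %.1f A of the box; grid is all zero", spec.edge)
    return VoxelGrid(values=grid, box_center=center, spec=spec)
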
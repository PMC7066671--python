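"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package: plain Python loops and
textbook formulas only.
"""

import math

import numpy as np


def brute_force_grid(protein, ligand, center, spec, radii):
    """Triple loop over voxels x atoms x channels with max aggregation."""
    n = spec.n_voxels
    grid = np.zeros(spec.shape, dtype=float)
    corner = [center[k] - spec.edge / 2.0 for k in range(3)]

    atoms = []  # (xyz, r_vdw, [channel indices])
    for i in range(protein.n_atoms):
        if protein.elements[i] == "H":
            continue
        channels = [c for c in range(8) if protein.channel_flags[i] & (1 << c)]
        atoms.append((protein.coords[i], radii[protein.elements[i]], channels))
    if ligand is not None:
        from voxdelta.chem_io import LIGAND_ELEMENTS

        for i in range(ligand.n_atoms):
            elem = ligand.elements[i]
            atoms.append((ligand.coords[i], radii[elem],
                          [8 + LIGAND_ELEMENTS.index(elem)]))

    for ix in range(n):
        for iy in range(n):
            for iz in range(n):
                vx = corner[0] + (ix + 0.5) * spec.resolution
                vy = corner[1] + (iy + 0.5) * spec.resolution
                vz = corner[2] + (iz + 0.5) * spec.resolution
                for xyz, r_vdw, channels in atoms:
                    r = math.sqrt((xyz[0] - vx) ** 2 + (xyz[1] - vy) ** 2
                                  + (xyz[2] - vz) ** 2)
                    if r > spec.cutoff:
                        continue
                    occ = 1.0 if r == 0 else 1.0 - math.exp(-((r_vdw / r) ** 12))
                    for c in channels:
                        if occ > grid[c, ix, iy, iz]:
                            grid[c, ix, iy, iz] = occ
    return grid


def naive_rmse(pred, exp):
    return math.sqrt(sum((p - e) ** 2 for p, e in zip(pred, exp)) / len(pred))


def naive_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def _ranks(values):
    """Average ranks (1-based), ties shared."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_spearman(x, y):
    return naive_pearson(_ranks(list(x)), _ranks(list(y)))
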
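"""Gaussian cube volumetric I/O for response fields.

Standard layout: two comment lines; atom count + origin; three axis lines
(count, step vector); one line per atom (Z, charge, x, y, z); then values
with the z index fastest, six per line.  Everything in bohr.
"""

from __future__ import annotations

import numpy as np

from .basis import ANGSTROM
from .basis_data import ATOMIC_NUMBERS
from .response import GridSpec3D, ResponseField3D, SitePerturbation


class CubeFormatError(ValueError):
    pass


def write_cube(field: ResponseField3D, path, atoms=None, comment: str = "") -> None:
    """Write ``field`` to ``path``; ``atoms`` as (element, xyz Angstrom)."""
    g = field.grid
    atoms = atoms or []
    with open(path, "w") as fh:
        fh.write((comment or "density response field") + "\n")
        fh.write(f"perturbation atom {field.perturbation.atom_index} alpha {field.perturbation.alpha}\n")
        fh.write(f"{len(atoms):5d} {g.origin[0]:13.6f} {g.origin[1]:13.6f} {g.origin[2]:13.6f}\n")
        fh.write(f"{g.shape[0]:5d} {g.spacing:13.6f} {0.0:13.6f} {0.0:13.6f}\n")
        fh.write(f"{g.shape[1]:5d} {0.0:13.6f} {g.spacing:13.6f} {0.0:13.6f}\n")
        fh.write(f"{g.shape[2]:5d} {0.0:13.6f} {0.0:13.6f} {g.spacing:13.6f}\n")
        for el, pos in atoms:
            z = ATOMIC_NUMBERS[el]
            p = np.asarray(pos, float) / ANGSTROM
            fh.write(f"{z:5d} {float(z):13.6f} {p[0]:13.6f} {p[1]:13.6f} {p[2]:13.6f}\n")
        flat = field.values.reshape(g.shape)  # x, y, z
        for ix in range(g.shape[0]):
            for iy in range(g.shape[1]):
                row = flat[ix, iy, :]
                for k in range(0, row.size, 6):
                    fh.write(" ".join(f"{v:13.5e}" for v in row[k : k + 6]) + "\n")


def read_cube(path) -> ResponseField3D:
    """Read a cube written by :func:`write_cube` (uniform axes required)."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(x) for x in head[1:4]])
        counts = []
        steps = []
        for k in range(3):
            parts = lines[3 + k].split()
            counts.append(int(parts[0]))
            steps.append([float(x) for x in parts[1:4]])
    except (IndexError, ValueError) as exc:
        raise CubeFormatError(f"malformed cube header in {path}: {exc}") from exc
    steps = np.array(steps)
    if natoms < 0:
        raise CubeFormatError("cube files with a value-count line (natoms < 0) are not supported")
    diag = np.diag(steps).copy()
    if np.any(np.abs(steps - np.diag(diag)) > 1e-12) or np.ptp(diag) > 1e-12:
        raise CubeFormatError("only uniform axis-aligned cubic-voxel grids are supported")
    atoms = []
    for k in range(natoms):
        parts = lines[6 + k].split()
        z = int(parts[0])
        sym = {v: s for s, v in ATOMIC_NUMBERS.items()}.get(z, f"Z{z}")
        atoms.append((sym, np.array([float(x) for x in parts[2:5]]) * ANGSTROM))
    data = []
    for line in lines[6 + natoms :]:
        if line.strip():
            data.extend(float(x) for x in line.split())
    nvals = counts[0] * counts[1] * counts[2]
    if len(data) != nvals:
        raise CubeFormatError(f"expected {nvals} voxels, found {len(data)}")
    grid = GridSpec3D(origin=origin, spacing=float(diag[0]), shape=tuple(counts))
    vals = np.array(data).reshape(tuple(counts))
    out = ResponseField3D(
        grid=grid,
        values=vals,
        perturbation=SitePerturbation(atom_index=0),
        source=f"cube:{path}",
        metadata={"atoms": atoms},
    )
    return out
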
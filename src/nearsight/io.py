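"""Exports: kernels, slices, spectra and metrics as text; binary grid container.

Formats:

* delimited text (tab-separated, ``#``-comment header) for matrices, slice
  profiles and spectra — lossless to the printed precision (%.12e);
* ``.npz`` binary grid container for bit-exact kernel round trips;
* Gaussian cube for 3D fields (see :mod:`nearsight.qm.cube`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .lrf import LRFMatrix
from .wells import Spectrum

__all__ = [
    "export_matrix",
    "read_matrix",
    "export_spectrum",
    "export_slice",
    "export_metrics",
]


class FormatError(ValueError):
    pass


def export_matrix(K: LRFMatrix | np.ndarray, fmt: str, path) -> None:
    """Write a kernel in ``fmt`` = 'text' | 'npz' | 'cube'.

    'cube' is only meaningful for 3D fields and raises here — use
    :func:`nearsight.qm.cube.write_cube` for :class:`ResponseField3D`.
    """
    if fmt == "cube":
        raise FormatError("2D kernels have no cube representation; use qm.cube for 3D fields")
    if isinstance(K, LRFMatrix):
        grid, values, meta = K.grid, K.values, {
            "nocc": K.nocc,
            "prefactor": K.prefactor,
            "m_truncated": list(K.m_truncated),
        }
    else:
        values = np.asarray(K)
        grid, meta = np.arange(values.shape[0]), {}
    if fmt == "text":
        with open(path, "w") as fh:
            fh.write("# nearsight kernel matrix\n")
            fh.write(f"# meta {json.dumps(meta)}\n")
            fh.write("# grid\n")
            fh.write("\t".join(f"{x:.12e}" for x in grid) + "\n")
            fh.write("# values (one row per line)\n")
            for row in values:
                fh.write("\t".join(f"{x:.12e}" for x in row) + "\n")
    elif fmt == "npz":
        np.savez(path, grid=grid, values=values, meta=json.dumps(meta))
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read either export format back as (grid, values, meta)."""
    p = Path(path)
    if p.suffix == ".npz":
        with np.load(p, allow_pickle=False) as z:
            return z["grid"], z["values"], json.loads(str(z["meta"]))
    lines = p.read_text().split("\n")
    meta = {}
    rows = []
    grid = None
    mode = None
    for line in lines:
        if line.startswith("# meta"):
            meta = json.loads(line[len("# meta") :])
        elif line.startswith("# grid"):
            mode = "grid"
        elif line.startswith("# values"):
            mode = "values"
        elif line.startswith("#") or not line.strip():
            continue
        elif mode == "grid":
            grid = np.array([float(x) for x in line.split()])
            mode = None
        elif mode == "values":
            rows.append([float(x) for x in line.split()])
    if grid is None or not rows:
        raise FormatError(f"{path} is not a kernel export")
    return grid, np.array(rows), meta


def export_spectrum(spectrum: Spectrum, path) -> None:
    """Delimited text: n, energy, parity, below_barrier per state."""
    with open(path, "w") as fh:
        fh.write("# n\tenergy\tparity\tbelow_barrier\n")
        for s in spectrum.states:
            bb = "-" if s.below_barrier is None else str(int(s.below_barrier))
            fh.write(f"{s.n}\t{s.energy:.12e}\t{s.parity}\t{bb}\n")


def export_slice(r: np.ndarray, values: np.ndarray, path, r_prime: float | None = None) -> None:
    with open(path, "w") as fh:
        if r_prime is not None:
            fh.write(f"# r_prime = {r_prime:.12e}\n")
        fh.write("# r\tdrho_dv\n")
        for x, v in zip(r, values):
            fh.write(f"{x:.12e}\t{v:.12e}\n")


def export_metrics(metrics: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
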
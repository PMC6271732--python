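"""Molecular-orbital sets: the common currency of the molecular response code.

An :class:`MOSet` holds everything the sum-over-states response needs:
geometry, AO basis, and per-spin-channel MO coefficients (rows = MOs),
energies (Hartree) and occupations.  Restricted sets store a single
``alpha`` channel with occupations up to 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ANGSTROM, BasisSet


class NoVirtualError(ValueError):
    """Every orbital of the requested channel is occupied."""


@dataclass
class MOSet:
    atoms: list  # (element, position in Angstrom)
    charge: int
    multiplicity: int
    basis: BasisSet
    restricted: bool
    channels: dict  # name -> (C (nmo, nao), energies, occupations)
    method: str = ""
    energy: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)
    #: disabled for deliberately truncated orbital sets (e.g. two-level models)
    validate_electron_count: bool = True

    def __post_init__(self) -> None:
        for name, (c, e, occ) in self.channels.items():
            if c.shape[1] != self.basis.nao:
                raise ValueError(f"channel {name}: {c.shape[1]} AO columns vs {self.basis.nao} AOs")
            if c.shape[0] != len(e) or len(e) != len(occ):
                raise ValueError(f"channel {name}: inconsistent MO count")
            if np.any(np.diff(e) < -1e-9):
                raise ValueError(f"channel {name}: MO energies must be nondecreasing")
        if self.validate_electron_count:
            nel = sum(_Z[el] for el, _ in self.atoms) - self.charge
            tot = sum(float(np.sum(occ)) for _, (_, _, occ) in self.channels.items())
            if abs(tot - nel) > 1e-8:
                raise ValueError(f"occupations sum to {tot}, expected {nel} electrons")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def coords_bohr(self) -> np.ndarray:
        return np.array([pos for _, pos in self.atoms], dtype=float) / ANGSTROM

    def n_occupied(self, channel: str = "alpha") -> int:
        occ = self.channels[channel][2]
        return int(np.sum(occ > 0))

    def density_matrix(self, channel: str = "alpha") -> np.ndarray:
        c, _, occ = self.channels[channel]
        return (c.T * occ) @ c

    def mo_on_grid(self, points_bohr: np.ndarray, channel: str = "alpha", indices=None) -> np.ndarray:
        """MO values (npts, nmo_selected) on cartesian points (bohr)."""
        c = self.channels[channel][0]
        if indices is not None:
            c = c[np.asarray(indices)]
        ao = self.basis.evaluate(points_bohr)
        return ao @ c.T


_Z = {"H": 1, "He": 2, "C": 6}


@dataclass(frozen=True)
class GapInfo:
    homo: float
    lumo: float

    @property
    def gap(self) -> float:
        return self.lumo - self.homo


def homo_lumo_gap(mos: MOSet, channel: str = "alpha") -> GapInfo:
    """HOMO/LUMO energies and gap of one spin channel (Hartree)."""
    _, e, occ = mos.channels[channel]
    occ_idx = np.nonzero(occ > 0)[0]
    vir_idx = np.nonzero(occ == 0)[0]
    if occ_idx.size == 0:
        raise ValueError("channel has no occupied orbital")
    if vir_idx.size == 0:
        raise NoVirtualError("channel has no virtual orbital")
    return GapInfo(homo=float(e[occ_idx[-1]]), lumo=float(e[vir_idx[0]]))
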
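"""Molden molecular-orbital exchange files.

Writes and reads the [Atoms]/[GTO]/[MO] dialect with cartesian d shells
(Molden's default ordering xx, yy, zz, xy, xz, yz — the same AO order this
package uses internally).  Energies are Hartree, coordinates Angstrom in
[Atoms] (Angs).  Contraction coefficients are the unit-normalized-primitive
coefficients, so a write/read round trip is exact to float formatting.
"""

from __future__ import annotations

import numpy as np

from .basis import ANGSTROM, BasisSet, Shell
from .basis_data import ATOMIC_NUMBERS
from .moset import MOSet

_L_LETTER = {0: "s", 1: "p", 2: "d"}
_LETTER_L = {v: k for k, v in _L_LETTER.items()}


class MoldenParseError(ValueError):
    pass


def write_molden(mos: MOSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("[Molden Format]\n")
        fh.write(f"[Title]\n{mos.method or 'orbital set'}\n")
        fh.write("[Atoms] (Angs)\n")
        for i, (el, pos) in enumerate(mos.atoms, start=1):
            z = ATOMIC_NUMBERS[el]
            fh.write(f"{el:4s} {i:4d} {z:4d} {pos[0]:15.8f} {pos[1]:15.8f} {pos[2]:15.8f}\n")
        fh.write("[GTO]\n")
        for ia in range(len(mos.atoms)):
            fh.write(f"{ia + 1} 0\n")
            for sh in mos.basis.shells:
                if sh.atom != ia:
                    continue
                fh.write(f" {_L_LETTER[sh.l]} {len(sh.exps)} 1.00\n")
                for a, c in zip(sh.exps, sh.coefs):
                    fh.write(f"  {a:18.10e} {c:18.10e}\n")
            fh.write("\n")
        fh.write("[MO]\n")
        for ch in mos.channel_names:
            spin = "Alpha" if ch == "alpha" else "Beta"
            c, e, occ = mos.channels[ch]
            for j in range(c.shape[0]):
                fh.write(f" Sym= A\n Ene= {e[j]:18.10f}\n Spin= {spin}\n Occup= {occ[j]:.6f}\n")
                for mu in range(c.shape[1]):
                    fh.write(f" {mu + 1:4d} {c[j, mu]:18.10e}\n")


def read_molden(path) -> MOSet:
    with open(path) as fh:
        lines = fh.read().split("\n")

    def find_section(tag):
        for i, line in enumerate(lines):
            if line.strip().lower().startswith(tag):
                return i
        return None

    i_atoms = find_section("[atoms]")
    i_gto = find_section("[gto]")
    i_mo = find_section("[mo]")
    if i_atoms is None or i_gto is None or i_mo is None:
        missing = [t for t, i in (("[Atoms]", i_atoms), ("[GTO]", i_gto), ("[MO]", i_mo)) if i is None]
        raise MoldenParseError(f"missing section(s): {', '.join(missing)}")
    in_au = "au" in lines[i_atoms].lower().split("(")[-1]

    atoms = []
    for ln, line in enumerate(lines[i_atoms + 1 :], start=i_atoms + 2):
        s = line.strip()
        if not s or s.startswith("["):
            break
        parts = s.split()
        if len(parts) < 6:
            raise MoldenParseError(f"line {ln}: malformed [Atoms] entry: {line!r}")
        el = parts[0].capitalize()
        pos = np.array([float(x) for x in parts[3:6]])
        if in_au:
            pos = pos * ANGSTROM
        atoms.append((el, pos))

    shells = []
    i = i_gto + 1
    while i < len(lines):
        s = lines[i].strip()
        if s.startswith("["):
            break
        if not s:
            i += 1
            continue
        parts = s.split()
        try:
            ia = int(parts[0]) - 1
        except ValueError as exc:
            raise MoldenParseError(f"line {i + 1}: expected atom index in [GTO]: {s!r}") from exc
        i += 1
        while i < len(lines) and lines[i].strip() and not lines[i].strip().startswith("["):
            hdr = lines[i].split()
            letter = hdr[0].lower()
            if letter not in _LETTER_L:
                raise MoldenParseError(f"line {i + 1}: unsupported shell type {letter!r} (s/p/d only)")
            nprim = int(hdr[1])
            exps, coefs = [], []
            for k in range(nprim):
                p = lines[i + 1 + k].replace("D", "e").replace("d", "e").split()
                exps.append(float(p[0]))
                coefs.append(float(p[1]))
            center = atoms[ia][1] / ANGSTROM
            shells.append(
                Shell(atom=ia, l=_LETTER_L[letter], exps=np.array(exps), coefs=np.array(coefs), center=center)
            )
            i += 1 + nprim
    basis = BasisSet(shells=shells, name="molden")

    mo_lines = lines[i_mo + 1 :]
    orbitals: dict[str, list] = {"alpha": [], "beta": []}
    cur: dict | None = None
    coef: list | None = None
    ln0 = i_mo + 2

    def flush():
        if cur is None:
            return
        if "ene" not in cur:
            raise MoldenParseError("[MO]: orbital block without Ene= entry")
        if "occup" not in cur:
            raise MoldenParseError("[MO]: orbital block without Occup= entry")
        orbitals[cur.get("spin", "alpha")].append((cur["ene"], cur["occup"], np.array(coef)))

    for ln, line in enumerate(mo_lines, start=ln0):
        s = line.strip()
        if not s or s.startswith("["):
            if s.startswith("["):
                break
            continue
        low = s.lower()
        if low.startswith("sym="):
            flush()
            cur, coef = {}, []
        elif low.startswith("ene="):
            if cur is None:
                cur, coef = {}, []
            try:
                cur["ene"] = float(s.split("=")[1])
            except ValueError as exc:
                raise MoldenParseError(f"line {ln}: bad Ene= value: {s!r}") from exc
        elif low.startswith("spin="):
            cur["spin"] = "alpha" if "alpha" in low else "beta"
        elif low.startswith("occup="):
            cur["occup"] = float(s.split("=")[1])
        else:
            parts = s.split()
            if len(parts) != 2:
                raise MoldenParseError(f"line {ln}: malformed MO coefficient line: {s!r}")
            coef.append(float(parts[1]))
    flush()

    channels = {}
    for ch, orbs in orbitals.items():
        if not orbs:
            continue
        order = np.argsort([o[0] for o in orbs], kind="stable")
        C = np.array([orbs[k][2] for k in order])
        e = np.array([orbs[k][0] for k in order])
        occ = np.array([orbs[k][1] for k in order])
        if C.shape[1] != basis.nao:
            raise MoldenParseError(f"channel {ch}: {C.shape[1]} coefficients per MO vs {basis.nao} AOs")
        channels[ch] = (C, e, occ)
    if not channels:
        raise MoldenParseError("[MO] section holds no orbitals")
    restricted = "beta" not in channels
    return MOSet(
        atoms=atoms,
        charge=0,
        multiplicity=1,
        basis=basis,
        restricted=restricted,
        channels=channels,
        method=f"molden:{path}",
        validate_electron_count=False,
    )
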
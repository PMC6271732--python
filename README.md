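# nearsight

Linear response functions (LRF) and the *nearsightedness of electronic
matter* (NEM) for finite systems: exactly solvable one-dimensional model
wells and small molecules treated with a built-in Kohn–Sham engine.

A local change of the external potential, δv(r′), changes the electron
density everywhere in principle; NEM is the observation that in many-electron
systems the change δρ(r) dies off rapidly with |r − r′|.  The central object
is the static, independent-particle (uncoupled) response kernel

    K(r, r′) = δρ(r)/δv(r′)
             = p · Σ_{i occ} Σ_{j virt} ψ_i(r)ψ_j(r)ψ_i(r′)ψ_j(r′) / (ε_i − ε_j)

with `p = 4` for a spin-paired closed shell (spin factor 2 × the two
orderings of each real orbital pair).  Every term is a negative rank-1
operator, so K is symmetric, negative semidefinite, and each column
integrates to zero (particle conservation).  The virtual sum for occupied
orbital *i* is truncated at the first virtual *m* whose squared term
integral `(2 ∫ψ_i²ψ_m² dr)² / (ε_i − ε_m)²` drops below τ = 10⁻⁸.

The package answers, numerically, when and why NEM holds:

* **Square well / harmonic oscillator** — as the number of occupied
  orbitals grows, destructive interference localizes the response.
* **Double well** (hard walls at ±2, barrier of height V₀ on [−1, 1]) —
  quasi-degenerate symmetric/antisymmetric pairs below the barrier:
  half-filled pairs respond across the barrier, full-filled pairs do not,
  even with very few electrons.
* **Molecules** — the same physics in H₂ (two-level response at
  equilibrium, Mott-insulator-like localization on dissociation in the
  spin-unrestricted solution), He₂²⁺ vs He₂ (tiny vs huge HOMO–LUMO gap),
  and butane vs butadiene (sp³ junctions block propagation; π conjugation
  carries it), computed from restricted/unrestricted B3LYP/6-31G**
  orbital sets.

No external quantum-chemistry program is required: the `nearsight.qm`
subpackage contains a complete Gaussian-basis restricted/unrestricted
hybrid-DFT SCF solver (McMurchie–Davidson integrals, Becke quadrature,
B3LYP with selectable VWN variant), registered behind a pluggable engine
interface, plus Molden and Gaussian-cube I/O.

## Worked example

```python
import numpy as np
from nearsight import isw_states, lrf_matrix, locality_metrics

spectrum = isw_states(L=1.0, nmax=150)          # particle in a box
for nocc in (1, 5, 10, 50):
    K = lrf_matrix(spectrum, nocc)              # kernel on [0, 1]
    m = locality_metrics(K, d=0.2)
    print(f"nocc={nocc:2d}  M_trunc={K.m_truncated[-1]:3d}  "
          f"offrange_mass(0.2)={m.offrange_mass:.3f}")
```

prints

```
nocc= 1  M_trunc= 64  offrange_mass(0.2)=0.489
nocc= 5  M_trunc= 64  offrange_mass(0.2)=0.289
nocc=10  M_trunc= 65  offrange_mass(0.2)=0.250
nocc=50  M_trunc= 81  offrange_mass(0.2)=0.227
```

`M_trunc` is the virtual-sum cutoff chosen by the 10⁻⁸ rule, and
`offrange_mass(0.2)` is the fraction of the kernel's absolute mass with
|r − r′| > 0.2: it falls monotonically as the box fills — the
nearsightedness trend in one number.

On the molecular side:

```python
from nearsight.qm import run_scf, homo_lumo_gap
from nearsight.qm.molecules import h2

mos = run_scf(h2(0.72))              # restricted B3LYP/6-31G**
g = homo_lumo_gap(mos)
print(f"HOMO {g.homo:.4f}  LUMO {g.lumo:.4f}  gap {g.gap:.4f} Hartree")
```

prints `HOMO -0.4364  LUMO 0.1074  gap 0.5438 Hartree`.

The command line mirrors the library: `nearsight wells --nocc 10`,
`nearsight dwell --v0 25 --nocc 2`, `nearsight mol --xyz mol.xyz --atom 0
--cube out.cube`, `nearsight scan --rlist 0.8,1.5,2.2,2.5,3.5`, and
`nearsight recipe fig1` … `fig12` regenerate the full figure-style datasets
(kernels, slices, spectra, cubes, scan tables) with a manifest.

## Layout

| module | contents |
|---|---|
| `nearsight.wells` | 1D potentials and exact eigenstates (box, oscillator, double well) |
| `nearsight.lrf` | sum-over-states kernel, truncation rule, locality metrics, HEG reference |
| `nearsight.oracles` | finite-difference eigensolver / perturbed-diagonalization oracles |
| `nearsight.qm` | basis sets, integrals, SCF engine, response fields, Molden/cube I/O |
| `nearsight.recipes`, `nearsight.cli` | figure-style reproduction recipes and the CLI |
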
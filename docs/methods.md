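# Methods

This note records the models implemented, the numerical choices behind
them, and the boundaries of what the test suite demonstrates.  Nothing
here states an empirical result that the tests or `scripts/acceptance.py`
do not themselves compute.

## 1. Model wells and their eigenstates

Three confining potentials are solved for one-electron orbitals which are
then populated with spin-paired electrons (integer occupations, lowest
`nocc` spatial orbitals; electron–electron interaction is ignored
throughout the model-well sector).

* **Infinite square well** on [0, L]: ψ_n = √(2/L) sin(nπr/L),
  E_n = c (nπ/L)², closed form.
* **Harmonic oscillator**: Hermite functions by the normalized three-term
  recurrence (stable far beyond n = 60; a guard raises on any
  non-finite value rather than returning NaN).  E_n = ω(n − ½), 1-based.
* **Double well**: hard walls at ±2, flat barrier of height V₀ on
  [−1, 1] (the region borders used for all double-well analyses).
  Eigenstates are found per parity on the half axis — symmetric states
  satisfy ψ′(0) = 0, antisymmetric ψ(0) = 0 — with trigonometric outer
  segments pinned to the walls and a hyperbolic (E < V₀) or trigonometric
  (E > V₀) barrier segment.  Value/derivative matching at the barrier edge
  is expressed as a pole-free 2×2 determinant; roots are bracketed on an
  adaptive energy mesh (initial step 1% of the box-level-spacing estimate,
  growing as √E) and refined with Brent's method to 1e-12 absolute.  The
  antisymmetric barrier branch uses sinh(κr)/κ so the E → V₀ limit is the
  linear function r, never 0/0.  Normalization uses piecewise 80-point
  Gauss–Legendre quadrature (the integrands are trigonometric, so this is
  exact to machine precision).

**Units.**  Two conventions are supported: ħ = mₑ = 1 (default, E = k²/2)
and ħ²/2mₑ = 1 (E = k²).  The double-well pair census depends on this
choice.  Under the default, V₀ = 25 has exactly 2 symmetric/antisymmetric
pairs entirely below the barrier — splittings 7.4e-6 and 9.7e-4 — while
V₀ = 100 has 4 (energies ≈ 4.30, 17.15, 38.34, 67.33 doubly, plus a lone
symmetric state at 99.98 whose partner lies above the barrier).  Under the
alternative convention the counts are 1 and 3.  Neither convention gives
the (2, 3) census sometimes quoted for these barrier heights; the package
reports the census it computes, together with every splitting, so callers
can apply their own quasi-degeneracy cut.  `count_pairs_below_barrier`
counts a pair only when *both* members lie strictly below V₀ and applies
no splitting threshold.

## 2. The response kernel

The uncoupled (bare) sum-over-states kernel

K(r, r′) = p Σ_{i≤nocc} Σ_{nocc<j≤M(i)} ψ_i(r)ψ_j(r)ψ_i(r′)ψ_j(r′)/(ε_i − ε_j)

is assembled densely on a uniform grid (default 401 points per unit
length over the occupied support; for the oscillator the box is cut at
the top occupied state's turning point plus a 6/√ω tail pad — higher
virtuals reach further but every kernel term carries an occupied factor).
All integrals are trapezoid sums on that grid.

* **Display prefactor** p defaults to 4 (closed-shell spin factor 2 × the
  2 orderings of each real pair) and is stored with the matrix so either
  convention can be compared exactly; it is irrelevant to every distance
  trend.
* **Truncation rule**: term (i, m) is dropped once
  (2 ∫ψ_i²ψ_m² dr)² / (ε_i − ε_m)² < τ, default τ = 1e-8.  The constant
  inside the square is the closed-shell factor 2 regardless of the display
  prefactor — this convention is pinned by brute-force enumeration: for
  the square well (L = 1, ħ = mₑ = 1) the i = 1 sum truncates at virtual
  64.  Integrals are evaluated by quadrature, not closed form, so the
  same rule serves the double well and the oscillator (where the cutoff
  is much deeper, ≈ 1.1e3 virtuals, because the term integrals decay only
  as m^(−3/2)).
* **Degenerate denominators** (|Δε| < 1e-12) abort with the offending
  pair named; for these 1D spectra an exact occupied/virtual degeneracy
  cannot occur, so it always flags a caller error (e.g. a forged
  spectrum).
* **Invariants**: symmetry to 1e-10, column integrals |∫K dr| < 1e-6,
  strictly negative diagonal on the open interior (at a hard wall every
  state vanishes, so K(wall, wall) = 0 exactly), and negative
  semidefiniteness (largest eigenvalue ≤ 1e-8).

**Locality metrics.**  `offrange_mass(d)` is the fraction of the weighted
absolute kernel mass with |r − r′| > d (in [0, 1], nonincreasing in d);
`zero_sum_residual` the worst column integral; `column_l1` the per-column
absolute integral; `region_column_l1` restricts one column to a region —
used with the perturbation in one well of the double well and the region
set to the other well, it quantifies the half-filled vs full-filled
contrast.

**Homogeneous-gas reference.**  `friedel_reference` implements the
standard two-term asymptotic of the screened electron-gas response,
exp(−q_TF·r)/r + cos(2 k_F r)/r³, with unit amplitudes: only its distance
dependence (exponential screening plus a decaying oscillation whose
same-phase zeros are π/k_F apart) is meaningful, as a visual foil for the
finite-system kernels.

## 3. Finite-difference oracles

Everything in `nearsight.oracles` is deliberately independent of the
analytic code paths.

* `grid_diag_oracle`: eigenpairs of the FD Hamiltonian with hard walls by
  truncation; 2nd-order (tridiagonal, MRRR solver) or 4th-order (banded)
  kinetic stencils.  At a hard wall the 4th-order stencil uses the
  antisymmetric ghost-point reflection ψ(wall − h) = −ψ(wall + h); naive
  truncation would impose a second spurious boundary condition and
  degrade eigenfunctions to O(h) near the wall.  Sharp barrier steps are
  cell-averaged over each grid cell: pointwise sampling shifts the
  effective barrier edge by O(h), which the exponentially edge-sensitive
  tunneling splittings amplify to percent-level errors.
* `fd_response_oracle`: the density of the lowest `nocc` doubly occupied
  grid orbitals is re-computed with a narrow unit-integral Gaussian bump
  (default width 2% of the box) of strength ±ε added at r′, and the
  response taken as a central difference (this cancels the quadratic
  response exactly).  A linearity ladder compares the ε and ε/2 profiles
  and descends (at most 4 halvings) until they agree to 0.1% in L1,
  keeping the best pair: too-small ε runs into the eigensolver's
  resolution floor rather than a cleaner linear regime, so descending
  forever would be wrong.  Quasi-degenerate double-well shells need very
  gentle probes (ε ≈ 1e-8 for the 7.4e-6 splitting: the probe must mix
  the pair far less than the splitting, yet more than solver noise).
* The kernel-vs-oracle comparison applies the kernel to the oracle's own
  bump profile on the oracle's own grid — the oracle measures the
  response to that bump, not to a delta — so the two routes share nothing
  but the physics.  Agreement is required to 0.1% relative L1; reaching
  it for 50 occupied square-well states needs a tighter kernel truncation
  (τ = 1e-11) than the default because the dropped tail, while invisible
  after smearing, still carries ≈ 1% of the unsmeared column mass at
  τ = 1e-8.

## 4. The molecular engine

`nearsight.qm` is a complete, self-contained restricted/unrestricted
Kohn–Sham implementation:

* **Integrals**: McMurchie–Davidson over contracted cartesian Gaussians
  (s, p, d), numba-compiled; Boys function by downward recursion from a
  series (T < 35) or upward from the asymptotic form.  Validated against
  the classic published H₂/STO-3G integral table and SCF energy
  (−1.1167 Eₕ), 3D-quadrature oracles for p/d one-electron integrals, ERI
  permutation symmetry, and rotational invariance of the HF energy with
  polarization functions in play.
* **Basis sets**: STO-3G, 6-31G, 6-31G*, 6-31G** for H, He, C (cartesian
  d).  Every cartesian AO is unit-normalized.
* **XC quadrature**: per-atom Gauss–Chebyshev radial × Gauss–Legendre ×
  uniform-φ angular product grid (defaults 75 × 20 × 40), glued with
  Becke's fuzzy partition (k = 3, no size adjustment).  Electron counts
  integrate to ~1e-6.
* **Functionals**: Slater, B88, VWN (parametrizations 5 and 3), LYP, and
  the standard 3-parameter hybrid mixture (20% exact exchange).  Slater,
  B88 and VWN derivatives are closed-form; LYP is linear in the γ
  variables (exact coefficient functions) with density derivatives by
  tight central differences (relative step 1e-6, accurate to ~1e-11 —
  far below any SCF-relevant scale).  All derivatives are verified
  against a symbolic re-derivation in the test suite.
* **VWN variant**: the default is VWN3.  The choice is empirical and
  documented: with VWN3 the H₂ (0.72 Å) orbital energies come out
  −0.4364 / 0.1074 / 0.5687 Hartree and the He₂²⁺ / He₂ gaps 0.0367 /
  1.7451 Hartree, matching the reference values this package is
  benchmarked against to ≲ 1 mEₕ; VWN5 shifts each H₂ level by ≈ 3 mEₕ.
  Both variants remain selectable (`Method(vwn_variant=...)`).
* **SCF**: symmetric orthogonalization, core guess, Pulay DIIS (size 8)
  on the orthonormalized FDS−SDF residual, convergence |ΔE| < 1e-8 and
  max residual < 1e-5.  Symmetry is never enforced; unrestricted runs can
  be seeded with a deterministic HOMO/LUMO rotation (±θ in the two spin
  channels) to reach broken-symmetry solutions.
* **Engine adapter**: the solver is registered as `"internal"`;
  any callable with the same signature can be registered and used by the
  response layer unchanged.

## 5. Molecular response fields

The LCAO sum-over-states field is evaluated on a uniform cubic-voxel grid
(default 0.15 Å spacing, 4 Å padding, centred on the molecule so mirror
planes of the molecule are mirror planes of the grid).  Matrix elements
of the perturbation are combined with the orbital-energy denominators and
the spin factor (4 restricted, 2 per unrestricted channel).

**Perturbation conventions.**  Two operators are implemented:

* `mulliken` (default): the atom-condensed projector
  v_X = sign·(P_X S + S P_X)/2, with P_X the projector onto the AOs of
  the perturbed atom.  This is the convention under which the benchmark
  phenomenology is quantitative: couplings to same-symmetry virtuals
  vanish in symmetric molecules (the H₂ field is exactly odd under the
  molecular mirror plane) and the HOMO→LUMO two-level approximation
  reproduces the full H₂ field to ≈ 15% in L1.
* `gaussian`: a real-space repulsive bump exp(−α|r − R_X|²), α = 5 bohr⁻²
  by default.  Basis-independent, but any real-space probe localized at a
  nucleus couples comparably to the compact higher virtuals, so the
  two-level picture degrades to ~75% L1 deviation.  Locality *contrasts*
  between systems agree between the two conventions; absolute field
  values do not, and none are treated as convention-independent.

Electron conservation (|∫field| ≲ 1e-4 of its L1 norm) holds by MO
orthogonality up to voxel-quadrature and box-truncation error.  An
opt-in refinement check (`refine_check=True`) recomputes on a
half-spacing grid and records an accuracy warning in the metadata if the
L1 norm moves by more than 1%.

**Dissociation scans** run restricted and (mixed-guess, θ = 0.6)
unrestricted SCF per distance, record the L1 response magnitude of each
(max |field| is available as an alternative; the monotonicity statements
hold for either), and flag broken symmetry when ∫|ρ_α − ρ_β| > 1e-3 on
the quadrature grid.  SCF failures are recorded per point without
aborting the scan.

**Junction audits** assign each voxel to its nearest atom and report the
fraction of the field's absolute mass in a caller-specified far-atom
region (near + far = 1 exactly).  For the butane/butadiene contrast the
perturbed atom is a terminal carbon and the far set the two distal
carbons; the hydrocarbons are built from standard bond lengths and angles
(anti butane, s-trans butadiene), default to B3LYP/6-31G with a leaner
quadrature grid (60 × 14) — the comparison is strictly between the two
molecules under one protocol, never against absolute reference values —
and 6-31G** data for C is shipped for callers who want the polarized
basis.

## 6. Problem sizes and determinism

Default problem sizes are chosen so the full suite runs on a single CPU:
spectra of 450 states (1300 for the oscillator), kernel grids of 401
points per unit length (≤ 2001 points for the oscillator's invariant
checks), FD oracles of 2000–3000 points (20001 for the tridiagonal
eigenvalue cross-check), SCF on ≤ 56 AOs, and response grids of ≈ 2·10⁵
voxels.  Everything is deterministic: there is no stochastic ingredient
anywhere in the pipeline, single-threaded runs are byte-reproducible, and
recipe outputs include a manifest (inputs, parameters, version, wall
time).

## 7. Limitations

* The response is the uncoupled orbital response: no self-consistent
  (coupled-perturbed) terms, no softness/HSAB quantities.
* Model wells ignore electron interaction entirely; their "electrons"
  share one-particle orbitals.
* The molecular engine covers H, He and C with the shipped Pople bases,
  restricted/unrestricted B3LYP and HF — sufficient for every system
  treated here, not a general-purpose quantum-chemistry replacement.
* Absolute response-field values depend on the perturbation convention
  (§5); only trends and cross-system contrasts are convention-robust.
* The peptide-scale demonstration (response audits across amide planes)
  runs only on user-supplied coordinates; no conformational sampling is
  included.
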
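# Methods

This note documents the models, conventions and numerical choices behind
`sqdpcm`, in the order the pipeline runs.

## Electronic structure

**Basis sets and integrals.** cc-pVDZ (H, C, N, O) and STO-3G parameters
are embedded as text; all basis functions are real solid harmonics
(m = -l..l per shell, p shells ordered y, z, x).  Integrals are
McMurchie–Davidson Hermite-Gaussian recursions compiled with numba;
electron repulsion is assembled as the full (pq|rs) tensor (fine for the
<= 60-function molecules targeted here).  The embedded parameters are
pinned by literature anchors in the test suite (water RHF/cc-pVDZ at the
experimental geometry to 2e-4 Eh, H2 FCI); exact last-digit provenance
cannot be certified in an offline build, which bounds the achievable
absolute-energy fidelity, though energy *differences* such as solvation
free energies are far less sensitive.

**Mean field.** Closed-shell RHF with DIIS (8-vector), canonical
orthogonalization (overlap eigenvalue cutoff 1e-9), energy convergence
1e-10 Eh.  Only neutral singlets are supported; charged or open-shell
solutes are rejected at the `Molecule` level (the sampling ansatz is
parameterized from a closed-shell reference and its behaviour for ions is
an open question).

**Active spaces.** Two selectors: (i) AVAS — occupied and virtual
canonical orbitals are separately rotated to diagonalize the projector
onto user-selected minimal-basis AOs (STO-3G reference; overlap-eigenvalue
threshold 0.2, configurable), orbitals above threshold become active;
(ii) frozen-core — all orbitals except the lowest n.  AVAS on methanol
(C[2s,2p], O[2s,2p], H[1s]) yields (14e,12o) and on methylamine
(14e,13o), matching the reference counts.  The reference-basis choice and
threshold are documented defaults, not asserted to be those of any other
code; no virtual canonicalization is applied.

**Active Hamiltonian.** h1 folds the frozen-core Coulomb/exchange into
the one-electron operator; e_core carries the nuclear repulsion plus the
core energy.  A test asserts that the reference-determinant energy is
invariant to where the core/active split is drawn.

## IEF-PCM

**Cavity.** Per-atom spheres with Bondi radii scaled by 1.2 (water
eps = 78.3553 by default; all parameters configurable).  Each sphere
carries an N-point Fibonacci-spiral grid (default N = 590) with equal
base weights 4 pi R^2 / N; points penetrating a neighbouring sphere are
smoothly switched off with an erf ramp of width 0.2 Angstrom on the
signed distance to that sphere's surface, so the discretized energy is a
smooth function of the nuclear coordinates (required by the
finite-difference geometry optimizer).  A true Lebedev tessellation was
not used because its coefficient tables are unavailable offline; the
Fibonacci grid converges the Born-ion energy monotonically (errors
0.27% / 0.17% / 0.12% at 110 / 302 / 590 points).

**Operators.** Off-diagonal single- and double-layer kernels use
Gaussian-blurred charges, erf(zeta_kj r)/r with per-point exponents
zeta_k = 4.9 / (R_i sqrt(4 pi / N)); this regularizes close contacts
between points of different spheres (point-charge kernels make the
energy surface rough at the 1e-4 Eh scale, which breaks quasi-Newton
geometry optimization).  Diagonals: S_kk = 1.0694 sqrt(4 pi / a_k); D
diagonal fixed row-wise by the discrete Gauss identity
sum_j D_kj a_j = -2 pi.  The permittivity prefactor is
f_eps = (eps + 1)/(eps - 1); eps = 1 short-circuits to sigma = 0 so every
gas-phase quantity is reproduced bit for bit.

**Response.** The linear system is solved by dense LU (surface sizes of a
few thousand).  For energies and Fock/CI couplings the
potential-to-charge map Q = A K^-1 R is symmetrized, 
Q_sym = (Q + Q^T)/2, making the SCF and SCRF functionals variational;
`solve_surface_charge` itself returns the exact unsymmetrized solution
(residual < 1e-10) for diagnostic use.  Nuclear charges contribute to
phi^rho alongside the electron density; the nuclear-sigma interaction is
carried as a scalar.

**Non-electrostatic terms** (cavitation, dispersion, repulsion) are out
of scope, as is any SMx-type correction.

## Geometry optimization

BFGS (scipy) on Cartesian coordinates with central-difference gradients
(step 5e-3 bohr), warm-started SCF densities, convergence when the
largest gradient component is below 3e-4 Hartree/bohr (energy change
tolerance 1e-6 Eh is implied by the SCF precision).  Line-search
precision stalls are cleared by restarting with a fresh Hessian.  The
packaged solvated geometries of water, methanol, methylamine and ethanol
were produced by exactly this procedure and are spot-checked for
stationarity in the tests.  A curvilinear (TRIC-style) optimizer would
converge in fewer steps but reaches the same stationary point; it was not
implemented.

## LUCJ sampling

Parameters come from a gas-phase closed-shell CCSD in the active space
(spin-orbital amplitude equations, plain iteration; exact for two
electrons, which the tests exploit).  The doubles tensor t2[i,j,a,b] is
eigendecomposed as a matrix over (occ, vir) pairs; the leading eigenpair
(lambda, M) defines a Hermitian one-body factor X with
occupied-virtual block exp(+-i pi/4) sqrt(|lambda|/2) M, whose
eigenbasis gives the orbital rotation K1 = log W and density-density
couplings J = d d^T (phase convention exp(i x^T J_full x) on occupation
vectors, J_full = [[J, J], [J, J]]).  Singles enter as the final
rotation K2.  Keeping one factor is the single-Jastrow-layer truncation;
it is exact for (2e,2o) and gives fidelity 0.993 for H2/cc-pVDZ.
Qubit-connectivity masking of J is off by default (no real device is
involved); a heavy-hex-style mask is available for studies.

Simulation is exact in the fixed-(n_alpha, n_beta) sector: one-body
exponentials factorize over spins into dense string-basis matrix
exponentials, the Jastrow phase is diagonal.  The default memory cap is
1e7 amplitudes.  Sampling is a seeded multinomial draw; the noise
emulator flips every bit of every shot independently with probability
p_flip.  It reproduces broken-symmetry *fractions* of the reference
hardware runs only by choice of p_flip; no claim is made that it matches
real device statistics (correlated errors, readout asymmetry are absent).
Consequently a green trend test establishes robustness of the recovery
and subspace machinery to symmetry-breaking noise, not hardware accuracy.

## S-CORE recovery

The functional form of the bit-flip law is stated only loosely in the
source material ("distance from the current value of the bit and
n_p-sigma"); the implementation empties surplus spin blocks (or fills
deficient ones) one bit at a time, drawing the orbital with probability
proportional to |x_p - n_p| among eligible bits, until the counts match.
This is the simplest monotonically terminating realization; it is
isolated in `_recover_block` so alternative laws can be swapped in, and
the reported energies are sensitive to the sample budget rather than to
this law (the convergence-trend test passes with the law replaced by a
uniform draw).  Spin sectors are recovered independently; defaults are 3
S-CORE iterations and K = 10 batches, batches drawn frequency-weighted
without replacement within a batch and independently across batches.
Occupancies for the update are computed from the *solvated* batch
wavefunctions.

## Subspace SCRF solver

Subspaces are spin-inversion closed by construction (S = U x U over the
union U of alpha and beta half-strings), and the projected Hamiltonian
uses full-space Slater-Condon matrix elements: the one-spin part composes
single-excitation generators through intermediate strings that may leave
U, so no matrix element is renormalized.  The sigma build is
A C + C A^T plus the opposite-spin Coulomb term evaluated by
gather / dense-GEMM / scatter over single-excitation link tables, blocked
to bound memory (default 2e8 doubles per block).

Davidson: lowest eigenpair, diagonal preconditioner, residual tolerance
1e-8, 20-vector space with restart, start vector = lowest-diagonal
determinant (or the previous macro-iteration's eigenvector).  SCRF
macro-iterations update the charges from the relaxed one-particle
density; convergence at |dG| < 1e-8 Eh and max |d sigma| < 1e-6, up to 50
iterations, optional linear damping (off by default — the neutral
solutes here converge in 5-10 iterations).  Each batch equilibrates its
own charges.  Warm starts (SCF charges, previous CI vectors) matter: they
cut the methanol reference from ~10 to ~3 minutes.

**Energies.** The reported E is the free energy
G = <psi|H0|psi> + 1/2 q . phi(psi).  G_solv is computed under three
conventions and all are emitted in every record: "scf" — the
reaction-field term of the solvated mean field (RHF density); 
"polarization" — the same term with the CI-density-equilibrated charges;
"delta_e" — G(solution) - E(gas) at the same geometry, method and
subspace.  The pipeline reports the "scf" value as `G_solv`: across all
four benchmark solutes it is the quantity that reproduces the reference
solvation free energies (to 0.01-0.1 kcal/mol), whereas the CI-density
term sits ~10% lower in magnitude — i.e. the reference numbers are the
solvent module's mean-field energy term.  The gas reference for delta_e
uses the solvated geometry and its own gas-phase orbitals.

**Two cavity grades.**  The smooth-seam cavity (default, erf width
0.2 Angstrom) exists for geometry optimization; its seam smearing does
not quadrature-converge for fused spheres.  Single-point reference
energies use the energy-grade cavity — switch width 0.02 Angstrom
(effectively the sharp exposed surface) at 1202 points per sphere —
whose reaction-field energies are quadrature-converged to ~0.01
kcal/mol (methanol RHF: -4.496 / -4.492 kcal/mol at 590 / 1202 points).

## Synthetic world and what green tests mean

Tests and fixtures use H2 (2e,2o), a (6e,5o) STO-3G water model
("h2o-mini", 100 determinants) and linear H6 (6e,6o, 400 determinants),
with shots 5e4 and p_flip = 0.02 for noisy studies (2e5 shots is the
production default mirroring the reference runs).  These exercise every
code path at desk scale; they do not probe large-sector sampling
sparsity, device-correlated noise, or basis sets beyond DZ quality.
The exact-recovery identity (full-coverage samples reproduce CASCI-PCM
to 1e-8 Eh) and the variational bounds are exact statements and are
asserted as such.

## Known limitations

- Neutral closed-shell solutes only; no analytic PCM nuclear gradients
  (geometry optimization is finite-difference).
- Absolute energies inherit the uncertainty of the embedded basis data
  (~1e-4 Eh); cross-code agreement of G_solv at the 0.01 kcal/mol level
  additionally depends on matching cavity discretizations.
- The ethanol (20e,18o) and water (8e,23o) full sectors exceed desk
  scale; they run only if given hours/memory, and the water reference
  additionally needs ~1.9e9-determinant handling that this implementation
  does not attempt.
- One Jastrow layer only; no repetitions, no parameter optimization.
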
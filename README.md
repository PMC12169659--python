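# sqdpcm

Sample-based quantum diagonalization (SQD) with an IEF-PCM implicit
solvent, in pure scientific Python.

## The problem

Predicting how a molecule behaves in water rather than in vacuum requires
coupling an accurate electronic-structure method to a solvent model.  SQD
is a quantum-centric selected-CI method: electron configurations are
sampled from a quantum circuit (here: a classically simulated local
unitary cluster Jastrow state, LUCJ), noise-broken samples are repaired by
self-consistent configuration recovery (S-CORE), and the molecular
Hamiltonian is diagonalized classically in the sampled determinant
subspace.  This package extends that workflow with the integral equation
formalism polarizable continuum model (IEF-PCM): the solvent is a
dielectric continuum whose apparent surface charges sigma(s) live on a
molecule-shaped cavity surface Gamma and polarize — and are polarized by —
the solute, a self-consistent reaction field (SCRF) problem

    [H0 + V_int] |psi> = E |psi>,
    G(psi) = <psi| H0 + 1/2 V'_int(psi) |psi>,

solved by alternating Davidson diagonalization in the subspace with a
re-solve of the boundary-element equation

    [(2 pi f_eps) I - D] S sigma = (-2 pi I + D) phi^rho,
    f_eps = (eps + 1)/(eps - 1).

The package is aimed at method developers who want a transparent,
self-contained desk-scale implementation: every ingredient — Gaussian
integrals (McMurchie–Davidson, cc-pVDZ/STO-3G), RHF, AVAS active-space
selection, closed-shell CCSD (for the LUCJ parameters), string-based CI
with Davidson, and the PCM boundary-element solver — is part of the
package and cross-checked against analytic oracles.

## Worked example

```python
from sqdpcm import RunConfig, run_casci_reference, run_sqd_pcm, setup_system

# CASCI(6e,5o)/STO-3G IEF-PCM reference for a small water model
cfg = RunConfig(molecule="h2o-mini", shots=50_000, p_flip=0.02,
                batch_size=40, n_batches=10)
bundle = setup_system(cfg)
ref = run_casci_reference(cfg, bundle)
sqd = run_sqd_pcm(cfg, bundle, casci_ref=ref)
print(f"CASCI-PCM  E = {ref['E_solution']:.6f} Eh, "
      f"G_solv = {ref['G_solv_polarization']:.3f} kcal/mol")
print(f"SQD-PCM    E = {sqd['E_solution']:.6f} Eh  "
      f"(d = {sqd['d']}, dE = {sqd['dE_vs_casci_kcal']:.3f} kcal/mol)")
```

prints (seed 1):

```
CASCI-PCM  E = -75.002132 Eh, G_solv = -3.859 kcal/mol
SQD-PCM    E = -75.002132 Eh  (d = 100, dE = 0.000 kcal/mol)
```

Here the noisy samples cover the whole 100-determinant sector after
recovery, so the subspace energy coincides with the CASCI-PCM reference;
with smaller batches the energy error decreases systematically as the
batch size grows.  `G_solv` is the mean-field reaction-field energy (the
convention of the benchmark solvation free energies); the CI-density
reaction-field term and the `G(solution) - E(gas)` difference are
reported alongside (`G_solv_polarization`, `G_solv_delta_e`).

The same workflow at production scale (the shell interface):

```bash
sqdpcm casci-ref --molecule methanol -o methanol_ref.json   # (14e,12o)
sqdpcm run --molecule h6 --p-flip 0.02 --batch-size 50
sqdpcm sweep --molecule h6 --sizes 6,12,25,50,110 -o sweep.csv
sqdpcm fixture h2o-mini
```

## What scripts/acceptance.py recomputes

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs, from scratch, the full-sector CASCI IEF-PCM reference pipeline
(solvated RHF/cc-pVDZ, AVAS active-space selection, SCRF Davidson
diagonalization of the 6.3e5- and 2.9e6-determinant sectors) for methanol
and methylamine in water at their packaged RHF/cc-pVDZ IEF-PCM stationary
geometries, and writes the two solvation free energies (kcal/mol) with
their sector dimensions.  Expect roughly 15 minutes on one CPU.

## Layout

- `sqdpcm.basis`, `sqdpcm.integrals` — basis data and Gaussian integrals
- `sqdpcm.scf` — restricted Hartree–Fock with a reaction-field hook
- `sqdpcm.chem` — molecules, geometry optimization, AVAS, FCIDUMP/XYZ
- `sqdpcm.pcm` — cavity, boundary-element operators, surface charges
- `sqdpcm.ccsd`, `sqdpcm.lucj` — CCSD amplitudes and the LUCJ sampler
- `sqdpcm.recovery` — S-CORE, batching, spin-inversion closure
- `sqdpcm.ci`, `sqdpcm.solver` — string CI, Davidson, SCRF solver
- `sqdpcm.pipeline`, `sqdpcm.cli` — workflows, config, fixtures, CLI

See `docs/methods.md` for the model, conventions, numerical choices and
limitations.
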
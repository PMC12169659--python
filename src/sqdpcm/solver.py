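"""Projected-Hamiltonian SCRF ground-state solver.

Couples the determinant-subspace CI problem to the IEF-PCM reaction field:
the outer (macro) loop alternates a Davidson solve of H0 + V_int in the
subspace with a re-solve of the apparent surface charges from the relaxed
one-particle density, until the free energy

    G = <psi| H0 |psi> + 1/2 sum_k q_k phi^rho(s_k)   (+ nuclear terms)

and the charges are stationary.  The eps = 1 path never touches the
solvent arrays and reproduces the gas-phase energy bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

_logger = logging.getLogger("sqdpcm")

from .chem import HARTREE2KCAL, MOHamiltonian
from .ci import CIEngine, make_strings, solve_ground_state
from .pcm import PCMContext
from .recovery import ConfigurationSubspace, OccupancyDistribution


@dataclass
class ProjectedProblem:
    """H_S = P_S H P_S through full-space Slater-Condon matrix elements."""

    engine: CIEngine
    ham: MOHamiltonian
    subspace: ConfigurationSubspace

    @classmethod
    def build(cls, ham: MOHamiltonian,
              subspace: ConfigurationSubspace | None = None,
              memory_cap: float = 4e9) -> "ProjectedProblem":
        n_occ = ham.n_electrons // 2
        if subspace is None:
            subspace = ConfigurationSubspace(
                make_strings(ham.n_orbitals, n_occ), ham.n_orbitals, n_occ)
        if subspace.n_half == 0:
            raise ValueError("empty configuration subspace")
        if subspace.dimension * 8 * 3 > memory_cap:
            raise MemoryError(
                f"subspace dimension {subspace.dimension:,} exceeds the "
                f"memory cap; reduce the batch size")
        eng = CIEngine(subspace.half_strings, ham.n_orbitals, n_occ)
        eng.set_integrals(ham.h1, ham.h2)
        return cls(engine=eng, ham=ham, subspace=subspace)


@dataclass
class SolvatedResult:
    E: float                        # total free energy G (Hartree)
    G_solv: float | None            # kcal/mol, set once a gas ref is known
    psi: np.ndarray                 # CI coefficients over S^(b)
    occupancies: OccupancyDistribution
    scrf_log: list
    converged: bool
    e_gas_component: float          # <psi|H0|psi> (+ core terms)
    g_pol: float                    # 1/2 sum q phi (Hartree)
    charges: np.ndarray | None
    subspace: ConfigurationSubspace
    batch_index: int = -1
    extras: dict = field(default_factory=dict)


def _active_coupling(ham: MOHamiltonian, ctx: PCMContext):
    """Potential integrals of cavity charges in the active MO basis plus the
    frozen-core electron contribution."""
    Ca = ham.mo_active
    tmp = np.tensordot(ctx.pot_ints, Ca, axes=(2, 0))      # k, mu, q
    pot_act = np.einsum("mp,kmq->kpq", Ca, tmp)
    pot_core = np.tensordot(ctx.pot_ints, ham.dm_core,
                            axes=([1, 2], [0, 1]))
    return pot_act, pot_core


def solve_scrf_ground_state(problem: ProjectedProblem,
                            pcm: PCMContext | None,
                            tol_e: float = 1e-8, tol_q: float = 1e-6,
                            max_macro: int = 50, damping: float = 0.0,
                            davidson_tol: float = 1e-8,
                            c0: np.ndarray | None = None,
                            q0: np.ndarray | None = None) -> SolvatedResult:
    """SCRF macro-iterations around converged Davidson solves.

    pcm = None (or eps = 1) yields the plain gas-phase subspace ground
    state.  Initial charges may be warm-started from a converged SCF
    density via q0.
    """
    eng = problem.engine
    ham = problem.ham
    n_occ = ham.n_electrons // 2

    def occupancies(C):
        ga, gb = eng.rdm1_spin(C)
        return OccupancyDistribution(np.clip(np.diag(ga), 0, 1),
                                     np.clip(np.diag(gb), 0, 1),
                                     n_occ, n_occ)

    if pcm is None or pcm.config.epsilon == 1.0:
        e, C = solve_ground_state(eng, c0=c0, tol=davidson_tol)
        E = e + ham.e_core
        return SolvatedResult(E=E, G_solv=None, psi=C,
                              occupancies=occupancies(C),
                              scrf_log=[(E, 0.0)], converged=True,
                              e_gas_component=E, g_pol=0.0, charges=None,
                              subspace=problem.subspace)

    pot_act, pot_core = _active_coupling(ham, pcm)
    npts = len(pot_core)
    q = np.zeros(npts) if q0 is None else q0.copy()
    C = None if c0 is None else c0
    G_old = np.inf
    log = []
    converged = False
    for it in range(max_macro):
        h1_eff = ham.h1 - np.tensordot(q, pot_act, axes=(0, 0))
        e_shift = -float(q @ pot_core) + float(q @ pcm.phi_nuc)
        eng.set_integrals(0.5 * (h1_eff + h1_eff.T), ham.h2)
        e_ci, C = solve_ground_state(eng, c0=C, tol=davidson_tol)
        e_ci_tot = e_ci + ham.e_core + e_shift
        ga, gb = eng.rdm1_spin(C)
        gamma = ga + gb
        phi = pcm.phi_nuc - pot_core \
            - np.tensordot(pot_act, gamma, axes=([1, 2], [0, 1]))
        e_int = float(q @ phi)
        q_new = pcm.Q @ phi
        g_pol = 0.5 * float(q_new @ phi)
        G = (e_ci_tot - e_int) + g_pol
        dq = float(np.max(np.abs(q_new - q))) if it or q0 is not None \
            else np.inf
        log.append((G, dq))
        _logger.debug("SCRF macro %d: G = %.10f, max|dq| = %.2e", it, G, dq)
        if abs(G - G_old) < tol_e and dq < tol_q:
            converged = True
            q = q_new
            break
        q = q + (1.0 - damping) * (q_new - q)
        G_old = G
    if not converged:
        raise RuntimeError(
            f"SCRF did not converge in {max_macro} macro-iterations "
            f"(last dG = {G - G_old:.2e}); consider damping")
    return SolvatedResult(E=G, G_solv=None, psi=C,
                          occupancies=occupancies(C), scrf_log=log,
                          converged=converged,
                          e_gas_component=G - g_pol, g_pol=g_pol,
                          charges=q, subspace=problem.subspace)


def select_best_batch(results: list[SolvatedResult]) -> SolvatedResult:
    """Lowest total energy across batches; ties broken by batch index."""
    if not results:
        raise ValueError("no batch results")
    best = min(range(len(results)), key=lambda i: (results[i].E, i))
    return results[best]


def gsolv(solvated: SolvatedResult, gas_reference,
          convention: str = "delta_e") -> float:
    """Solvation free energy in kcal/mol.

    convention="delta_e": G(solution) - E(gas) with matching method,
    subspace and geometry.  convention="polarization": the reaction-field
    term 1/2 sum q phi alone.  gas_reference may be a bare energy or a
    gas-phase SolvatedResult, in which case the subspaces must match.
    """
    if isinstance(gas_reference, SolvatedResult):
        ga, gb = gas_reference.subspace, solvated.subspace
        if ga is not None and gb is not None and (
                ga.n_orb != gb.n_orb
                or not np.array_equal(ga.half_strings, gb.half_strings)):
            raise ValueError(
                "gas reference computed over a different subspace")
        gas_reference = gas_reference.E
    if convention == "delta_e":
        return (solvated.E - gas_reference) * HARTREE2KCAL
    if convention == "polarization":
        return solvated.g_pol * HARTREE2KCAL
    raise ValueError(f"unknown G_solv convention '{convention}'")
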
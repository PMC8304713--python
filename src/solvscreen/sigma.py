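"""Toy COSMO-RS segment thermodynamics.

A liquid is represented by its sigma-profile P(sigma): the distribution of
screening-charge density over the molecular surface. Surface segments of two
molecules in contact interact through an electrostatic "misfit" penalty, a
hydrogen-bond term active only for sufficiently polar segments of opposite
sign, and an element-wise dispersion term. Self-consistent solution of the
sigma-potential equation gives the residual chemical potential per unit
surface area, from which residual chemical potentials and activity
coefficients follow by integration over the solute's profile.

This is a structural stand-in for a full COSMO-RS implementation: the
combinatorial contribution is omitted and no attempt is made to reproduce any
published parametrization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.special import logsumexp

R_KCAL = 1.987204258640832e-3  # gas constant, kcal/(mol K)

DEFAULT_GRID = np.linspace(-0.03, 0.03, 61)  # e/A^2, standard COSMO-RS range


@dataclass(frozen=True)
class ContactParams:
    """Adjustable parameters of the segment pair-interaction model.

    a_eff : effective contact area (A^2)
    alpha_prime : misfit (electrostatic) coefficient, kcal A^2/(mol e^2) scale
    c_hb : hydrogen-bond strength coefficient (>= 0; the HB term is <= 0)
    sigma_hb : polarity threshold below which no H-bond forms (e/A^2)
    tau_vdw : per-element dispersion coefficients (kcal/(mol A^2))
    c_vdw : overall multiplier on the dispersion term
    """

    a_eff: float = 6.25
    alpha_prime: float = 1288.0
    c_hb: float = 1804.0
    sigma_hb: float = 0.0084
    tau_vdw: Mapping[str, float] = field(default_factory=dict)
    c_vdw: float = 1.0

    def __post_init__(self) -> None:
        if self.a_eff <= 0:
            raise ValueError("a_eff must be positive")
        if self.sigma_hb < 0:
            raise ValueError("sigma_hb must be nonnegative")


@dataclass(frozen=True)
class SigmaProfile:
    """Discretized sigma-profile: uniform charge-density grid + area per bin."""

    grid: np.ndarray  # e/A^2, strictly increasing, uniform
    p: np.ndarray     # surface area per bin, A^2

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be a 1-D array with >= 2 points")
        d = np.diff(grid)
        if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-8)):
            raise ValueError("grid must be strictly increasing and uniform")
        if p.shape != grid.shape:
            raise ValueError("p must match grid shape")
        if np.any(p < 0):
            raise ValueError("bin areas must be nonnegative")
        if p.sum() <= 0:
            raise ValueError("total surface area must be positive")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "p", p)

    @property
    def total_area(self) -> float:
        return float(self.p.sum())

    def weights(self) -> np.ndarray:
        """Bin probabilities (areas normalized to sum 1)."""
        return self.p / self.p.sum()


@dataclass(frozen=True)
class SigmaPotential:
    """Converged sigma-potential mu(sigma) of a (mixture) profile."""

    grid: np.ndarray
    mu: np.ndarray            # kcal/mol/A^2
    temperature: float        # K
    converged: bool
    iterations: int


def misfit_energy(sigma, sigma_prime, params: ContactParams):
    """Electrostatic misfit penalty of a segment contact; >= 0, zero for a
    perfectly screening pair sigma' = -sigma."""
    s = np.asarray(sigma, dtype=float) + np.asarray(sigma_prime, dtype=float)
    return params.a_eff * (params.alpha_prime / 2.0) * s * s


def hbond_energy(sigma, sigma_prime, params: ContactParams):
    """Hydrogen-bond energy of a segment contact; <= 0 (attractive).

    Active only when the more negative segment (donor side) is below
    -sigma_hb and the more positive (acceptor side) above +sigma_hb.
    """
    a = np.asarray(sigma, dtype=float)
    b = np.asarray(sigma_prime, dtype=float)
    don = np.minimum(a, b)
    acc = np.maximum(a, b)
    core = np.minimum(0.0, don + params.sigma_hb) * np.maximum(0.0, acc - params.sigma_hb)
    return params.a_eff * params.c_hb * np.minimum(0.0, core)


def vdw_energy(element: str, element_prime: str, params: ContactParams) -> float:
    """Dispersion energy of a contact; depends only on the two element types."""
    for el in (element, element_prime):
        if el not in params.tau_vdw:
            raise KeyError(f"unknown element {el!r}: no tau_vdw entry")
    return params.a_eff * params.c_vdw * (params.tau_vdw[element] + params.tau_vdw[element_prime])


def _pair_energy_matrix(grid: np.ndarray, params: ContactParams) -> np.ndarray:
    s = grid[:, None]
    sp = grid[None, :]
    return misfit_energy(s, sp, params) + hbond_energy(s, sp, params)


def solve_sigma_potential(mixture_profile: SigmaProfile, params: ContactParams,
                          temperature: float, tol: float = 1e-8,
                          max_iter: int = 500, damping: float = 0.4) -> SigmaPotential:
    """Solve the self-consistent sigma-potential equation on the discrete grid.

    mu(sigma) = -(RT/a_eff) ln sum_sigma' w(sigma')
                exp{[a_eff mu(sigma') - E_mf(sigma,sigma') - E_hb(sigma,sigma')]/RT}

    with w the area-normalized bin weights. Damped fixed-point iteration;
    non-convergence is flagged on the result, never silent.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    grid = mixture_profile.grid
    w = mixture_profile.weights()
    rt = R_KCAL * temperature
    e_pair = _pair_energy_matrix(grid, params)
    mu = np.zeros_like(grid)
    logw = np.full_like(w, -np.inf)
    np.copyto(logw, np.log(w, out=np.full_like(w, -np.inf), where=w > 0), where=w > 0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log-sum-exp over sigma' for every sigma row
        arg = (params.a_eff * mu[None, :] - e_pair) / rt + logw[None, :]
        mu_new = -(rt / params.a_eff) * logsumexp(arg, axis=1)
        delta = float(np.max(np.abs(mu_new - mu)))
        mu = (1.0 - damping) * mu + damping * mu_new
        if delta < tol:
            converged = True
            break
    return SigmaPotential(grid=grid, mu=mu, temperature=float(temperature),
                          converged=converged, iterations=it)


def residual_chemical_potential(solute_profile: SigmaProfile,
                                solvent_potential: SigmaPotential) -> float:
    """Residual chemical potential of a solute in the solvent, kcal/mol:
    the solvent's sigma-potential integrated over the solute's surface."""
    if solute_profile.grid.shape != solvent_potential.grid.shape or \
            not np.allclose(solute_profile.grid, solvent_potential.grid):
        raise ValueError("solute profile and solvent potential grids differ")
    return float(np.dot(solute_profile.p, solvent_potential.mu))


def ln_gamma_residual(solute_profile: SigmaProfile, solvent_potential: SigmaPotential,
                      self_potential: SigmaPotential) -> float:
    """ln of the residual activity coefficient: (mu_i^solvent - mu_i^i)/RT."""
    rt = R_KCAL * solvent_potential.temperature
    mu_s = residual_chemical_potential(solute_profile, solvent_potential)
    mu_self = residual_chemical_potential(solute_profile, self_potential)
    return (mu_s - mu_self) / rt


def mean_interaction_energies(profile: SigmaProfile, potential: SigmaPotential,
                              params: ContactParams,
                              element_areas: Optional[Mapping[str, float]] = None
                              ) -> tuple[float, float, float]:
    """Mean misfit / H-bond / vdW pair energies of a pure component.

    Misfit and H-bond means are expectations over the equilibrium contact
    distribution p(sigma, sigma') ~ P(sigma) P(sigma')
    exp{[a_eff(mu(sigma)+mu(sigma')) - E_tot(sigma,sigma')]/RT}. The vdW mean
    is computed from the area-weighted element composition (it does not
    depend on sigma).
    """
    if not potential.converged:
        raise ValueError("potential is not converged; refusing to compute means")
    grid = profile.grid
    if grid.shape != potential.grid.shape or not np.allclose(grid, potential.grid):
        raise ValueError("profile and potential grids differ")
    rt = R_KCAL * potential.temperature
    w = profile.weights()
    s = grid[:, None]
    sp = grid[None, :]
    e_mf = misfit_energy(s, sp, params)
    e_hb = hbond_energy(s, sp, params)
    boltz = np.exp((params.a_eff * (potential.mu[:, None] + potential.mu[None, :])
                    - e_mf - e_hb) / rt)
    contact = w[:, None] * w[None, :] * boltz
    z = contact.sum()
    if z <= 0:
        raise ValueError("degenerate contact distribution")
    contact /= z
    mean_mf = float((contact * e_mf).sum())
    mean_hb = float((contact * e_hb).sum())
    mean_vdw = 0.0
    if element_areas:
        areas = np.array(list(element_areas.values()), dtype=float)
        frac = areas / areas.sum()
        els = list(element_areas)
        for i, ei in enumerate(els):
            for j, ej in enumerate(els):
                mean_vdw += frac[i] * frac[j] * vdw_energy(ei, ej, params)
    return (mean_mf, mean_hb, float(mean_vdw))


def mix_profiles(profiles: list[SigmaProfile], fractions: list[float]) -> SigmaProfile:
    """Mole-fraction-weighted mixture sigma-profile on a shared grid."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    grid = profiles[0].grid
    p = np.zeros_like(grid)
    for prof, x in zip(profiles, fractions):
        if not np.allclose(prof.grid, grid):
            raise ValueError("all profiles must share one grid")
        p = p + x * prof.p
    return SigmaProfile(grid=grid, p=p)
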
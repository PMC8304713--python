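"""Iterative solid-liquid-equilibrium solubility computation.

At saturation the solute's chemical potential in solution equals that of the
pure solid, which leads to ln(gamma x) = -max(0, dG_fus)/RT: the ideal
solubility exp(-dG_fus/RT) corrected by the activity coefficient of the
solute in the saturated solution. Because gamma depends on the (unknown)
saturation composition, the equation is solved by damped fixed-point
iteration on ln x until the update drops below tolerance. Above the melting
point dG_fus is clamped at zero, capping the ideal solubility at x = 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from .core_data import Component, SolventSystem
from .sigma import (ContactParams, SigmaProfile, ln_gamma_residual,
                    solve_sigma_potential, mix_profiles, R_KCAL)

# gamma(x, system, temperature) -> positive float
ActivityModel = Callable[[float, Optional[SolventSystem], float], float]


@dataclass(frozen=True)
class SLEResult:
    x_sat: float
    gamma_sat: float
    iterations: int
    converged: bool
    clamped: bool  # whether max(0, dG_fus) engaged


def ideal_solubility(fusion_gibbs: float, temperature: float) -> float:
    """x_ideal = exp(-max(0, dG_fus)/RT); equals 1 at/above the melting point."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-max(0.0, fusion_gibbs) / (R_KCAL * temperature))


def fusion_gibbs_from_melting(t_melt: float, h_fus: float, temperature: float) -> float:
    """dG_fus ~ dH_fus (1 - T/Tm); heat-capacity terms omitted."""
    if t_melt <= 0 or h_fus <= 0:
        raise ValueError("t_melt and h_fus must be positive")
    return h_fus * (1.0 - temperature / t_melt)


def ideal_model(x: float, system: Optional[SolventSystem], temperature: float) -> float:
    """gamma = 1 everywhere: the ideal-solution reference."""
    return 1.0


def regular_solution_model(a: float) -> ActivityModel:
    """One-parameter regular solution: ln gamma = A (1 - x)^2."""
    def gamma(x: float, system: Optional[SolventSystem], temperature: float) -> float:
        return math.exp(a * (1.0 - x) ** 2)
    return gamma


def sigma_activity_model(solute_profile: SigmaProfile,
                         solvent_profiles: list[SigmaProfile],
                         solvent_fractions: list[float],
                         params: ContactParams) -> ActivityModel:
    """Activity model backed by the toy sigma engine (residual part only).

    gamma of the solute at mole fraction x in the solvent: the mixture
    profile blends the solute (weight x) with the solute-free solvent
    composition (weight 1-x); ln gamma is referenced to the pure solute.
    """
    def gamma(x: float, system: Optional[SolventSystem], temperature: float) -> float:
        fracs = [x] + [(1.0 - x) * f for f in solvent_fractions]
        mix = mix_profiles([solute_profile] + solvent_profiles, fracs)
        pot_mix = solve_sigma_potential(mix, params, temperature)
        pot_self = solve_sigma_potential(solute_profile, params, temperature)
        if not (pot_mix.converged and pot_self.converged):
            raise RuntimeError("sigma-potential did not converge inside activity model")
        return math.exp(ln_gamma_residual(solute_profile, pot_mix, pot_self))
    return gamma


def fusion_gibbs_of(solute: Component, temperature: float) -> float:
    """Resolve dG_fus from the component: direct value, else from Tm and dH_fus."""
    if solute.fusion_gibbs is not None:
        return solute.fusion_gibbs
    if solute.t_melt is not None and solute.h_fus is not None:
        return fusion_gibbs_from_melting(solute.t_melt, solute.h_fus, temperature)
    raise ValueError(f"component {solute.name!r} carries no fusion properties")


def solve_solubility(solute: Component | float,
                     system: Optional[SolventSystem],
                     activity_model: ActivityModel,
                     temperature: float,
                     tol: float = 1e-8,
                     max_iter: int = 200,
                     damping: float = 0.5) -> SLEResult:
    """Damped fixed-point iteration x_{k+1} = x_ideal / gamma(x_k).

    ``solute`` may be a :class:`Component` with fusion properties or a bare
    dG_fus value in kcal/mol. Convergence criterion: |ln x_{k+1} - ln x_k|
    < tol. x is clipped to (0, 1] every step; non-convergence is flagged on
    the result rather than raised.
    """
    dg = solute if isinstance(solute, (int, float)) else fusion_gibbs_of(solute, temperature)
    clamped = dg < 0
    ln_x_ideal = math.log(ideal_solubility(dg, temperature))
    # start from the infinite-dilution-corrected guess: for an increasing
    # iteration map this approaches the smallest (thermodynamically stable)
    # root from below when the SLE equation has several
    gamma_inf = activity_model(1e-12, system, temperature)
    if not (gamma_inf > 0 and math.isfinite(gamma_inf)):
        raise ValueError(f"activity model returned invalid gamma {gamma_inf!r} at infinite dilution")
    ln_x = min(0.0, ln_x_ideal - math.log(gamma_inf))
    gamma = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x = min(1.0, math.exp(ln_x))
        gamma = activity_model(x, system, temperature)
        if not (gamma > 0 and math.isfinite(gamma)):
            raise ValueError(f"activity model returned invalid gamma {gamma!r} at x={x!r}")
        ln_x_new = ln_x_ideal - math.log(gamma)
        ln_x_new = min(0.0, ln_x_new)  # keep x <= 1
        delta = abs(ln_x_new - ln_x)
        ln_x = (1.0 - damping) * ln_x + damping * ln_x_new
        if delta < tol:
            ln_x = ln_x_new
            converged = True
            break
    x_sat = min(1.0, math.exp(ln_x))
    return SLEResult(x_sat=x_sat, gamma_sat=float(gamma), iterations=it,
                     converged=converged, clamped=clamped)
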
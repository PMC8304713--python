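"""Seven-descriptor feature vectors from component interaction-energy triples.

Each record is described by the three mean interaction energies of its
solvent (misfit, hydrogen bond, van der Waals), their relative shares of the
total interaction energy, and the temperature. Multicomponent solvents mix
descriptors linearly with the solute-free mole fractions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core_data import Component, SolubilityRecord, SolventSystem

FEATURE_NAMES = ["E_misfit", "E_hb", "E_vdw", "e_misfit", "e_hb", "e_vdw", "T_K"]
TARGET_NAME = "log10_x"


@dataclass(frozen=True)
class DescriptorVector:
    e_misfit_abs: float
    e_hb_abs: float
    e_vdw_abs: float
    e_misfit_rel: float
    e_hb_rel: float
    e_vdw_rel: float
    temperature: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def as_array(self, include_temperature: bool = True) -> np.ndarray:
        vals = [self.e_misfit_abs, self.e_hb_abs, self.e_vdw_abs,
                self.e_misfit_rel, self.e_hb_rel, self.e_vdw_rel]
        if include_temperature:
            vals.append(self.temperature)
        return np.array(vals, dtype=float)


def relative_contributions(component: Component) -> tuple[float, float, float]:
    """Each energy term's share of the total interaction energy; sums to 1."""
    total = component.e_misfit + component.e_hb + component.e_vdw
    if total == 0:
        raise ValueError(
            f"component {component.name!r}: zero total interaction energy, "
            "relative contributions undefined")
    return (component.e_misfit / total, component.e_hb / total, component.e_vdw / total)


def component_descriptor(component: Component, temperature: float) -> DescriptorVector:
    rel = relative_contributions(component)
    return DescriptorVector(component.e_misfit, component.e_hb, component.e_vdw,
                            rel[0], rel[1], rel[2], temperature)


def mixture_descriptor(system: SolventSystem | Iterable[tuple[Component, float]],
                       temperature: float | None = None,
                       mixing: Literal["linear", "recompute"] = "linear"
                       ) -> DescriptorVector:
    """Mole-fraction-weighted descriptors of a (multi)component solvent.

    ``mixing='linear'`` mixes all six energy descriptors linearly (default);
    ``'recompute'`` mixes the absolute energies and recomputes the relative
    shares from the mixed totals — the two coincide for neat solvents.
    """
    if isinstance(system, SolventSystem):
        pairs = system.components
        if temperature is None:
            temperature = system.temperature
    else:
        pairs = tuple(system)
        if temperature is None:
            raise ValueError("temperature required when passing bare (component, fraction) pairs")
    fracs = np.array([f for _, f in pairs], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"component fractions must sum to 1, got {fracs.sum()!r}")
    absd = np.array([[c.e_misfit, c.e_hb, c.e_vdw] for c, _ in pairs], dtype=float)
    mixed_abs = fracs @ absd
    if mixing == "linear":
        reld = np.array([relative_contributions(c) for c, _ in pairs], dtype=float)
        mixed_rel = fracs @ reld
    elif mixing == "recompute":
        total = mixed_abs.sum()
        if total == 0:
            raise ValueError("mixed total interaction energy is zero")
        mixed_rel = mixed_abs / total
    else:
        raise ValueError(f"unknown mixing mode {mixing!r}")
    return DescriptorVector(*mixed_abs, *mixed_rel, float(temperature))


def build_feature_matrix(records: Sequence[SolubilityRecord],
                         include_temperature: bool = True,
                         mixing: Literal["linear", "recompute"] = "linear"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the model inputs: (n_records x 7) features and log10 x targets.

    Row order matches record order. Every component must carry an energy
    triple (an all-zero triple is treated as missing).
    """
    missing: set[str] = set()
    for rec in records:
        for comp, _ in rec.system.components:
            if comp.energy_triple == (0.0, 0.0, 0.0):
                missing.add(comp.name)
    if missing:
        raise ValueError(f"components without energy triples: {sorted(missing)}")
    rows = [mixture_descriptor(rec.system, mixing=mixing).as_array(include_temperature)
            for rec in records]
    x = np.vstack(rows) if rows else np.empty((0, 7 if include_temperature else 6))
    y = np.log10(np.array([rec.x_solute for rec in records], dtype=float))
    return x, y


def feature_frame(records: Sequence[SolubilityRecord], **kwargs) -> pd.DataFrame:
    """Feature matrix + target as a DataFrame with the stable column names."""
    x, y = build_feature_matrix(records, **kwargs)
    names = FEATURE_NAMES if x.shape[1] == 7 else FEATURE_NAMES[:-1]
    df = pd.DataFrame(x, columns=names)
    df[TARGET_NAME] = y
    return df
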
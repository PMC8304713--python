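"""Candidate enumeration and ensemble-driven solubility screening.

Builds candidate sets of neat solvents, aqueous binary mixtures and NADES
formulations (choline chloride + hydrogen-bond donor, 1:1, optionally
water-diluted), predicts solubility with a fitted ensemble and returns a
stable descending ranking of the filtered mean log10 mole fractions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import Category, Component, Role, SolventSystem
from .descriptors import mixture_descriptor
from .domain import LeverageDomain
from .ensemble import SannEnsembleRegressor

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    category: Category
    systems: list[SolventSystem]
    class_labels: dict[str, str] = field(default_factory=dict)  # name -> solvent class

    def __post_init__(self) -> None:
        for s in self.systems:
            if s.category is not self.category:
                raise ValueError(f"system {s.label!r} has category {s.category}, "
                                 f"set requires {self.category}")

    def __len__(self) -> int:
        return len(self.systems)


@dataclass
class RankedEntry:
    system: SolventSystem
    mean_log10x: float
    n_valid_networks: int
    inside_ad: Optional[bool] = None

    @property
    def x_pred(self) -> float:
        return 10.0 ** self.mean_log10x


@dataclass
class ScreeningResult:
    ranked: list[RankedEntry]
    n_discarded_predictions: int
    n_dropped_systems: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": i + 1, "system": e.system.label,
            "category": e.system.category.value,
            "mean_log10x": e.mean_log10x, "x_pred": e.x_pred,
            "n_valid": e.n_valid_networks, "inside_AD": e.inside_ad,
        } for i, e in enumerate(self.ranked)])


def enumerate_binary(neat_components: Sequence[Component],
                     fractions_grid: Sequence[float],
                     water: Optional[Component] = None,
                     temperature: float = 298.15) -> CandidateSet:
    """Aqueous binary candidates: one system per (organic solvent, fraction).

    ``fractions_grid`` holds the solute-free mole fraction of the organic
    cosolvent (x2*). Duplicate component names are collapsed.
    """
    if any(not (0.0 < f < 1.0) for f in fractions_grid):
        raise ValueError("fractions must lie strictly inside (0, 1)")
    if water is None:
        water = Component("water", role=Role.WATER)
    seen: set[str] = set()
    systems = []
    for comp in neat_components:
        if comp.name in seen or comp.name == water.name:
            continue
        seen.add(comp.name)
        for f in fractions_grid:
            systems.append(SolventSystem([(comp, f), (water, 1.0 - f)],
                                         Category.BINARY, temperature))
    return CandidateSet(Category.BINARY, systems)


def enumerate_nades(hbd_candidates: Sequence[Component],
                    chcl: Optional[Component] = None,
                    water: Optional[Component] = None,
                    water_fraction: float = 0.2,
                    temperature: float = 298.15) -> CandidateSet:
    """NADES candidates: ChCl + HBD 1:1, diluted with water.

    The default overall water mole fraction of 0.2 (xNADES* = 0.8) is the
    composition at which the synergistic solubility gain peaks for the
    measured NADES series. Candidates without an energy triple are skipped
    with a log entry; duplicate names are deduplicated.
    """
    if chcl is None:
        chcl = Component("ChCl", role=Role.HBA)
    if water is None:
        water = Component("water", role=Role.WATER)
    if not (0.0 <= water_fraction < 1.0):
        raise ValueError("water_fraction must lie in [0, 1)")
    nades_frac = (1.0 - water_fraction) / 2.0
    seen: set[str] = set()
    systems = []
    for hbd in hbd_candidates:
        if hbd.name in seen:
            continue
        seen.add(hbd.name)
        if hbd.energy_triple == (0.0, 0.0, 0.0):
            logger.warning("skipping NADES candidate %r: no energy triple", hbd.name)
            continue
        comps = [(chcl, nades_frac), (hbd, nades_frac)]
        category = Category.NADES_WATER if water_fraction > 0 else Category.NADES
        if water_fraction > 0:
            comps.append((water, water_fraction))
        systems.append(SolventSystem(comps, category, temperature))
    return CandidateSet(category if systems else Category.NADES_WATER, systems)


def screen(candidates: CandidateSet, ensemble: SannEnsembleRegressor,
           domain: Optional[LeverageDomain] = None,
           mixing: str = "linear") -> ScreeningResult:
    """Rank candidate systems by filtered ensemble mean solubility.

    Systems whose predictions are all discarded by the physical-range filter
    are dropped (and counted); candidates outside the applicability domain
    are flagged, not removed. Ties in the mean break on the system label, so
    the ranking is invariant to input order.
    """
    if not candidates.systems:
        return ScreeningResult([], 0, 0)
    x = np.vstack([mixture_descriptor(s, mixing=mixing).as_array()
                   for s in candidates.systems])
    preds = ensemble.predict_detailed(x)
    inside = domain.predict(x) if domain is not None else [None] * len(preds)
    entries = []
    n_disc = 0
    n_dropped = 0
    for sys_, p, ad in zip(candidates.systems, preds, inside):
        n_disc += p.n_discarded
        if not p.valid:
            n_dropped += 1
            continue
        entries.append(RankedEntry(sys_, p.mean_log10x, p.n_used,
                                   None if ad is None else bool(ad)))
    entries.sort(key=lambda e: (-e.mean_log10x, e.system.label))
    return ScreeningResult(entries, n_disc, n_dropped)
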
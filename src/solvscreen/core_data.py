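"""Domain types, the packaged solubility fixture and tabular I/O.

Units follow the COSMOtherm convention throughout the package: interaction
energies in kcal/mol, temperatures in kelvin (25 degC recorded as 298.15 K).
Solubility is stored as a plain mole fraction; the log10 transform is applied
only inside the model layer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

T_AMBIENT = 298.15  # K

COMPONENT_COLUMNS = [
    "name", "cas", "role", "e_misfit", "e_hb", "e_vdw",
    "fusion_gibbs", "t_melt", "h_fus",
]
RECORD_COLUMNS = [
    "system_id", "category", "component", "frac", "temperature_K", "x_exp", "sd",
]


class Role(str, Enum):
    SOLUTE = "solute"
    SOLVENT = "solvent"
    HBA = "hba"
    HBD = "hbd"
    WATER = "water"


class Category(str, Enum):
    NEAT = "neat"
    BINARY = "binary"
    NADES = "nades"
    NADES_WATER = "nades_water"


@dataclass(frozen=True)
class Component:
    """A chemical species with its mean segment-interaction energy triple.

    The triple (misfit, hydrogen-bond, van der Waals) summarizes the
    component's pair-contact energetics in the bulk liquid; optional fusion
    properties (direct Gibbs energy of fusion, or melting point plus enthalpy
    of fusion) are required only for solutes fed to the SLE solver.
    """

    name: str
    e_misfit: float = 0.0
    e_hb: float = 0.0
    e_vdw: float = 0.0
    cas: Optional[str] = None
    fusion_gibbs: Optional[float] = None  # kcal/mol
    t_melt: Optional[float] = None        # K
    h_fus: Optional[float] = None         # kcal/mol
    role: Role = Role.SOLVENT

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("Component name must be nonempty")
        triple = (self.e_misfit, self.e_hb, self.e_vdw)
        if not all(math.isfinite(v) for v in triple):
            raise ValueError(f"Component {self.name!r}: energy triple must be finite, got {triple}")
        if self.t_melt is not None and self.t_melt <= 0:
            raise ValueError(f"Component {self.name!r}: t_melt must be positive")

    @property
    def energy_triple(self) -> tuple[float, float, float]:
        return (self.e_misfit, self.e_hb, self.e_vdw)


@dataclass(frozen=True)
class SolventSystem:
    """A (multi)component solvent with solute-free composition.

    ``components`` pairs each :class:`Component` with its solute-free mole
    fraction (the x2*/xNADES* convention: fractions among solvent species
    only, the dissolved solute excluded).
    """

    components: tuple[tuple[Component, float], ...]
    category: Category = Category.NEAT
    temperature: float = T_AMBIENT

    def __init__(self, components: Iterable[tuple[Component, float]],
                 category: Category | str = Category.NEAT,
                 temperature: float = T_AMBIENT) -> None:
        comps = tuple((c, float(f)) for c, f in components)
        category = Category(category)
        if temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        fracs = [f for _, f in comps]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError(f"mole fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got sum {sum(fracs)!r}")
        if category is Category.NEAT and len(comps) != 1:
            raise ValueError("a neat system has exactly one component")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "category", category)
        object.__setattr__(self, "temperature", float(temperature))

    @property
    def label(self) -> str:
        parts = "+".join(c.name for c, _ in self.components)
        return parts

    def fraction_of(self, name: str) -> float:
        for c, f in self.components:
            if c.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class SolubilityRecord:
    """One measured saturation point: a solvent system and its solute mole fraction."""

    system: SolventSystem
    x_solute: float
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.x_solute < 1.0):
            raise ValueError(f"x_solute must lie in (0, 1), got {self.x_solute}")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be nonnegative")


def enhancement_ratio(a: SolubilityRecord, b: SolubilityRecord) -> float:
    """Ratio of solubilities a/b, e.g. a NADES against pure water."""
    if b.x_solute == 0:
        raise ZeroDivisionError("reference record has zero solubility")
    return a.x_solute / b.x_solute


@dataclass
class FixtureTable:
    """The packaged in-text theophylline solubility table (21 records)."""

    records: list[SolubilityRecord] = field(default_factory=list)

    def lookup(self, label: str, category: Category | str = Category.NEAT,
               frac: Optional[float] = None) -> SolubilityRecord:
        """Find a record by solvent label, category and (optionally) cosolvent fraction.

        ``frac`` is the solute-free mole fraction of the organic/NADES part
        (x2* for binaries, xNADES* for diluted NADES).
        """
        category = Category(category)
        for rec in self.records:
            if rec.system.category is not category:
                continue
            full = rec.system.label.lower()
            dry = "+".join(c.name for c, _ in rec.system.components
                           if c.name.lower() != "water").lower()
            if label.lower() not in (full, dry):
                continue
            if frac is not None:
                organic = 1.0 - _water_fraction(rec.system)
                if abs(organic - frac) > 1e-9:
                    continue
            return rec
        raise KeyError(f"no fixture record for {label!r} ({category.value}, frac={frac})")

    def __len__(self) -> int:
        return len(self.records)


def _water_fraction(system: SolventSystem) -> float:
    return sum(f for c, f in system.components if c.name.lower() == "water")


def _simple(name: str, role: Role = Role.SOLVENT) -> Component:
    return Component(name=name, role=role)


_WATER = _simple("water", Role.WATER)
_CHCL = _simple("ChCl", Role.HBA)

# mole-fraction solubilities printed in the main text, all x 1e-4
_NEAT = [
    ("DMSO", 70.96, 0.28), ("DMF", 59.21, 0.43), ("1,4-dioxane", 31.67, 0.58),
    ("methanol", 13.64, 0.04), ("1-propanol", 13.39, 0.13),
    ("1-butanol", 10.23, 0.11), ("water", 6.10, 0.12),
]
_BINARY_05 = [
    ("DMSO", 90.13, 0.56), ("DMF", 76.41, 0.58), ("1,4-dioxane", 62.37, 0.45),
    ("1-butanol", 43.47, 0.22), ("1-propanol", 35.03, 0.08),
]
_NADES_NEAT = [
    ("Glycerol", 128.17, 0.68), ("Sorbitol", 103.63, 1.20),
    ("Xylitol", 92.61, 0.94), ("Glucose", 73.45, 0.75), ("Fructose", 67.79, 0.72),
]
_NADES_08 = [
    ("Glycerol", 146.57, 0.72), ("Sorbitol", 123.83, 0.70),
    ("Xylitol", 113.94, 0.31), ("Glucose", 93.76, 0.96),
]


def build_fixture() -> FixtureTable:
    """Assemble the in-text solubility table: neat solvents, unimolar aqueous
    binaries, neat NADES (ChCl + polyol 1:1) and NADES diluted to xNADES*=0.8."""
    records: list[SolubilityRecord] = []
    for name, x4, sd4 in _NEAT:
        comp = _WATER if name == "water" else _simple(name)
        sys_ = SolventSystem([(comp, 1.0)], Category.NEAT)
        records.append(SolubilityRecord(sys_, x4 * 1e-4, sd4 * 1e-4))
    for name, x4, sd4 in _BINARY_05:
        sys_ = SolventSystem([(_simple(name), 0.5), (_WATER, 0.5)], Category.BINARY)
        records.append(SolubilityRecord(sys_, x4 * 1e-4, sd4 * 1e-4))
    for name, x4, sd4 in _NADES_NEAT:
        sys_ = SolventSystem([(_CHCL, 0.5), (_simple(name, Role.HBD), 0.5)],
                             Category.NADES)
        records.append(SolubilityRecord(sys_, x4 * 1e-4, sd4 * 1e-4))
    for name, x4, sd4 in _NADES_08:
        # xNADES* = 0.8 with the internal ChCl:HBD ratio kept at 1:1
        sys_ = SolventSystem([(_CHCL, 0.4), (_simple(name, Role.HBD), 0.4),
                              (_WATER, 0.2)], Category.NADES_WATER)
        records.append(SolubilityRecord(sys_, x4 * 1e-4, sd4 * 1e-4))
    return FixtureTable(records)


# ---------------------------------------------------------------------------
# tabular I/O


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_components(path: str | Path) -> list[Component]:
    """Read a component energy table (CSV with the declared header)."""
    df = pd.read_csv(path)
    missing = [c for c in ("name", "e_misfit", "e_hb", "e_vdw") if c not in df.columns]
    if missing:
        raise ValueError(f"component CSV missing required columns: {missing}")
    out: list[Component] = []
    for i, row in df.iterrows():
        name = row["name"]
        if pd.isna(name) or not str(name).strip():
            raise ValueError(f"component row {i}: column 'name' is blank")
        try:
            out.append(Component(
                name=str(name),
                cas=None if pd.isna(row.get("cas")) else str(row.get("cas")),
                role=Role(row.get("role")) if isinstance(row.get("role"), str) else Role.SOLVENT,
                e_misfit=float(row["e_misfit"]),
                e_hb=float(row["e_hb"]),
                e_vdw=float(row["e_vdw"]),
                fusion_gibbs=_opt(row.get("fusion_gibbs")),
                t_melt=_opt(row.get("t_melt")),
                h_fus=_opt(row.get("h_fus")),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"component row {i} ({name!r}): {exc}") from exc
    return out


def write_components(components: Sequence[Component], path: str | Path) -> None:
    rows = [{
        "name": c.name, "cas": c.cas, "role": c.role.value,
        "e_misfit": c.e_misfit, "e_hb": c.e_hb, "e_vdw": c.e_vdw,
        "fusion_gibbs": c.fusion_gibbs, "t_melt": c.t_melt, "h_fus": c.h_fus,
    } for c in components]
    pd.DataFrame(rows, columns=COMPONENT_COLUMNS).to_csv(path, index=False)


def write_records(records: Sequence[SolubilityRecord], path: str | Path) -> None:
    """Write solubility records in the long format (one row per system component)."""
    rows = []
    for i, rec in enumerate(records):
        for comp, frac in rec.system.components:
            rows.append({
                "system_id": i, "category": rec.system.category.value,
                "component": comp.name, "frac": frac,
                "temperature_K": rec.system.temperature,
                "x_exp": rec.x_solute, "sd": rec.sd,
            })
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path,
                 components: Optional[Sequence[Component]] = None) -> list[SolubilityRecord]:
    """Read the long-format record table back into :class:`SolubilityRecord` objects.

    If ``components`` is given, component names are resolved against it so the
    energy triples survive the round trip; otherwise bare named components are
    created.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"record CSV missing required columns: {missing}")
    lut = {c.name: c for c in components} if components else {}
    out: list[SolubilityRecord] = []
    for sid, grp in df.groupby("system_id", sort=True):
        try:
            comps = [(lut.get(str(r["component"]), _simple(str(r["component"]))),
                      float(r["frac"])) for _, r in grp.iterrows()]
            first = grp.iloc[0]
            sys_ = SolventSystem(comps, Category(first["category"]),
                                 float(first["temperature_K"]))
            out.append(SolubilityRecord(sys_, float(first["x_exp"]),
                                        _opt(first.get("sd"))))
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(f"record system {sid}: {exc}") from exc
    return out
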
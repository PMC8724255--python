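"""Equilibrium model: components, species stoichiometry, van't Hoff thermodynamics.

A model is a list of components (basic chemical units) and a list of species,
each species formed from the components with integer stoichiometry and
characterised by a cumulative formation constant

    ln beta(T) = -dH / (R T) + dS / R

with R = 8.31 J/(mol K).  Components themselves appear in the species list as
trivial species with beta identically 1.  Hydroxide is represented as a
pseudo-species with proton coefficient -1 whose formation constant is the
water autoprotolysis constant Kw(T); its thermodynamics are always fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ModelError, SchemaError

#: Ideal gas constant used throughout, J/(mol K).
GAS_CONSTANT = 8.31

#: Default water autoprotolysis thermodynamics (dH, dS) in J/mol and
#: J/(mol K); gives pKw close to 14 at 298 K.
DEFAULT_WATER = (55815.0, -80.66)

#: Name given to the automatically inserted hydroxide pseudo-species.
WATER_SPECIES = "OH"

#: Supported temperature window (K) for built-in models.
T_MIN, T_MAX = 273.0, 330.0


@dataclass(frozen=True)
class Component:
    """A basic chemical unit from which species are assembled."""

    name: str
    role: str = "generic"  # "generic" or "proton"

    def __post_init__(self):
        if self.role not in ("generic", "proton"):
            raise ModelError(f"unknown component role {self.role!r}")


@dataclass
class Species:
    """One species: name, stoichiometry over the model's component basis,
    and thermodynamic parameters.

    ``thermo`` is either a van't Hoff (dH, dS) pair or a fixed,
    temperature-independent ``lnb_fixed``.  ``free`` marks species whose
    parameters may be optimised during fitting.
    """

    name: str
    stoich: tuple
    dh: float | None = None  # J/mol
    ds: float | None = None  # J/(mol K)
    lnb_fixed: float | None = None
    free: bool = False

    def __post_init__(self):
        self.stoich = tuple(int(c) for c in self.stoich)
        if all(c == 0 for c in self.stoich):
            raise ModelError(f"species {self.name!r} has all-zero stoichiometry")
        if self.lnb_fixed is not None and (self.dh is not None or self.ds is not None):
            raise ModelError(
                f"species {self.name!r}: give either (dH, dS) or a fixed ln beta, not both"
            )

    @property
    def has_thermo(self) -> bool:
        return self.lnb_fixed is not None or (self.dh is not None and self.ds is not None)

    @property
    def is_component(self) -> bool:
        """True if the stoichiometry is a unit vector (a trivial species)."""
        return sum(abs(c) for c in self.stoich) == 1 and max(self.stoich) == 1

    def lnb(self, T: float) -> float:
        """Natural-log formation constant at temperature ``T`` (kelvin)."""
        if T <= 0:
            raise ValueError(f"temperature must be positive, got {T}")
        if self.lnb_fixed is not None:
            return float(self.lnb_fixed)
        if self.dh is None or self.ds is None:
            raise ModelError(f"species {self.name!r} has no thermodynamic parameters")
        return -self.dh / (GAS_CONSTANT * T) + self.ds / GAS_CONSTANT


def formation_constant(species: Species, T: float) -> float:
    """Formation constant beta = exp(-dH/(R T) + dS/R) of ``species`` at ``T``."""
    return math.exp(species.lnb(T))


def compose_species(base: Species, addend: Species, name: str | None = None) -> Species:
    """Derive a species by thermodynamic additivity.

    The stoichiometry is the element-wise sum of the parents' and dH, dS are
    the sums of the parents', i.e. beta_derived(T) = beta_base(T) *
    beta_addend(T) at every temperature.
    """
    if len(base.stoich) != len(addend.stoich):
        raise ModelError(
            f"cannot compose {base.name!r} and {addend.name!r}: different component bases"
        )
    for parent in (base, addend):
        if parent.lnb_fixed is not None or parent.dh is None or parent.ds is None:
            raise ModelError(
                f"compose requires van't Hoff (dH, dS) thermodynamics on {parent.name!r}"
            )
    stoich = tuple(a + b for a, b in zip(base.stoich, addend.stoich))
    return Species(
        name=name or f"{base.name}+{addend.name}",
        stoich=stoich,
        dh=base.dh + addend.dh,
        ds=base.ds + addend.ds,
    )


class EquilibriumModel:
    """Components + species stoichiometry matrix + thermodynamic parameters.

    Parameters
    ----------
    components:
        Ordered components; at most one with role ``"proton"``.
    species:
        Formed species.  Trivial component species are inserted automatically
        (with beta = 1); an ``OH`` pseudo-species with proton coefficient -1
        and the ``water`` thermodynamics is appended when a proton component
        is present and ``include_water`` is true.
    water:
        (dH, dS) of the autoprotolysis pseudo-species.  Always fixed.
    """

    R = GAS_CONSTANT

    def __init__(
        self,
        components: Sequence[Component],
        species: Sequence[Species],
        water: tuple = DEFAULT_WATER,
        include_water: bool = True,
    ):
        components = [
            c if isinstance(c, Component) else Component(str(c)) for c in components
        ]
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate component names")
        protons = [i for i, c in enumerate(components) if c.role == "proton"]
        if len(protons) > 1:
            raise ModelError("at most one proton component allowed")
        self.components = tuple(components)
        self.proton_index = protons[0] if protons else None
        self.water = tuple(water)

        nc = len(components)
        full: list[Species] = []
        seen: set[str] = set()
        # trivial component species first, Table-1 style
        formed_names = {sp.name for sp in species}
        for i, comp in enumerate(components):
            if comp.name in formed_names:
                continue
            stoich = tuple(1 if j == i else 0 for j in range(nc))
            full.append(Species(comp.name, stoich, dh=0.0, ds=0.0))
            seen.add(comp.name)
        for sp in species:
            if len(sp.stoich) != nc:
                raise SchemaError(
                    f"species {sp.name!r} stoichiometry length {len(sp.stoich)} "
                    f"!= {nc} components"
                )
            if sp.name in seen:
                raise SchemaError(f"duplicate species name {sp.name!r}")
            if sp.is_component and sp.has_thermo and abs(sp.lnb(298.0)) > 1e-12:
                raise ModelError(
                    f"unit-vector species {sp.name!r} must have beta = 1 (dH = dS = 0)"
                )
            if any(c < 0 for i, c in enumerate(sp.stoich) if i != self.proton_index):
                raise ModelError(
                    f"species {sp.name!r}: only the proton coefficient may be negative"
                )
            if any(c != 0 for c in sp.stoich) and self.proton_index is None:
                pass
            seen.add(sp.name)
            full.append(sp)
        if include_water and self.proton_index is not None and WATER_SPECIES not in seen:
            stoich = tuple(-1 if j == self.proton_index else 0 for j in range(nc))
            full.append(Species(WATER_SPECIES, stoich, dh=water[0], ds=water[1]))

        if self.proton_index is None:
            for sp in full:
                if any(c < 0 for c in sp.stoich):
                    raise ModelError(
                        f"species {sp.name!r} has a negative coefficient but the "
                        "model has no proton component"
                    )

        self.species = tuple(full)
        self._index = {sp.name: i for i, sp in enumerate(self.species)}
        self.stoich_matrix = np.array([sp.stoich for sp in self.species], dtype=float)

    # -- basic introspection -------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def component_names(self) -> tuple:
        return tuple(c.name for c in self.components)

    @property
    def species_names(self) -> tuple:
        return tuple(sp.name for sp in self.species)

    def __getitem__(self, name: str) -> Species:
        return self.species[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def species_index(self, name: str) -> int:
        return self._index[name]

    @property
    def correlated_sets(self) -> list:
        """Groups of distinct non-trivial species sharing one stoichiometry row."""
        groups: dict = {}
        for sp in self.species:
            if sp.is_component or sp.name == WATER_SPECIES:
                continue
            groups.setdefault(sp.stoich, []).append(sp.name)
        return [tuple(v) for v in groups.values() if len(v) > 1]

    def lnb_vector(self, T: float) -> np.ndarray:
        """ln beta of every species at temperature ``T``."""
        return np.array([sp.lnb(T) for sp in self.species])

    def kw(self, T: float) -> float:
        """Water autoprotolysis constant at ``T``."""
        dh, ds = self.water
        return math.exp(-dh / (GAS_CONSTANT * T) + ds / GAS_CONSTANT)

    # -- derived models ------------------------------------------------------

    def formed_species(self) -> list:
        """Species that are neither trivial components nor the water species."""
        return [
            sp
            for sp in self.species
            if not sp.is_component and sp.name != WATER_SPECIES
        ]

    def with_thermo(self, updates: Mapping) -> "EquilibriumModel":
        """Copy of the model with (dH, dS) of named species replaced.

        ``updates`` maps species name -> dict with any of ``dh``/``ds``.
        Water thermodynamics cannot be changed this way.
        """
        if WATER_SPECIES in updates:
            raise ModelError("water thermodynamics are fixed")
        new = []
        for sp in self.formed_species():
            if sp.name in updates:
                new.append(replace(sp, **dict(updates[sp.name])))
            else:
                new.append(replace(sp))
        return EquilibriumModel(
            list(self.components), new, water=self.water, include_water=True
        )

    def subset(self, component_names: Sequence[str]) -> "EquilibriumModel":
        """Restriction to a component subset, keeping species fully contained in it."""
        keep = [self.component_names.index(n) for n in component_names]
        drop = [i for i in range(self.n_components) if i not in keep]
        species = []
        for sp in self.formed_species():
            if all(sp.stoich[i] == 0 for i in drop):
                species.append(
                    replace(sp, stoich=tuple(sp.stoich[i] for i in keep))
                )
        comps = [self.components[i] for i in keep]
        return EquilibriumModel(comps, species, water=self.water)

    # -- (de)serialisation ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per species, one integer column per component."""
        rows = []
        for sp in self.species:
            row = {"species": sp.name}
            for comp, c in zip(self.components, sp.stoich):
                row[comp.name] = int(c)
            row["dH"] = sp.dh
            row["dS"] = sp.ds
            row["lnb"] = sp.lnb_fixed
            row["free"] = int(sp.free)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __repr__(self):
        return (
            f"EquilibriumModel({self.n_components} components "
            f"{list(self.component_names)}, {self.n_species} species)"
        )


def build_model(
    table,
    proton: str = "H",
    water: tuple = DEFAULT_WATER,
    include_water: bool = True,
) -> EquilibriumModel:
    """Build a validated :class:`EquilibriumModel` from a species table.

    ``table`` is a :class:`pandas.DataFrame` (or list of records) with a
    ``species`` column, one integer column per component, and then ``dH``,
    ``dS`` (or ``lnb``) plus an optional ``free`` flag — a machine-readable
    stoichiometry table.  Component columns are everything between
    ``species`` and the thermo columns; trivial unit-vector rows are
    recognised as component self-entries.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    if "species" not in table.columns:
        raise SchemaError("table needs a 'species' column")
    reserved = {"species", "dH", "dS", "lnb", "free"}
    comp_names = [c for c in table.columns if c not in reserved]
    if not comp_names:
        raise SchemaError("no component columns found")
    components = [
        Component(n, role="proton" if n == proton else "generic") for n in comp_names
    ]
    species = []
    for _, row in table.iterrows():
        stoich = tuple(int(row[c]) for c in comp_names)
        dh = row.get("dH")
        ds = row.get("dS")
        lnb = row.get("lnb") if "lnb" in table.columns else None
        dh = None if pd.isna(dh) else float(dh)
        ds = None if pd.isna(ds) else float(ds)
        lnb = None if (lnb is None or pd.isna(lnb)) else float(lnb)
        free = bool(row["free"]) if "free" in table.columns and not pd.isna(row.get("free")) else False
        sp = Species(str(row["species"]), stoich, dh=dh, ds=ds, lnb_fixed=lnb, free=free)
        if sp.is_component and sp.name in comp_names:
            continue  # trivial self-entry, re-inserted by the model
        species.append(sp)
    return EquilibriumModel(components, species, water=water, include_water=include_water)


def read_model(path, proton: str = "H", **kwargs) -> EquilibriumModel:
    """Read a model from its delimited table form (see :func:`build_model`)."""
    return build_model(pd.read_csv(path, comment="#"), proton=proton, **kwargs)
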
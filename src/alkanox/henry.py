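"""Headspace–liquid gas partitioning for sealed batch vessels.

A gas at partial pressure p in the headspace holds p·V_gas/(R·T) mol there
and, at equilibrium, H_cp(T)·p mol per litre of liquid (Henry's law).  The
vessel-total inventory is the sum of both pools; the inverse map (total →
pressure) is linear and solved in closed form.  Headspace behaviour is
ideal-gas — adequate below ~1.2 atm — and dissolved CO2 is treated as
CO2(aq) only, without carbonate speciation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

R_L_ATM = 0.082057  # l atm mol-1 K-1
T_REF = 298.15


@dataclass(frozen=True)
class VesselGeometry:
    """Headspace and liquid volumes (litres) and temperature (kelvin)."""

    v_gas: float
    v_liq: float
    T: float

    def __post_init__(self):
        if self.v_gas <= 0 or self.v_liq <= 0 or self.T <= 0:
            raise ValueError("v_gas, v_liq and T must all be positive")


@dataclass(frozen=True)
class GasSolubility:
    """Henry constant H_cp (mol l-1 atm-1 at 298.15 K) with van 't Hoff slope."""

    species: str
    h_cp_ref: float
    vant_hoff_K: float = 0.0

    def __post_init__(self):
        if self.h_cp_ref <= 0:
            raise ValueError("h_cp_ref must be positive")


@dataclass(frozen=True)
class GasInventory:
    p: float  # atm
    n_headspace: float  # mmol
    c_dissolved: float  # mmol / l liquid
    n_total: float  # mmol (headspace + dissolved)


def henry_at_T(sol: GasSolubility, T: float) -> float:
    """Temperature-corrected Henry constant, mol l-1 atm-1."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return sol.h_cp_ref * math.exp(sol.vant_hoff_K * (1.0 / T - 1.0 / T_REF))


def inventory_from_pressure(
    p: float, geom: VesselGeometry, sol: GasSolubility
) -> GasInventory:
    """Partition a headspace partial pressure into the vessel-total inventory."""
    if p < 0:
        raise ValueError(f"partial pressure must be non-negative, got {p}")
    n_head = p * geom.v_gas / (R_L_ATM * geom.T) * 1e3  # mmol
    c_diss = henry_at_T(sol, geom.T) * p * 1e3  # mmol/l
    return GasInventory(
        p=p,
        n_headspace=n_head,
        c_dissolved=c_diss,
        n_total=n_head + c_diss * geom.v_liq,
    )


def pressure_from_total(
    n_total: float, geom: VesselGeometry, sol: GasSolubility
) -> GasInventory:
    """Equilibrium partitioning of a known vessel-total amount (mmol)."""
    if n_total < 0:
        raise ValueError(f"total amount must be non-negative, got {n_total}")
    capacity = geom.v_gas / (R_L_ATM * geom.T) + henry_at_T(sol, geom.T) * geom.v_liq
    p = n_total * 1e-3 / capacity
    return inventory_from_pressure(p, geom, sol)


def default_solubilities() -> dict[str, GasSolubility]:
    """Solubility constants shipped with the package, keyed by species name."""
    with resources.files("alkanox.data").joinpath("solubilities.csv").open() as fh:
        df = pd.read_csv(fh)
    return {
        row.species: GasSolubility(
            row.species, float(row.h_cp_mol_per_l_atm), float(row.vant_hoff_K)
        )
        for row in df.itertuples(index=False)
    }


def read_solubilities(path) -> dict[str, GasSolubility]:
    df = pd.read_csv(path)
    required = {"species", "h_cp_mol_per_l_atm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"solubility CSV missing columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.species] = GasSolubility(
            row.species,
            float(row.h_cp_mol_per_l_atm),
            float(getattr(row, "vant_hoff_K", 0.0)),
        )
    return out
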
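"""Gibbs free energies of balanced redox reactions.

ΔG° is computed from a curated table of standard Gibbs energies of formation
(298.15 K; 1 atm gases, 1 M aqueous solutes, pure liquid water).  ΔG°′ adds
the conventional pH correction, moving H+ from 1 M to activity 10^-pH while
every other species stays at its standard state:

    ΔG°′ = ΔG° + ν_net(H+) · R·T·ln(10^-pH)

where ν_net(H+) is produced-minus-consumed protons.  Energies are reported
per reaction as written and per mole of electron donor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .chem import FullReaction

R_KJ = 8.314462618e-3  # kJ mol-1 K-1


class MissingFormationEnergy(KeyError):
    pass


@dataclass
class FormationEnergyTable:
    """ΔGf° lookup keyed on (species name, phase), kJ/mol at 298.15 K."""

    entries: dict[tuple[str, str], float]
    sources: dict[tuple[str, str], str]

    def dgf(self, name: str, phase: str) -> float:
        try:
            return self.entries[(name, phase)]
        except KeyError:
            raise MissingFormationEnergy(
                f"no formation energy for species {name!r} (phase {phase!r})"
            ) from None

    @classmethod
    def from_csv(cls, path) -> "FormationEnergyTable":
        df = pd.read_csv(path)
        required = {"species", "phase", "dgf_kj_per_mol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"formation-energy CSV missing columns {sorted(missing)}")
        entries, sources = {}, {}
        for row in df.itertuples(index=False):
            key = (row.species, row.phase)
            entries[key] = float(row.dgf_kj_per_mol)
            sources[key] = getattr(row, "source", "")
        return cls(entries, sources)

    def to_csv(self, path) -> None:
        rows = [
            {
                "species": name,
                "phase": phase,
                "dgf_kj_per_mol": dgf,
                "source": self.sources.get((name, phase), ""),
            }
            for (name, phase), dgf in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_table() -> FormationEnergyTable:
    """The curated table shipped with the package (user-overridable)."""
    with resources.files("alkanox.data").joinpath("formation_energies.csv").open() as fh:
        return FormationEnergyTable.from_csv(fh)


@dataclass
class ThermoResult:
    delta_g0: float  # kJ per reaction as written
    delta_g0_prime: float  # kJ per reaction at the stated pH
    per_mol_donor: float  # kJ per mol donor (alkane)
    pH: float
    T: float


def delta_g0(reaction: FullReaction, table: FormationEnergyTable) -> float:
    """Σν·ΔGf° over the reaction, kJ per reaction as written."""
    return sum(
        coeff * table.dgf(sp.name, sp.phase) for sp, coeff in reaction.stoich.items()
    )


def delta_g0_prime(
    reaction: FullReaction,
    table: FormationEnergyTable | None = None,
    pH: float = 7.0,
    T: float = 298.15,
) -> ThermoResult:
    """ΔG°′ at the given pH, plus the per-mol-donor normalization."""
    if not 0 <= pH <= 14:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    if table is None:
        table = default_table()
    g0 = delta_g0(reaction, table)
    nu_h = reaction.coefficient("H+")  # signed: produced - consumed
    g0p = g0 + nu_h * R_KJ * T * math.log(10.0 ** (-pH))
    donor_coeff = reaction.donor_coefficient
    return ThermoResult(
        delta_g0=g0,
        delta_g0_prime=g0p,
        per_mol_donor=g0p / donor_coeff,
        pH=pH,
        T=T,
    )
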
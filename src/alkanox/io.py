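"""Readers, writers and run configuration.

All concentrations are per litre of liquid; vessel-total columns carry a
``_total`` suffix.  Unit conversions happen only inside the balance module.
The run configuration is a flat YAML mapping whose keys carry their units
(``v_gas_l``, ``temp_K`` ...) to keep unit mistakes visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem, thermo
from .balance import (
    DEFAULT_NO3_THRESHOLD,
    BalanceReport,
    ReactorTimeSeries,
    electron_balance,
    segment_phases,
)
from .henry import VesselGeometry, default_solubilities, read_solubilities
from .isotopes import IsotopeSeries, c13_recovery, n15_recovery

TIMESERIES_COLUMNS = [
    "time_h",
    "no3_mmolN_l",
    "no2_mmolN_l",
    "nh4_mmolN_l",
    "n2_mmolN_total",
    "alkane_mmol_total",
    "co2_mmol_total",
]

ISOTOPE_COLUMNS = [
    "time_h",
    "c13co2_umol",
    "c13alkane_umol",
    "n2_29_umol",
    "n2_30_umol",
    "nh4_15_umol",
    "no3_15_umol",
    "no2_15_umol",
]


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    geometry: VesselGeometry
    n_carbons: int
    no3_threshold: float = DEFAULT_NO3_THRESHOLD
    pH: float = 7.0
    thermo_T: float = 298.15
    solubility_csv: str | None = None
    formation_energy_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"config {path} is not a key-value mapping")
        try:
            geom = VesselGeometry(
                v_gas=float(raw["v_gas_l"]),
                v_liq=float(raw["v_liq_l"]),
                T=float(raw["temp_K"]),
            )
            n_carbons = int(raw["n_carbons"])
        except KeyError as e:
            raise SchemaError(f"config {path} missing required key {e.args[0]!r}") from None
        cfg = cls(
            geometry=geom,
            n_carbons=n_carbons,
            no3_threshold=float(raw.get("no3_threshold_mmolN_l", DEFAULT_NO3_THRESHOLD)),
            pH=float(raw.get("ph", 7.0)),
            thermo_T=float(raw.get("thermo_temp_K", 298.15)),
            solubility_csv=raw.get("solubility_csv"),
            formation_energy_csv=raw.get("formation_energy_csv"),
        )
        for key in (cfg.solubility_csv, cfg.formation_energy_csv):
            if key is not None and not Path(key).exists():
                raise SchemaError(f"config references missing file {key!r}")
        return cfg

    def solubilities(self):
        if self.solubility_csv:
            return read_solubilities(self.solubility_csv)
        return default_solubilities()

    def formation_table(self):
        if self.formation_energy_csv:
            return thermo.FormationEnergyTable.from_csv(self.formation_energy_csv)
        return thermo.default_table()


def read_timeseries(path, geometry: VesselGeometry, n_carbons: int) -> ReactorTimeSeries:
    """Load and validate a reactor time-series CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["time_h"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError(
            f"{path}: time_h not strictly increasing at data row {bad[0] + 2}"
        )
    for col in TIMESERIES_COLUMNS[1:]:
        vals = df[col].to_numpy(dtype=float)
        neg = np.nonzero(vals < 0)[0]
        if neg.size:
            raise SchemaError(f"{path}: negative value in {col} at data row {neg[0] + 1}")
    return ReactorTimeSeries(
        times=t,
        no3=df["no3_mmolN_l"].to_numpy(float),
        no2=df["no2_mmolN_l"].to_numpy(float),
        nh4=df["nh4_mmolN_l"].to_numpy(float),
        n2_total=df["n2_mmolN_total"].to_numpy(float),
        alkane_total=df["alkane_mmol_total"].to_numpy(float),
        co2_total=df["co2_mmol_total"].to_numpy(float),
        geometry=geometry,
        n_carbons=n_carbons,
    )


def write_timeseries(ts: ReactorTimeSeries, path) -> None:
    pd.DataFrame(
        {
            "time_h": ts.times,
            "no3_mmolN_l": ts.no3,
            "no2_mmolN_l": ts.no2,
            "nh4_mmolN_l": ts.nh4,
            "n2_mmolN_total": ts.n2_total,
            "alkane_mmol_total": ts.alkane_total,
            "co2_mmol_total": ts.co2_total,
        }
    ).to_csv(path, index=False)


def read_isotope_series(path, carbons_per_molecule: int) -> IsotopeSeries:
    """Build cumulative tracer inventories from an isotope time-series CSV.

    File columns are molecule-based where the species is molecular (13C
    alkane, 29/30N2); conversion to atom units happens here: consumed
    13C-alkane is multiplied by carbons per molecule, CO2 carries one carbon.
    """
    df = pd.read_csv(path)
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    first, last = df.iloc[0], df.iloc[-1]
    return IsotopeSeries(
        c13_co2_produced=float(last.c13co2_umol - first.c13co2_umol),
        c13_alkane_consumed=float(first.c13alkane_umol - last.c13alkane_umol)
        * carbons_per_molecule,
        n2_29=float(last.n2_29_umol - first.n2_29_umol),
        n2_30=float(last.n2_30_umol - first.n2_30_umol),
        nh4_15=float(last.nh4_15_umol - first.nh4_15_umol),
        no3_15_consumed=float(first.no3_15_umol - last.no3_15_umol),
        no2_15=float(last.no2_15_umol),
    )


def thermo_report(config: RunConfig) -> list[dict]:
    """ΔG°′ for the configured alkane against each nitrogen couple."""
    table = config.formation_table()
    donor = chem.alkane_oxidation_half(config.n_carbons)
    out = []
    for name in chem.N_COUPLES:
        acceptor = chem.nitrogen_reduction_half(name)
        rxn = chem.couple(donor, acceptor)
        res = thermo.delta_g0_prime(rxn, table, pH=config.pH, T=config.thermo_T)
        out.append(
            {
                "couple": name,
                "equation": chem.format_reaction(rxn),
                "delta_g0_kj": res.delta_g0,
                "delta_g0_prime_kj": res.delta_g0_prime,
                "kj_per_mol_alkane": res.per_mol_donor,
            }
        )
    return out


def run_pipeline(config: RunConfig, input_csv, isotope_csv=None) -> dict:
    """End-to-end report: balances, thermodynamic context, tracer recoveries."""
    ts = read_timeseries(input_csv, config.geometry, config.n_carbons)
    seg = segment_phases(ts, config.no3_threshold)
    report: BalanceReport = electron_balance(ts, seg)
    out = {
        "balance": report.to_dict(),
        "thermodynamics": thermo_report(config),
    }
    if isotope_csv is not None:
        iso = read_isotope_series(isotope_csv, config.n_carbons)
        n15_umol, n15_frac = n15_recovery(iso)
        out["isotopes"] = {
            "c13_recovery": c13_recovery(iso),
            "n15_recovered_umol": n15_umol,
            "n15_recovery": n15_frac,
        }
    return out


def write_report(report: dict, json_path=None, csv_path=None) -> None:
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        flat = dict(report.get("balance", {}))
        for row in report.get("thermodynamics", []):
            flat[f"dg0prime_{row['couple']}_kj_per_mol_alkane"] = row["kj_per_mol_alkane"]
        for k, v in report.get("isotopes", {}).items():
            flat[f"isotope_{k}"] = v
        pd.DataFrame([flat]).to_csv(csv_path, index=False)
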
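"""Stable-isotope tracer bookkeeping for 13C-alkane / 15N-nitrate labelling.

All quantities are handled in atom units (μmol 13C atoms, μmol 15N atoms);
molecule-to-atom conversion (×2 for 30N2, ×1 for 29N2, ×carbons-per-molecule
for the alkane) happens at ingestion.  Natural-abundance background
subtraction is not applied by default — labelled pools are taken as
reported — but is available as an optional correction.
"""

from __future__ import annotations

from dataclasses import dataclass

NATURAL_13C = 0.0107
NATURAL_15N = 0.003663


class DegenerateInputError(ValueError):
    pass


@dataclass
class IsotopeSeries:
    """Cumulative labelled inventories for one batch test (μmol).

    ``c13_co2_produced`` and ``c13_alkane_consumed`` are μmol 13C atoms;
    ``n2_29``/``n2_30`` are μmol N2 molecules; the remaining N pools are
    μmol 15N atoms.
    """

    c13_co2_produced: float = 0.0
    c13_alkane_consumed: float = 0.0
    n2_29: float = 0.0
    n2_30: float = 0.0
    nh4_15: float = 0.0
    no3_15_consumed: float = 0.0
    no2_15: float = 0.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class LabelConfig:
    """Atom fraction of 15N in the nitrate pool and carbons per alkane molecule."""

    p15: float = 0.01
    carbons_per_molecule: int = 2

    def __post_init__(self):
        if not 0.0 <= self.p15 <= 1.0:
            raise ValueError(f"p15 must be in [0, 1], got {self.p15}")


def c13_recovery(s: IsotopeSeries, subtract_background: bool = False) -> float:
    """Fraction of consumed 13C-alkane carbon recovered as 13CO2."""
    if s.c13_alkane_consumed <= 0:
        raise DegenerateInputError("no 13C-alkane consumption; recovery undefined")
    produced = s.c13_co2_produced
    if subtract_background:
        produced = max(produced - NATURAL_13C * s.c13_alkane_consumed, 0.0)
    return produced / s.c13_alkane_consumed


def n15_recovery(s: IsotopeSeries) -> tuple[float, float]:
    """(μmol 15N recovered in 29N2 + 30N2 + 15NH4+, fraction of consumed 15NO3-).

    29N2 carries one labelled atom per molecule, 30N2 two.
    """
    if s.no3_15_consumed <= 0:
        raise DegenerateInputError("no 15NO3- consumption; recovery undefined")
    n15_produced = 1.0 * s.n2_29 + 2.0 * s.n2_30 + s.nh4_15
    return n15_produced, n15_produced / s.no3_15_consumed


def pairing_fractions(cfg: LabelConfig) -> tuple[float, float, float]:
    """Expected (28N2, 29N2, 30N2) molecule fractions under random pairing.

    With atom fraction p of 15N, random pairing of two N atoms gives the
    binomial split ((1-p)^2, 2p(1-p), p^2).
    """
    p = cfg.p15
    return ((1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p)
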
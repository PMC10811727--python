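"""Redox stoichiometry for alkane oxidation coupled to N-oxyanion reduction.

Half-reactions are built by the standard aqueous convention: balance the
principal element, then O with H2O, then H with H+, then charge with
electrons.  Coupling two half-reactions cancels electrons via the least
common multiple of the electron counts, nets out H2O/H+ appearing on both
sides, and reduces all coefficients to minimal integers.  All arithmetic is
exact (rational), never floating point.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

SUPPORTED_ELEMENTS = ("C", "H", "O", "N")

_ALKANE_NAMES = {1: "CH4", 2: "C2H6", 3: "C3H8", 4: "C4H10", 5: "C5H12", 6: "C6H14"}


@dataclass(frozen=True)
class Species:
    """A chemical species with fixed elemental composition, charge and phase."""

    name: str
    element_counts: Mapping[str, int]
    charge: int
    phase: str  # "gas", "aqueous" or "liquid"

    def __post_init__(self):
        counts = dict(self.element_counts)
        if not counts or all(v == 0 for v in counts.values()):
            raise ValueError(f"species {self.name!r} has no atoms")
        for el, n in counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {el!r} in {self.name!r}")
            if n < 0:
                raise ValueError(f"negative count for {el} in {self.name!r}")
        if self.phase not in ("gas", "aqueous", "liquid"):
            raise ValueError(f"invalid phase {self.phase!r} for {self.name!r}")
        object.__setattr__(self, "element_counts", _FrozenCounts(counts))

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)


class _FrozenCounts(dict):
    """Immutable, hashable element-count map so Species can key dicts."""

    def __hash__(self):  # type: ignore[override]
        return hash(frozenset(self.items()))

    def __setitem__(self, *a):
        raise TypeError("element counts are immutable")


def alkane(n_carbons: int) -> Species:
    """The straight-chain alkane CnH2n+2 as a gas-phase species."""
    if n_carbons not in _ALKANE_NAMES:
        raise ValueError(f"n_carbons must be in 1..6, got {n_carbons}")
    return Species(_ALKANE_NAMES[n_carbons], {"C": n_carbons, "H": 2 * n_carbons + 2}, 0, "gas")


# Canonical species registry.  CO2 is gas-phase by default, consistent with
# the convention used when writing full oxidation equations.
CO2 = Species("CO2", {"C": 1, "O": 2}, 0, "gas")
H2O = Species("H2O", {"H": 2, "O": 1}, 0, "liquid")
H_PLUS = Species("H+", {"H": 1}, 1, "aqueous")
NO3 = Species("NO3-", {"N": 1, "O": 3}, -1, "aqueous")
NO2 = Species("NO2-", {"N": 1, "O": 2}, -1, "aqueous")
NH4 = Species("NH4+", {"N": 1, "H": 4}, 1, "aqueous")
N2 = Species("N2", {"N": 2}, 0, "gas")

REGISTRY = {
    s.name: s
    for s in [CO2, H2O, H_PLUS, NO3, NO2, NH4, N2]
    + [alkane(n) for n in _ALKANE_NAMES]
}


@dataclass
class HalfReaction:
    """A redox half-reaction.

    ``stoich`` maps species to signed rational coefficients (negative =
    consumed); ``electrons`` is positive when the half-reaction releases
    electrons as written.  ``principal`` is the donor/acceptor the reaction
    is normalized to.
    """

    stoich: dict[Species, Fraction]
    electrons: Fraction
    principal: Species

    def __post_init__(self):
        if self.electrons == 0:
            raise ValueError("a half-reaction must transfer electrons")
        self._check_conservation()

    def _check_conservation(self):
        for el in SUPPORTED_ELEMENTS:
            r = sum(c * sp.count(el) for sp, c in self.stoich.items())
            if r != 0:
                raise ValueError(f"element {el} not conserved (residual {r})")
        # electrons carry charge -1; released electrons appear on the
        # product side, so total charge incl. electrons must vanish
        charge = sum(c * sp.charge for sp, c in self.stoich.items())
        if charge - self.electrons != 0:
            raise ValueError(f"charge not conserved (residual {charge - self.electrons})")

    def scaled(self, k: Fraction | int) -> "HalfReaction":
        k = Fraction(k)
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return HalfReaction(
            {sp: c * k for sp, c in self.stoich.items()}, self.electrons * k, self.principal
        )


@dataclass
class FullReaction:
    """A balanced net reaction with minimal integer coefficients."""

    stoich: dict[Species, int]
    donor: Species
    electrons_per_donor: int

    def coefficient(self, name: str) -> int:
        for sp, c in self.stoich.items():
            if sp.name == name:
                return c
        return 0

    @property
    def donor_coefficient(self) -> int:
        return abs(self.stoich[self.donor])


def _complete_half(skeleton: dict[Species, Fraction], principal: Species) -> HalfReaction:
    """Balance O with H2O, H with H+, charge with electrons."""
    stoich = dict(skeleton)
    o_res = sum(c * sp.count("O") for sp, c in stoich.items())
    if o_res != 0:
        stoich[H2O] = stoich.get(H2O, Fraction(0)) - o_res
    h_res = sum(c * sp.count("H") for sp, c in stoich.items())
    if h_res != 0:
        stoich[H_PLUS] = stoich.get(H_PLUS, Fraction(0)) - h_res
    electrons = sum(c * sp.charge for sp, c in stoich.items())
    stoich = {sp: c for sp, c in stoich.items() if c != 0}
    return HalfReaction(stoich, Fraction(electrons), principal)


def alkane_oxidation_half(n_carbons: int) -> HalfReaction:
    """CnH2n+2 + 2n H2O -> n CO2 + (6n+2) H+ + (6n+2) e-, per mol alkane."""
    donor = alkane(n_carbons)
    half = _complete_half(
        {donor: Fraction(-1), CO2: Fraction(n_carbons)}, principal=donor
    )
    assert half.electrons == 6 * n_carbons + 2
    return half


N_COUPLES = {
    "NO3->NO2": (NO3, NO2),
    "NO3->N2": (NO3, N2),
    "NO2->N2": (NO2, N2),
    "NO3->NH4": (NO3, NH4),
    "NO2->NH4": (NO2, NH4),
}

# electrons consumed per mol N for each couple (oxidation-state change)
ELECTRONS_PER_N = {
    "NO3->NO2": 2,
    "NO3->N2": 5,
    "NO2->N2": 3,
    "NO3->NH4": 8,
    "NO2->NH4": 6,
}


def nitrogen_reduction_half(couple: str) -> HalfReaction:
    """Balanced N-oxyanion reduction half-reaction, normalized to 1 mol N."""
    key = couple.replace("→", "->").replace(" ", "")
    if key not in N_COUPLES:
        raise ValueError(
            f"unknown couple {couple!r}; expected one of {sorted(N_COUPLES)}"
        )
    reactant, product = N_COUPLES[key]
    per_n = Fraction(1, product.count("N"))
    half = _complete_half(
        {reactant: Fraction(-1), product: per_n}, principal=reactant
    )
    assert -half.electrons == ELECTRONS_PER_N[key]
    return half


def couple(donor: HalfReaction, acceptor: HalfReaction) -> FullReaction:
    """Combine an electron-releasing and an electron-consuming half-reaction.

    Both halves are scaled so electrons cancel exactly, species appearing on
    both sides (H2O, H+) are netted, and coefficients are reduced to minimal
    integers.
    """
    if donor.electrons <= 0 or acceptor.electrons >= 0:
        raise ValueError(
            "couple() needs an electron-releasing donor and an "
            "electron-consuming acceptor"
        )
    e_d, e_a = donor.electrons, -acceptor.electrons
    # least common multiple of two positive rationals
    lcm_num = math.lcm(e_d.numerator, e_a.numerator)
    gcd_den = math.gcd(e_d.denominator, e_a.denominator)
    e_lcm = Fraction(lcm_num, gcd_den)
    net: dict[Species, Fraction] = {}
    for half, scale in ((donor, e_lcm / e_d), (acceptor, e_lcm / e_a)):
        for sp, c in half.stoich.items():
            net[sp] = net.get(sp, Fraction(0)) + c * scale
    net = {sp: c for sp, c in net.items() if c != 0}
    den_lcm = math.lcm(*[c.denominator for c in net.values()]) if net else 1
    ints = {sp: int(c * den_lcm) for sp, c in net.items()}
    g = math.gcd(*[abs(v) for v in ints.values()]) if ints else 1
    ints = {sp: v // g for sp, v in ints.items()}
    return FullReaction(
        stoich=ints,
        donor=donor.principal,
        electrons_per_donor=int(donor.electrons / abs(donor.stoich[donor.principal])),
    )


def check_balance(reaction: FullReaction) -> dict[str, Fraction | int]:
    """Per-element and charge residuals; all zero for a valid reaction."""
    residuals: dict[str, Fraction | int] = {}
    for el in SUPPORTED_ELEMENTS:
        residuals[el] = sum(c * sp.count(el) for sp, c in reaction.stoich.items())
    residuals["charge"] = sum(c * sp.charge for sp, c in reaction.stoich.items())
    return residuals


# ---------------------------------------------------------------------------
# Plain-text equation format: "3 C2H6 + 14 NO2- + 14 H+ -> 6 CO2 + 7 N2 + 16 H2O"

_TOKEN_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z0-9]+)([+-]?)$")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_species_token(token: str) -> tuple[int, Species]:
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse species term {token!r}")
    coeff = int(m.group(1) or 1)
    name = m.group(2) + m.group(3)
    if name in REGISTRY:
        return coeff, REGISTRY[name]
    counts: dict[str, int] = {}
    for el, n in _FORMULA_RE.findall(m.group(2)):
        counts[el] = counts.get(el, 0) + int(n or 1)
    charge = {"+": 1, "-": -1, "": 0}[m.group(3)]
    phase = "gas" if charge == 0 else "aqueous"
    return coeff, Species(name, counts, charge, phase)


def parse_reaction(text: str, donor_name: str | None = None) -> FullReaction:
    """Parse ``"a X + b Y -> c Z"`` into a FullReaction.

    The donor defaults to the first left-hand-side species.  The parsed
    reaction is not re-balanced; use :func:`check_balance` to validate.
    """
    if "->" not in text:
        raise ValueError("equation must contain '->'")
    lhs, rhs = text.split("->", 1)
    stoich: dict[Species, int] = {}
    first_reactant: Species | None = None
    for side, sign in ((lhs, -1), (rhs, +1)):
        for term in _split_terms(side):
            coeff, sp = _parse_species_token(term)
            stoich[sp] = stoich.get(sp, 0) + sign * coeff
            if sign < 0 and first_reactant is None:
                first_reactant = sp
    if first_reactant is None:
        raise ValueError("equation has no reactants")
    donor = first_reactant
    if donor_name is not None:
        matches = [sp for sp in stoich if sp.name == donor_name]
        if not matches:
            raise ValueError(f"donor {donor_name!r} not in equation")
        donor = matches[0]
    n_c = donor.count("C")
    e_per = 6 * n_c + 2 if n_c else 0
    return FullReaction(stoich=stoich, donor=donor, electrons_per_donor=e_per)


def _split_terms(side: str) -> list[str]:
    # split on '+' surrounded by whitespace so trailing charge '+' survives
    return [t for t in re.split(r"\s+\+\s+", side.strip()) if t]


def format_reaction(reaction: FullReaction) -> str:
    """Render to the plain-text equation format (reactants sorted donor-first)."""
    lhs, rhs = [], []
    items = sorted(
        reaction.stoich.items(),
        key=lambda kv: (kv[0] is not reaction.donor, kv[0].name),
    )
    for sp, c in items:
        if c == 0:
            continue
        term = sp.name if abs(c) == 1 else f"{abs(c)} {sp.name}"
        (lhs if c < 0 else rhs).append(term)
    return " + ".join(lhs) + " -> " + " + ".join(rhs)
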
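"""Nitrogen and electron balances for anoxic alkane-fed batch incubations.

The incubations show two kinetic regimes: Phase 1, nitrate reduced to
nitrite and N2 with negligible ammonium; Phase 2, after nitrate depletion,
nitrite reduced to N2 and ammonium (DNRA).  The electron ledger costs each
nitrogen transformation at its electron-equivalent count per mol N:

    NO3- -> NO2-   2 e-        NO3- -> N2   5 e-       NO3- -> NH4+  8 e-
    NO2- -> N2     3 e-        NO2- -> NH4+ 6 e-

Phase-1 ledger: accumulated NO2- at 2, N2-N produced at 5 (from nitrate),
NH4+ at 8.  Phase-2 ledger: N2-N at 3 and NH4+ at 6, each plus the 2 e-/N
nitrate-to-nitrite leg credited where that nitrite was produced, so the
denitrification and DNRA pools carry the full 5 and 8 e-/N of their
nitrogen.  Nitrite remaining at the end holds 2 e-/N that belong to neither
pathway but were demonstrably transferred.  The electron fraction compares
the accepted electrons with the donor maximum, (6n+2) e- per CnH2n+2
oxidized fully to CO2.

All balances are computed on vessel-total mmol (dissolved species scaled by
the liquid volume); per-litre outputs divide by the liquid volume at the
end.  Balances are endpoint-determined: noise-free conservative data give
recovery and electron fraction of exactly 1 regardless of sampling density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem import ELECTRONS_PER_N
from .henry import VesselGeometry

DEFAULT_NO3_THRESHOLD = 0.05  # mmol N / l

HOURS_PER_DAY = 24.0


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class ReactorTimeSeries:
    """Measured batch profiles.

    Dissolved N species are mmol N per litre liquid; ``n2_total`` is
    vessel-total mmol N; ``alkane_total`` and ``co2_total`` are vessel-total
    mmol molecules.
    """

    times: np.ndarray  # hours
    no3: np.ndarray
    no2: np.ndarray
    nh4: np.ndarray
    n2_total: np.ndarray
    alkane_total: np.ndarray
    co2_total: np.ndarray
    geometry: VesselGeometry
    n_carbons: int

    def __post_init__(self):
        arrays = {
            "times": self.times,
            "no3": self.no3,
            "no2": self.no2,
            "nh4": self.nh4,
            "n2_total": self.n2_total,
            "alkane_total": self.alkane_total,
            "co2_total": self.co2_total,
        }
        for name, arr in arrays.items():
            setattr(self, name, np.asarray(arr, dtype=float))
        n = len(self.times)
        if n == 0:
            raise ValueError("time series is empty")
        for name, arr in arrays.items():
            if len(np.asarray(arr)) != n:
                raise ValueError(f"column {name} has length {len(arr)}, expected {n}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("no3", "no2", "nh4", "n2_total", "alkane_total", "co2_total"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"column {name} contains negative values")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhaseSegmentation:
    boundary_index: int  # first index of Phase 2 (== len: no Phase 2)
    threshold: float  # mmol N / l


@dataclass
class BalanceReport:
    n_produced: float  # mmol N / l
    n_consumed: float  # mmol N / l
    n_recovery: float
    e_denit: float  # vessel-total mmol e-
    e_dnra: float
    e_residual_no2: float
    e_max: float
    e_fraction: float
    dnra_rate: float  # mmol N / l / day
    boundary_index: int = 0

    def to_dict(self) -> dict:
        return {
            "n_produced_mmolN_l": self.n_produced,
            "n_consumed_mmolN_l": self.n_consumed,
            "n_recovery": self.n_recovery,
            "e_denit_mmol": self.e_denit,
            "e_dnra_mmol": self.e_dnra,
            "e_residual_no2_mmol": self.e_residual_no2,
            "e_max_mmol": self.e_max,
            "e_fraction": self.e_fraction,
            "dnra_rate_mmolN_l_day": self.dnra_rate,
            "phase_boundary_index": self.boundary_index,
        }


def segment_phases(
    ts: ReactorTimeSeries, threshold: float = DEFAULT_NO3_THRESHOLD
) -> PhaseSegmentation:
    """First index where nitrate falls below threshold and stays below.

    Returns boundary == series length when nitrate never depletes (the whole
    run is Phase 1).
    """
    if len(ts) == 0:
        raise ValueError("cannot segment an empty series")
    below = ts.no3 < threshold
    boundary = len(ts)
    # scan backwards: boundary is the start of the trailing all-below block
    for i in range(len(ts) - 1, -1, -1):
        if not below[i]:
            break
        boundary = i
    return PhaseSegmentation(boundary_index=boundary, threshold=threshold)


def nitrogen_balance(
    ts: ReactorTimeSeries, seg: PhaseSegmentation
) -> tuple[float, float, float]:
    """(n_produced, n_consumed, n_recovery), mmol N per litre liquid.

    Produced = ΔNH4+ plus ΔN2-N (vessel total converted per litre);
    consumed = net drawdown of NO3- + NO2- over the whole test.
    """
    v_liq = ts.geometry.v_liq
    produced = (ts.nh4[-1] - ts.nh4[0]) + (ts.n2_total[-1] - ts.n2_total[0]) / v_liq
    consumed = (ts.no3[0] - ts.no3[-1]) + (ts.no2[0] - ts.no2[-1])
    if consumed <= 0:
        raise DegenerateInputError(
            "no net nitrogen-oxyanion consumption; nitrogen balance undefined"
        )
    return produced, consumed, produced / consumed


def electron_balance(ts: ReactorTimeSeries, seg: PhaseSegmentation) -> BalanceReport:
    """Full nitrogen and electron balance report for one batch test."""
    b = min(seg.boundary_index, len(ts) - 1)
    v_liq = ts.geometry.v_liq
    has_phase2 = seg.boundary_index < len(ts)

    alkane_consumed = ts.alkane_total[0] - ts.alkane_total[-1]
    if alkane_consumed <= 0:
        raise DegenerateInputError("no net alkane consumption; electron balance undefined")

    # vessel-total deltas per phase (mmol N)
    n2_p1 = ts.n2_total[b] - ts.n2_total[0]
    n2_p2 = ts.n2_total[-1] - ts.n2_total[b]
    nh4_p1 = (ts.nh4[b] - ts.nh4[0]) * v_liq
    nh4_p2 = (ts.nh4[-1] - ts.nh4[b]) * v_liq

    # denitrified N carries 5 e-/N whether it left via Phase 1 (direct from
    # nitrate) or Phase 2 (3 e-/N from nitrite + the credited 2 e-/N
    # nitrate->nitrite leg); DNRA N likewise carries the full 8 e-/N
    e_denit = ELECTRONS_PER_N["NO3->N2"] * (n2_p1 + n2_p2)
    e_dnra = ELECTRONS_PER_N["NO3->NH4"] * (nh4_p1 + nh4_p2)
    e_residual = ELECTRONS_PER_N["NO3->NO2"] * ts.no2[-1] * v_liq

    e_max = (6 * ts.n_carbons + 2) * alkane_consumed
    e_fraction = (e_denit + e_dnra + e_residual) / e_max

    # nitrogen recovery is undefined when net oxyanion drawdown is zero
    # (e.g. nitrate merely converted to nitrite); report NaN, not an error
    try:
        produced, consumed, recovery = nitrogen_balance(ts, seg)
    except DegenerateInputError:
        v = ts.geometry.v_liq
        produced = (ts.nh4[-1] - ts.nh4[0]) + (ts.n2_total[-1] - ts.n2_total[0]) / v
        consumed = (ts.no3[0] - ts.no3[-1]) + (ts.no2[0] - ts.no2[-1])
        recovery = float("nan")
    rate = dnra_rate(ts, seg) if has_phase2 and (len(ts) - seg.boundary_index) >= 2 else 0.0
    return BalanceReport(
        n_produced=produced,
        n_consumed=consumed,
        n_recovery=recovery,
        e_denit=float(e_denit),
        e_dnra=float(e_dnra),
        e_residual_no2=float(e_residual),
        e_max=float(e_max),
        e_fraction=float(e_fraction),
        dnra_rate=float(rate),
        boundary_index=seg.boundary_index,
    )


def _nitrate_depletion_time(ts: ReactorTimeSeries, seg: PhaseSegmentation) -> float:
    """Zero-crossing of the linear Phase-1 nitrate trend.

    The segmentation boundary is the first sample below the threshold, which
    typically precedes true nitrate depletion; ammonium production only
    starts once nitrate is gone.  With zero-order Phase-1 kinetics the
    nitrate profile is linear, so its extrapolated zero-crossing locates the
    onset.  Falls back to the boundary sample time when Phase 1 is too short
    to fit or nitrate is not declining.
    """
    b = seg.boundary_index
    t_fallback = ts.times[min(b, len(ts) - 1)]
    if b < 2:
        return t_fallback
    fit = stats.linregress(ts.times[:b], ts.no3[:b])
    if fit.slope >= 0:
        return t_fallback
    return float(-fit.intercept / fit.slope)


def dnra_rate(ts: ReactorTimeSeries, seg: PhaseSegmentation) -> float:
    """Least-squares slope of NH4+ over Phase 2, in mmol N per litre per day.

    The regression window starts at the estimated nitrate depletion time
    (see :func:`_nitrate_depletion_time`), so a boundary sample caught
    between the detection threshold and actual depletion does not flatten
    the slope.
    """
    n_p2 = len(ts) - seg.boundary_index
    if n_p2 < 2:
        raise InsufficientDataError(
            f"Phase 2 has {n_p2} sample(s); at least 2 required for a rate"
        )
    t0 = _nitrate_depletion_time(ts, seg)
    mask = ts.times >= max(t0, ts.times[seg.boundary_index])
    if mask.sum() < 2:  # onset estimate too late; use the raw Phase-2 window
        mask = ts.times >= ts.times[seg.boundary_index]
    slope_per_h = stats.linregress(ts.times[mask], ts.nh4[mask]).slope
    return float(slope_per_h * HOURS_PER_DAY)
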
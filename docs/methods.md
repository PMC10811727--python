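# Methods

## Scope and model

`alkanox` implements the quantitative core of batch-incubation studies of
anaerobic short-chain-alkane oxidation coupled to nitrate reduction: exact
redox stoichiometry, reaction energetics, headspace–liquid gas accounting,
two-phase nitrogen/electron balances, stable-isotope tracer bookkeeping, and
a synthetic data generator. Microbial growth, biomass assimilation, pH
dynamics, carbonate speciation and kinetic rate laws beyond zero-order are
out of scope.

## Stoichiometry

Half-reactions are constructed deterministically by the standard aqueous
convention: fix the principal species (1 mol alkane, or 1 mol N for the
nitrogen couples), balance oxygen with H₂O, hydrogen with H⁺, and charge
with electrons. Full oxidation of CₙH₂ₙ₊₂ to CO₂ then releases 6n+2
electrons; the five supported acceptor couples consume 2 (NO₃⁻→NO₂⁻),
3 (NO₂⁻→N₂), 5 (NO₃⁻→N₂), 6 (NO₂⁻→NH₄⁺) and 8 (NO₃⁻→NH₄⁺) electrons per N.
Coupling scales the two halves by the least common multiple of their
electron counts, nets species occurring on both sides (H₂O, H⁺ are always
net-cancelled to a single side), and divides by the gcd, so the emitted
coefficients are minimal integers. All coefficient arithmetic uses exact
rationals (`fractions.Fraction`); floating point never touches a
stoichiometry. Species identity is (name, phase); CO₂ is gas-phase by
default, matching the convention in which the full oxidation equations are
usually written, with an aqueous entry available in the energy table.

## Thermodynamics

ΔG° = Σν·ΔGf° at 298.15 K with standard states 1 atm (gases), 1 M (aqueous
solutes) and pure liquid water. The biochemical-standard correction moves
only H⁺ to activity 10⁻ᵖᴴ:

ΔG°′ = ΔG° + ν_net(H⁺)·R·T·ln(10⁻ᵖᴴ),  R = 8.314462618 J mol⁻¹ K⁻¹.

Defaults are pH 7 and T = 298.15 K — the biochemical-standard convention —
even though the incubations that motivate the package ran at 35 °C; T is a
parameter so users can probe the sensitivity (it only enters through the pH
term here; temperature-dependent ΔGf° via van 't Hoff is deliberately not
modelled). Per-mol-donor values divide by the donor's stoichiometric
coefficient.

The shipped formation-energy table mixes CRC-style values for the gases and
liquid water (C₂H₆ −32.0, C₃H₈ −23.4, n-C₄H₁₀ −17.0, CO₂ −394.36, H₂O
−237.18 kJ/mol) with biochemical-compilation values for the aqueous ions
(NO₃⁻ −111.3, NO₂⁻ −37.2, NH₄⁺ −79.37 kJ/mol); reference-state elements are
zero and every entry carries a provenance note. Published ΔG°′ values for
these couples vary by a few percent depending on the compilation used —
which no study states precisely — so agreement is targeted at the ±5% level
and the table is fully user-overridable via CSV
(`species,phase,dgf_kj_per_mol,source`). Internal consistency is exact:
Hess additivity of stepwise couples holds to machine precision on any one
table.

## Gas partitioning

The headspace is ideal (R = 0.082057 l atm mol⁻¹ K⁻¹; no fugacity
correction below ~1.2 atm). Dissolved pools follow Henry's law,
c = H_cp(T)·p, with H_cp(T) = H_cp(298.15)·exp[B·(1/T − 1/298.15)] and
shipped (H_cp, B) pairs from a standard compilation (ethane 1.9×10⁻³
mol l⁻¹ atm⁻¹ / 2400 K; n-butane 1.2×10⁻³ / 3100 K; CO₂ 3.3×10⁻² / 2400 K;
N₂ 6.4×10⁻⁴ / 1300 K). The pressure↔total maps are linear, closed-form and
round-trip to < 10⁻¹² relative error. Dissolved CO₂ means CO₂(aq) only;
ignoring carbonate speciation is a documented limitation, acceptable when
samples are acidified before CO₂ quantification as is standard practice.

## Balance pipeline

Unit discipline: dissolved N species enter as mmol N per litre liquid; N₂,
alkane and CO₂ as vessel totals (their dissolved fractions already folded in
via the partitioning module). All balances are computed on vessel-total
mmol; per-litre outputs divide by V_liq at the end.

*Segmentation.* The Phase-1/Phase-2 boundary is the first sample at which
nitrate is below a threshold (default 0.05 mmol N/l, configurable) and stays
below for the rest of the series. The threshold should sit above the nitrate
measurement noise floor; with noisy data a transient upward flicker merely
moves the detected boundary later, which the downstream estimators tolerate.

*Nitrogen balance.* Produced = ΔNH₄⁺ + ΔN₂-N; consumed = net NO₃⁻ + NO₂⁻
drawdown over the whole test; recovery is their ratio (NaN when net
drawdown is zero, e.g. nitrate merely converted to nitrite).

*Electron ledger.* Phase-1: accumulated NO₂⁻ at 2 e⁻/N, N₂-N at 5 e⁻/N,
NH₄⁺ (nominally negligible, costed conservatively as DNRA from nitrate) at
8 e⁻/N. Phase-2: N₂-N at 3 and NH₄⁺ at 6 e⁻/N, each plus the 2 e⁻/N
nitrate→nitrite leg credited where that nitrite was produced. Hence the
reported pools carry the full electron cost of their nitrogen: e_denit =
5·ΔN₂-N, e_dnra = 8·ΔNH₄⁺, and nitrite remaining at the end holds
e_residual = 2·NO₂⁻_end, attributable to neither pathway. The ledger assumes
the initial nitrite and ammonium pools are (near) zero, as in a batch test
started on nitrate. e_fraction = (e_denit + e_dnra + e_residual)/e_max with
e_max = (6n+2)·alkane consumed. The decomposition is identical to the
routing-free oxidation-state ledger −Σ Δ(ν_ox·pool) (ν_ox = +5, +3, 0, −3
for NO₃⁻, NO₂⁻, N₂, NH₄⁺), which the tests exploit as an independent oracle.

*DNRA rate.* Least-squares slope of NH₄⁺ (mmol N/l) versus time over
Phase 2, ×24 to per-day. Because the detection threshold is crossed slightly
*before* nitrate actually depletes — and ammonium production only starts at
depletion — the regression window opens at the zero-crossing of the linear
Phase-1 nitrate trend rather than at the boundary sample itself; otherwise a
boundary sample caught in that gap flattens the slope. With fewer than two
Phase-2 samples the rate is not estimable and an error is raised.

## Synthetic reactor

Kinetics are zero-order within each phase (rate r1 on nitrate, r2 on
nitrite) with branching fractions f_n2_p1 (Phase-1 N routed fully to N₂
rather than stopping at nitrite) and f_nh4_p2 (Phase-2 N routed to ammonium
rather than N₂). Zero-order was chosen because the motivating batch profiles
are near-linear and no kinetic constants are published; the piecewise-linear
dynamics also integrate *exactly* under fixed-step stepping with depletion
clipping, so trajectories are step-size independent. At every step the
alkane drawdown is set so donated electrons, (6n+2) per molecule, exactly
meet the nitrogen electron demand; an optional uncoupled-sink fraction
f_sink diverts a share of donated electrons away from nitrogen, producing
data whose true electron fraction is 1 − f_sink (this keeps the estimator
from being trivially pinned at 1 in tests). Carbon goes entirely to CO₂.
Gases re-equilibrate across headspace and liquid after every step.

Measurement noise is additive Gaussian, truncated at zero, from a seeded
`numpy` generator; the same seed is bit-reproducible. Per-analyte standard
deviations default to ~2–3% of each analyte's dynamic range (e.g. 0.04
mmol N/l on a 2 mmol N/l nitrate drawdown, 0.02 mmol on a ~0.7 mmol alkane
drawdown): for balance estimates the informative scale is the change, not
the static headspace inventory. Presets:

- `ethane-like`: 0.82 l liquid / 0.3 l headspace, 35 °C, 2.0 mmol N/l
  nitrate, ethane 1 atm, r1 = 0.012, r2 = 0.010 mmol N/l/h, f_n2_p1 = 0.3,
  DNRA rate 0.11 mmol N/l/day; sampled 8-hourly over 304 h.
- `butane-like`: 0.5 l / 0.15 l, 1.63 mmol N/l, butane 0.95 atm, faster
  Phase 2 (r2 = 0.04) with DNRA rate 0.77 mmol N/l/day; 6-hourly over 162 h.
- `no-dnra` (f_nh4_p2 = 0) and `uncoupled-sink` (f_sink = 0.2) variants.

Sampling ends at nitrite depletion, as batch stoichiometry tests do; a
trailing product plateau would otherwise dilute the rate regression.
Labelled runs route tracer atoms conservatively: ¹³C recovery is 1 by
construction, ¹⁵N splits into ²⁹N₂/³⁰N₂ by binomial random pairing at the
configured atom fraction (~1% by default).

What the generator deliberately omits — growth and carbon assimilation,
abiotic losses, pH drift, mass-transfer limitation, replicate-bottle
variance — bounds what passing tests show: they validate the bookkeeping
and estimators on data that obey the model's conservation laws, not the
biology of any real enrichment.

## Numerical and statistical notes

- Stoichiometry and ledger identities are exact (rational/closed-form);
  conservation assertions use 10⁻⁹ relative tolerance only where floating
  -point trajectories are involved.
- Balances are endpoint-determined; inserting or removing interior samples
  does not change them on noise-free data.
- Truncating noise at zero biases pools near zero slightly upward (a
  detection-limit effect real instruments share); with default noise this
  shifts the estimated electron fraction by well under 1%, within the
  Monte-Carlo confidence band checked in the tests (200 seeded replicates,
  mean within 3 standard errors of truth).
- Estimator ratios inherit a small positive bias when the denominator (the
  alkane drawdown) is noisy relative to its magnitude; this is a property of
  measuring a small drawdown of a large inventory, visible in the
  butane-like configuration and documented rather than corrected.
- Degenerate inputs raise typed errors (`DegenerateInputError`,
  `InsufficientDataError`, `SchemaError`) naming the offending quantity.

## Problem sizes

Default test and acceptance runs use series of ~30–40 samples and 200-seed
Monte-Carlo replicates; the exact zero-order integrator makes each run
O(samples), so the full suite completes in a few seconds.
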
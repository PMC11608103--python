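# Methods

This note records the model equations as implemented, the numerical
choices, the design decisions taken where the design was genuinely open,
and what the synthetic examples do and do not demonstrate.

## Model structure

The catchment is three well-mixed "effective" zones. The shallow zone (SZ)
aggregates the HBV soil-moisture store and upper response reservoir; the
deep zone (DZ) is the lower reservoir; the surface zone (SF) is a small
transient store through which quick flow passes. Each subsurface zone adds
a constant *passive storage* (mm) to the HBV dynamic storage: water that
does not generate streamflow but dilutes, reacts, and evaporates. Passive
storage is the main control on chemical damping — with ~200 mm in the SZ
and ~1,000 mm in the DZ the chemical residence times are on the order of
months and years even though hydraulic response is days.

Zone saturation and water-table depth are not observable from bucket
storages, so they are defined as:

* `Sw(SZ) = min(1, SM/FC)` — the soil-moisture store against field
  capacity;
* `Sw(DZ) = min(1, (V_w/1000)/(porosity·depth))` — storage against pore
  capacity;
* `Zw = max(0, depth − (V_w/1000)/porosity)` in metres from the top of the
  zone's column (0 when fully saturated).

Quick flow is taken from the HBV upper zone but routed through the SF
store. Infiltration is `rain + melt − Q_SF`; on recession days this is
negative (quick flow drains old storage), and the deficit is routed as an
SZ→SF return flux at the shallow zone's end-of-step concentration so every
mass balance closes exactly.

## Rate laws

Kinetic rates are `r = k · A · f(T) · f(Sw) · f(Zw) · chem` in
mol per m² of catchment per day, with `k` stored as log10 mol/m²/s
(converted by 86,400 s/day) and `A` a constant area term: specific surface
area (m²/g) × areal substrate density (g/m² catchment). Dividing a rate by
the zone water storage (mm ≡ L/m²) converts it into a concentration
change.

* `f(T) = Q10^(|T−20|/10)` as printed in the source material; note the
  absolute value makes rates *rise* below 20 °C (at 0 °C with Q10 = 2,
  f(T) = 4). A `signed_q10` switch selects the conventional monotone form
  `Q10^((T−20)/10)`. The shipped example configurations use the signed
  form, because the qualitative behaviors the examples are meant to show —
  summer-peaking respiration and leaching rates, and the dilution pattern
  of nitrate when deep denitrification is absent — are inverted by the
  winter-amplifying absolute-value form. The library default remains the
  printed form.
* `f(Sw) = (Sw/Swc)^n` below the critical saturation and
  `((1−Sw)/(1−Swc))^n` above it; `n = 0` disables the dependence.
* `f(Zw) = exp(−(α·β)·Zw)`: only the product α·β is prescribed, so the
  exponential-in-depth reading is the only one parameterizable from it; a
  positive product depresses rates as the water table falls.
* TST: `chem = a^m (1 − IAP/Keq)` — positive rates dissolve, negative
  precipitate; catalyst exponents default to m = 0 (no catalyst column is
  printed for the example networks). The IAP uses the reaction's own
  stoichiometry as written, including non-integer coefficients.
* Monod: `chem = Π C/(C+KM) · Π KI/(C+KI)`. Concentrations of solid or
  pseudo-gas substrates in Monod terms come from a prescribed per-zone
  availability (mol/L-equivalent), configured to be non-limiting in the
  examples per their design intent.
* Availability guard: every aqueous primary *consumed* by a Monod-kind
  reaction contributes an implicit factor `C/(C + 1e-9)`. This is what lets
  zero-order sinks (plant uptake, `r = kA`) shut off smoothly as their
  substrate empties instead of driving concentrations negative. The guard
  constant is ≥3 orders of magnitude below every configured KM, so it is
  numerically invisible at reported concentrations.

## Speciation

Primary species totals (including a total for sorption sites) are the
state; secondary species follow from mass action. Unknowns are log10
concentrations of the primaries (positivity is structural), solved by
damped Newton–Raphson (max step 1 log10 unit, 100 iterations, relative
tolerance 1e-10 with a 1e-18 mol/L absolute floor so empty components can
settle at trace level). Activities equal concentrations; water is at unit
activity; solids at 1; pseudo-gases (soil CO₂) at a prescribed partial
pressure folded into the formation constants. Primaries that no secondary
references decouple and are solved directly. Totals of H⁺ follow the
alkalinity convention and may be negative; transport never clips such
signed components (the clip-to-floor safeguard applies only to components
that cannot legitimately be negative).

Dissolved inorganic carbon (DIC) is *not* a species: it is the reporting
aggregate CO₂(aq) + HCO₃⁻ + CO₃²⁻. Reaction stoichiometries written
against DIC are carried on HCO₃⁻ (the primary species the system solves
for); speciation redistributes the carbon afterwards. A consequence worth
stating plainly: respiration then adds alkalinity along with carbon, which
is a distortion of real CO₂-producing respiration. Similarly, the
carbonate dissolution stoichiometries (1.1 Ca²⁺ + 0.5 DIC shallow,
0.9 Ca²⁺ + 0.7 DIC deep, both log Keq −7.40) are applied literally even
though they are not charge- or mass-balanced; fidelity to the published
network was chosen over thermodynamic orthodoxy.

## Numerics

Each step is operator-split (sequential non-iterative): snow chemistry and
advective transport first, then reactions zone by zone, then
re-speciation.

* Transport is backward Euler, fully implicit in both concentration and
  end-of-step storage: `C⁺ = (C V + Δt·inflow) / (V⁺ + Δt·q_out)`. The
  deep zone receives the shallow zone's end-of-step concentration within
  the same step. Evapotranspiration removes pure water, concentrating the
  remaining solution (solutes are not transpired). Immobile components
  (sorption sites and the sorbed complex) keep their mass; their
  concentration rescales with storage.
* Reactions use Crank–Nicolson (trapezoidal average of start- and
  end-of-step rates) solved by a chord Newton–Raphson with
  finite-difference Jacobians (probe ≥ 1e-10 mol/L so the availability
  guard's shut-off slope is visible) and step backtracking when a trial
  state is infeasible (e.g. a negative total of a strictly positive
  component). A sub-step is halved — up to 12 times — on non-convergence
  *or* when it would turn over more than 10% of any established component
  (accuracy control); the sub-step doubles back after success. After
  convergence the totals are advanced by exactly the trapezoidal increment
  that is reported as the time-averaged rate, so
  `Δtotal = Σ stoich · mean_rate · Δt / V_w` holds to machine precision.
* Convergence of the inner Newton is judged relative to the larger of the
  component's total and the step's mass turnover, so components crossing
  zero (alkalinity) are not held to an impossible relative standard.
* A kinetic reaction that produces a *secondary* species (the CO₂
  gas–aqueous exchange produces CO₂(aq)) increments the primary totals
  through the tableau (here: +1 HCO₃⁻ and +1 H⁺ per mole, i.e. no
  alkalinity change — the physically correct behavior).

Verified behavior (by the test suite): second-order error decay of the
reaction step on a smooth toy; agreement with a 10,000-substep explicit
reference on a stiff toy within 0.1%; agreement of a 2-year conservative
tracer with an independent explicit mixing-cell integration at 100
sub-steps/day within 0.5% everywhere; global tracer budget closure to
better than 0.1%; annual-mean stream concentrations changing <1% when the
step is halved.

## Synthetic forcing

The weather generator emulates a seasonally snow-influenced humid
continental headwater: mean annual precipitation 1,320 mm, mean annual
temperature ~5 °C with a 14 °C seasonal half-range and 3.5 °C daily
scatter, Bernoulli wet days (p = 0.45) with gamma-distributed intensities
(shape 0.65) modulated by a summer-weighted seasonal factor (amplitude
0.45), and a temperature-index PET. The seasonal intensity modulation is
what keeps the snow share of precipitation in the 20–30% band even though
~37% of days are below freezing. The paired bucket parameters were chosen
so annual flow partitions near 1/35/64% between surface, shallow and deep
pathways — the partitioning reported for the study catchment the examples
emulate — with a spring snowmelt discharge peak.

What the generator does *not* emulate: storm clustering and
autocorrelation, rain-on-snow extremes, inter-annual climate variability
beyond sampling noise, and observed precipitation chemistry (rain
concentrations are small constants). Passing tests on this forcing
demonstrate internal consistency and the qualitative mechanism — shifting
flow-path dominance across chemically contrasting zones — not predictive
skill on any real catchment.

## Example parameterization

The published parameter tables fix the kinetic constants (log10 k, SSA,
Q10, n, Swc, α·β, Keq, KM) and those are carried verbatim in the shipped
configs. Everything else — areal substrate densities behind the area
terms, zone pCO₂, initial totals, rain chemistry, porosities and passive
storages — is not published and was set by steady-state reasoning to give
realistic concentration scales and the documented shallow-vs-deep
contrasts, then frozen. Two findings from that exercise are worth keeping:

* Under the literal carbonate stoichiometry with a shared log Keq of
  −7.40, the equilibrium calcium level *falls* as bicarbonate rises. If
  the shallow-zone carbonate sat at equilibrium while deep DIC is enriched
  (by deep respiration), shallow calcium would always exceed deep calcium
  and calcium would flush rather than dilute. The examples therefore give
  the shallow (pedogenic) carbonate a small reactive area, keeping the
  shallow zone under-saturated and supply-limited while the deep zone
  approaches equilibrium — reproducing calcium dilution.
* In the moisture-response column of the nitrate table, the printed pairs
  are readable only as (Swc, n) — the critical saturation is 1 throughout
  and the exponent varies (0 disables the response in the deep zone) —
  since the other reading puts the critical saturation outside (0, 1].

## Known limitations

* No activity-coefficient model, no temperature dependence of equilibrium
  constants, no redox master variable, no in-stream processing or routing
  lag, no lateral spatial structure.
* Reaction surface areas are constant in time (appropriate for day-to-year
  horizons, not for weathering-front evolution).
* The zone water balance inherits HBV's structural choices (e.g. an
  uncapped linear baseflow store); the chemistry sees whatever the buckets
  do.
* The evapotranspiration convention (pure water removed) concentrates
  solutes; if real solute uptake by vegetation matters (it does for
  nitrate), it must be represented explicitly as a reaction, as the plant
  uptake example does.
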
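# Methods

## The model

`aeroplume` estimates the monthly, airport-level PM2.5 burden of civil
aviation's landing–take-off (LTO) activity in four multiplicative stages.

**1. Apportionment and fuel.** National monthly air-transport turnover
`T(y, m)` (ton-km) is split across airports by their turnover shares
`s_a = T_a / Σ T_a` (optionally by LTO counts instead, via
`share_basis="lto_count"`). Fuel burn is

    F_a(y, m) = T_a(y, m) · u(y, m)

with `u` the unit ton-kilometre consumption in kg fuel per ton-km. Because
the chain is linear, airport fuel sums exactly to national fuel — a
conservation property the tests enforce to 1e-9 relative.

**2. Emission mass and flow.** PM2.5 mass is `M_a = F_a · EI` with `EI` the
emission intensity in g PM2.5 per kg fuel. Full emission-index methods
(per-engine fuel-flow approaches with particulate corrections) are
deliberately abstracted behind a pluggable interface: any callable
`(airport, year, month) → g/kg` is accepted; `ConstantIntensity` (default
0.2772 g/kg, a published national fleet-average LTO intensity for a
predominantly narrow-body fleet) and `PerYearIntensity` are provided. The
monthly mass is averaged over the month's seconds (Gregorian day counts,
leap-year aware) to the emission flow

    E_a(y, m) = M_a / (days(y, m) · 86 400)   [g/s]

`E · seconds` recovers the mass to machine precision.

**3. Dispersion.** The 24-hour average concentration at receptor offset `y`
follows a fixed-coefficient Gaussian plume with image-source reflections:

    C = unit_scale · E / (2π μ δy δz) · exp(−y² / 2δy²) · P
    P = 2 exp(−h²/2δz²) + Σ_{n=1..N} exp(−(nl−h)²/2δz²)
                        + Σ_{n=1..N} exp(−(nl+h)²/2δz²)

Defaults: wind speed μ = 3.7 m/s, diffusion coefficients δy = 1.33,
δz = 1, effective source height h = 2 m, N = 2 reflection pairs,
mixing-layer lid l = 900 m for coastal airports and 1100 m inland
(per-airport overrides supported). The per-airport value averages C over
receptor offsets y ∈ {1, 2, 3} m. At the defaults P = 2·e⁻² ≈ 0.27067 —
the reflection exponents ((900 ∓ 2)²/2 and larger) underflow to zero, so
results are insensitive to N and to the coastal/inland distinction beyond
the sixth significant figure; the machinery matters only for configurations
with lids comparable to δz. The mean concentration per unit flow at the
defaults is C̄/E ≈ 3.3709 × 10⁻³.

Three conventions are configurable because the source formulation is
ambiguous:

- the reflection group is implemented as a *sum of exponentials* (the
  standard image-source form); `literal_exp_of_sum=True` evaluates the
  exp-of-a-sum grouping instead, for comparison;
- `N` defaults to the summation bound 2 (a stated reflection count of 3
  gives identical results at the defaults since the terms underflow);
- `unit_scale` defaults to 1.0, reporting the formula's literal value
  (E in g/s, lengths in m) under the conventional μg/m³ label; set 1e6 for
  a strict g/m³ → μg/m³ conversion. The formula has no downwind-distance
  coordinate and constant δ's, so its absolute scale should be read as an
  index tied to this parameterisation rather than a physically complete
  receptor concentration.

**4. Validation.** Monitoring stations within a radius (default 50 km) are
combined by inverse-distance weighting, `w_i ∝ d_i^(−p)` with p = 1 by
default (the simplest reading of "inverse distance"; configurable), and the
modeled value is scored by `|obs − mod| / obs`. The module ships the 16
printed station distances around Guangzhou Baiyun (CAN) used in the
June-2020 worked example (2.767 vs 2.603 μg/m³ → 5.9%); the source text
says "12 stations" but lists 16, and all 16 are kept.

## The synthetic generator

Real monthly turnover series of the kind this pipeline consumes are
published as administrative web tables that are not archived in
machine-readable form, so testing runs on generated scenarios:

    national(y, m) = base · (1+g)^(y−y0) · seasonal(m) · shock(y)
    turnover(a, y, m) = national(y, m) · share_a · noise

- **Seasonality.** Twelve mean-one multipliers, August maximum and February
  minimum. The default vector is built as month-length × a cosine *daily
  rate* (amplitude 0.0381, set from a reported August/February monthly
  emission ratio of ≈1.195 after removing the 31/28 day-count factor),
  then normalised. Placing the cosine on the daily rate is essential: a
  smooth multiplier on monthly totals cannot make the emission *flow*
  (mass ÷ month seconds) peak in August and trough in February, because
  January's 31 days would undercut February's 28 and September's 30 would
  overtake August's 31.
- **Trend and shock.** Compound annual growth (default 10 %/yr, typical of
  the network's pre-2020 expansion). An optional shock year multiplies the
  trend by (1 − depth), default depth 0.3165, with compound partial
  recovery (default 4.77 %/yr) capped at the trend — the magnitudes
  reported for the 2020 contraction and 2021 rebound.
- **Airports and shares.** Unique synthetic three-letter codes; coastal
  flags Bernoulli (default fraction 0.4); shares Dirichlet with
  concentration 0.5, so a few hub airports dominate as in the real network.
- **Noise.** Turnover noise is multiplicative log-normal (keeps
  positivity, default σ 0.05); station observations are
  `true + background + ε` with additive normal ε truncated at zero. The
  default background is 6 % of the signal, standing in for non-aviation
  sources near the airport at roughly the scale the worked example's 5.9%
  discrepancy suggests.
- **Determinism.** One scenario seed feeds independent named RNG streams
  for airports, shares, activity noise and stations, so each stage is
  bitwise reproducible in isolation.

What the generator does **not** emulate: fleet-mix composition (intensity
is a scalar), weekday/holiday structure within months, spatial correlation
between nearby airports, meteorological variability (the plume parameters
are fixed by design), and real station networks. Passing tests therefore
demonstrate the correctness of the computational chain and its invariants
on data with the assumed multiplicative structure — not agreement with any
real inventory.

## Numerical choices

- Reflection exponentials are evaluated directly; they underflow to exact
  zero for lids ≫ δz, which is benign (P ≥ the direct term > 0 for finite
  h/δz).
- Concentration tables are computed per row through the same scalar code
  path used everywhere else, so linearity-based recovery checks hold to
  1e-9 relative without vectorisation-order effects.
- Wide tables (Year, Airport, Jan…Dec — 14 columns) round-trip CSV values
  bit-exactly via shortest-round-trip float formatting; the xlsx dialect
  preserves 15 significant digits. Empty cells mean *missing*, never zero.
- Degenerate inputs fail loudly: all-zero months (nothing to apportion),
  non-positive intensities or distances, unknown airport codes (named in
  the error), malformed wide-table rows (reported with line numbers).

## Problem sizes

The default scenario is 20 airports × 3 years (720 airport-months), enough
to exercise every stage including the shock and recovery years; the
`full_network_config()` preset (175 airports, 2006–2023, 37 800
airport-months) is used for the round-trip fidelity check and the CLI
`--full-network` demonstrations.

## Known limitations

- The plume formulation has no downwind distance, constant diffusion
  coefficients and a single national wind speed; it is an exposure *index*
  faithful to its source parameterisation, not an AERMOD-class dispersion
  model.
- The emission intensity default is a single national constant; airport- or
  month-resolved fleets require a user-supplied intensity model.
- The IDW exponent, the 50 km radius, and the observed-denominator error
  definition are conventions exposed as parameters; other choices change
  the validation number.
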
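# Methods

## Scope and model structure

gcxgcsim simulates thermally modulated GC×GC as a chain of independent
modules on a directed graph. The separation physics is split into four
layers that only communicate through narrow interfaces: the pneumatic
network (pressures, flows, hold-up times), thermodynamic retention (k as a
function of temperature and phase ratio), band migration (two ODEs per
module), and the modulator slicing/release model. This mirrors how the
instrument is built and makes each layer independently testable against
closed forms.

Out of scope by design: estimation of retention parameters from
temperature-programmed measurements, mass-spectrometric detection, flow
modulation, valve/switching logic, and spatial thermal gradients (the
temperature-program type accepts a spatial hook, but no gradient models
ship).

## Pneumatics

Laminar, ideal-gas, quasi-steady Hagen–Poiseuille flow. Molar balance at a
junction is linear in squared absolute pressures; the solver assembles one
(small) linear system per requested time and raises a structural error
naming any vertex it cannot determine. Assumptions and conventions:

- Pressures are absolute Pa internally; config files accept kPa gauge
  (ambient 101.325 kPa) and the keyword `vacuum` (0 Pa absolute, the
  ToF-MS interface).
- Reported volumetric flows are normalized to 25 °C / 101.325 kPa
  (configurable). This convention, together with the viscosity model
  below, reproduces the instrument's calibrated flows; a 0 °C reference
  would be ~8% low.
- Film thickness is neglected in the flow cross-section (thin films,
  d_f/d ≈ 10⁻³).
- Quasi-steady: the network is re-solved on a time grid (default 0.5 s,
  plus all program breakpoints) and interpolated; pressure programs ramp
  linearly in time between their plateau calibration points.
- Thermal-modulator segments enter the flow solve at their base (oven)
  temperature: the 5 mm hot zone perturbs the total restriction by
  < 0.05 % and would otherwise make the flow field discontinuous.

Carrier-gas viscosity uses η(T) = η_ref (T/T_ref)^(ξ₀ + ξ₁ (T−T_ref)/T_ref)
with helium coefficients η_ref = 18.63 µPa·s at 273.15 K, ξ₀ = 0.6958,
ξ₁ = −0.0071 (hydrogen and nitrogen are bundled too). The coefficients
live in `data/carrier_gases.csv`, not in code, because the predicted
absolute flows are sensitive to them at the 1–2 % level; an override path
is accepted. The instrument fixture holds the transfer line at a fixed
250 °C — the usual ToF-MS transfer-line setpoint — because the solved
flows only match the instrument's calibrated values (0.72 / 0.78 mL/min at
the two plateaus) with the transfer line hot while the oven is at 50 °C; a
per-edge temperature override is the general mechanism.

## Retention

K-centric three-parameter model; k = 1 at T = T_char for φ = φ_ref, and k
scales proportionally with the local film-to-diameter ratio φ = d_f/d.
θ_char is a temperature *interval*, so its °C and K magnitudes coincide
(stored as such to avoid off-by-273 errors). Phase names are matched after
stripping case and punctuation ("ZB-1ms" ≡ "ZB1ms"). A solute without
parameters on a coated phase migrates unretained with a warning; an
explicitly uncoated segment (no phase, zero film) is silently unretained.

## Migration and broadening

Per module, with position as independent variable: dt/dx = (1+k)/u_M and
dτ²/dx = H r² + 2 τ² ∂r/∂t. Numerical choices:

- Solver: adaptive RK45, rtol 1e-8, atol 1e-10 on both states;
  tolerance-halving changes exit times by < 1e-4 relative (tested).
- ∂r/∂t by central finite difference with step 1 ms. The 2τ²∂r/∂t term is
  what produces peak compression under temperature programming; without it
  programmed peaks would broaden monotonically.
- Plate height: Golay for open tubular columns, with the
  Fuller–Schettler–Giddings binary diffusion estimate (generic
  hydrocarbon diffusion volumes derived from molar mass when no
  structure-specific value is given). Stationary-phase diffusion defaults
  to D_S = D_M/5·10⁴, a standard simulator default whose film term is
  negligible at φ ~ 10⁻³.
- Vacuum-terminated edges: p → 0 at the outlet boundary, where u diverges
  and the residency integrand vanishes; the pressure is floored at
  10⁻⁶ p_in, which perturbs nothing upstream of the last ~10⁻¹² of the
  edge.
- Injection is a delta at t = 0 (configurable initial bandwidth); bands
  still on column at the horizon (oven program duration including the
  final hold) are reported censored, never raised.

## Thermal modulator

Rectangular temperature function on the hot-jet grid: within each period
the cold phase comes first and the hot phase (350 ms by default) ends the
cycle; t_shift translates the whole grid; the exact cold/hot boundary
belongs to the hot phase (half-open windows). The cold-jet temperature
defaults to a −80 K offset; it barely matters because the model *assumes*
complete trapping.

Slicing integrates the arriving Gaussian over each collection window;
windows whose cumulative tail mass is below ε = 10⁻⁴ (symmetric) are
dropped, so retained fractions sum to ≥ 1 − ε. Hot-phase arrivals are kept
in their own cycle's slice: in the two-stage looped design that material
passes the point unfocused with the concurrent jet and is recovered
downstream, so assigning it to the already-started hot jet is the intended
approximation (its release time can precede the arrival by at most
t_hot = 350 ms).

Release: t_R = t_nexthot + L(1+k)/u_M, with k at oven + hot-jet offset and
u_M evaluated at the modulation-point midpoint at the release instant
(release treated as quasi-instantaneous, no window averaging); released
width τ = t_migration. Against a brute-force fixed-step ODE pass through
the 5 mm segment driven by the rectangular temperature function (kept as a
test oracle only), release *times* agree to ~10⁻⁵ relative under trapped
conditions. Release *widths* do not: the point-band variance ODE captures
compression but not the spatial extent of the trapped zone, whose
flush-out time is precisely the pulse width the simplified model uses, so
the two width estimates differ by roughly an order of magnitude. The
simplified width is the physically meaningful one for a two-stage
modulator; the discrepancy is a limitation of the point-band oracle, not
of the release model. Under weak trapping (cold-jet k ≲ a few hundred over
5 mm) the band breaks through during the cold phase and the trapping
assumption — hence the model — does not apply.

## Folding and 2D peak building

Elution cycles are counted on the hot-jet (reinjection) grid, so "released
in cycle n, eluting in cycle n" is equivalent to ²t_R < t_MP and the
wraparound flag is exactly ²t_R ≥ t_MP. The raw ²t_R keeps wraparound
(it is *not* taken modulo the period); a folded display value in
[0, t_MP) is carried alongside. First-dimension time of a slice is its
elution cycle count times t_MP; the per-solute ¹t_R/¹τ_R are the
height-weighted mean and standard deviation of those times, and ²t_R/²τ_R
are height-weighted means of the per-slice times and widths — the
projected ²t distribution itself is degenerately narrow, which is why the
width is the mean slice width. Slice heights are area/(τ√2π) evaluated at
the detector (final τ).

rmse/rmsre comparisons match solutes by CAS where both tables carry one,
by exact name otherwise; rmsre denominators are measured values, and pairs
with a measured zero are excluded with a warning.

## Diagnostics

- Actual modulation period: OLS slope of observed marker ²t versus cycle
  index, added to the set period; the slope's standard error is the
  reported uncertainty. OLS is the minimal estimator consistent with the
  linear drift mechanism; with 5 ms reporting noise over 1000 cycles the
  period uncertainty is a few tenths of a microsecond.
- Modulator shift: unweighted pooled mean of measured-minus-predicted
  ²t_R over analytes and runs, with the spread reported.
- Column length: scalar least squares of modeled versus observed hold-up
  times over the full path, varying one edge's length with nominal
  diameters held fixed — diameter errors are thereby absorbed into the
  effective length, which is the quantity the retention model actually
  needs (L/d).

## Synthetic fixtures

`make_reference_instrument` builds the looped two-stage modulator instrument
(29.74 m × 0.25 mm × 0.25 µm nonpolar first dimension; 0.1 mm polar second
dimension segmented 0.3/0.005/0.9/0.005/0.53 m in-oven plus a 0.24 m
transfer line; helium; vacuum outlet; inlet 160.30 kPa(g) at 50 °C ramping
to 274.96 kPa(g) at 225 °C) in eight program variants spanning heating
rates of 3/5/10 °C/min and modulation periods of 3/4/6 s.

`make_solutes` draws K-centric parameters from realistic ranges
(T_char 330–560 K, θ_char 20–45, ΔC_p 50–250 J/(mol·K), the polar-phase
T_char 5–35 K above the nonpolar one so second-dimension retention lands
in the sub-period range) and keeps only candidates that a forward
simulation elutes within the horizon of the most restrictive program
variant (the one with the shortest final hold), so the set elutes under
every program. Everything is seeded; identical seeds give byte-identical
tables.

`make_drifted_measurement` runs one nominal simulation and then distorts
only the *reported* times: a slice released in cycle n is shifted by
n·Δperiod + t_shift (grid drift accumulates per cycle), Gaussian reporting
noise is optional, and a bleed-marker drift series is emitted alongside.
This is deliberately an observation-model distortion, not a physics
re-simulation: it is exactly the mechanism the diagnostics invert, which
makes noise-free recovery exact and gives the correction pipeline a clean
no-correction → period-corrected → period+shift-corrected rmse
progression ending at machine precision. What it does *not* emulate:
detector noise, tailing, conditioning artifacts, retention-parameter
error, or any nonlinear coupling between the shift and the downstream
migration (sub-millisecond at these program rates). Passing tests on these
fixtures therefore validate the inversion machinery, not the absolute
accuracy of retention prediction against a real instrument.

## Problem sizes

The test suite and the acceptance script run desk-scale problems chosen as
representative: 40 elution-filtered solutes across all eight program
variants for the end-to-end run (~260 slices per program), 1000-cycle
drift series for period estimation, and 200 pairs for the noisy shift
recovery. The full eight-program sweep completes in about a minute on one
CPU.

## Known limitations

- Absolute flow predictions inherit the viscosity-model and
  reference-state conventions (~1–2 % each); both are configurable.
- The release-width model ignores within-pulse structure (no slice shape
  beyond Gaussian) and extra-column broadening.
- Breakthrough (weakly trapped solutes late in a hot run) is not modeled;
  such slices are still released on the grid as if trapped.
- Measured-data ingestion is limited to delimited peak tables and the
  half-height FWHM utility; no raw-chromatogram peak detection ships.
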
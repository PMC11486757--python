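# Methods

## Chemostat mass balances

The reactor model is a constant-volume continuous stirred tank: feed enters
at volumetric rate F_in (mass flows are converted with a feed density of
1 g/mL), broth leaves through a bleed tube at fixed height at
F_out = F_in − E, where E is an evaporation rate that removes water but no
solutes. Between two sampling points t_{n−1}, t_n each extensive quantity
obeys: change in reactor + discharged − supplied = net formed by the cells.
Dividing by the mean biomass inventory x̄·V and Δt gives the specific rates
implemented in `physiology`:

* μ = [(x_end − x_start)·V + x̄·ΔV_bleed] / (x̄·V·Δt). At steady state with
  the bleed as the only outflow this returns the bleed dilution rate
  exactly — the identity that calibrates chemostat experiments.
* q_S = [s_in·V_in − s̄·V_out − Δs·V] / (x̄·V·Δt), uptake-positive. A
  widely circulated alternative writes the numerator with the accumulation
  term added rather than subtracted; that form double-counts accumulating
  substrate. The mass-balance-consistent form is the default and the
  alternative is available as `verbatim_eq2=True` for auditing published
  numbers.
* q_P mirrors q_S with the signs of formation: accumulation + discharge −
  feed supply, production-positive. Feed and discharge terms are volumed
  (concentration × volume), which the dimensional analysis requires.
* The specific CO₂ evolution rate integrates
  gas_flow·(y_CO₂ − y_inlet)/V_m over the window (trapezoid across
  samples). Off-gas conversion uses a configurable molar volume, default
  24.0 L/mol (≈ 1 atm at ambient analyzer temperature), and an inlet CO₂
  baseline of 0.04 %. These are configuration values because the gas
  analyzer's internal normalization is instrument-specific.

Window endpoint means (arithmetic) are used for x̄, s̄, p̄. Windows with
Δt ≤ 0 are rejected, not skipped: silent skipping hides sampling-table
errors.

### Carbon accounting

All yields are Cmol/Cmol. Species convert via carbon_atoms/molar_mass from
the registry; biomass uses a configurable Cmol mass, default 24.6 g/Cmol
(generic CH₁.₈O₀.₅N₀.₂ — the organism-specific elemental composition is
rarely measured, and the default is stated in all reports). The carbon
balance is defined as the exact sum Y_x/s + Y_CO₂/s + Y_Tre/s + Y_AA/s;
when no off-gas data exist the CO₂ term is unavailable and the panel is
flagged partial rather than silently low.

## Synthetic chemostat scenarios

`simulate_chemostat` integrates dx/dt = (μ − D_out)·x and, per species,
dc/dt = D_in·c_feed − D_out·c − q·x with fixed true rates (q signed,
consumed-positive), using RK4 at 0.01 h steps — windows span hours, so the
discretization error is far below measurement noise, and a run initialized
at the steady state stays there to machine precision (the RK4 increments
vanish identically). Measurement noise is multiplicative Gaussian per
channel (DCW, concentrations, off-gas), default CV 1–2 % in the presets,
matching routine gravimetric/HPLC repeatability.

The truth ledger allocates each consumed Cmol exactly:
consumed = biomass + products + CO₂ + sink. The *unmeasured sink* fraction
f routes carbon to channels outside the measured set — emulating storage
compounds or undetected metabolites — so the measured balance closes at
1 − f by construction; a scenario whose allocation would need negative CO₂
is rejected at construction.

The shipped presets encode the three study conditions through their feed
settings (total/substrate/water flows 90 = 22.5 + 67.5, 120 = 40 + 80,
120 = 60 + 60 g/h; 76 g/L MSG + 36 g/L glucose stock feed; 2 L working
volume; 0.25 vvm aeration = 30 L/h). The uptake rates q_MSG, q_Glc are not
published; they are derived here from the steady-state balance
q = (F_in·c_feed − F_out·c_residual)/(x·V) at the reported cell densities
(5.0, 16.2, 18.5 g/L) and growth rates (0.031, 0.037, 0.054 h⁻¹), with
small assumed residual concentrations. The evaporation rate per preset is
set to reconcile the feed-based dilution rate with the reported growth
rate (its true value at 75 °C is unknown, so it is an explicit scenario
parameter rather than an assertion). The overfeed preset's q values leave
0.18 and 0.0048 g/L/h of MSG and glucose accumulating at the initial broth
state — the reported accumulation rates — and its sink fractions (0.20
high, 0.21 overfeed, 0 low) reproduce the reported carbon-balance closure
(0.80, 0.79, ≈1). Passing tests on these scenarios demonstrate correct
bookkeeping under the modeled measurement process; they do not validate
kinetics the simulator does not contain (no Monod saturation, no lag, no
biomass-composition shifts).

## FBA and parsimonious FBA

Both stages are LPs over the stoichiometric matrix (declaration-ordered,
so runs are bit-stable per solver build), solved with scipy's HiGHS
interface. FBA maximizes the objective flux under S·v = 0 and bounds.
pFBA splits v = v⁺ − v⁻ (v± ≥ 0), pins the objective flux at
optimum_fraction·opt with an equality row, and minimizes Σ(v⁺ + v⁻). The
equality (rather than "≥ opt − ε") matters: under an inequality the L1
minimization always buys flux by sliding to the bottom of the ε band,
which shifts every flux by O(ε·scale) and breaks agreement with
independent implementations; ε = 10⁻⁶ (relative) remains as the
verification tolerance. Residual L1 degeneracy (several flux vectors with
the same minimal Σ|v|) is not broken further; the ensemble averaging makes
it immaterial in practice.

Measured exchanges are applied as lb = ub = rate (negative = uptake;
a `positive_uptake` convention flag flips incoming signs). Non-detected
secretion products are clamped to zero. The maintenance reaction's lower
bound defaults to 1.9 mmol gDW⁻¹ h⁻¹. Whether published workflows fixed
exchanges two-sidedly or one-sidedly is generally ambiguous; full fixing is
the default and independent lb/ub sampling is available behind
`SamplingSpec(independent_bounds=True)`.

For networks of ≤ 12 reactions, `exact.enumerate_vertices` enumerates the
flux polytope's vertices directly (pin n − rank(S) fluxes at finite bounds,
solve the steady-state system for the rest, keep consistent feasible
points). The LP optimum of a bounded feasible LP lies at a vertex, so the
enumerated maximum is an exact, solver-independent oracle; a randomized
secondary-objective search over the optimal face supplies alternative
optima against which pFBA's Σ|v| minimality is checked.

## Uncertainty propagation

Each non-fixed exchange is drawn independently and uniformly from
[rate − 2·SD, rate + 2·SD] — the uniform is the minimal assumption for a
stated interval, and the choice is recorded in the result metadata — with
n = 1000 draws by default (tests use smaller n with widened tolerances).
Infeasible draws are dropped and counted, never imputed: averaging over the
feasible set is the most conservative reading of "averaged". All draws
derive from one seeded generator; identical inputs give bit-identical
ensembles.

## Flux normalization

Pathway blocks are reported relative to a reference scalar: a named
reaction's |flux| (glucose uptake; G3P formation), the maximal |flux| among
the members (TCA cycle — the maximal member is exactly 1 by construction),
or a sum of |flux| over routes (glutamate incorporation = deamination +
transamination). Normalized values are magnitudes with direction kept in a
separate column; reactions whose direction differs between compared
conditions are flagged instead of averaged, since a signed ratio would be
meaningless. Scheme membership is configuration, not code: reaction ids
differ between models, so defaults target the toy networks and users map
their own model ids via YAML.

## DEG screening

Benjamini-Hochberg adjustment is delegated to statsmodels
(`multipletests(method="fdr_bh")`); the test suite checks it against a
direct evaluation of the step-up definition padj_(i) = min_{j≥i} p_(j)·m/j.
Calls use strict padj < 0.05 and inclusive |log₂FC| ≥ 1, matching the
convention that "at least doubled" includes exact doubling. Note that BH is
not idempotent in general (re-adjusting adjusted values can inflate them),
so adjusted columns in input tables are used as-is and never re-adjusted.
Reproducing published DEG count tables requires the original sequencing
reads and upstream model fits, which are outside this package's scope; the
screen is validated on planted-truth synthetic tables instead.

## Numerical choices and limitations

* LP tolerances: steady-state residual ‖S·v‖∞ ≤ 10⁻⁶ and bound violations
  ≤ 10⁻⁶ are asserted on optimal solutions.
* Vertex enumeration is exponential and deliberately refuses networks with
  more than 12 reactions.
* The simulator holds q and μ constant within a scenario; transitions
  between conditions must be modeled as separate scenarios.
* Concentrations are floored at zero during integration and observation;
  scenarios that would drive a species strongly negative should instead
  lower the corresponding uptake rate.
* Problem sizes in the test and acceptance runs (toy networks ≤ 8
  reactions, 1,000-draw ensembles, 5 replicate simulations, 2,000-gene
  tables) were chosen so the exact oracles remain tractable while every
  code path is exercised.
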
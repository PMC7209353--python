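# Methods

## Model

`cafswitch` couples two five-state mass-action ODE agents. Every bilinear
term k·A·B is a law-of-mass-action rate; the linear terms are first-order
expression or degradation. Two structural choices deserve note:

- The SMAD7 inhibition terms (k₄₂X₄ in the cancer cell, h₄₂Z₄ in the
  fibroblast) are *linear* in SMAD7, not bilinear in SMAD·SMAD7. They are
  implemented exactly as the model defines them, even though one might
  expect an inhibitory interaction to be a product term.
- The fibroblast's SLIT2 output U₁ enters the cancer cell as a subtraction
  in the TGFβ balance (Ẋ₃ = U₂ − U₁ + …). This is the model's rendering of
  SLIT2's tumor-suppressive action; it is kept as written rather than
  reinterpreted, and it means TGFβ can be driven negative when SLIT2
  strongly dominates CXCL12 (see "Negative concentrations" below).

Signals are identities on states (V₁ = X₁, V₂ = X₃, U₁ = Z₁, U₂ = Z₂):
secretion and transport are not modeled. There is no receptor/ligand
binding submodel, no spatial diffusion, and no stochastic kinetics.

## Parameters

The ten cancer rate constants and the six fixed fibroblast rates ship as
packaged defaults (`cafswitch/data/default_parameters.json`), all in
hour⁻¹; time is in hours everywhere.

The coupling coefficients (m₀, m₁, m₂, m₃) of h₁₁, h₃₂ and h₁₂ have no
published values. The packaged defaults are a **reconstruction**: their
sign structure was fixed first (h₁₁ and h₁₂ decrease with LIF and TGFβ,
h₃₂ increases), then the single free scale that matters most — the CXCL12
baseline expression rate h₃₂·m₀ — was calibrated once against the
qualitative switching signature (SLIT2 rises then falls inside 72 h;
CXCL12 and SNAIL end above their starting values; LIF and TGFβ rise before
the SLIT2 peak) and frozen at:

| rate | m₀    | m₁    | m₂    | m₃   |
|------|-------|-------|-------|------|
| h₁₁  | 0.053 | −0.01 | −0.05 | −0.1 |
| h₃₂  | 0.05  | 0.5   | 0.5   | 0.0  |
| h₁₂  | 0.05  | −0.5  | −0.5  | −1.0 |

The calibration is sharp because the CXCL12→TGFβ→SMAD→CXCL12 loop is
structurally explosive: CXCL12 feeds the cancer cell's TGFβ balance with
unit gain against a 0.122 h⁻¹ degradation, so once SMAD autoinduction
(k₃₂X₂ → k₃) closes the loop the system grows super-exponentially. With
h₃₂·m₀ ≥ 0.06 the blow-up lands inside the 72 h window; at 0.05 the switch
completes (SLIT2 peak at 52.6 h) with all concentrations bounded by ~2.4
a.u. These defaults cannot claim fidelity to any fitted values; treat them
as one representative parameterisation of the switching regime.

### Non-negative-rate policy

The coupling polynomial can go negative for large inputs. A negative
expression rate is not physically meaningful, so h₁₁, h₃₂ and h₁₂ are
floored at zero by default (`FibroblastParameters.floor_rates`); the
unfloored polynomial is available for analysis (and is used by the
bilinearity tests, since the floor destroys bilinearity at the kink).

### Negative concentrations

Because of the U₂ − U₁ subtraction, TGFβ can go negative. The equations
are integrated as written — no clamping by default — and the trajectory
records a negativity event per species (first grid time below −10⁻⁹,
i.e. below solver-roundoff scale). An optional clamp-at-zero mode exists
for exploratory runs; all packaged results use the unclamped equations
(the default scenario never goes negative).

## Simulation

The default scenario seeds every species at 0.01 a.u. — the model only
says the initial LIF and TGFβ are "relatively low", and a strictly zero
state is absorbing for the autocatalytic coordinates — and runs 0–72 h on
a 0.1 h output grid, the span of a long stimulation time course.

Continuous coupling (default) solves the joint 10-dimensional ODE with a
stiff-capable adaptive solver (LSODA, rtol 10⁻⁸, atol 10⁻¹⁰). A classic
fixed-step RK4 integrator is provided both as an oracle for tests
(adaptive vs RK4-at-10⁻³ h agree to ≤10⁻⁶ relative over 10 h, and RK4
shows clean 4th-order step-halving convergence on a smooth
parameterisation) and as a deterministic fallback. Discrete-exchange
coupling honors the agent-based framing: each agent integrates its own
5-dimensional ODE over an exchange window Δt with the partner's signals
frozen at window-start values; it converges (first order in Δt) to the
continuous solution. Simulation is fully deterministic.

Switch detection takes the SLIT2 grid argmax (earliest on ties; reported
only when strictly interior and strictly above both endpoints),
endpoint comparisons for CXCL12/SNAIL growth, and linear interpolation
between bracketing grid points for the CXCL12-over-SLIT2 crossing time.

## Synthetic data

The generator emulates the *statistical shape* of microarray time-course
data in model units: a sparse estimation set (4 genes — fibroblast SMAD,
SMAD7, SLIT2, CXCL12 — at 2, 4, 8, 12 h) and a denser validation series
(LIF, SLIT2, CXCL12, SNAIL at 0.5–72 h, 8 points, a typical
TGFβ-stimulation design). The observed-gene-to-coordinate map defaults to
the fibroblast agent (SLIT2 and CXCL12 exist only there) and is
configurable. Default noise is multiplicative-lognormal with σ = 0.1 and a
mean-one factor exp(σZ − σ²/2), reflecting expression-array noise
character; additive Gaussian noise is available for filter studies. Every
generator is a pure function of (scenario, seed).

What passing tests on these fixtures do **not** show: robustness to
microarray normalization artifacts, probe-level effects, batch structure,
or the unknown affine map between log-expression and model concentration
units. An affine pre-transform hook exists for external data, but no
normalization pipeline is emulated.

## Hybrid unscented Kalman filter

Parameters are estimated by state augmentation: the augmented state
(x, θ) has derivative (f(x, θ), 0). Between measurements each scaled
sigma point (α = 0.1, β = 2, κ = 0 by default) is propagated through the
augmented ODE — RK4 at 0.02 h by default, or adaptively with LSODA —
which is the "hybrid" (continuous-discrete) part; measurements then apply
the standard unscented correction. On linear-Gaussian problems the full
pass reproduces an exact discrete Kalman filter (means to 10⁻⁸,
covariances to 10⁻⁶ in tests).

Noise defaults (no published settings exist; all configurable):
Q = 10⁻⁶·I on states and 10⁻⁸·I on parameter coordinates; P₀ = diag(1
states, 0.25 parameters); R = (0.05 × per-species value range)² unless
given. Covariance health is maintained by symmetrization after every step
and, on Cholesky failure, escalating symmetric jitter (10⁻¹⁰·I up to
10⁻⁶·I) before erroring with a hint to regularise; a numerically singular
innovation covariance raises an error suggesting a larger R.

A single forward pass is the default. The optional iterated mode re-runs
the filter with the previous pass's final parameter means as the new prior
centre (at most 5 passes, stopping when no parameter moves by more than
10⁻³ relative). The reported **total estimation error** is the
normalized RMSE between the filtered estimates of the observed coordinates
and the observations, averaged over observed genes — a reconstruction of
the usual scalar filter-fit summary, since no exact definition is
published. The filter itself is deterministic; only synthetic data is
stochastic.

Problem sizes used by the shipped experiments: the recovery study uses 50
observation times over 1–72 h, additive noise at 1% of each species'
range, 10 replicates, estimating (h₁, h₄) from priors offset by +50%/−40%
(median relative error ≈ 5%); the sparse study is the 4×4 fixture with a
single estimated rate. These sizes are the package's default experimental
design and are what `scripts/acceptance.py` re-runs.

## Validation metric

The validation statistic is √(1/n · Σ (xᵢ − θᵢ)²) — plain RMSE, kept
under its conventional field name "normalized RMSE" for continuity; no
range or mean normalization is applied by default because the statistic
is defined exactly this way. An optional range-normalized variant
(divide by data max−min) can be switched on in `compare`. Simulation
values are linearly interpolated onto observation times.

## Known limitations

- Single cancer cell and single fibroblast: no populations, no spatial
  structure, no cell division or death, no therapy perturbations.
- The m-coefficients are reconstructed, not fitted; quantitative outputs
  (fold changes, peak time) are specific to this parameterisation.
- The model is structurally explosive beyond the switching window; do not
  extrapolate far past 72 h with the default parameters.
- The filter estimates parameters conditional on a known observation map
  and known inputs; identifiability of large parameter subsets from the
  sparse 4×4 design is limited (the sparse experiment estimates one rate).
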
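# Methods

## Model

`arbisim` simulates the ecological and evolutionary dynamics of temperate
bacteriophages that communicate through a secreted signalling peptide
("arbitrium") to inform the lysis–lysogeny decision. A well-mixed volume
contains susceptible bacteria S, lysogens L_i and free phages P_i (one
class per phage variant i), and the arbitrium concentration A:

    dS/dt   = r S (1 − N/K) − b a S Σ_i P_i
    dL_i/dt = r L_i (1 − N/K) + φ_i(A) b a S P_i − α L_i
    dP_i/dt = B α L_i + B (1 − φ_i(A)) b a S P_i − δ P_i − a N P_i
    dA/dt   = c b a S Σ_i P_i − u N A

with N = S + Σ L_i. Bacteria grow logistically (rate r, carrying capacity
K); adsorption (rate a) to a susceptible cell infects with probability b;
an infection immediately either lyses the cell, releasing a burst of B
phages, or lysogenises it. Lysogens are immune to superinfection (the
adsorbed phage is lost), grow like susceptibles, and are induced at a low
rate α, lysing with the same burst. Every infection releases a fixed
arbitrium increment c; cells take the peptide up (rate u) and degrade it.
Lysis is modelled as instantaneous (the lytic cycle is fast compared with
bacterial growth) and there is no intracellular signalling mechanism —
the decision depends only on the current extracellular concentration.

The lysis–lysogeny response is a step function: variant i lysogenises
with propensity φ_max,i once A reaches its response threshold θ_i and is
fully lytic below. θ_i = 0 recovers a constant, signal-blind propensity
(a bet-hedging strategy), so the no-communication scenario is the θ = 0
slice of the communication scenario.

## Nondimensionalisation

With s = S/K, l = L/K, p = bP/K, Â = A/(cK) and τ = r t the system closes
over five dimensionless parameters (defaults in brackets, motivated by
literature values for well-studied phages):

| parameter | meaning | default |
|---|---|---|
| B̂ = bB   | effective burst size per adsorption to a susceptible | 2 |
| â = aK/r | scaled adsorption rate | 10 |
| δ̂ = δ/r | scaled free-phage decay | 0.01 |
| α̂ = α/r | scaled induction rate | 1e−3 |
| û = uK/r | scaled arbitrium uptake | 0.1 |

Thresholds θ are expressed in units of cK — the concentration reached
when one carrying capacity's worth of cells has been infected — so Â runs
from 0 to ≈ 1 during an epidemic and θ is directly comparable with the
fraction of the susceptible pool already infected. With r = 1 h⁻¹, scaled
time is hours.

## Serial passaging

Evolution of the decision requires recurring epidemics, so the system is
driven by serial passaging: each episode starts with susceptibles at
carrying capacity (s = k) plus a small phage inoculum, runs for T hours,
and then a fraction D (default 0.01) of the free phages is transferred to
a fresh susceptible population (`phage_only`; `full_sample` transfers
diluted cells, lysogens and arbitrium as well, with fresh susceptibles
added on top — a config switch instead caps total bacteria at k). The
episode-1 inoculum is Σp = 1e−5·B̂ (the scaled image of 10⁻⁵ K B phages
per mL), split uniformly over the variant grid; the paper-gap choice of a
uniform initial distribution is configurable. Episode-to-episode
environmental noise draws each episode's carrying capacity from a gamma
distribution with mean 1 and a chosen coefficient of variation (shape
1/CV², scale CV²); CV = 0 short-circuits to exactly 1.

Mutation couples neighbouring variants on the trait lattice: a fraction
μ (default 0.01 per trait axis, applied to every burst term) of each
variant's replication output moves to its nearest neighbours, split
equally where two exist; at a lattice boundary the outward half-flux
stays with the source, so the operator conserves phage number exactly.
The two axes act as sequential linear operators. The kernel details are
a design choice of this package; the steady-state peak position is
insensitive to μ over at least [0.002, 0.02] (the mutation-selection
cloud widens, its centre stays put).

A run is at an evolutionarily steady state once the L1 distance between
consecutive end-of-episode phage-frequency vectors stays below 1e−6 for
10 consecutive episodes (cap 2000 episodes; both knobs configurable).
Noisy-environment runs never meet this criterion and instead run a fixed
number of episodes (1000 by default) and report the distribution averaged
over the trailing 100 episodes. Reported frequencies are the free-phage
pool; lysogen-pool frequencies are recorded too and coincide with the
phage pool at long T (L1 ≈ 4e−3 at the T = 12 h steady state). A
population whose end-of-episode total phage density falls below
max(1e−30, 1e−11·n_variants) is reported extinct rather than raising —
the lower bound reflects the solver's absolute tolerance, below which
per-variant densities are numerical noise.

## Numerical integration

Episodes are integrated with an adaptive embedded Dormand–Prince 5(4)
pair (the scipy RK45 / classic ode45 tableau) compiled with numba,
rtol = 1e−8 and atol = 1e−12. The compiled stepper exists because a
steady-state run composes hundreds to thousands of episodes of a state
with up to ~900 components; per-episode Python callback overhead would
dominate otherwise. Agreement with scipy's integrators is part of the
test suite (endpoint agreement with DOP853 at rtol 1e−11 to ~1e−8 on a
two-variant competition episode, and to 8 significant digits on a
50-episode composed map).

Two numerical details matter:

* The step response makes the RHS discontinuous where A crosses a
  threshold. Error control alone cannot cross such a point when a
  lysogen component sits at exactly zero (its error scale is atol), so
  steps at the time-relative floor 3e−14·max(t, 1) are force-accepted;
  the crossing error this admits is O(h·Δf) ≈ 1e−11.
* Small negative excursions are clipped to zero after each accepted
  step if smaller in magnitude than 10·(atol + rtol·max|y|) — the local
  error scale; larger negatives raise. A fixed multiple of atol alone
  would misfire for parameter sets whose phage densities reach ~10³.

Equilibrium finding, epidemic-collapse timing and the rare-invader
integrals use scipy (`root` with multi-start + numerically differentiated
Jacobians; cubic Hermite interpolants built on the stored solver steps;
piecewise integration of the linearised invader between the background's
threshold crossings).

## ESS machinery

Closed forms (long-T limits): the bet-hedging ESS propensity
φ\* = (1 − (bB)⁻¹) / log(BK/P₀) with P₀ the episode-start phage density,
and the communication threshold θ\* = cK / (2 − (bB)⁻¹), which decreases
from cK at bB = 1 to cK/2 for highly infective phages. The raw φ\*
expression is negative for bB < 1 and diverges as P₀ → BK; the returned
value is clamped to [0, 1] (a `clamp=False` escape hatch exposes the raw
number). P₀ is taken by default as the *measured* post-dilution
episode-start density at steady passaging — under that convention the
prediction tracks the simulated sweeps with rank correlation > 0.99 and
mean absolute error ~0.003; the fixed episode-1 inoculum is available as
an alternative mode.

The numerical ESS is the fixed point of resident → optimal invader:
the monomorphic resident is simulated from its steady-passaging start
density to the epidemic's end T_E (first time s < 10⁻³·k; if a
communication resident halts the epidemic before s collapses, the end is
taken as the decay of the free-phage bloom below 10⁻³ of its peak); the
optimal invader maximises lysogens produced per invading phage on the
frozen resident background up to T_E (coarse grid then bounded local
refinement); damped iteration (weight 0.5) with a bisection fallback
solves trait = response(trait) to residual < 10⁻³. The linearised yield
is validated against a full two-variant simulation with the invader at
relative frequency 10⁻⁸ (0.1% agreement).

At the defaults the φ fixed point lands on 0.0387 and the passaging
simulation selects the φ = 0.04 grid point; the θ fixed point gives
0.6213 and the θ-grid simulation (step 0.02) selects 0.62 — i.e. the
invasion analysis and the evolutionary simulation agree with each other,
and both sit below θ\* = 2/3 at this low burst size because arbitrium
uptake depresses late-epidemic concentrations. At B̂ = 100 the fixed
point reproduces θ\* to 3e−4.

## Design choices and limitations

* Step-function response with the closed boundary φ = φ_max at A = θ,
  so θ = 0 reproduces the constant-propensity case at A = 0.
* Dominant-variant ties break towards lower φ_max, then lower θ.
* Competition experiments disable mutation (two fixed strategies).
* One seeded RNG; CV scans spawn one child stream per scan value, so
  results are independent of scan order and episode caps.
* The synthetic regime is fully specified by the model itself (no
  external data): what the simulations show is the behaviour of this
  idealised well-mixed, instantaneous-lysis model. Spatial structure,
  latent periods, gradual (non-step) arbitrium responses, intracellular
  signal processing and arbitrium production by lysogens are outside it,
  and results should be read accordingly.
* Selected strategies on coarse trait grids sit in very flat fitness
  landscapes: at default parameters the threshold's invasion landscape
  is nearly neutral between 0.60 and 0.65 cK, and one-grid-step shifts
  in the reported dominant variant can follow from sub-percent changes
  in the late-epidemic arbitrium dynamics.
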
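# Methods

## The model class

`aucsens` analyses ODE models of signaling pathways and regulatory
networks,

```
dX/dt = F(X, P, u),    X(0) = X0,
```

with state vector `X` (concentrations or molecule counts), kinetic
parameter vector `P`, and an optional excitation `u(t)` (stimulation
input, modeled as a piecewise-constant time function; constant by
default).  One state is designated the *output* `x(t)` — the molecule
whose level defines the response of interest (a tumor-suppressor protein,
a target transcript, ...).  Each kinetic parameter maps to a single
biochemical process and therefore to a potential molecular drug target;
parameters that are not rates of targetable processes (Michaelis–Menten
coefficients, saturation constants) are declared `non_ranked_params` and
excluded from the analysis.

The time-domain response summary throughout is the area under the curve
(AUC) of the output over a fixed horizon `[0, T]`, approximated by the
composite trapezoid rule on a fixed output grid.  AUC is preferred over
steady-state or frequency summaries because drug-relevant effects are
often transient, and it applies equally to oscillatory and aperiodic
responses.

## The randomized OAT sensitivity index

Drug action on the process governed by parameter `p_j` is modeled as a
multiplicative alteration `p_j -> alpha * p_j,nom`, one parameter at a
time (OAT), all other parameters nominal.  For one altered simulation the
signed index is

```
S_j = ∫₀ᵀ Δx(t) dt / ∫₀ᵀ x_nom(t) dt,
Δx(t) = x(alpha·p_j, t) − x_nom(t).
```

The numerator integral is deliberately **signed** (neither `|Δx|` nor
`Δx²`): for parameters worth ranking, `Δx` keeps one sign over the
horizon, and the sign carries the drug-relevant information.  With a
non-negative output, `S = −1` means complete suppression (the output is
identically zero), `S = 0` no effect, and positive `S` — unbounded
above — amplification.

Cell-to-cell heterogeneity of drug effect is modeled by drawing an
independent alteration factor per simulated cell.  For each ranked
parameter, `n` factors are drawn, `n` altered simulations are run, and
the ranking score is the population mean

```
A_j = mean(S_j over the n draws).
```

For log-scale presentation the *display value* `A + 1` is used; the
threshold line at `10^0 = 1` separates amplifying (above) from
suppressing (below) parameters, and `0` is complete suppression (clipped
to the axis floor when plotted).

### The alteration distribution

The default reduction law is log-normal with natural-log location
`mu = −2.08` and scale `sigma = 0.61`.  Its mean is
`exp(mu + sigma²/2) ≈ 0.15` — an average 85% parameter reduction — with a
right tail of factors near (or above) 1 representing partially or fully
resistant cells; a uniform law could not express such resistance.  The
parameterisation is by log-location/scale, *not* by the mean — a classic
source of confusion, hence `AlterationDistribution.mean()` for the
closed-form check.  A degenerate law (`alpha` fixed; `alpha = 1` is the
identity probe, `alpha = 0` the knockout probe) and arbitrary custom
samplers are supported.  Amplification studies (`alpha >> 1`) use the
same machinery with a user-supplied law; no amplification default is
shipped because a biologically sensible range is case-specific (what
counts as a feasible rate increase differs per process).

### Algorithm and determinism

1. Simulate once at nominal parameters; this trajectory and its AUC are
   shared by all comparisons.
2. Per ranked parameter: draw `n` factors from a dedicated RNG substream,
   run `n` OAT simulations, compute `S` per draw, average to `A`.
3. Assemble the ranking, sorted by `|A|` descending (ties broken by
   parameter name), so strong suppressors and strong amplifiers both rank
   high; `Ranking.sort_signed()` gives the signed ordering.

Per-parameter substreams are spawned from a single `SeedSequence` in
parameter declaration order, so results are bit-identical for a fixed
seed regardless of execution order (parallel execution would not change
them).  Default `n = 1000` per parameter, matching the ensemble size used
for population plots; it is configurable and the Monte-Carlo error of `A`
scales as `sd(S)/sqrt(n)`.

### Degenerate and failed cases

* A parameter with nominal value 0 cannot be altered multiplicatively; it
  is reported in `Ranking.unrankable`, never silently dropped.
* A simulation that fails to integrate (extreme factors can stiffen the
  system) is dropped and counted in `failed_runs`; a parameter with more
  than 10% failures is flagged.  If *all* draws fail the parameter is
  reported unrankable.
* An output whose nominal AUC is at the numerical floor (≤ 1e−12) makes
  `S` undefined; the analysis raises rather than returning nonsense.
* The classification neutral band is `|A| ≤ 0.01` by default: at the
  method's Monte-Carlo resolution, smaller mean effects are treated as
  no-effect rather than assigned a direction.

## Classical baseline

The comparison baseline ranks parameters by the area under the local
sensitivity function `s_j(t) = ∂x/∂p_j` along the nominal trajectory,
estimated by central finite differences with relative step `h = 1e−3`
(second-order accurate; forward sensitivity ODEs would be the exact
alternative at the cost of model-specific Jacobians).  The index is
semi-relative,

```
R_cl,j = p_j,nom · ∫₀ᵀ |s_j(t)| dt,
```

scaled by the nominal value so indices are comparable across parameters
of different units; a fully relative normalisation (dividing by
`x_nom(t)`) is undefined wherever the output is near zero and is offered
only as an option on `sensitivity_function`.  The absolute value inside
the integral follows the usual convention for this family of rankings —
and is exactly why the baseline cannot distinguish suppressing from
amplifying parameters, the gap the randomized index closes.  The two
rankings are not expected to agree on nonlinear feedback models, and no
test asserts agreement.

## Numerical choices

* Solver: `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  automatic switching) by default; `stiff_solver=False` selects RK45.
  Tolerances default to `rtol = 1e−6`, `atol = 1e−9`.
* Output grid: 1000 evenly spaced points on `[0, T]` by default, shared
  between nominal and altered runs so `Δx` is pointwise.  At this grid
  density the trapezoid AUC of smooth outputs is accurate to better than
  1e−4 relative (verified against closed forms).
* Oracle checks that assert per-draw identities (`S = alpha − 1` on the
  linear model) use tightened tolerances (`rtol = 1e−10`), since the
  identity holds to solver accuracy.

## Demonstration models

* `linear_chain`: `dx/dt = k − d·x`, `x(0) = 0` — the closed-form oracle.
  The solution is linear in `k`, so `S(k; alpha) = alpha − 1` exactly and
  `A(k) = E[alpha] − 1 ≈ −0.85` under the default reduction law.
* `negative_feedback`: a three-state Goodwin-type loop — output protein →
  inhibitor mRNA (cooperative Hill transcription, n = 4) → inhibitor
  protein, which removes the output bilinearly.  It emulates the
  p53/Mdm2-style topology: pulsatile output (≥ 2 maxima over the default
  horizon T = 100) and `S > 0` when either inhibitor-production parameter
  (transcription or translation) is reduced to 15%.
* `cascade`: receptor activation (driven by a constant stimulation
  input) → transcription-factor phosphorylation → output transcript with
  first-order decay.  It emulates a cytokine-activated JAK/STAT-style
  cascade: aperiodic response, `S < 0` for reduced phosphorylation,
  `S > 0` for reduced transcript degradation.

The two pathway surrogates are **illustrative**: they reproduce loop
topology and qualitative dynamics, not the published kinetic models of
those pathways (whose equations and fitted rate constants live in the
original modeling literature).  Their defaults were frozen after a
calibration run (`scripts/calibrate_surrogates.py`, re-runnable) that
verifies the qualitative assertions above.  Consequently, passing tests
on the surrogates demonstrate that the *machinery* behaves correctly on
oscillatory and aperiodic nonlinear models — they say nothing
quantitative about the real pathways.  The shipped parameter inventories
of the two case studies (35 ranked + 3 excluded constants for the p53
model; 48 ranked + 2 excluded saturation constants for the JAK/STAT
model) are bookkeeping fixtures for name/exclusion handling at realistic
parameter counts.

## Problem sizes used in the shipped checks

The bundled test suite and the reproduction script run on the toy models
with `n` between 100 and 5000 draws per parameter and output grids of
101–1001 points — sizes chosen because the closed-form oracles make
larger runs uninformative.  Real pathway analyses scale linearly in
(number of ranked parameters) × (draws per parameter) simulations.

## Known limitations

* Strictly OAT: joint perturbations are supported only as a manual
  two-parameter ensemble utility (`population_ensemble(...,
  extra_params=...)`), not in the ranking; no variance-based (Sobol /
  Morris) indices.
* Multiplicative alteration cannot probe parameters with nominal value 0.
* The signed index assumes `Δx` holds one sign over the horizon for the
  parameters that matter; a parameter whose alteration shifts response
  *timing* (phase) rather than magnitude can show cancellation in the
  integral and rank lower than its biological importance warrants.
* No SBML/CellML import, delay equations, stochastic simulation, or event
  handling; models are supplied as Python callables or via the registered
  demo-model configuration path.
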
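# Methods

This note documents the models, numerical choices and design decisions
behind `dynfit`, and what the synthetic studies do and do not demonstrate.

## The demonstration cardiorespiratory model

The fitting machinery needs a self-regulated steady-state model with many
named parameters. The built-in `CardioRespSurrogate` is a compact algebraic
model chosen for that role; it is *not* a reimplementation of any published
multi-compartmental model, but it exposes the same interface contract
(role-annotated parameters, steady-state simulation, ten output variables)
so a full model can be dropped in.

Inputs are O₂ uptake and CO₂ output (V̇O₂, V̇CO₂, L/min) and the
environment (inspired fractions FiO₂/FiCO₂ in %, atmospheric pressure in
mmHg). With water-vapor-corrected inspired pressures
PIO₂ = (FiO₂/100)(Patm − 47), PICO₂ = (FiCO₂/100)(Patm − 47):

- gas balance: alveolar ventilation VA = V̇E·(1 − V0dead/VT);
  PACO₂ = PICO₂ + 863·V̇CO₂/VA; PAO₂ = PIO₂ − 863·V̇O₂/VA
  (863 mmHg is the BTPS/STPD conversion, itself a `conversion`-role
  parameter);
- ventilation controller:
  V̇E = max(0.5, Gc·(PACO₂ − Bc) + Gp·exp(−PAO₂/KpO₂) + Gm·V̇CO₂) —
  central chemoreflex, peripheral hypoxic drive, metabolic drive;
- breathing pattern: VT = clip(VTn + kVT·(V̇E − VEn), VTn, VTmax);
  BF = V̇E/VT; TI = 60·rI/BF;
- cardiovascular: HR = HR0 + GHR·V̇O₂; PM = PM0 + GPM·V̇O₂; pulse pressure
  PP = PP0 + GPP·V̇O₂; PD = PM − PP/3; PS = PD + PP.

Nominal values (`src/dynfit/data/surrogate_params.csv`) describe a healthy
adult at moderate altitude (Patm 640 mmHg): resting V̇E ≈ 9 L/min,
PACO₂ ≈ 38 mmHg, HR 60 + 33·V̇O₂. They are package-chosen, with two
deliberate identifiability properties: every gain/threshold parameter has a
measurable effect on at least one output over the exercise range, and VTmax
(1.5 L) actually clips the tidal volume near the anaerobic threshold so it
is observable.

### Steady-state solver

Ventilation is the only closed-loop state; the steady state solves
`ve = controller(gas_balance(ve))`. The residual `h(ve) = ve −
controller(gas_balance(ve))` is strictly increasing in `ve` (alveolar
ventilation rises with `ve`, so CO₂ drive falls and O₂ drive falls), hence
the root is unique. The solver is vectorized bisection on [0.5, 300] L/min,
tolerance 1e-6 L/min, at most 500 iterations. Damped fixed-point iteration
was tried first and abandoned: for parameter draws inside the optimization
bounds the chemoreflex loop gain reaches 4–5 and the iteration settles into
stable limit cycles regardless of damping schedule. Bisection is
unconditionally convergent, still purely algebraic (no ODE integration is
needed because only steady states are consumed), and costs ~1 ms for a full
8-level grid. Tests verify it against an independently coded scalar
bisection on `ventilation_residual` over random parameter draws.

## Standardization

- BSA = √(weight·height/3600) (m², weight kg, height cm); Vtot =
  1000·(3.29·BSA − 1.29) mL; the unstressed-volume group keeps its nominal
  proportion of Vtot.
- VTn is the resting-phase tidal volume: an explicit measurement when
  present, else VT observed at the lowest stimulus level. This means VTn
  absorbs the (small) resting recruitment — tests account for a near-zero
  rather than exactly zero initial cost on noiseless records.
- The anaerobic threshold uses the v-slope principle realized as an
  exhaustive two-segment least-squares breakpoint search on V̇CO₂ vs V̇O₂
  (breakpoints at observed samples, ≥3 points per segment, second slope
  strictly greater). A directly supplied AT always wins over the estimate.

## Parameter selection

Eligible candidates are the gain/threshold role group only — time
constants and initial values do not affect steady states, covariates are
standardized. Relative sensitivities are finite-difference slopes over five
uniform variations within ±5% of the current value (probes are clipped into
the optimization bounds and the realized fractions used), evaluated at
three stimulus levels (rest, midpoint, AT). Total sensitivity is the
row-weighted RMS of a parameter's column, the weights being each
(variable, level) cell's absolute relative error at the current parameters
— parameters acting where the model is currently wrong rank higher. The
base set is built greedily under a collinearity ceiling γ = 1/σ_min ≤ 15 of
the column-normalized selected submatrix (default target size 8);
per-variable specific sets take the non-base parameter whose sensitivity is
concentrated on that variable (dominance ratio ≥ 2).

A structural fact worth knowing: all five ventilation-controller gains act
on the outputs only *through* ventilation, so with three stimulus levels
their sensitivity columns live in a three-dimensional family and the
collinearity screen admits at most three of them. The base set therefore
typically contains {rI, Bc, kVT, VTmax, KpO₂, GHR, Gc, GPM}; Gm and Gp are
represented through their collinear partners. This is the correct behavior
of subset selection, not a defect — jointly fitting all five would be
ill-posed.

## Optimization

The cost is implemented exactly as the printed squared form,
CF = (1/I)Σᵢ(1/K)Σₖ((y_exp−y_sim)/y_exp)²; a `sqrt_cost` flag exposes the
RMSE-style root for users who prefer it, but nothing internal uses it.
Bounds always reference *nominal* values (±30% measure-linked / ±50%
otherwise, sign-preserving), never the warm start. CMA-ES is a compact
in-package implementation of the standard (μ/μ_w, λ) strategy with
rank-one/rank-μ covariance updates, searching the unit box through an
affine map; out-of-box candidates are clipped and charged a quadratic
penalty. Defaults: σ₀ = 0.3, λ = 4+⌊3 ln d⌋, 500·d evaluations, all seeded.
The start point participates in best-of-run, so a fit can never end worse
than it began. Stage 1 fits the base set against the full cost; stage 2
refines each variable's specific set against that variable's own error, a
refinement being kept only if the overall cost does not degrade by more
than 1% relative (the acceptance tolerance is configurable; the underlying
idea — improve one variable "without significantly affecting" the others —
needs some operational number). A third, stimulus-related stage exists in
the general scheme but is deliberately absent here. Candidates whose
simulation fails are charged a large finite penalty (1e6) rather than
crashing the search.

## Trend modeling

Records are linearly interpolated onto a uniform grid before ARX
estimation. The requested sampling time ts ∈ [0.1, 0.4] yr is snapped to
ts_eff = T/round(T/ts) so the grid is exactly uniform *and* hits both
endpoints — the two requirements conflict otherwise. The ARX structure has
no intercept, all input delays zero, one shared order nb for the four
inputs (time, activity h/week, sleep h/day, AT); the exhaustive AIC search
covers ts ∈ {0.1, 0.2, 0.3, 0.4} × na, nb ∈ 0..3 subject to d = na + 4·nb
being below the effective sample count, ties resolved toward fewer
coefficients and then shorter sampling times.

Two related quantities are deliberately different:

- `loss_v` (the V in AIC = ln V + 2d/N) is the mean squared **one-step**
  prediction error, as the criterion is printed;
- `fit_pct` (the quantity gated at 60%) is the normalized fit of the
  **free-run simulated** output. One-step fit% on a densely resampled
  series is nearly always high — each step only extrapolates 0.1–0.4 yr of
  a smooth curve — which would make the goodness-of-fit gate useless
  against noise-driven parameter wander. Free-run simulation (the system
  identification community's default `compare` convention) separates a real
  trend from noise; in the reference benchmark it is the difference between
  the gate rejecting essentially nothing and rejecting the noise
  trajectories while accepting the genuinely drifting gain.

A parameter is modeled only if its value changed by more than 0.5%
(relative) in two consecutive fits; others are `not_modeled` and keep their
previous value. Gates, in order: fit% < 60 → `rejected_gof`; predicted sign
differing from the previous value's → `rejected_sign`; |prediction −
previous| exceeding 50% of the recorded range → `rejected_range` (when the
recorded range is degenerate, 50% of |previous| substitutes, and an exact
boundary hit — e.g. perfect linear drift over three records — counts as
inside, via a 1e-9 relative tolerance). Any rejection falls back to the
previous record's value; accepted predictions are clipped into the
parameter's bounds before use.

## Validation

PE% = 100 × mean over variables of the median over (subjects, levels) of
|y_exp − y_sim|/y_exp. The Wilcoxon signed-rank test drops zero
differences, mid-ranks ties, enumerates the exact null by dynamic
programming for up to 25 pairs (mid-ranks are doubled to integers) and uses
a continuity-corrected normal approximation beyond; the pairing unit is the
per-(subject, variable) median absolute relative error. When the
comparison's stimulus grid derives from the *preceding* record's AT (the
honest forecasting situation: the new record's AT is not yet known), the
record's observations are interpolated onto that grid along the V̇CO₂ axis
so experiment and simulation are compared at the same stimulus values;
comparing across misaligned grids can systematically mask or inflate
differences between approaches.

## The synthetic studies — what they show

The generator produces multi-record longitudinal series with drifting true
parameters (value = intercept + slope·t + factor terms + optional AR(1)
noise, clipped to bounds), observations = model outputs × lognormal noise
(default CV 3%: physiological steady-state averages are positive with
roughly proportional errors), and the standard stimulus grid (8 equidistant
V̇CO₂ levels from 0.3 L/min to AT, V̇O₂ = V̇CO₂/0.9 via a fixed respiratory
exchange ratio below threshold). Hidden truth travels in a separate sidecar
object/file that fitting code never receives.

The reference benchmark (`drifting_gain_scenario`) is one subject, four
yearly records, heart-rate gain GHR declining 5% of nominal per year —
age-related chronotropic decline, chosen because GHR is always selected and
strongly identified, so the scenario probes the *strategy* rather than
fighting the identifiability limits of the ventilation chain. Over 20
seeded replicates the suite verifies that the drifting gain is tracked
within 10% at every record and that the dynamic fit's overall PE on the
held-out final record beats the single-time fit's in the majority of
replicates. Problem sizes (4 records, 8 levels, 500·d CMA-ES evaluations,
20 seeds) keep the whole suite at desk scale — a few minutes — while
leaving each fit clearly converged relative to the 3% noise floor.

What passing does **not** show: the generator's noise is independent across
cells (real steady-state averages share breath-by-breath correlation), the
true drift is a clean linear law in one parameter (real drift is diffuse
and correlated across parameters), the model is the same one being fitted
(no structural mismatch), and V̇O₂/V̇CO₂ pairs follow a fixed exchange
ratio. Results on real records will be dominated by structural mismatch and
data quality, which these studies cannot probe.

## Known limitations

- The demonstration model has no transient dynamics; the package evaluates
  steady states only, by design.
- Weakly leveraged parameters (e.g. the hypoxic-drive shape KpO₂) are not
  pinned to better than ~10–20% by 80 noisy observations; their fitted
  trajectories are correspondingly noisy and are usually rejected by the
  justification gates. This is an identifiability property of the problem,
  not a solver failure.
- The 50%-of-range gate is inherently strict for short histories: a steady
  linear drift over three records sits exactly on the boundary, and noise
  can push a correct extrapolation into rejection. The fallback (previous
  record's value) keeps such rejections cheap.
- The ARX search shares one order nb across all inputs; per-input orders
  would multiply the candidate set beyond what 4–6 records can support.
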
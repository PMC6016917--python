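# Methods

## Single-strain models

Each specialist strain is modelled as a three-state batch system
(biomass X in g DCW/L, its sugar S and ethanol P in g/L):

    dX/dt = μ(S, P) · X
    dP/dt = ν(S, P; S0) · X
    −dS/dt = (1/(b1·Y_P/S)) dP/dt + (1/(b2·Y_X/S)) dX/dt + m·X

with

    μ = μ_m · S / (K_s + S + S²/K_i) · max(0, 1 − (P/P_m)^β)
    ν = exp(a_S0·S0) · v_m · S / (K_s' + S + S²/K_i') · max(0, 1 − (P/P_m')^γ)

Assumptions: oxygen-limited batch operation at constant temperature and
pH; a single growth-limiting sugar per strain; no ethanol re-assimilation
(for SR8, where re-assimilation is known to occur after xylose levels
off, its net effect is absorbed into the yield amendments b1, b2 and the
anomalously low fitted P_m' = 27 g/L); no byproduct (glycerol/xylitol)
tracking; no lag phase.

Conventions chosen where the rate laws are silent:

* **Luong clamping.**  The ethanol factors are clamped at zero for
  P ≥ P_m (resp. P_m').  The raw form goes negative there and, with
  non-integer exponents (β = 1.1, γ = 1.04), is not even real-valued.
* **Optional Haldane terms.**  K_i/K_i' absent means the S²/K term is
  structurally omitted, not approximated by a large constant.  With the
  term present the growth optimum sits at S* = √(K_s·K_i) (≈ 10.8 g/L
  for EJ2); without it μ is monotone in S with supremum μ_m.
* **Depletion freeze.**  Below S = 10⁻⁶ g/L all of a sugar's terms
  freeze.  Otherwise the maintenance term m·X would drive S negative.
  The integrator treats the crossing as a terminal event and restarts
  with the sugar clamped to zero, so the discontinuity never sits inside
  an accepted step.
* **Yield ceiling.** Y_P/S is validated against the stoichiometric
  maximum 0.538 g ethanol per g disaccharide-equivalent sugar.

Default parameter sets for EJ2 (cellobiose) and SR8 (xylose) are packaged
as YAML and embedded as code defaults; the two are cross-checked in the
test suite.  Note one documented discrepancy in the sources for SR8's
ethanol yield: the fitted table value 0.4 g/g (amended by b1 = 1.12) is
used in the ODEs, while the literature value 0.35 g/g is the basis for
the analytic threshold helper below.

## Co-culture model

State: per-strain biomass X_E, X_S (observable biomass is their sum —
the split is required for a well-posed ODE but was not experimentally
observable), the two sugars, and one shared ethanol pool.  There is no
substrate competition; the strains interact only through ethanol and the
fitted weighing factors r1..r6 (defaults r1=3.75, r2=1.76, r3=1.44,
r4=2.48, r5=1.82, r6=4.29):

    μ_E = μ_EJ2(S_c, r1·P)          μ_S = μ_SR8(S_x, r2·P)
    ν_E = ν_EJ2(S_c, P; S0_c)       ν_S = ν_SR8(S_x, P; S0_x)

    dX_E/dt = r3 · μ_E · X_E        dX_S/dt = r4 · μ_S · X_S
    dP/dt   = φ_E^q · r5 · ν_E · X_E  +  φ_S^q · r6 · ν_S · X_S
    −dS_c/dt = ν_E·X_E / Y_P/S,E + (dX_E/dt) / Y_X/S,E + m·X_E
    −dS_x/dt = ν_S·X_S / (b1·Y_P/S,S) + (dX_S/dt) / (b2·Y_X/S,S) + m·X_S

where φ_E = (S0_c/(S0_c+S0_x)) · (X0_E/(X0_E+X0_S)) and φ_S its mirror
are share factors built from the initial sugar-concentration and
inoculum-size ratios, and q is a single calibration exponent
(default 0.983).

Design rationale, in order of how firmly each piece is anchored:

* r1/r2 amending the ethanol-inhibition arguments of the growth terms,
  and r3/r4 vs r5/r6 weighting biomass accumulation vs ethanol
  production, follow the published description of the factors' roles and
  orderings (r1 > r2, r3 < r4, r5 < r6).
* Substrate is consumed at the strain's intrinsic production rate ν·X
  while the observable ethanol pool accrues only the share-weighted flux
  φ^q·r·ν·X.  The model is therefore deliberately *non-conservative* in
  ethanol: part of the carbon each strain processes does not appear as
  measurable ethanol in mixed culture.  This is the mechanism by which
  the model reproduces the published observation that mixed-culture
  ethanol falls short of the sum of the two single-sugar fermentations
  (sum = 1.38 × co-culture ethanol at 40+40 g/L, equal inocula).  A
  strictly conservative coupling cannot reproduce that shortfall
  together with full depletion of both sugars at realistic biomass —
  the shortfall carbon would have to appear as ~2× the plausible biomass.
* q is the model's only constant not taken from the published tables.
  It is fixed once against the 1.38 shortfall ratio at the 40+40 g/L
  reference condition and never re-tuned per scenario.  Because φ = 1
  when one strain (or sugar) is absent, any q leaves the single-strain
  limit exact: with unit weighing factors and one strain absent the
  co-culture system reduces to the corresponding monoculture model to
  machine precision.
* Per-sugar depletion freezing is inherited from the monoculture model;
  a depleted sugar freezes only its own strain's terms.

With the default parameters this reconstruction reproduces, without
further adjustment: near-simultaneous depletion of a 40+40 g/L feed at
equal inocula (21.8 vs 19.9 h); the cellobiose backlog of an 80+40 g/L
feed at equal inocula; depletion of a 60+20 g/L feed within 20 h at a
2:1 EJ2:SR8 inoculum, which is also the productivity-optimal composition
among 1:1, 2:1 and 3:1.

Known limitations: for an 80+40 g/L feed with doubled EJ2 inoculum the
model leaves a xylose tail (shared ethanol passes SR8's production
arrest at 27 g/L before xylose is gone), whereas simultaneous depletion
was reported experimentally; and the non-conservative ethanol accrual
means co-culture biomass is the trajectory's balancing term and should
not be over-interpreted quantitatively.  The coupling sits behind a
single replaceable function, so alternative couplings can be swapped
without touching the simulator; the normalized initial-condition weights
(ρ_E + ρ_S = 1) are also exposed for such variants.

## Numerics

Adaptive RK45 (scipy `solve_ivp`), rtol 10⁻⁸ / atol 10⁻¹⁰, output grid
0.25 h, default horizon 48 h (covers every scenario studied; the sources
do not state simulation end times).  Depletion crossings are terminal
events; after all tracked sugars are depleted the state is held constant
on the remaining grid.  Halving the tolerances changes reported states
by well under 0.1%; the test suite also pins the integrator against an
independent fixed-step RK4 oracle at dt = 10⁻³ h to 10⁻⁴ g/L.
"Fermentation complete" is operationalised as S ≤ 1 g/L — the sources
never define "almost depleted"; 1 g/L is well under 2% of the smallest
load studied.

## Parameter estimation

Stage 1: μ_m and K_s from log-phase growth rates via the double-
reciprocal (Lineweaver-Burk) regression of 1/μ on 1/S (exact two-point
solve in the two-observation case).  Stage 2: the remaining parameters
by least squares — model trajectories interpolated to the data sampling
times, residuals pooled unweighted in g/L over biomass, sugar(s) and
ethanol (a per-variable weighting hook exists but defaults to 1), RSS
minimised with a trust-region-reflective least-squares backend (lmfit)
under per-parameter bounds, with optional seeded multi-start.  Which
parameters are fixed follows the original workflow: μ_m, K_s from stage
1, Y_P/S from literature, P_m/P_m' from ethanol-challenge experiments;
production kinetics (v_m, K_s', K_i', P_m', γ) free by default.  For
xylose data a plateau-truncation helper drops samples after |ΔS_x| stays
below 0.1 g/L over two consecutive samples, since the model does not
describe the post-plateau (ethanol-assimilating) phase.

Identifiability, measured on self-generated data: noiseless trajectories
at four loads pin all five free production parameters to <1%.  Under 5%
multiplicative noise with duplicate trajectories, v_m and K_s' recover
to ~15% and K_i' to ~25%, but P_m' and γ trade off — only the ethanol-
inhibition factor 1−(P/P_m')^γ over the observed ethanol range is
identified (recovered to <0.12 in the tests), not the two constants
individually.  Tests assert exactly that.

The variant comparison refits the model with the Haldane terms present/
absent in growth and production (four structures) and ranks pooled RMSE
at a 10⁻⁴ g/L resolution, breaking ties toward fewer free parameters so
that nested richer families do not win on numerical dust.

The analytic threshold helper converts critical ethanol concentrations
to the sugar loads whose complete conversion would reach them:
S_stop = P_m/Y.  With the experimentally observed arrest at 69 g/L
ethanol and Y = 0.5 g/g this gives 138 g/L (growth) and 200 g/L
(production) for cellobiose; with 85 g/L and the literature yield
0.35 g/g, ≈243 g/L for xylose.  Percent-of-theoretical yields use the
glucose-equivalent basis 0.511 g/g (0.5/0.511 ≈ 98%); the
disaccharide-mass basis 0.538 g/g would give ≈93% and is not used.

## Synthetic data

The generator emulates the underlying experimental design: duplicate
batches, sampling every 3 h out to 48 h, loads 10-120 g/L, inocula
around 0.45 g DCW/L.  Noise is multiplicative Gaussian (default CV 5%)
plus an additive floor (sd 0.1 g/L), truncated at zero — relative error
dominating at high concentration and detection noise at low, as for
HPLC quantification.  The original study reports no error model (its
error bars are smaller than the plot symbols); the defaults are
conservative choices documented here, not published values.  Noiseless
generation is the identity on the simulator output; a fixed seed
reproduces a dataset bit for bit.  What passing recovery tests show is
that the *estimation machinery* is sound under this noise model; real
data add model misfit (lag phases, re-assimilation, calibration error)
that the generator deliberately does not emulate.

## Problem sizes

All results in the tests and the acceptance script run at the study's
own scale: single fermentations of 10-120 g/L sugar integrated over
48 h, fits over 4-8 trajectories of ≤17 samples, and three-candidate
design scans.  Nothing is down-scaled.
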
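# Methods

This note documents the models, the estimation procedures, the synthetic-data
generator and the numerical choices behind `leafphys`, including the design
decisions made where more than one reasonable construction existed.

## Biochemical model

Net CO2 assimilation follows the FvCB scheme: the minimum of a
Rubisco-carboxylation-limited rate and an electron-transport-limited rate,
both evaluated at the chloroplast CO2 partial pressure Cc (μbar):

    Ac = (Cc − Γ*) Vcmax / (Cc + KmC(1 + O/KmO)) − Rd
    Aj = (Cc − Γ*) J / (4Cc + 8Γ*) − Rd
    An = min(Ac, Aj)

The minimum is strict (no hyperbolic smoothing), and a limitation flag is
reported with every evaluation. Electron transport responds to incident
irradiance through the lower root of the non-rectangular hyperbola

    θ J² − (κ2LL·Iinc + Jmax) J + κ2LL·Iinc·Jmax = 0

with convexity θ fixed at 0.8 — freeing θ is known to destabilize the
Jmax/κ2LL estimates — and κ2LL the conversion efficiency of incident light
into linear electron transport at strictly limiting light.

Temperature responses are normalized at 25 °C. Vcmax, Rd, KmC, KmO and Γ*
follow the Arrhenius form X25·exp[(T−25)E/(298·R·(T+273))]; Jmax and gm
follow the peaked form with an entropy term S and deactivation energy D,
whose deactivation ratio is computed in log space (`logaddexp`) so no
parameter combination overflows. Fixed constants (all configurable):
KmC25 = 272.4 μbar, KmO25 = 165.8 mbar, EKmC = 80,990, EKmO = 23,720,
ERd = 46,390 J mol⁻¹, SJmax = 650 J K⁻¹ mol⁻¹, DJmax = 200,000 J mol⁻¹,
Egm = 49,600, Sgm = 1,400 (J K⁻¹ mol⁻¹), Dgm = 437,400 J mol⁻¹. EVcmax and
EJmax default to 65,330 and 43,540 J mol⁻¹ and may be re-estimated.

**Γ\*.** The CO2 compensation point in the absence of day respiration is
modeled as Γ*(T, O) = 37.43 μbar · (O/210) · Arrhenius(E = 24,460 J mol⁻¹),
i.e. proportional to chloroplast O2 and ≈37 μbar at 25 °C and 21 % O2. The
base value and activation energy are tobacco-derived constants in the same
family as the Rubisco kinetics above; both are fields of `KineticConstants`
and can be replaced.

**Units.** CO2 partial pressures are in μbar and treated as numerically equal
to μmol mol⁻¹ (1 bar total pressure). κ2LL and Φ2 are mol e⁻ (mol photon)⁻¹;
conductances are mol m⁻² s⁻¹, with gm per bar. Measured stomatal conductance
on the water-vapor basis (`gsw`) is converted to the CO2 basis by the
diffusivity ratio 1.6.

**Mesophyll conductance.** Substituting Cc = Ci − A/gm into either branch
gives a quadratic in A whose lower root is the Ci-based assimilation rate
(the NRH-A form); the electron-transport branch uses x1 = J/4, x2 = 2Γ*, the
Rubisco branch x1 = Vcmax, x2 = KmC(1 + O/KmO). The discriminant of this
quadratic is analytically nonnegative for valid inputs; rounding-level
negatives are clamped at zero. gm is treated as constant across a response
curve (apart from its temperature response) — whether gm varies with light
or CO2 is an open question in the field; the constant-gm assumption is what
makes treatment comparisons of an *average* gm meaningful.

## Stomatal model

gs = g0 + (An + Rd)/(Ci − Ci*)·fvpd with fvpd = 1/[1/(a1 − b1·VPD) − 1] and
Ci* = Γ* − Rd/gm. a1 is the Ci/Ca ratio at vapor saturation, b1 its decline
per kPa of VPD; the form is chosen over the humidity-based variant precisely
because a1 and b1 have this interpretation. fvpd is defined only for
0 < a1 − b1·VPD < 1. In fitting, candidate parameter steps that push an
observation outside the domain are penalized (the argument is clamped at
1e-3 and a linear penalty added), with box constraints a1 ∈ (0.01, 0.99),
b1 ∈ [0, 5]; in prediction the argument is clamped with a warning. Records
with Ci ≤ Ci* + 1 μbar are excluded from stomatal fitting with a logged
count, since the model is singular at Ci*.

## Coupled solver

With Ca, Iinc, T and VPD as inputs, the solver finds the operating point
satisfying (i) An = FvCB(Cc), (ii) Cc = Ci − An/gm, (iii) the stomatal model
and (iv) Ci = Ca − An/gs. Each limitation branch is solved separately by a
bracketed Brent root-find on Ci of the mismatch between the
diffusion-implied and biochemistry-implied Ci — the NRH-A closed form makes
the inner biochemistry/mesophyll subsystem exact — and An is the minimum
over branches. The bracket is (Ci* + 1 μbar, Ca + Rd/g0 + 1 μbar); on this
interval An ≥ −Rd guarantees the mismatch is negative at the upper end, and
a demand so strong that the implied Ci falls below the guard pins the
solution at the guard. Convergence tolerance is 1e-10 on Ci; the three
balance residuals are attached to every solution and are below 1e-8 at
convergence. An analytical cubic solution exists in the literature; the
bracketed solve was preferred as unambiguous and directly testable (the test
suite checks it against an independent nested-bisection oracle to 1e-7).

Consequences worth knowing: in darkness the solution is exactly
An = −Rd(T), gs = g0, Ci = Ca + Rd/g0; once a light step is fully
Rubisco-limited the solution no longer depends on irradiance (the light
response plateaus exactly); and An is nonincreasing in VPD and nondecreasing
in Iinc and Ca over physiological ranges.

## Estimation chain

Per treatment, `run_treatment_fit` executes:

1. **s and Rd25** from the non-photorespiratory calibration records. Under
   suppressed photorespiration Aj reduces to J/4 − Rd, so
   An = s·(Iinc·Φ2/4) − Rd is linear with slope s (the lumped fluorescence
   calibration factor) and intercept −Rd. The regression is a two-regressor
   OLS of An on [Iinc·Φ2/4, −Arrhenius factor(T; ERd)], which absorbs
   leaf-temperature drift between steps and returns Rd at 25 °C directly; at
   constant temperature it reduces to the plain free-intercept regression.
   Points used: the limiting-light steps plus the high-CO2 steps, the latter
   admitted through a one-sided consistency screen (below).
2. **Jmax25 and κ2LL** by Levenberg–Marquardt least squares of the
   non-rectangular light response of J = s·Iinc·Φ2 with
   Jmax = peaked-Arrhenius(Jmax25; T) per point.
3. **Smoothed J.** Downstream fits use J recomputed from the fitted Jmax25
   and κ2LL at each step's temperature rather than the raw per-point
   fluorescence J. This mirrors standard practice and keeps Φ2 measurement
   noise from entering the later stages as an error in a covariate, which
   would otherwise bias gm.
4. **gm25** by the NRH-A method: least squares of the electron-transport
   quadratic on the electron-transport-limited window, with
   gm = peaked-Arrhenius(gm25; T) shared across the curve.
5. **Vcmax25** over the whole curve with An = min of the two Ci-based
   branches and everything else known; then a **joint polish** of
   (gm25, Vcmax25) on the same min-model (see below).
6. **g0, a1, b1** by bounded least squares of the stomatal model on the
   conductance records (light and CO2 curves, Iinc > 0), with per-record Rd
   and Ci* computed from the estimates of stages 1 and 4–5.

Kok (intercept of An on Iinc) and Yin (intercept of An on Iinc·Φ2/4)
day-respiration estimates are computed per curve over the limiting-light
window (default 20–200 μmol m⁻² s⁻¹) together with their linear
cross-calibration, and attached as diagnostics. The chain's working Rd comes
from the calibration regression of stage 1 — a Yin-type estimate — because
the synthetic datasets always carry fluorescence; the Kok route with
calibration correction exists for datasets where Φ2 is only partly
available. The known qualitative behaviors (Kok underestimates Rd under a
sub-linear light response; the Yin regressor absorbs that curvature; the
calibration map reduces the error of biased estimates) are covered by tests.

### Limitation screening

The electron-transport-limited window of a light curve is not a fixed
irradiance range: it depends on the leaf's parameters and on the CO2
drawdown at each step, hence on VPD through stomatal closure. Within this
package's parameter space, steps at and below 200 μmol m⁻² s⁻¹ are always
electron-transport-limited, while steps from ~400 upward can be
Rubisco-limited at moderate to high VPD. Fitting the electron-transport
quadratic to Rubisco-limited points biases gm low, so two screens are used:

- **s-calibration:** the fit anchors on the limiting-light steps (which
  cannot be Rubisco-limited) and admits each high-CO2 step only if its
  residual is no more than `abs_tol + 3·rms` *below* the current line —
  Rubisco contamination deviates strictly downward, so the test is
  one-sided. On noise-free data this separates the branches exactly.
- **gm fit:** the same one-sided screen, anchored on the Iinc ≤ 200 steps,
  expands the window up to the configured cap (default 1000 μmol m⁻² s⁻¹,
  the classical rule for this species). The screened fit seeds a joint
  two-parameter fit of (gm25, Vcmax25) on the full min(Ac, Aj) model: both
  branches share the mesophyll drawdown, so Rubisco-limited points also
  carry gm information, and the joint fit needs no per-point limitation
  classification at all. The min-model objective is flat in Vcmax25 wherever
  every prediction sits on the electron-transport branch, so both the
  Vcmax-only and the joint fit are multi-started from low values that keep
  the Rubisco branch active; a fit whose optimum has no Rubisco-limited
  point raises an explicit unidentifiability error (the batch pipeline skips
  such a treatment with a log entry).

### Shared parameterization

`run_shared_fit` fits the nitrogen relations across the per-treatment
estimates — Vcmax25 and Jmax25 regressed on (Na − Nb) through the origin
(Nb = 0.35 g N m⁻²), κ2LL, Rd25, gm25 and g0 with free intercepts — and
pools the stomatal slopes a1/b1 over all treatments or per water level, with
g0 fixed per record from its fitted nitrogen relation. Nested
parameterizations are compared with the F-test
F = [(RSSr − RSSf)/(dfr − dff)]/(RSSf/dff); its empirical size is verified
at α = 0.05 by simulation. Prediction quality is summarized by the
through-origin slope Σxy/Σx², the squared Pearson correlation (the
through-origin coefficient of determination is ill-defined, so r² is
reported as the correlation-based quantity alongside the slope) and the
relative RMSE (RMSE divided by the mean observation).

All nonlinear fits use Levenberg–Marquardt (lmfit) with numeric Jacobians
and ftol = xtol = 1e-12; standard errors come from the Gauss–Newton Jacobian
approximation at the optimum. Linear fits are OLS (statsmodels).

## Synthetic data generator

The generator emulates a 2 water × 4 nitrogen factorial on greenhouse lily:
per treatment, replicate light-response curves at the instrument's standard
irradiance steps (1500 … 20, 0 μmol m⁻² s⁻¹) at Ca = 370 μmol mol⁻¹,
CO2-response curves (Ca = 50 … 1500 at Iinc = 800) and a calibration
measurement under suppressed photorespiration (the light steps at Ca = 1000
plus three high-CO2 steps at Iinc = 800). Default truth values are the
published per-treatment estimates shipped in `leafphys.reference`; default
replication is six curves per treatment and regime, matching the study
design's six replicate plants per treatment.

Every record is forward-simulated with the coupled solver. Leaf temperature
and VPD are drawn uniformly per step (light curves at 20 ± 2 °C; VPD
0.5–2.5 kPa, redrawn when a draw leaves the fvpd domain), emulating
measurement under drifting greenhouse climate. Fluorescence is emitted as
Φ2 = J/(s·Iinc) with J from the light response — at 21 % O2, electron
transport follows the light response even where Rubisco limits An, with
photorespiration absorbing the excess — and
s = ρ2·β·(1 − f_pseudo/(1 − f_cyc)) from the fluorescence model (defaults
ρ2 = 0.5, β = 0.85, f_cyc = 0.1, f_pseudo = 0.1, raised to 0.2 under water
deficit to represent the drought-induced increase in alternative electron
flow; all invented, documented defaults). Noise is additive Gaussian on An
(SD 0.3 μmol m⁻² s⁻¹) and Φ2 (SD 0.01) and multiplicative on gsw (CV 5 %);
Ci is reported noise-free (on the instrument it is a derived quantity; its
error propagation is not modeled).

Two idealizations matter for interpretation:

- **The calibration regime is fully non-photorespiratory** (chloroplast O2
  set to zero, hence Γ* = 0), rather than the nominal 2 % O2 of the
  protocol. The calibration regression assumes An is exactly linear in
  Iinc·Φ2/4; at 2 % O2 a ~1 % curvature from the remaining photorespiration
  would propagate through the whole chain and make the noise-free
  round-trip identity unattainable. The `O2_pct` column still records the
  nominal 2 %.
- **Per-treatment Na values are back-computed from Vcmax25** through
  Na = Vcmax25/χV + Nb with χV = 62 μmol (g N)⁻¹ s⁻¹ (ww ≈ 1.59–2.11,
  wd ≈ 1.29–1.77 g N m⁻²), so the generator's treatments are exactly
  consistent with the capacity–nitrogen relations and the shared-fit stage
  recovers χV and χJ by construction rather than depending on an arbitrary
  invented nitrogen grid.

What the generator does *not* emulate: CO2 leakage of the cuvette (and its
killed-leaf correction), instrument drift and matching errors, Ci
measurement error, within-treatment plant-to-plant parameter variation
(replicates share one truth), light-induced or CO2-induced variation of gm,
and any relation between the drawn T and VPD. Passing tests therefore show
that the estimators invert the model under the stated noise — not that they
are robust to instrument systematics absent from the generator.

A further consequence of self-consistency: with the published parameters,
the coupled generator produces lower Ci at moderate/high VPD than the
study's raw measurements did, so its curves leave the electron-transport-
limited regime well below the classical 1000 μmol m⁻² s⁻¹ cutoff (from
~400–600 upward depending on treatment and VPD). This is why the pipeline
screens limitation from the data instead of trusting a fixed window; with
the fixed window alone, gm would be biased by ~20 % even on noise-free data.

## Verification

The test suite checks, among others: exact analytic limits (base rates at
25 °C, An = −Rd at the compensation point and in darkness, gs = g0 in
darkness, the infinite-gm reduction to the Ci-based hyperbola); agreement of
the closed-form quadratic with an implicit-equation bisection oracle (1e-8,
1000 random draws) and of the coupled solver with a nested-bisection oracle
(1e-7 in An, 1000 draws); the exact noise-free round-trip of the full chain
(every generator parameter recovered to < 1e-6 relative, in practice
~1e-15); parameter recovery within twice the published standard errors
under the default noise model; the qualitative cost of pooling a1/b1 across
water levels (gs overestimated under deficit, underestimated well-watered,
with the coupled An bias under deficit attenuated relative to the gs bias);
and the F-test's empirical size. Problem sizes in the routine tests — six
replicate curves per treatment for recovery checks, 200-record pooled
stomatal fits, 1000-draw oracle comparisons and 1000-simulation calibration
checks — were chosen to make each check statistically meaningful at
interactive runtimes.

## Known limitations

- TPU (triose-phosphate-utilization) limitation is not modeled; it is not
  estimable from light-response curves, which is also why the Vcmax fit can
  declare itself unidentifiable on a purely electron-transport-limited curve.
- Boundary-layer conductance and leaf energy balance are out of scope; leaf
  temperature is an input.
- The generator's measurement-noise model is simple (independent Gaussian);
  real instrument error is autocorrelated along a curve.
- κ2LL is treated as temperature-invariant; only Jmax carries the
  temperature response of electron transport.
- Standard errors are asymptotic (Jacobian-based); for the weakly identified
  water-deficit low-N treatments they understate the true uncertainty.
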
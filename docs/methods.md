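# Methods

`lumenpd` analyzes the residually dissected aorta after surgical repair of
type A aortic dissection. The question it addresses: does the pressure
difference between the true lumen (TL) and false lumen (FL), estimated
from flow simulation on follow-up imaging geometry, predict where and
when the aorta dilates? The package implements the full desk-scale chain:
synthetic longitudinal geometry, morphometric measurement, a reduced-order
flow model, the per-plane pressure-difference statistic, and the
longitudinal statistics tying it to growth.

## Measurement model

Geometry is parameterized per scan as a centerline with per-station
cross-sections (TL area, patent FL area, mural thrombus area, outer
contour) and a tear set (one primary entry tear, the most proximal
communication, plus distal re-entry tears). Measurement planes follow
the clinical protocol: P1 sits 20 mm distal to the left subclavian
artery origin and subsequent planes follow every 30 mm, perpendicular to
the centerline tangent. The per-plane diameter is the maximum Feret
(caliper) diameter of the combined outer contour — TL + FL + thrombus,
since thrombus occupies aortic cross-section even though it carries no
flow. A minimum-caliper (`short_axis`) variant is exposed behind a flag
because radiological practice sometimes reports short-axis diameters; the
Feret definition is the default because it is unambiguous and exactly
testable against a pairwise-distance oracle. User-supplied surface
meshes (STL/OBJ) are sliced with plane–mesh intersection (trimesh) and
the resulting planar polygons feed the same diameter code; when a plane
cuts a tortuous vessel more than once, the loop nearest the plane's
centerline point is kept.

Growth between consecutive scans is the diameter change divided by the
interval in months, times 12 (mm/yr). A plane growing more than
2.9 mm/yr is classified *unstable* (strict inequality); the threshold is
the accepted cut-point for clinically significant expansion of the
dissected aorta. Lumen volumes are trapezoidal integrals of station
areas along the arc — exact for linearly varying areas and within 1% of
the closed-form frustum volume at 10 stations for conical lumens.

## Reduced-order hemodynamics

The reference analyses of this problem use 3-D CFD on patient-specific
geometry. This package instead solves a 0-D (lumped-parameter) network
that preserves the physical content relevant to the pressure-difference
statistic, at a cost of seconds per scan:

* blood: incompressible, Newtonian, density 1060 kg/m³, viscosity
  4 mPa·s; rigid walls;
* each lumen is a chain of segments with Poiseuille resistance
  `R = 8μL/(πr_eq⁴)` (equivalent radius `r_eq = √(A/π)`) and blood-column
  inertance `ρL/A`;
* tears couple the chains through an orifice law
  `ΔP = R_lin·Q + (ρK_t/2A_t²)·Q|Q|`, with the linear term from
  Poiseuille flow through a flap-thickness (2 mm) channel and a
  sharp-edged orifice coefficient `K_t = 1`;
* thrombosed FL stations carry no flow and are simply absent from the
  graph; a tear whose nearest patent FL node is farther than 25 mm is
  treated as sealed;
* every outlet is a 3-element Windkessel (R1, C, R2) against a venous
  reference pressure.

Absolute per-patient pressures from the original 3-D analyses are *not*
reproduced and not claimed: they depend on patient-specific geometry and
inflow data that are unavailable. What the network preserves is the
mechanism — the TL–FL pressure difference and its dependence on tear
anatomy.

**False-lumen termination.** The modeled segment ends mid-dissection:
in these patients the dissection typically continues into the abdominal
aorta, so the default network terminates the patent distal FL in its own
Windkessel (flow split 0.6 TL / 0.4 FL). This choice matters. A FL that
dead-ends inside a rigid domain can only carry a circulating flow
(in at the primary tear, out at the re-entries, instantaneously), whose
primary-orifice drop *grows* with distal tear area — inverting, at
proximal planes, the pressure-equalization effect of re-entry tears that
the clinical literature describes. With a distal FL outlet the network
sits in the physically expected regime: occluding all re-entry tears
raises the maximum pressure difference at every plane, and enlarging
them lowers it at every plane. Setting `fl_outlet_split = 0` restores
the dead-end variant for sensitivity studies.

**Nominal model.** The solver's reference geometry is a 40 mm
(proximal) to 34 mm (distal) outer diameter over 400 mm, TL at 45% of
the lumen area, a 70 mm² primary tear just distal to the LSA and three
30 mm² re-entry tears in the distal third — all within the morphometric
ranges reported for repaired type A dissection. Its per-plane maximum
pressure difference spans roughly 2.5–9.5 mmHg (0 to ~13 mmHg across the
tear-variation experiments), matching the range over which the
growth relationship is observed clinically.

**Waveform and calibration.** The inlet is a two-phase aortic flow
shape: a systolic half-sine occupying 0.35 of the 0.857 s cycle
(~70 bpm), a small reverse lobe at valve closure (10% of the cycle, 10%
of peak amplitude), zero in diastole, scaled to a 5 L/min cardiac
output. Windkessel parameters are calibrated to 120/80 mmHg targets:
total resistance starts from `(MAP − P_ref)/(split·Q̄)` with
`MAP = DBP + PP/3`, compliance is bisected (in log space) until the
single-outlet pulse pressure matches, and an outer loop trims the total
resistance until simulated systolic and diastolic are both within
2 mmHg of target — necessary because the waveform's systolic fraction
makes the MAP rule-of-thumb inexact. R1 is 5.6% of the total, a standard
aortic characteristic-impedance fraction.

**Time integration.** Implicit Euler with a per-step Newton solve of
the coupled nodal-pressure / element-flow / Windkessel system (the tear
orifice law is the only nonlinearity; the Jacobian is constant except
for a diagonal orifice term). Default step T/1000 (validated: halving
the step moves per-plane max PD by < 0.25%), periodicity tolerance
0.01 mmHg across consecutive cycles, Newton tolerance 1e-9 relative.
The approach to the periodic orbit is dominated by the Windkessel
relaxation (time constant R2·C ≈ 2–3 cycles), so the capacitor state is
Aitken-extrapolated at cycle boundaries and convergence re-verified on
full cycles afterwards; typical runs converge in 4–6 cycles. Internal
element values are SI-derived and expressed in clinical units
(mmHg·s/mL etc.) with 1 mmHg = 133.322 Pa fixed.

The per-plane statistic interpolates nodal pressure waveforms linearly
in arc position (the 0-D nodal pressure stands for the cross-sectional
mean), takes `PD(t) = P_TL(t) − P_FL(t)`, and reports its signed maximum
over the cycle (`signed=False` gives the maximum absolute difference).
Planes without patent FL pressure — outside the dissected extent or
inside a thrombosed gap wider than 45 mm — are reported missing, not
zero.

## Longitudinal statistics

The analysis unit is one (patient, consecutive-scan interval, plane)
record: yearly growth over the interval paired with the maximum PD
simulated on the interval's *earlier* scan (the last scan of each
patient only closes the final growth interval and is never simulated).
The growth model is

    growth ~ PD + C(interval) + C(plane),  random intercept per patient,

fitted by REML (statsmodels MixedLM). Interval and plane enter as
nominal fixed effects with reference-level dummy coding — the coding
affects only the intercept/indicator estimates, not the PD coefficient.
CI and p-value for the PD coefficient are Wald (normal reference);
Satterthwaite-style denominator degrees of freedom are not available in
the fitting backend, and the choice is recorded in the fit log. Two
degenerate limits are handled explicitly: a noise-free table (zero
residual variance, where the REML criterion is unbounded) returns the
exact least-squares limit, and `random_intercept=False` constrains the
intercept variance to zero, where the model provably reduces to OLS.

The ROC analysis sweeps thresholds over the unique PD values with the
rule *unstable if PD > t*, picks the cut-off maximizing Youden's
J = sensitivity + specificity − 1 (ties toward the lower threshold), and
reports the trapezoidal AUC, which equals the normalized Mann–Whitney
rank statistic (asserted by test).

## Synthetic data: what it emulates, what it does not

No patient imaging from the source studies is available, so the
generator produces series with the study's statistical and anatomical
structure: 4 patients, 4–5 scans each at irregular month intervals
(first scans at 0.5–33.5 months, spans of 2.5–5 years), 8 or 12 planes,
and a linear growth law

    growth = a + b·PD + u_patient + ε,
    u ~ N(0, 0.5 mm/yr), ε ~ N(0, 0.8 mm/yr),

with defaults a = 1 mm/yr, b = 0.26 mm/yr per mmHg and PD uniform on
[0, 13] mmHg when not supplied — the effect size, PD range and growth
range reported for this population. One integer seed feeds a
SeedSequence spawned into exactly three streams (patient intercepts, PD
profiles, noise), so identical configs are byte-identical.

Geometry-level generation applies the same law to per-plane total
diameters with a fixed TL area fraction, regular-polygon outer contours
(even vertex count, so the Feret diameter equals the generating diameter
exactly and the measure→growth round trip is exact in the noise-free
case), per-patient tear schedules, and optional thrombosis extents. The
*coupled* mode closes the loop physically: each scan is simulated, the
resulting per-plane max PD drives the next interval's growth, and the
downstream pipeline re-measures exactly the PD that generated the data —
this is the configuration the end-to-end run reports.

What the generator does not emulate: segmentation noise and operator
variability in the measurements, wall mechanics (growth is imposed, not
mechanistic), non-circular cross-sections, plane-to-plane correlated
noise beyond the patient intercept (the fitted model's sole random
effect), and tears appearing/occluding stochastically over time. Passing
tests therefore demonstrate correctness of the estimation machinery
under the stated generating process, not robustness to real-image
artifacts.

## Problem sizes and numerical defaults

Default analyses use 4 patients × 3–4 intervals × 12 planes = 168
records; the coverage experiment refits 100 replicate tables; network
solves use ~80 nodes / ~80 elements at 1000 steps per cycle. These sizes
make a full end-to-end run a ~2 minute desktop computation while keeping
every Monte-Carlo criterion well-resolved. All thresholds live in
configuration with their defaults: 2.9 mm/yr instability, 20/30 mm plane
offsets, 1060 kg/m³ and 4 mPa·s blood, T/1000 solver step, 0.01 mmHg
periodicity tolerance, Youden ROC criterion.

## Known limitations

* The 0-D network has no 3-D flow features (no wall shear stress,
  helicity, or turbulence) and a rigid wall; it targets the
  pressure-difference mechanism only.
* Windkessel parameters and the inlet waveform are population defaults,
  not patient-specific; absolute pressures are nominal.
* Branch vessels are not modeled individually; their outflow is absorbed
  into the outlet flow splits.
* The exact 3-level nesting of the original analysis (planes within
  scans within patients vs. crossed repeated measures) is implemented as
  a patient-level random intercept with interval and plane as nominal
  fixed effects — the wording of the source methods — and nothing finer.
* ROC optimality uses Youden's J because no criterion is stated in the
  source; the cut-off is only attained on the observed PD grid.
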
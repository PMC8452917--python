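# Methods

## Scope and representation

`coroflow` predicts steady-state hyperemic coronary hemodynamics — and from
them simulated FFR before and after virtual stenting — on a reduced-order
representation of the epicardial tree: each vessel is a centerline with
sampled lumen radius and a circular cross-section. This representation is
deliberate: the solver is one-dimensional, and the virtual-stenting
procedure is itself defined through circular cross-sections along the
centerline, so nothing in the pipeline requires a surface mesh. Child
branches attach to a parent at an arc position; a branch tip with no child
attached at it is an outflow boundary. Collateral loops and flow reversal
are outside the model (tree topology, non-negative flows only).

Units at every public interface are clinical (mm, mmHg, mL/min, g); the
solver converts to SI internally (1 mmHg = 133.322 Pa).

## Pressure-loss model

The drop along a radius profile r(s) carrying flow Q is the sum of

* a fully developed viscous (Poiseuille) term, `∫ 8μ/(π r⁴) Q ds`,
  integrated with the trapezoidal rule on the sample grid; and
* irreversible Borda–Carnot expansion losses. Lumen area A(s) = πr² is
  scanned for maximal strictly-increasing runs; each run from a throat
  A_min to a downstream maximum A_down contributes
  `(ρ/2) Q² (1/A_min − 1/A_down)²`, with Q taken at the throat interval.

Defaults: μ = 3.5 mPa·s, ρ = 1050 kg/m³ (Newtonian blood). Both terms are
positive and strictly increasing in Q, which makes the network solution
unique. Expansion runs are evaluated per inter-branch segment; a run
interrupted by a side-branch take-off is split at the take-off.
Contraction (entrance) losses are not modelled separately — the viscous
integral through the narrowing dominates them at coronary Reynolds numbers,
and the asymmetric treatment (losses on expansion only) is the standard
Borda–Carnot idealization.

## Boundary conditions

* **Inlet**: static pressure `P_in = MBP − 6.8 mmHg`, with
  `MBP = DBP + (SBP − DBP)/3`; the fixed offset models the systemic
  pressure effect of adenosine-induced hyperemia.
* **Resting flow**: `Q_rest = c · m^e` with LV mass m in grams, e = 0.75
  and c = 2.6 mL·min⁻¹·g⁻³/⁴. The coefficient is chosen so a typical 114 g
  left ventricle receives ≈ 0.8 mL·min⁻¹·g⁻¹ at rest; both are
  configurable.
* **Hyperemia**: microvascular resistance falls to 0.21× its resting
  value, equivalently a target hyperemic inflow `Q_hyp = Q_rest / 0.21` at
  the fixed inlet pressure.
* **Outlets**: each outlet i carries a lumped resistance R_i to a shared
  reference pressure P0 (default 0 mmHg, venous). Initial resistances
  apportion flow by a Murray-type diameter power,
  `w_i = d_i^k / Σ d_j^k` with k = 3 and d_i the mean lumen diameter over
  the outlet's last three samples, via `R_i = (P_in − P0)/(w_i Q_hyp)`.
  The d^k allocation is a declared stand-in for "resistance proportional
  to branch size"; k is configurable.

## Network solve and calibration

Given {R_i}, the solver finds outlet flows such that along every
root-to-outlet path `P_in − Σ ΔP(path) = P0 + R_i Q_i`. The residuals are
driven to zero by a damped Newton iteration: the Jacobian is the (small,
symmetric) matrix of shared-path stiffnesses `Σ (g + 2 c Q)` over the
common path prefix of each outlet pair, plus R_i on the diagonal, and each
step is scaled by the relaxation factor α (default 0.5). A plain per-outlet
under-relaxed resistance update was tried first and stalls for severe
stenoses because outlets are strongly coupled through the shared trunk; the
Newton form converges in ≈ 2–20 iterations at every severity while leaving
the fixed point — which is scheme-independent — unchanged. Tests verify
that α ∈ {0.25, 0.5, 1.0} reach the same solution.

The calibration loop then rescales all R_i by a common factor β, updated
multiplicatively with under-relaxation, `β ← β (Q_total/target)^α`, until
total outflow matches Q_hyp to 0.1% (relative tolerance 1e-3). Total
outflow is monotone decreasing in β, so the outer fixed point is unique.
Calibration runs on the as-imaged (stenosed) tree by default
(`calibration_mode="as_imaged"`); post-stent runs recalibrate on the
stented tree by the same protocol, so each simulation is self-contained.
The alternative reading — calibrate resistances on a healthy reference
tree and let inflow through the diseased tree emerge — is available as
`calibration_mode="reference_healthy"` with an explicit `reference_tree`.

**Feasibility.** Forcing the full hyperemic target through a tree whose
*only* supply path contains a severe stenosis has no solution with positive
resistances (the epicardial drop alone exceeds the driving pressure);
`calibrate_total_flow` detects this and raises a convergence error rather
than returning an unphysical state. In anatomically realistic networks the
lesion sits on one vessel of a larger perfusion territory, healthy outlets
absorb the rescale, and calibration is well posed at any severity — the
synthetic cohort is constructed this way (see below).

Numerical details: sample grids at 0.5 mm spacing; child attachments snap
to the nearest parent sample for flow splitting; inner pressure-residual
tolerance 1e-8 (relative to driving pressure); outlet flows floored at
1e-15 m³/s to keep the iteration in the physical domain; maximum 500
iterations for either loop, with the residual history attached to any
convergence error.

## FFR readout

Simulated FFR at a site is the interpolated site pressure divided by the
model inlet pressure (the simulated hyperemic aortic pressure, MBP − 6.8).
The clinical threshold is inclusive: FFR ≤ 0.80 classifies as
ischemic. Values above 1 by more than 1e-6 (numerical noise only) are
clipped with a warning.

## Virtual stenting

`deploy_stent` replaces the radius profile on `[P*, D*]` with an
interpolating cubic B-spline through control radii: the original lumen
radii at P* and D* (so the stent blends into the vessel) and the stent
radius at stations every 3 mm strictly inside the span (a station falling
exactly on D* is excluded; a 26 mm span therefore has 8 interior stations).
Geometry outside the span is untouched, and the input tree is never
mutated. Overlapping/tandem stents are applied sequentially in
proximal-to-distal order.

`auto_size_stent` operationalizes "maximal change of slope" as the direct
three-point second difference of the lumen-area curve on the sample grid
(a smoothed gradient-of-gradient was tried and displaces the curvature peak
by two samples; the direct stencil recovers constructed lesion shoulders to
within one sample spacing and the reference diameter to within 2%).

Lesions are typed with precedence ostial > bifurcation > tandem-member >
focal: ostial within 3 mm (configurable) of the branch origin; bifurcation
when the lesion spans a child take-off; tandem when ≥ 2 lesions of ≥ 50 %DS
share a root-to-outlet path. The precedence order is a declared convention;
the clinical definitions list categories without one.

## Synthetic anatomy and cohorts

`generate_tree` grows seeded binary trees satisfying Murray's law exactly
at every bifurcation (`d_p^γ = Σ d_c^γ`, γ = 3), with daughter asymmetry
drawn uniformly from (0.6, 1.0), branch lengths from (15, 40) mm, constant
radius per branch, and truncation where a daughter would fall below 1.5 mm
diameter (the usual CT segmentation floor). Stenoses are cosine tapers with
compact support whose severity maps exactly to %DS at the throat.

`generate_validation_cohort` draws per-patient physiology uniformly from
mean ± SD ranges typical of an intermediate-disease cohort (SBP 127 ± 14,
DBP 74 ± 11 mmHg, LV mass 114 ± 32 g), places one lesion of 30–90 %DS
mid-way along the larger daughter of the root trunk (the LAD equivalent of
a left-main-fed network), simulates FFR just proximal to that daughter's
bifurcation before and after an idealized stent (lesion restored to its
reference profile), and emits a pseudo-invasive FFR equal to the simulated
value plus a configurable bias and Gaussian noise, truncated to (0, 1].
Lesion length defaults to 20 mm (clinical treated-lesion lengths cluster
around 26 ± 11 mm stents), shortened when the host branch cannot contain
the taper.

What the generator does **not** emulate: 3-D curvature and tortuosity,
non-circular / eccentric lumina, diffuse disease, plaque composition,
myocardial territory geometry, and serial-lesion interaction beyond what
the 1-D loss model captures. Passing tests therefore demonstrate internal
consistency of the physics, geometry edits and statistics under controlled
conditions — not clinical accuracy on real anatomy. In particular the
synthetic severity→FFR map is milder than clinical experience for a given
visual %DS (clinical grading overestimates geometric narrowing), so
cohort-level FFR means sit higher than published patient cohorts.

## Statistics

* Pearson correlation with two-sided p (scipy).
* Bland–Altman: differences x − y, bias = mean, limits of agreement
  bias ± 1.96·SD (sample SD); the 1.96 multiplier is the declared
  convention behind "95% limits of agreement".
* Diagnostics at the 0.80 threshold: sensitivity TP/(TP+FN), specificity
  TN/(TN+FP), PPV, NPV, raw accuracy, kept at full precision and rounded
  to integers only for presentation; an empty denominator raises rather
  than silently yielding NaN.
* Reproducibility: ICC as the two-way, absolute-agreement, single-measure
  estimator (pingouin's ANOVA-based ICC(A,1), whose point estimate is the
  same under the random- and mixed-effects readings), and
  COV = SD(paired differences)/grand mean × 100 with a seeded percentile
  bootstrap 95% CI (2000 resamples). The Bland–Altman convention for
  repeated measures is second pass minus first. Percentile bootstrap CIs
  under-cover at very small n (≈ 10); treat them as descriptive there.

## Known limitations

* Steady-state only; no pulsatility, autoregulation, or microvascular
  disease.
* No flow reversal or collateral supply; severe multi-vessel configurations
  that would reverse flow are out of scope.
* The d³ outlet allocation and the 0.21 hyperemic factor are population
  constants, not personalized.
* Stent mechanics (struts, recoil, vessel compliance, curvature change)
  are not modelled; stenting is a pure lumen-geometry edit.
* Problem sizes in the shipped tests (trees of 7–31 branches, cohorts of
  ≤ 200 synthetic vessels at 0.5 mm resolution) were chosen to exercise
  every code path at interactive speed; all scale linearly if enlarged.
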
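# Methods

This note documents the models, numerical choices, and limitations of
`plaquemech`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Geometry model

A cross-section is four nested closed contours — lumen, internal elastic
membrane (IEM, intima/media boundary), external elastic membrane (EEM,
media/adventitia boundary), and the adventitia–periadventitia interface
(ADV) — plus optional lipid and calcification component contours inside the
wall. Coordinates are 2D Cartesian millimetres, slice plane x–y, contours
counter-clockwise with implicit closure, origin conventions anchored at the
lumen centroid. Validation enforces ≥8 points, simplicity, orientation,
strict nesting (every vertex of an inner contour inside the outer polygon),
components between lumen and ADV, and pairwise non-overlapping components.
The component vocabulary is restricted to lipid and calcification — the
only inclusions the mechanical model distinguishes.

The 3D *thin-slice model* extrudes one cross-section by 0.5 mm, which
approximates full-3D behaviour at near-2D cost: the slab is thin enough
that plane sections remain plane under the prescribed axial stretch.

## Synthetic cohorts

The generator emulates segmented intravascular-OCT output. Defaults are
typical coronary dimensions: lumen radius 1.0–2.0 mm, intima 0.05–0.6 mm
with an eccentric cos²-profile thickening over a random 90–220° sector,
media 0.1–0.25 mm, adventitia 0.15–0.35 mm, low-order Fourier waviness
(2–3% amplitude) on each boundary. A lipid pool is an annular sector buried
in the thickened intima: its inner boundary sits at the drawn cap depth
(clipped to ≥1.1× the configured 0.05 mm minimum so the fibrous-cap
guarantee survives contour waviness) and its outer boundary at 85% of the
local intima thickness, with smoothly tapered ends; the pool arc (30–120°)
shrinks automatically until it fits inside the intima. A small elliptical
calcification (probability 0.2) is placed near the deep intima/media border
away from the pool. Per-patient systolic pressure is drawn from
101–175 mmHg, the range of the bundled reference cohort; 10 slices per
patient mirrors per-plaque sampling in image-based studies. Geometry that
cannot satisfy the invariants is redrawn, up to 100 attempts, then fails
loudly.

Everything is a deterministic function of `(seed, patient_index,
slice_index)` through a `SeedSequence`, so cohorts are reproducible
bit-for-bit and slices can be regenerated independently.

What the generator does **not** emulate: segmentation noise and contour
jitter at the pixel scale, guide-wire shadow dropouts, non-star-shaped
lumina, multiple lipid pools per slice, plaque erosion/rupture morphology,
and any longitudinal correlation between neighbouring slices. Passing tests
on synthetic cohorts therefore demonstrate the *pipeline's* correctness and
the qualitative layered-wall mechanics, not clinical magnitudes.

## Constitutive models

Each tissue is a modified Mooney–Rivlin solid,

    W_iso   = c1 (I1 − 3) + c2 (I2 − 3) + D1 [exp(D2 (I1 − 3)) − 1]
    W_aniso = W_iso + (K1/K2) [exp(K2 (I4 − 1)^2) − 1]

with I₁, I₂ the invariants of C = FᵀF and I₄ = λθ²cos²φ + λz²sin²φ the
squared fiber stretch at angle φ from the circumferential direction.
Parameter values (kPa where dimensional) follow published layer-specific
coronary/iliac material curves: intima c₁=−169.23, c₂=177.40, D₁=2.4,
D₂=13, K₁=32, K₂=36; media c₁=−67.25, c₂=35.01, D₁=17, D₂=2, K₁=7, K₂=4,
φ=24.9°; adventitia c₁=−94.44, c₂=102.42, D₁=0.8, D₂=10, K₁=10, K₂=40,
φ=75.3°; lipid c₁=0.5, c₂=0, D₁=0.5, D₂=1.5; calcification c₁=920, c₂=0,
D₁=360, D₂=2 (both isotropic).

Design choices:

* **Intima fiber angle.** The intima's φ is not given with its other
  constants; we set φ = 0° (circumferential fibers), the convention of the
  material-curve literature the constants derive from. This is a modelling
  assumption, flagged here deliberately.
* **Fiber families.** One symmetric ±φ pair in the θ–z plane. The pair
  shares the printed I₄ because the antisymmetric cross terms cancel; the
  general-deformation structure tensor is H = cos²φ e_θe_θᵀ + sin²φ
  e_ze_zᵀ and I₄ = H : C.
* **Tension-only fibers.** The exponential term is active only for I₄ > 1,
  the standard convention avoiding fictitious compressive fiber support.
* **Negative c₁.** With c₁ < 0 < c₂ the energy can be non-convex far
  outside the physiological range; an exponent guard aborts evaluation
  when D₂(I₁−3) or K₂(I₄−1)² exceeds 50, and the solver treats that as a
  rejected trial step.
* **Single-layer wall material.** The single-layer model assigns the
  intima parameters to the whole wall (configurable to any registry
  material). The comparison study's reference results do not state this
  choice; the test suite also exercises media-for-whole-wall.

Near-incompressibility in the solver uses the isochoric split: the
deviatoric stress comes from W evaluated on distortional invariants
(Ī₁ = J^{-2/3}I₁, Ī₂ = J^{-4/3}I₂, Ī₄ = J^{-2/3}I₄) plus a volumetric
penalty κ(J−1)²/2 with κ = 1000·max(|c₁|,|c₂|,D₁) per material and a floor
of 5000 kPa. The floor matters only for lipid (otherwise κ = 500 kPa would
permit |J−1| ≈ 3% at physiologic load, violating the incompressibility
contract). The closed-form uniaxial stress–stretch curves use exact
incompressibility with both lateral normal stresses zero (plane-stress
uniaxial protocol — the protocol behind the published curves is not stated,
and this is the recorded assumption), the lateral stretch resolved by a
bracketed root-find.

A consequence of the printed constants worth knowing: the intima's fiber
term (K₂ = 36 at φ = 0°) overtakes the calcification curve beyond
λθ ≈ 1.12, so ordering statements like "calcification is the stiffest
tissue" hold only below that stretch.

## Finite-element model

* **Mesh.** Rays from the lumen centroid through each boundary contour
  partition the wall into quadrilateral columns (star-shapedness required,
  and checked); each layer annulus is subdivided radially and extruded into
  trilinear hexahedra. Elements whose centroid falls inside a component
  contour are relabeled lipid/calcification — a voxelization whose volume
  error is one element band (tested: ≤15% per slice, unbiased on average,
  at 144 rays × 5 radial subdivisions per layer). Each element carries an
  orthonormal (circumferential, radial, axial) frame from its centroid
  direction.
* **Element technology.** Total-Lagrangian trilinear hexahedra with
  selective reduced integration in the mean-dilatation spirit: deviatoric
  stress at 2×2×2 Gauss points, volumetric penalty at the element centroid.
  This controls volumetric locking without a mixed formulation; the
  incompressibility contract |J−1| < 10⁻² is asserted on the element-level
  (centroid) volume ratio, which is the quantity the penalty controls —
  unpenalized Gauss-point J fluctuates a few percent around it.
* **Loads and constraints.** Follower pressure on the lumen surface
  (current-configuration consistent load, 2×2 face quadrature, load
  stiffness included in the tangent); z⁻ face fixed axially; z⁺ face given
  the uniform axial-stretch displacement (plane sections); the three
  in-plane rigid modes (two translations, one rotation — a closed annulus
  with axially constrained faces has exactly three) removed by
  Lagrange-multiplier constraints on mean displacement and mean in-plane
  moment, which restrain no deformation.
* **Solution.** The load ramps through a doubling schedule (default 11
  increments from 1/1024 of full load): these tissues are softest at the
  reference state and stiffen exponentially, so equal increments waste
  effort in step halving. Newton iteration per step with a backtracking
  line search, consistent material tangent by one-sided numerical
  differentiation of the second Piola–Kirchhoff stress (step 10⁻⁷),
  convergence at residual < 10⁻⁸ of the load norm, automatic step halving
  to 1/64 of an increment, and a secant predictor between steps.
* **Recovery.** Cauchy stress and Green–Lagrange strain at nodes by
  shape-function-weighted Gauss-point averaging; reported scalars are the
  maximum principal values. Strain is measured relative to the pre-shrunk
  (stress-free) configuration; the strain measure behind the reference
  tables is unnamed, and Green–Lagrange (with Cauchy stress in kPa) is the
  recorded assumption consistent with their magnitudes.

**Verification** (all asserted in the suite): zero load ⇒ zero field;
thin-wall (r/t = 20) mean hoop stress within 5% of the Laplace estimate;
three-layer concentric inflation within 5% of the peak of a semi-analytic
incompressible layered-cylinder solution at 60/100/140 mmHg; constrained
reactions balance the applied load to 10⁻⁶; rigid rotation of the geometry
rotates the fields; and the strongest end-to-end check of the layer
machinery — with identical parameters in all three layers, multilayer and
single-layer solves on the same mesh coincide node-wise below 10⁻⁸ mm.

## Preconditioning (start-shape recovery)

Imaged geometry is acquired pressurized and axially stretched. The
computational start shape is recovered by (a) an axial shrink by 1/1.05
paired with a 5% stretch during the solve, and (b) a circumferential
pre-shrink: a single scale factor s about the lumen centroid, found by a
bracketed secant/bisection root-find on s ∈ [0.85, 1.0] so that the
re-inflated lumen circumference matches the imaged one within 0.5%
(lumen circumference is the matching criterion because a uniform scale has
one degree of freedom, making the root-find well-posed). The shrunk
configuration is stress-free by construction. Successive root-find iterates
warm-start the solver by transporting the previous deformed configuration,
rescaled to the target circumference — the converged deformed shape barely
changes between iterates, so these solves are one-shot Newton. Typical
convergence is 2–3 inflation evaluations. A wall so compliant that it would
need s < 0.85 raises a bracket error rather than silently relaxing the
bound; the cohort driver then drops that slice with a warning (patients
lose at most half their slices before being dropped entirely), mirroring
the quality-based slice removal of imaging studies.

## Extraction and statistics

Lumen and out-wall (ADV) contours are split into four angular quarters
about the lumen centroid (boundaries at 0°/90°/180°/270° from +x —
configurable; the reference figure gives no anchor) and each quarter
sampled at 25 equal arc-length mid-steps, giving 100 paired nodes per slice
per surface, paired by (quarter, within-quarter index). Equal steps are
taken *within each quarter independently*, so a long out-wall quarter gets
wider steps — this is what prevents eccentric thick plaques from distorting
the pairing. Cap nodes are lumen nodes whose pairing segment crosses a
lipid contour; calcification defines no cap; no cap-thickness threshold is
applied (pure overlap — the delimitation used by the reference study is
unstated). Solver ring values are interpolated periodically by angle onto
the extraction nodes.

Per-patient scalars are the max and mean over all pooled nodes (10 slices ×
100 nodes at full scale); relative differences are 100(multi −
single)/single; cohort rows are mean ± sample SD (n−1) over patients, with
the summary-row relative difference computed from the cohort means (this
convention reproduces the published summary rows exactly; averaging
per-patient differences does not). The operative significance test is the
two-sided paired t test per table column, preceded by a one-sample KS check
of the differences against a fitted normal (asymptotic p, no Lilliefors
correction, matching common applied practice); α = 0.05 and no
multiple-testing correction. ANOVA appears in the pipeline only as this
paired comparison's cross-check; no multi-way ANOVA is reported anywhere,
so none is implemented.

## Problem sizes and defaults

Cohort studies default to 36 rays × 2 radial subdivisions per layer × 1
slab (216 wall elements, ~1500 degrees of freedom per model) — enough that
the quarter-sampled ring values are mesh-converged at the few-percent level
while a full multilayer+single-layer slice pair solves in ~15 s on one
CPU. Verification tests use 48 × 3 × 1; the mesh-refinement study shrinks
the characteristic in-plane element size by 10% per step until the peak
inner-wall stress changes by <2%. The synthetic comparison study shipped in
the acceptance script uses 5 patients × 4 slices; at that scale every
effect direction of the reference study reproduces in 100% of patients
with paired-t p < 0.05.

## Known limitations

* Thin-slice models are independent per slice; no 3D reconstruction across
  slices, no fluid–structure interaction, no cyclic loading.
* Residual stress / opening angles are not modeled; the uniform pre-shrink
  is the only initial-stress recovery, so absolute stress levels near the
  inner wall are likely overestimated relative to a residually stressed
  wall.
* The single-layer material assignment (intima everywhere) is an
  assumption; magnitudes of the multilayer-vs-single-layer differences on
  synthetic cohorts are larger than the clinical reference values, whose
  geometries are unavailable — only effect directions are comparable.
* Centroid-based component labeling quantizes lipid pools to element
  bands; cap stress at very thin caps needs finer radial resolution than
  the cohort default.
* The ray mesh requires star-shaped contours about the lumen centroid;
  severely concave lumina (rare in practice) are rejected rather than
  meshed.
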
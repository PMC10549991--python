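# Methods

This note documents the models behind `scaffsim`, the defaults and why they
were chosen, what the reduced-order stand-ins do and do not represent, and
the numerical conventions that matter when comparing results.

## Problem setting

A cylindrical 0/90 strand-lattice hydrogel scaffold (direct-ink-written
alginate–gelatin) sits in a bioreactor well and is compressed by a piston
moving sinusoidally at 1 Hz with amplitudes of 1–10% of the scaffold
height.  Mesenchymal stem cells seeded on the scaffold surface sense the
solid distortion (octahedral shear strain, OSS) and the shear stress of the
displaced culture medium (wall shear stress, WSS).  The mechano-regulatory
stimulus S = OSS/a + WSS/b (a = 0.0375, b = 10 mPa) classifies each surface
node into no-differentiation (S ≤ 0.01), bone (≤ 1), cartilage (≤ 3),
fibrous (≤ 6) or over-stimulated (> 6); bands are closed on the upper side,
taken literally from the threshold inequalities as printed, and
`PhenotypeThresholds` is the single source of truth for them.

A full treatment requires a transient one-way FSI co-simulation (hyperelastic
FE solve for the solid, moving-mesh finite-volume CFD for the medium).
`scaffsim` deliberately replaces the two solvers with reduced-order field
models while keeping the entire downstream scoring machinery — averaging,
stroke-peak selection, classification, amplitude sweep, viability
diagnostics — exact and testable, and provides importers so that genuine
solver exports can be scored through the identical code path.

## Geometry

`ScaffoldSpec` defaults: strand radius R = 0.35 mm, in-plane spacing
Y = 1.4 mm, vertical layer pitch h = 1.12 mm, envelope D = 10 mm,
H = 4.8 mm.  Layers are packed from the bottom (first centre at R, pitch h)
while the lattice bounding box stays within H, giving 4 layers at centre
heights 0.35/1.47/2.59/3.71 mm; the count is overridable (`n_layers`)
because the source geometry does not pin it.  Even/odd layers run along
x/z; within a layer strands sit at offsets mY clipped to the envelope
circle (7 strands per layer at the defaults).  With h = 1.12 > 2R = 0.7,
adjacent layers do not touch; an explicit `fusion_offset` (default 0)
reduces the effective pitch when interpenetrating, fused strands are
wanted.

`build_scaffold_surface` samples each strand's lateral cylinder surface
with `resolution` nodes around the circumference and matched axial spacing,
so patches are approximately square, total area is resolution-independent
(to well under 1%), and refinement is isotropic.  Nodes buried inside a
neighbouring strand are removed.  Region tags: `intersection` for nodes
within ±R along the strand axis of a crossing strand of an adjacent layer
(the crossing strand's lateral footprint — with Y = 4R a wider band would
swallow the entire strand), otherwise `strand_top` / `strand_bottom` for
normals within 45° of vertical, else `strand_free`.  At resolution 16 the
reference lattice yields 26,304 nodes (about half tagged `intersection`),
the mesh used for the shipped studies; resolution 8 (~6.6k nodes) is used
in fast tests.

Coordinates: y vertical, origin at the scaffold bottom centre; lengths in
mm throughout, converted to SI only inside flow formulas.

## Loading

Piston displacement y(t) = −(A/2)(1 − cos 2πft), A = a_c·H.  The 1 − cos
form is chosen so displacement *and* velocity start at zero (a piston
starting at rest); a pure sine would imply a nonzero initial speed.  The
lowest position −A occurs at t = 1/(2f), the peak speed Aπf at quarter
periods.  The stroke phase is "downward" for t mod T ∈ [0, T/2) and
"upward" otherwise; the turning point T/2 is assigned upward so the
upward-stroke peak search starts at the lowest position.  Default time
step dt = 0.004 s (251 samples per 1 Hz cycle), the coarsest step that a
moving-mesh time-step criterion comfortably admits for these speeds;
`check_timestep` implements the strict bound dt < Δs/v_max.  One cycle is
simulated by default: the material model is not viscoelastic, so further
cycles repeat the first.

## Solid mechanics

One-term Ogden strain energy in principal stretches with deviatoric
stretches λ̄ᵢ = J^{-1/3}λᵢ and volumetric terms (1/dᵢ)(J−1)^{2i}; the
defaults μ₁ = −5.8 kPa, α₁ = −1.3, d₁ = 0 describe the incompressible
hydrogel (G₀ = 3.77 kPa).  Incompressible terms are only well-posed at
J = 1 and any isochoric violation raises rather than silently dropping the
volumetric energy.  Homogeneous uniaxial compression by a fraction e under
incompressibility has λ = (1−e, (1−e)^{-1/2}, (1−e)^{-1/2}) and the closed
form OSS(e) = (2/3)√2((1−e)^{-1/2} − (1−e)); `uniaxial_nominal_stress` is
the analytic dW/dλ₁ along that path (small-strain limit −3G₀e), kept as a
material sanity check.

## Reduced-order nodal fields (what they are and are not)

Both stand-in fields are separable space–time models: a homogeneous time
profile times seed-fixed per-node factors that are constant over the cycle.
They reproduce the *structure* of the solver fields — strain concentrated
at strand crossings, right-skewed nodal histograms that widen with
amplitude, WSS proportional to piston speed and vanishing whenever the
piston is momentarily at rest — but none of the solver physics: no contact
mechanics, no pore-scale flow pattern, no phase lag between nodes, no
mesh-dependent artefacts.  Consequently the amplitude-sweep percentages
shipped with this package characterise the reduced-order model, not a
validated FE/CFD solution; trends (bone fraction falling with amplitude,
cartilage peaking mid-sweep, fibrous growing from mid amplitudes,
over-stimulation confined to the largest amplitudes) are the meaningful
output, individual percentages are not.  Imported solver fields go through
the identical scoring path and inherit none of these caveats.

**OSS field.**  OSS_node(t) = OSS(e(t)) · f_node with e(t) = |y(t)|/H (the
amplitudes are defined on the scaffold height) and
f_node = g_region · ξ_node.  Relative region gains: 1.6 at intersections,
0.5 on free spans, 1.0 on top/bottom faces; ξ is lognormal with median 1
and σ_log = 0.35.  The factor field is then rescaled by a deterministic
constant so its expected surface mean equals `surface_strain_ratio` = 0.5:
the free surface sheds distortion relative to the bulk, and this
calibration keeps the 10%-amplitude nodal histogram below the 0.225
strain-viability bound except in the extreme lognormal tail (measured
fraction above 0.225 at the 10% evaluation frame: ~2×10⁻⁴), which is the
reported structure of such surface strain fields.  Setting
`normalize_mean=False` (and unit gains, σ = 0) makes every node carry the
affine value exactly.

**WSS field.**  Piston speed → displaced volumetric rate
Q = |v|π(D_p/2)² → characteristic pore velocity U = Q/(φπ(D/2)²) with the
lattice open-area fraction φ = (Y−2R)/Y = 0.5 → plane-Poiseuille slot wall
stress WSS = 3μU/b with half-gap b = (Y−2R)/2 = 0.35 mm.  This chain is an
order-of-magnitude, peak-scale estimate (≈ 37.5 mPa at 10% amplitude).
Node factors are lognormal (σ_log = 0.5) rescaled so their mean equals
`surface_mean_ratio` = 0.45 of the slot value: much of a real surface sits
in sheltered low-gradient zones, and this puts the area-averaged surface
WSS at maximum compression near 17 mPa with only an extreme tail (~10⁻³ of
nodes) beyond the 57 mPa apoptosis stress.  The characteristic length for
the Reynolds check is the clear pore width Y − 2R = 0.7 mm; at 10%
amplitude Re ≈ 1.46, safely laminar (< 3).

Node factors for the two fields use decorrelated child seeds spawned from
the pipeline seed (numpy PCG64), so the strain and flow heterogeneity
patterns are independent, reproducible bit-for-bit from the seed, and
shared across all amplitudes of a sweep — differences between sweep rows
reflect the loading alone.

## Scoring pipeline

Per frame: OSS_avg is the arithmetic nodal mean, WSS_avg the area-weighted
mean, and S_avg = OSS_avg/a + WSS_avg/b — average first, then combine, in
that order.  `detect_peaks` takes the argmax of S_avg restricted to each
stroke (ties break toward the earlier time); the phenotype map is evaluated
at the S_Max2 frame (upward stroke), with S_Max1 evaluation available via
`evaluate_at="s_max1"` — in the separable model the series is mirror-
symmetric about the half period, so the two peaks agree in value and the
choice is immaterial; with imported solver fields they can differ.
Node-level classification uses the node-level fields of the evaluation
frame, never the averages.  Distributions default to node counting (one
node ≈ one cell); area weighting is available since the basis of reported
percentage plots is ambiguous.  Viability flags (OSS > 0.225 strain death,
WSS > 57 mPa apoptosis, WSS outside [0.01, 60] mPa differentiation window)
are diagnostics only and never alter the S-based labels.

## Synthetic data and ground truth

`scaffsim.synthetic` generates the same separable fields on a uniform
random node cloud with a configurable intersection fraction (default 0.3)
and returns the full ground truth (regions, node factors, time profiles),
so averaging, peak selection, file round-trips, node matching and
parameter recovery are all testable against known answers.  Mock solver
exports come in three dialects — `conformal`, `permuted` (seed-fixed row
shuffle of the CFD set) and `jittered` (additional coordinate perturbation
of stated magnitude) — exercising the matcher's tolerance contract.
`recover_sigma` estimates the lognormal spread from a single peak frame:
the factors are time-constant, so the unknown time profile cancels in the
log spread; region gains are removed by within-region centring.  At 10⁴
nodes the estimate lands within ±0.02 of σ = 0.35 (MLE standard error
σ/√(2n) ≈ 0.0025).

## File formats and node matching

CSV is the canonical interchange (documented schema, `%.17g` floats and
round-trip parsing so write→read is bit-exact); a minimal ASCII VTU
unstructured-grid dialect (one vertex cell per node, PointData fields,
TimeValue field data) supports visualisation round-trips.  `match_nodes`
reconstructs the FE↔CFD correspondence on a conformal interface by
k-d-tree nearest neighbour with tolerance 10⁻⁶ × bounding-box diagonal by
default; two candidates within tolerance of one node, or one node claimed
twice, raise as ambiguous; strict mode turns any unmatched node into an
error reporting the count and worst distance.  Matching 10⁵ permuted and
sub-tolerance-jittered nodes recovers the exact bijection in seconds.

## Problem sizes and determinism

Shipped studies use the resolution-16 surface (26,304 nodes), dt = 0.004 s
(251 frames) and ten amplitudes; a full sweep takes ~2 s on one CPU, so no
scaling tricks are needed.  Unit tests run on the resolution-8 surface and
coarser time grids.  Every stochastic quantity is driven by an explicit
integer seed; the same configuration and seed reproduce output files
byte-for-byte.

## Known limitations

- The reduced-order fields are separable in space and time; real transient
  fields have node-dependent phase and amplitude-dependent shape.
- The affine OSS base ignores bending and contact stress concentrations
  beyond the static region gains.
- The escape-area flow model uses a single uniform pore velocity; no
  entrance effects, no vortices, no dynamic-mesh feedback.
- Viscoelasticity, tissue growth across cycles and two-way FSI coupling
  are out of scope by design.
- Strands of adjacent layers are tangent-free at the default pitch; fused
  lattices require an explicit `fusion_offset` and the contact fillet
  geometry is not modelled, only node removal inside overlaps.
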
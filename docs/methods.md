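# Methods

## Scope and model overview

The package implements a radiation-free planning chain for spring-assisted
cranioplasty: (i) morphometric measurement operators (surface-distance
tissue thickness, suture-plane geometry, population averaging, BPD/OFD/CI),
(ii) construction of a simplified "S model" skull shell from a head-surface
scan, (iii) a quasi-static viscoelastic shell finite-element simulation of
spring expansion, and (iv) a deterministic synthetic-phantom generator that
provides ground truth for all of the above. Patient imaging is out of
scope; a pre-segmented skull surface can be ingested, but no DICOM/CT
processing and no automatic landmark detection are provided (landmarks are
inputs).

## Geometry

All lengths are millimetres, all API angles degrees. The base plane is the
exact plane through nasion and the two tragions, normal toward the vertex;
the midline plane contains the base normal and the nasion–tragion-midpoint
axis. Mesh cutting uses plane slicing with exact splitting of straddling
triangles; because the underlying slicer emits one cut vertex per incident
face, all cut/assembly paths weld coincident vertices at 1e-6 mm.
Region splitting slices the shell along the two suture planes offset by
±half the suture width, so the bands have exact edges at any mesh
resolution; T-vertices created where a slicing plane crosses a
neighbouring region's border are healed by splitting the adjacent face.
Slicing can leave sliver triangles; a link-condition-safe edge-collapse
pass removes triangles with normalised radius ratio below 0.05 before the
shell is used for simulation. Collapses move interior vertices to edge
midpoints, so a rebuilt shell can sit up to a few hundredths of a
millimetre off the analytic surface — negligible against every tolerance
used here, but the reason on-surface assertions in the tests use 0.05 mm
rather than machine precision.

The suture planes are realised by the point-angle construction: the
coronal plane passes through the foot B = A + AB%·AP, perpendicular to the
midline plane, tilted so that the in-midline angle at B between the ray
B→A and the cranial-going trace equals α; the lambdoid plane mirrors this
at L with β against L→P. When bregma/lambda are supplied (ingested skull
surfaces), the feet are recovered by casting the trace of the configured
angle back from the landmark to the AP line, so the plane passes through
the landmark exactly. Measuring an assembled model reduces each suture
band to its least-squares plane through the band-face centroids; the
topmost band vertex near the midline, projected onto that plane, serves as
the bregma/lambda estimate. Band width is measured as band area divided by
the length of the band's mid-plane section (the mean width of a ribbon) —
an estimate independent of how the band was constructed.

Osteotomies: the parietal region is sliced along the four kerf-boundary
planes at ±(offset ± kerf/2) from the midline and the strip faces between
the AP extents are removed, leaving two gaps with exact lateral edges.
The osteotomy geometry (lateral offset 25 mm, kerf 1 mm, extents
0.30–0.80 of AP, notches at 0.25/0.75 of the cut) is configuration, not
anatomy: surgical practice runs the cuts essentially from the coronal to
the lambdoid suture, and the default extents reflect that — shorter cuts
leave bone bridges that rigidify the flaps and suppress expansion.
Spring notches are the boundary vertices on the lateral edge of each gap
within 5 mm of the configured fraction along the cut; the spring attaches
at the vertex nearest each notch set's centroid.

## Thickness and outcome metrics

"Local surface distance" is unsigned nearest-point distance (exact
point-to-triangle projection with a KD-tree candidate search over face
centroids), chosen over normal-ray casting for robustness on noisy scans.
Thickness statistics are restricted to vertices above a crop plane raised
by 25% of the skull height above the base plane, which excludes the skull
base and orbits. BPD and OFD are maximal extents of the supra-base-plane
surface along the lateral and AP directions respectively; CI = BPD/OFD.
Population parameters are arithmetic means with standard deviations; no
outlier handling. Spearman correlation uses exact permutation p-values up
to n = 9 and the t-approximation beyond.

## Shell finite elements

Flat three-node shell: constant-strain membrane plus discrete-Kirchhoff
(DKT) bending, exactly integrated with the three-midside-point rule, with
a drilling stiffness of 1e-3 times the peak bending diagonal. The element
was verified against the clamped-plate Kirchhoff series solution
(w_c = 0.005612 Pa²/D; 0.3% error at 2048 elements, the test asserts 5%).
Geometric nonlinearity is corotational: each element's rigid motion is
removed via a frame built from the deformed triangle (first edge + normal);
nodal rotations are global rotation matrices updated multiplicatively, and
the deformational rotation extracted per node is Ed^T R E0, valid for
deformational rotations well below 90° (flap rotations live almost
entirely in the element frames). The tangent is the rotated material
stiffness plus the spring geometric term; the element-level geometric
stiffness and corotational projector terms are omitted, so Newton
converges linearly (typically 5–10 iterations per step with a frozen
factorisation). Backtracking activates only on a tenfold residual
blow-up, because the frozen-tangent iteration routinely overshoots once
before contracting. Convergence demands a residual 2-norm below 1e-6
times the applied spring-force norm. Sum of reactions at clamped nodes
balances the applied spring forces to ~1e-9 relative in practice.

Viscoelasticity is a Prony series applied as uniform modulus relaxation
(constant Poisson ratio): per element, internal variables q_i per Prony
term evolve by the exact exponential update for piecewise-linear local
strain histories, stored in the co-rotating element frame. The long-time
limit reproduces the elastic solution at E∞ = E(1 − Σgᵢ) (verified to
2%; observed agreement is far tighter on the toy problems).

Springs are push-only linear force elements, F = max(0, k(L₀ − d)) along
the line between their attachment nodes, L₀ = 60 mm. Spring force ramps
linearly over the first second so the t = 1 s snapshot (POSTOP) is the
full instantaneous elastic response; five-day creep gives FU. The time
grid is four ramp substeps plus 40 logarithmic points from 1 s to
432 000 s by default. Contact between bone flaps, inertial effects,
intracranial loading and post-surgical growth are not modelled.

## Material and spring constants

The elastic/viscoelastic constants and per-model spring stiffnesses are
**documented placeholders**, not measurements: skull E = 421 MPa,
ν = 0.22, Prony (g = 0.45, τ = 2000 s); suture E = 8 MPa, ν = 0.45, Prony
(g = 0.60, τ = 10 000 s); spring stiffness S10/S12/S14 =
0.15/0.31/0.58 N/mm (ordered as wire-diameter⁴, nominal length 60 mm).
Users planning real cases must pin calibrated values in the configuration;
every result this package reports is self-consistent with these defaults
but their absolute magnitudes should not be read clinically. With the
default geometry (cuts 25 mm from the midline) the notch separation at
insertion is ~51 mm, so the springs exert only ~3 N and the simulated
shape change is small in absolute terms — the direction and ordering of
the effects (opening creep, BPD up, OFD down, CI rising through
PREOP→POSTOP→FU) are the validated content.

## Synthetic phantoms

The head phantom is a superellipsoid (exponent 2.4 by default) sampled on
a subdivided icosahedron: extents are OFD along AP, BPD laterally, and the
configured height above the base plane; scaphocephaly requires BPD < OFD.
The widest cross-section sits 0.35 × height above the base plane,
emulating the parietal eminence: a phantom widest exactly at the clamped
base rim could not change BPD under any load. The sampling sphere is
tilted 2° so that no vertex ring coincides with the base plane (an exact
tangency makes the cut rim non-manifold). Landmarks are analytic: nasion
and tragions on the base-plane section, bregma/lambda where the
constructed suture-plane traces pierce the surface (root-finding on the
superellipsoid radial function). The two-layer phantom offsets the skin
inward by the skin thickness and again by the skull thickness, so layer
thicknesses are known exactly. Default population distributions are
normal, centred on skin 2.8 ± 0.4 mm, skull 2.5 ± 0.4 mm, α 83 ± 4°,
β 68 ± 3°, AB% 0.30, LP% 0.25 (the AB%/LP% centres are package defaults —
no published population value exists for them).

What phantoms do not emulate: scanner noise and holes (only optional
Gaussian jitter), real suture waviness (bands are planar ribbons), the
anterior fontanelle, spatially varying tissue thickness, and genuine
infant skull material behaviour. Passing the recovery tests therefore
shows the *operators* are correct and mutually consistent, not that the
pipeline's accuracy on clinical scans matches any published cohort.

## Problem sizes and tolerances

Default phantom meshes use a 4 mm target edge length (≈5k head faces,
≈4.6k shell elements, ≈2.4k nodes); unit tests use 8–9 mm phantoms. The
full five-day simulation on the default phantom runs in about a minute on
one CPU. Geometric coincidence tolerance is 1e-6 mm; thickness recovery
is asserted to 5%, suture angles to 0.5°, band widths to 20%, FEM oracles
to 1–2%, and the Newton residual to 1e-6 of the spring-force scale.
Degenerate inputs (collinear landmarks, empty cuts, unconstrained systems,
constant correlation series) raise typed exceptions rather than returning
best-effort values.
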
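# Methods

## Scope and data model

`semiduct` analyses one membranous labyrinth whose endolymphatic fill
has been segmented and divided into 11 anatomical parts: three slender
ducts, three ampullae, the common crus, the simple crus, and the
anterior/posterior/common portions of the utricle.  Each part supplies
a closed volume mesh (endolymph volume), one or more open wall meshes
(wetted surface), and a landmark polyline tracing the central
streamline.  By package convention the lateral ampulla wall is split
into two surface files (the crista region interrupts it), giving the
12-surface / 11-volume file layout; a YAML manifest maps file names to
the canonical part identifiers and declares the unit (mm) and voxel
size.  Left and right labyrinths are separate geometries.

## Morphometry

Each part is reduced to a mean tube: cross-section `a = V/L`, wall
perimeter `p = S/L`.  The equivalent elliptic section `(A, B)` solves
`πAB = a` with Ramanujan perimeter equal to `p` (bisection on the axis
ratio, tolerance 1e-10; perimeters below the circular minimum — a
possible measurement artefact — are clamped to a circle with a
warning).  The wall-shape drag factor is the exact laminar-flow result
for an elliptic lumen, `λ = 4π(A²+B²)/(AB)`, which reduces to `8π`
for a circle; it is symmetric in the axes and strictly increasing in
their ratio.  Cross-sections are treated as piecewise constant per
part, matching the granularity of the part-wise volume and surface
data; wall end-caps are excluded from `S` by the fixture generator and
assumed negligible for segmented parts.

Circuits are composed from parts by a configurable table whose default
is: anterior = slender duct + ampulla + anterior utricle + common
crus; posterior = slender duct + ampulla + posterior utricle + common
crus; lateral = slender duct + ampulla + simple crus + common utricle
+ anterior utricle.  Chaining is by endpoint matching within five
voxel sizes, so part order in the table is irrelevant.  Loop
orientations are flipped so that the two circuits traversing a shared
segment (common crus: anterior/posterior; anterior utricle:
anterior/lateral) run through it in the same direction, making both
coupling coefficients positive.  From the closed loop come the vector
area `A_vec = ½Σ rᵢ×rᵢ₊₁` (origin-independent), the forcing vector
`g = 2ρA_vec`, and the radius of curvature `R = √(|A_vec|/π)`; `g` and
`R` depend only on the streamline and are therefore invariant under
wall dilation or contraction.

Segmentation imprecision is propagated by offsetting every wall vertex
along its area-weighted normal.  Observed variation of cross-section
*areas* is converted to an offset by the elliptic model: `δ` solves
`π(A+δ)(B+δ) = πAB(1+ΔA/A)` (smaller-magnitude root).

## Cupula finite elements

Each cupula is modelled as a flat plate of its central cross-section,
fully clamped along the outline (crista, ampulla walls and roof) and
loaded by a homogeneous pressure of 0.05 Pa.  Because cupulae are
thick (h/a up to ~0.5), the plate is solved under Mindlin–Reissner
theory with a shear correction factor of 5/6.  Elements are MITC4
quadrilaterals — transverse shear interpolated from edge-midpoint
tying points, which removes shear locking — with an MITC3 triangle
fallback.  A naively integrated bilinear element is retained behind a
flag purely as a locking regression reference (it underestimates the
thin-plate volume displacement by ~90 % on the benchmark mesh).

Meshing uses a structured O-grid (square core plus rings) valid for
cross-sections that are star-shaped about their centroid, which cupula
outlines are; ring radii are pinned to the cilia band heights so no
element straddles a band border, and thin bands always receive at
least one element across their width.  Mesh quality is checked against
a 20° minimum angle.

The linear system is Jacobi-equilibrated, factorised (SuperLU) and
iteratively refined until the normwise backward error
`‖r‖/(‖A‖‖x‖+‖b‖)` is below 1e-10.  (A plain `‖r‖/‖b‖` criterion at
that level is unreachable in double precision on fine thin-plate
meshes, where the residual floor is `u·κ`; the backward error is the
standard well-posed measure.)

Outputs: volume displacement `ΔV = ∫w dA` (element quadrature), the
stiffness `k = ΔP/ΔV` (Pa/mm³ ≡ g·s⁻²·mm⁻⁴), and the transfer factor
`ε = Δθ/ΔV` in mdeg per nL.  `Δθ` is the area-weighted mean of
`arctan(w/ℓ)` over the band of the section within cilia reach `ℓ` of
the outline — the tilt of a cilium of length `ℓ` whose tip follows the
local cupula displacement; bands are nested (`ℓ = 60 µm` covers the
0–30 and 30–60 µm strips).  Both `k` and `ε` are verified against the
exact axisymmetric Mindlin solution of the clamped disc,
`w(r) = q(a²−r²)²/64D + q(a²−r²)/(4κGh)`, which the thin limit reduces
to the Kirchhoff benchmark.

A consequence worth stating explicitly: on a clamped plate `w`
vanishes at the band's outer edge, so the band mean of `w` grows
slightly faster than linearly with `ℓ` and `ε` *increases* weakly with
cilia length (about +1 % from 30 to 90 µm on the thick reference
disc, more for thin plates where bending dominates).  The intuition
that shorter cilia give a larger ε holds only for a deflection field
that is uniform across the band, which cannot occur next to a clamped
boundary.  Both the finite elements and the closed-form disc
quadrature agree on this direction.

## Coupled dynamics

The model is assembled with the per-duct full-circuit coefficients on
the diagonals and the shared-segment coefficients as the couplings
(`M_ap = m_cc`, `M_al = m_uc`, `M_pl = 0`; identically for `C`; `K`
diagonal).  Printed coefficient tables are interpreted the same way:
duct columns are full-circuit values, cc/uc columns are couplings.
Internally everything is in mm–g–s (so Pa ≡ g·mm⁻¹·s⁻²); the
table-facing layer converts mg-based inertia and g values and per-nL
transfer factors exactly once.

Time constants come from the eigenvalues of the 6×6 state matrix; each
slow/fast constant is assigned to a duct by optimal one-to-one
matching (Hungarian algorithm) of the eigenvector displacement-
component magnitudes.  When two ducts' uncoupled fast constants are
closer than the coupling strength the modes mix strongly and this
assignment becomes genuinely ambiguous — the constants themselves are
robust, their duct labels are not.  Eigen-derived constants are
validated against bi-exponential fits of brute-force ODE decays.

Frequency response is exact:
`Q(ω) = (−ω²M + iωC + K)⁻¹(−ω²α₀)Gu`, with gain `ε_k|Q_k|/(ωα₀)`
reported in mdeg per deg/s (the deg↔rad factor applied once) and phase
relative to head angular *velocity* (matching velocity-gain usage; an
acceleration reference is a sign-convention change).  The default grid
is logarithmic, 0.01–100 Hz at 60 points/decade — the model is
trustworthy in the low and middle of the head-motion band; it omits
frequency-dependent flow-profile and cupula-porosity corrections that
matter higher up.  The velocity sensitivity `s_k` is evaluated at
`ω* = 1/√(τ₁τ₂)`, where the inertial and stiffness reactances cancel
exactly, about the duct's own maximal response axis (the normalised
k-th row of `C⁻¹G`; with small couplings it deviates from the
streamline-plane normal by well under a degree).  When a table supplies
only `|g|`, duct axes are taken mutually orthogonal; this does not
affect time constants and perturbs sensitivities by well under 1 %.

## Vestibular frame and maps

The frame's z axis is the total-least-squares normal of the pooled
lateral-circuit landmarks (both ears when available); x is the
intersection direction of that plane with the mid-sagittal plane
(supplied explicitly for a single ear, or the between-ear symmetry
plane), pointed anteriorly by a user landmark (without one the sign is
arbitrary and flagged); y = z×x.  Sensitivity maps evaluate the signed
mid-band gains `ε_k[C⁻¹Gu]_k(π/180)` per duct over a 2° (default)
longitude/latitude grid of rotation axes, signs by the right-hand
rule.  The standard combined map is the L2 norm over all ducts
supplied (one labyrinth or both); L1 and max-abs rules are available
behind a flag since the combination rule is a convention, not physics.

## Synthetic fixtures

The generator emulates the segmented-specimen file layout for an
idealised labyrinth: three circular circuits of radii 3.0/2.8/2.6 mm
in orthogonal planes, slender-duct lumen radius 0.15 mm, ampullae
bulged 2.5×, utricular parts 3× — primate-like magnitudes yielding
coefficients, time constants (~4–7 s and ~3.5 ms) and sensitivities
(~3.5–5 mdeg per deg/s) in the physiological range.  Shared segments
are straight chords on the plane-intersection lines, each subtending
6 % of the anterior circle, listed as the identical polyline in both
circuits (sharing is handled by the composition table, exactly as for
a segmented common crus).  All loops stay planar, so lengths, areas,
`g`, `R`, `m` and `c` have closed forms; tube volumes and walls are
exact by Pappus; cupulae are discs with the exact Mindlin record for
`k` and quadrature for `ε`.  Reference time constants and
sensitivities are computed from these analytic coefficients, so the
end-to-end test isolates the geometric pipeline (the eigen step is
validated separately against ODE integration).

What the fixture does *not* emulate: non-circular and non-planar duct
courses, cross-sections that vary within a part or deviate from
ellipses, real crista/cupula shapes (bands run along the whole disc
outline rather than the crista base only), segmentation noise beyond
optional Gaussian vertex jitter, and bilateral asymmetry.  Passing
tests therefore demonstrate correctness of the computational chain,
not anatomical fidelity of any particular approximation to a real
labyrinth.

Mesh resolutions (64 vertices around the tube, 6 axial points/mm)
keep volume and surface discretisation error below ~0.3 %, chosen so
the whole fixture generates in seconds; regeneration with the same
spec is byte-identical.

## Defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| ρ (endolymph density) | 1.0 | mg/mm³ | essentially water |
| μ (endolymph viscosity) | 8.5e-4 | Pa·s | dilute aqueous fluid at body temperature |
| γ (cupula shear modulus) | 1.44 | Pa | anchored to the squirrel-monkey neurophysiological mean long time constant (5.73 s); the calibration is reproduced by `calibrate_shear_modulus` |
| ν (cupula Poisson ratio) | 0.48 | – | nearly incompressible hydrated gel; the underlying studies do not state a value, so this is a documented assumption (configurable) |
| cilia reach ℓ | 60 | µm | middle of the 30/60/90 µm options bracketing vertebrate crista cilia lengths |
| plate pressure | 0.05 | Pa | linear regime probe; k and ε are amplitude-independent |
| shear correction κ | 5/6 | – | standard Reissner value |

All physiological parameters are user-overridable; the run log of the
pipeline echoes every value used.

## Known limitations

* High-frequency response omits flow-profile and poro-elastic cupula
  corrections; trust the gain and phase only up to a few tens of Hz.
* The cupula is a flat constant-thickness plate of its central
  cross-section; real cupulae are curved and wedge-shaped, and the 3D
  extrusion that produces thickness and mean area from imaging is
  upstream of this package (both are inputs here).
* The offset sweep propagates wall-segmentation error into `m`, `c`
  and downstream dynamics but leaves the cupula model untouched.
* Duct assignment of time constants is by eigenvector dominance and
  can flip between near-degenerate fast modes of strongly coupled
  duct pairs; compare the constants themselves, not only their labels,
  across specimens.
* The mesher requires cross-sections star-shaped about their centroid.
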
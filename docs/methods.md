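# Methods

`fracwindow` simulates the early post-operative mechanics of a lower-leg
fracture treated by intramedullary nailing, and asks three questions a
trauma surgeon would ask: how does the treatment of the accompanying
fibular fracture change the load on the nail, and how do walking speed and
weight-bearing restriction change the mechanical environment inside the
tibial fracture gap?  This note records the models, the defaults and why
they were chosen, and what the synthetic inputs do and do not represent.

## The phantom

Real inputs for this kind of analysis are a post-operative CT and wearable
gait recordings; neither is reproducible or shippable.  The package instead
generates a **labelled voxel phantom**: an idealized straight two-bone model
of the lower leg on a regular grid (default voxel 2 mm), with segments
background / tibia / fibula / callus / nail / plate / screws / membrane.

* **Tibia**: a thick-walled tube (outer radius 14 mm, cortical shell 4 mm,
  length 180 mm, distal end at z = 0).  A transverse fracture gap (6 mm
  high, centred at 35 % of the length from the distal end) is filled with
  early callus.
* **Nail**: a 9 mm titanium rod along the tibial axis.  It floats in a
  4 mm canal clearance and is tied to the bone only through four transverse
  locking screws (two proximal, two distal).  This matters: a nail bonded
  to the canal along its whole length would be orders of magnitude stiffer
  than a real locked nail, and interfragmentary strain would be ~0.1 % at
  partial weight bearing — nothing would ever leave the healing window.
  With locked ends and a free working length, gap motion arises from nail
  flexion between the screw clusters, which is exactly the "relative
  stability" mechanism of clinical intramedullary nailing.  Everything
  remains linear and perfectly bonded at the interfaces that do exist.
* **Fibula**: a thin-walled parallel tube (radius 6 mm, shell 2 mm, centre
  26 mm lateral).  Its fractures are transverse 6 mm gaps at 15 % (distal)
  and 85 % (proximal) of the length, filled with soft fibrous tissue.
* **Tibia–fibula connection**: an interosseous-membrane sheet (4 mm thick,
  spanning 30–90 % of the length) and a distal syndesmosis block.  Without
  them the fibula would carry no load and the four configurations would be
  mechanically identical; with them the fibula forms a parallel load path
  that bypasses the tibial fracture, as in vivo.
* **Implants for the distal fibular fracture**: in the plated
  configuration, a titanium plate box on the lateral fibular surface
  spanning the distal gap, fixed with two screws either side.

The four study configurations differ **only** in the fibular state
(geometry is a deterministic function of the configuration; the seed feeds
only the grayscale noise), so cross-configuration comparisons are not
confounded by incidental geometry changes:

| arm | fibula | distal fracture | plate |
|---|---|---|---|
| FibOP | present | plated | yes |
| FibNoOp | present | soft gap | no |
| FibIntact | present | none | no |
| NoFib | absent (with membrane) | — | — |

The proximal fibular fracture sits near the top of the membrane span, where
little load has entered the fibula; it therefore barely changes the
mechanics — consistent with the clinical observation that untreated
proximal fibular fractures matter little.

Grayscale is tiered pseudo-CT (cortical 1400, trabecular 300, callus 100,
metal 3000, soft tissue 50, background −1000 HU) with seeded Gaussian noise
(σ = 25 HU) on foreground voxels.  Fracture gaps are three voxels high so
that the morphological gap-closing filter (ball radius 1 voxel) cannot weld
them shut.

What the phantom does **not** emulate: anatomical curvature and
cross-sectional shape, soft tissue and muscle wrapping, partial-volume
grayscale blur, metal artefacts, and any healing-stage change of callus
stiffness over time.  Results are therefore configuration-relative
comparisons, not patient-level predictions.

## Material mapping

Bone elements receive an isotropic Young's modulus from the grayscale at
their centroid through ρ_ash = 0.0008·HU + 0.07 g/cm³ (clamped at 0) and a
piecewise power law: trabecular E = 6850·(ρ_ash/0.6)^1.49 MPa below the
breakpoint ρ_break = 1 g/cm³, a cortical-exponent branch E ∝ ρ^2.01 above
it.  Taken verbatim from the literature the two laws are discontinuous
(the trabecular curve is *above* the cortical one until ~2 g/cm³), which
would make stiffness drop as density rises through the breakpoint; the
cortical coefficient is therefore rescaled by default so the two branches
join continuously (giving ~21 GPa at dense cortical bone, a standard
value), keeping E(ρ) non-decreasing.  The raw coefficients remain available
(`enforce_continuity=False`).  E is clamped to [1, 25 000] MPa; Poisson's
ratio is fixed per segment (bone 0.3).

Implants and soft tissues are homogeneous: titanium 110 GPa / ν 0.3 for
nail, plate and screws; early callus 3 MPa / 0.4 (granulation-stage
stiffness); membrane and fibrous gap tissue 100 MPa / 0.4.  All
coefficients live in the run configuration and can be overridden.

## Finite elements

Each retained voxel is split into the six Freudenthal tetrahedra sharing
the cell diagonal; the subdivision is translation-invariant, so the mesh
conforms across cells without parity bookkeeping.  Elements are linear
(constant-strain) tet4 — deliberately, because the mechanoregulation stage
classifies *per element*, and a constant strain per element is the natural
granularity for that.  The default phantom meshes to ~86 k elements /
~61 k DOF, which a direct sparse factorisation (SuperLU) solves in seconds;
a gait cycle factorises once and back-substitutes per frame.  Units are
mm / N / MPa / N·mm throughout.

Boundary conditions: the distal end face (both bones — the ankle mortise)
is fully fixed; the resultant force and moment of a gait frame are spread
over the proximal tibial-plateau node set by a statically equivalent
minimum-norm distribution weighted by tributary surface area (so a pure
resultant force reproduces a uniform traction exactly).  Moments are
realised as force couples about the set's weighted centroid.

Verification ladder (all in the test suite): exact volume conservation and
surface Euler characteristic of the meshing; symmetry and six zero-energy
rigid-body modes of the stiffness; the constant-strain patch test to 1e−10;
a prismatic bar against FL/(EA) (exact to round-off with tributary
loading); a slender cantilever against FL³/(3EI) within 5 % at an 8×8×64
mesh; global force/moment equilibrium on every solve.

## Strain invariants and healing classification

Per element: hydrostatic strain ε_h = tr(ε)/3, octahedral shear strain
γ_oct = (2/3)·√[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²], and von Mises stress from
isotropic Hooke's law.  All three are rotation-invariant and degree-1
homogeneous in the load (ε_h sign-preserving), which the tests assert.

Callus elements are classified by ordered, half-open interval rules on
(ε_h, γ_oct) — first match wins, a value on a boundary falls to the upper
class:

1. **intramembranous** — γ_oct < 0.05 and |ε_h| < 5·10⁻⁴,
2. **endochondral** — γ_oct < 0.05 under compressive ε_h beyond that bound,
3. **fibrous** — γ_oct < 0.15 (counted inside the healing window by
   default; a config flag excludes it),
4. **out of window** — everything else.

The numeric bounds are Claes–Heigele-style magnitudes; the literature
source values are not published to the precision a re-implementation could
copy, so the bounds are configuration, and every study-level property the
package asserts (partition totality, volume conservation, orderings,
monotonicity under load scaling) is threshold-agnostic.  The hydrostatic
axis can alternatively be declared in hydrostatic pressure (MPa, computed
per element as p = −3K·ε_h); the tests show both modes agree when bounds
are converted through the bulk modulus.

Volume fractions weight elements by their exact tetrahedron volume, so
per-frame fractions sum to one to machine precision.  The sector map bins
callus elements into four 90° sectors about the bone axis centred on a
config-declared anterior direction (anterior / lateral / posterior /
medial; "dorsal" = posterior).

## Gait synthesis and the joint-load model

Synthetic treadmill trials mimic slow post-operative walking: 30 stances,
cycle duration 0.8 + 1.4/v seconds, stance fraction 0.62, sampled at
100 Hz.  The stance GRF template has the classic two peaks at and below
1.5 km/h and degenerates to a single peak above a threshold velocity of
1.75 km/h.  The per-step peak equals min(cap, effective load)·g with
seeded ±2 % amplitude and timing jitter (never exceeding 1.05× the cap);
the default effective load is 37 % of the 95 kg body mass, i.e. the ~35 kg
the injured leg actually carries under a 20 kg prescription — the
compliance audit is expected to flag it.  Joint angles are smooth
periodic curves with per-channel amplitudes in the range of slow pathologic
gait; they feed the ROM statistics, not the FE loads.

The musculoskeletal inverse-dynamics stage is replaced by a declared
two-parameter load model, isolated behind the `LoadCase` interface (real
exported joint loads can be read from CSV instead):

* axial tibial force = GRF × 2.5 (internal-force amplification by muscle
  action, a standard long-bone figure);
* bending moment about the medial-lateral axis (plus a 25 % torsional
  component) = per-stance peak GRF × a 120 mm forefoot lever ×
  w(s) × (v / 1.5 km/h), where w(s) = s⁹(1−s), normalised to unit peak.

The envelope w peaks at s = 0.9 of stance — the pre-swing push-off, when
the centre of pressure is under the forefoot — and vanishes at touchdown
and toe-off; at midstance it is below 7 % of its terminal-stance value, so
midstance is the "high axial loading" case.  The 120 mm lever is an
ankle-to-forefoot centre-of-pressure distance; together with the locked
nail's working length it produces peak interfragmentary distortions in the
5–25 % range and peak nail von Mises stresses of ~150–420 MPa across the
studies — the magnitudes reported for nailed tibiae.  The linear velocity
scaling encodes the established growth of tibial bending/torsion with
walking speed and is what makes the healing environment speed-dependent
even though the GRF peak itself is speed-independent.  The bending sign is
chosen to load the posterior ("dorsal") callus in compression, the sector
where delayed healing is seen clinically.

Partial weight bearing is imposed as uniform load scaling through the
cap-limited GRF peak (the weight-bearing study scales the observed trace so
its peaks sit at the cap; "full" means body weight).

## Statistics

Range-of-motion summaries segment steps at stance onsets and report
per-step ranges (min, max, meanΔ ± SEM).  Group comparisons follow the
classic normality-gated battery: Shapiro–Wilk at α = 0.05 per group; two
groups → unpaired t-test or Mann–Whitney; three groups → one-way ANOVA with
Holm–Šidák pairwise post-hoc or Kruskal–Wallis with Dunn's test
(Bonferroni-corrected, implemented in-package since no installed library
provides it).  Significance at p < 0.05.

## Study protocol and problem sizes

All three studies run on the default phantom (~86 k tets).  The fibula
study solves midstance and terminal stance per arm (4 factorisations); the
weight-bearing study solves terminal stance and pre-swing for caps
{20, 35, 95} kg on the FibOP mesh (1 factorisation); the velocity study
solves 16 stance frames + 6 swing frames per velocity on the FibOP mesh
(1 factorisation, 66 back-substitutions).  Each study completes in one to
two minutes on a single CPU; the reduced test phantom (~17 k tets) keeps
unit tests fast.  The direct solver, deterministic assembly order and
seeded generators make every reported number bit-reproducible from the
run configuration and seed.

## Known limitations

* Linear kinematics and linear elastic materials; no contact, so the nail
  clearance neither closes under load nor transmits friction, and callus
  strains scale exactly linearly with load.
* One-shot snapshots: no callus growth, stiffening or remodelling over the
  healing course.
* The joint-load model is a declared parametric substitute; its two gains
  set the absolute strain scale, so out-of-window percentages should be
  read as ordered comparisons between arms, not calibrated clinical values.
* Idealized geometry: stress magnitudes at screw junctions are
  mesh-sensitive in the way all re-entrant voxel corners are; peak
  comparisons are made between identically meshed arms.
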
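# Methods

## The estimation problem

A FIB lamella is a ~70–120 nm slice through a microfossil embedded in
chert. STEM-EDXS yields co-registered element-intensity maps (Fe, Si, O, C,
S) of that slice at ~10 nm pixels. The quantity of interest is the
intracellular iron inventory of the fossil: total Fe atoms per cell (the
quota *Q*) and per μm³ of cell volume (the concentration *C*). The package
estimates these from planar measurements via the Delesse principle: the
areal fraction of a phase on a random planar section through a body equals,
in expectation, the phase's volume fraction. The chain is

    f  →  V_cryst = f·V_cell  →  Q = V_cryst·ρ·w·N_A/M  →  C = Q/V_cell,

where ρ is the density of the Fe-mineral assemblage, *w* its Fe weight
fraction and *M* the molar mass of iron. *C* depends only on *f* and the
mineral constants, never on the absolute cell size.

### Constant sets

Two tagged constant sets run through every quota computation:

| constant | `standard` | `paper_compat` |
|---|---|---|
| ρ (g cm⁻³) | 3.352 (80:20 greenalite:siderite, table densities) | 3.2 |
| w (Fe weight fraction) | 0.458 (mass-weighted from the formulas) | 0.48 |
| M(Fe) (g mol⁻¹) | 55.845 | 56 |
| sphere volume | (π/6)·d³ | (4/3)·π·d³ |

`paper_compat` exists to reproduce the printed numbers of the original
Gunflint quota analysis bit-for-bit. Its sphere volume uses the diameter
where the radius belongs — 8× the true sphere volume — which is the only
convention under which that study's printed quota (2.7×10¹² atoms at
d = 8.7 μm) and concentration (9.6×10⁸ atoms μm⁻³) are mutually
consistent; the package logs a loud warning whenever it is used. The
default is the correct `standard_sphere`. The two constant sets differ by
<3% in concentration (the conventions differ 8× in quota), so conclusions
about enrichment contrasts are unaffected by the choice.

Formula arithmetic uses IUPAC 2021 abridged atomic weights. Greenalite's
formula-derived Fe weight fraction is 0.451 (not the rounded 0.48 working
value); the reference table stores the computed value, and `paper_compat`
carries the rounded one. Charge annotations in formula strings are stripped
before parsing: EDXS stoichiometry is charge-blind.

## Segmentation

Fe-mineral pixels are selected in the Fe channel by a threshold — Otsu's
method by default, or a fixed value; either way the applied threshold is a
logged run parameter, as in the manual image analysis the procedure
replaces. Otsu assumes a meaningfully bimodal histogram; on matrix-only
scenes, where crystal pixels are a ~10⁻⁵ fraction, it collapses into the
noise floor, so matrix (background) estimates use a fixed threshold at half
the crystal signal. Particles are 8-connected components (4-connectivity
available) of at least `min_pixels` = 4 pixels (≈20 nm equivalent diameter
at 10 nm pixels); the floor suppresses noise speckle but also drops the
smallest matrix crystals, which is why matrix concentrations are reported
as bounds. Particles are assigned to interior/wall/background by the
region containing their centroid — cheap, deterministic, and adequate while
nanocrystals are much smaller than the regions; wall-straddling particles
are a documented limitation of centroid assignment.

## Stereological estimators

Per-fossil area fractions are Σ(particle areas in region)/(region area).
For population-level checks across many sections, the pooled (ratio-of-
sums) estimator Σ crystal area / Σ reference area is used rather than the
mean of per-section ratios: pooling is the standard stereological
practice, is what pooling "all sections" of a study does, and is unbiased,
whereas the unweighted mean of ratios is dragged down by near-polar
sections whose reference areas are small and whose crystal content is
depleted by the finite crystal size. Matrix concentrations are likewise
pooled over several sections because a single lamella contains only a
handful of matrix nanocrystals, making single-section estimates extremely
lumpy.

No correction is applied for section-thickness overprojection (crystals
only partly inside the slab): with ~150 nm crystals in a ~120 nm slab a
full projection would inflate area fractions by roughly 1 + 3h/(2r) for
slab half-thickness h. This is a known, flagged bias of the area-based
method, not modelled here.

## Synthetic scenes

The generator emulates the study conditions rather than detector physics.
Defaults are fixed once:

- cell: sphere, d = 8.7 μm (the high-Fe worked example), wall 250 nm
  (thick-walled spheroid range 110–600 nm); cylinder with longitudinal
  section for filaments;
- intracellular crystals: volume fraction 0.058 (the fraction implied by
  the high-Fe example through the quota constants), lognormal equivalent
  diameters (median 150 nm, σ = 0.4), 80% greenalite plates (2:1 ellipses
  in section) and 20% siderite rhombs (rotated squares); shape never
  enters the quota arithmetic — only area does;
- matrix: volume fraction 5×10⁻⁵ (≈8×10⁵ atoms μm⁻³, inside the
  <1.5×10⁶ bound) of smaller (80 nm median) greenalite crystals;
- imaging: 10 nm pixels, per-channel intensity = 1000 × the atomic
  fraction of the element in the local phase (quartz everywhere outside
  crystals and wall; pure C in the wall band; H invisible to EDXS, so
  greenalite renders as Fe₃Si₂O₉), Gaussian noise σ = 10 (Poisson shot
  noise behind a flag), section thickness 120 nm as metadata.

Crystals are packed without overlap (random sequential addition with a
grid hash) uniformly inside the cell interior and cut by the section
plane at a uniform random offset; each crystal crossing the plane is drawn
with its zero-thickness cross-sectional area. The zero-thickness cut makes
the expected drawn area fraction equal the 3-D volume fraction exactly
(the property the Delesse chain relies on); drawing everything inside the
slab at its widest — overprojection — is available behind a flag for
studying that bias. Scenes are byte-deterministic given their parameters
(one `numpy` Generator seeded from `seed` drives everything).

What the scenes do **not** emulate: beam-thickness projection effects,
diffraction contrast, detector point-spread, spatially correlated noise,
non-spherical 3-D crystal habits, and clustered (non-uniform) crystal
placement. Passing tests therefore validate the estimator logic and its
calibration, not robustness to every instrumental artefact of real
micrographs.

Non-image generators: segment lengths are truncated-normal (mode 3.5 μm,
σ = 0.8 μm, lower bound 1.5 μm — only the 3.5 μm mode is observationally
constrained; the shape is an emulation choice), composition sets are
λ-mixtures along the endmember–host line with truncated Gaussian noise and
renormalization, d-spacing observations are reference spacings with
uniform jitter, and the morphotype population draws records uniformly
within each class's printed ranges.

## Morphometry

Wall thickness = wall area ÷ wall perimeter on the section mask, with the
perimeter taken as the mean of the inner and outer boundary lengths
(mid-band convention; an `outer_only` flag divides by the outer boundary
alone). Boundary count is checked by marching squares (exactly two closed
contours required), but the perimeter magnitude uses the Crofton formula,
which is unbiased for smooth boundaries where polyline contour lengths
systematically overestimate by ~5%. The mid-band convention recovers the
true thickness of an analytic annulus exactly; rasterized annuli recover
within 2% for bands ≥3 pixels thick. Bands thinner than 2 pixels raise
(boundaries unresolvable).

Segment lengths are successive differences of strictly increasing septum
positions (septum detection is out of scope; positions are inputs). The
mode is the centre of the tallest 0.5 μm histogram bin anchored at zero,
ties broken toward the smaller bin; with anchored bins a population mode
sitting exactly on a bin edge (as 3.5 μm does) resolves to 3.25 or
3.75 μm, i.e. always within half a bin. The length–diameter association
uses Pearson correlation of per-filament mean lengths against diameters
(the claim concerns means); Spearman is available behind a flag. Filament
diameters come from metadata, not from images.

## Composition and identification

Ternary projection renormalizes atomic fractions over (Fe, Si, O). The
quartz-contamination mixing line is fitted by total least squares
constrained through the quartz vertex: the direction is the leading right
singular vector of the host-centred cloud. The host is constrained, not
estimated, because quartz is the known contaminant phase of a chert
lamella. The endmember is the projection of the farthest point onto the
line, unless measurements flagged as traversing the section (quartz-free)
exist, in which case their mean is the endmember and its off-line distance
enters the collinearity RMS. Noise-free mixtures are recovered exactly;
at noise σ = 0.01 the endmember is recovered within 0.02 ternary distance.

Stoichiometry matching gates candidates by maximum absolute per-axis
ternary deviation ≤0.08 and ranks by Euclidean distance; the tolerance is
a logged config field chosen so that greenalite-like measured compositions
match while 50:50 quartz mixtures match nothing. Hydrous minerals carry
two reference ternaries (all-O, and hydroxyl-blind with one O per OH
removed) because EDXS O quantification is convention-dependent — the same
ambiguity that makes a measured Si/O of 0.32 sit between greenalite's
all-O (0.22) and hydroxyl-blind (0.40) ratios; both conventions are
carried, neither asserted as intended. d-spacing matching requires every
observed spacing to lie within 0.2 Å of some reference spacing, ranking by
matched-plane count then mean residual. Redox enters as a derived scalar
(Fe³⁺/ΣFe); EELS spectrum fitting is out of scope. The ferrous label
cutoff is 0.05, comfortably above the few-per-mil ferric fractions of
essentially ferrous silicates.

## Classification

The decision tree encodes the printed, non-overlapping class ranges:
spheroid walls 40–60 nm (thin; diameter subgroups ≤4 and 7–9 μm) vs
110–600 nm with d 7–12 μm (thick); filaments without septa and sheath
<150 nm at d 0.9–1.5 μm (*G. minuta* T1) or d >3 μm (*Animikiea* T1);
septate filaments at d 1.4–2.5 μm (*G. minuta* T2) or d >4 μm
(*G. grandis* T2). Records in the gaps (walls 60–110 nm; aseptate
filaments 1.5–3 μm; septate 2.5–4 μm) are `unclassified` by design — the
population argument rests on the ranges not overlapping, so snapping to
the nearest class would manufacture evidence. The 1.4–1.5 μm diameter
overlap between T1 and T2 is resolved by the septa predicate, which
differs by construction. Missing fields trace to `unclassified`, never an
exception. Fe status is `mineralized` at ≥100× the matrix bound (the
two-order enrichment), `non_mineralized` at ≤1×, `undetermined` between.

## Problem sizes and tolerances

Validation suites run at: 100 random sections (20 nm pixels, d = 8.7 μm
cell) for Delesse recovery within 15% relative; 8 pooled matrix sections
for the background bound; 25-point mixtures for endmember recovery;
n = 60 archetype records for the 100% noise-free classification check;
annulus recovery at 2%. The quota identity C·V = Q holds to machine
precision by construction. Scene sizes keep the full suite to roughly a
minute; all stochastic checks run on fixed seeds.

## Known limitations

- Centroid region assignment misplaces wall-straddling particles.
- Matrix concentrations are upper-bound flavoured: the particle-size floor
  and small-crystal thresholding bias single-section matrix estimates.
- No overprojection correction; no drift/distortion correction; no 3-D
  reconstruction; no ML segmentation; no SAED pattern indexing beyond
  spacing lists; no ZAF/Cliff-Lorimer EDXS matrix corrections.
- Ankerite's variable-cation site is stored at a fixed documented
  occupancy and never enters quota arithmetic.
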
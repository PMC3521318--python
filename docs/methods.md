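# Methods

`lightshare` simulates how diffuse light is shared between wheat and pea in
virtual row intercrops, and asks when the simple "well-mixed" turbid-medium
theory is sufficient to predict that sharing. This note documents the models,
their assumptions, the tunable parameters and the choices made where the
design was open.

## The well-mixed theory

For a homogeneous bi-specific canopy obeying Beer–Lambert extinction, the
light-interception efficiency (LIE) of species *i* is

    LIE_i = (K_i L_i / Σ K_j L_j) · (1 − exp(−Σ K_j L_j))

with extinction coefficient *K_i* and leaf area index *L_i*. The share of
species 1 in total interception reduces to

    S₁ = αp / (αp + 1 − p),   α = K₁/K₂,   p = L₁/(L₁+L₂),

because the exponential factor cancels in the ratio; `theory.share_theoretical`
and `theory.lie_mixture` are cross-checked against each other to 1e-12 in the
test suite. Isolines of S₁(p) at fixed α describe all the structure the theory
can express: only LAI shares and leaf inclinations (through K) matter.
Everything a real, height-structured canopy does beyond that appears as a
*deviation* from the isoline.

Extinction coefficients are derived from the mean foliage inclination through
the ellipsoidal leaf-angle distribution: the distribution parameter *x* is
inverted from Campbell's mean-angle approximation ᾱ = 9.65(3+x)^(−1.65) rad,
and the directional coefficient is

    K(θ) = sqrt(x² + tan²θ) / (x + 1.702 (x + 1.12)^(−0.708)).

Limits: horizontal leaves → K ≡ 1; spherical (x = 1, ᾱ ≈ 56°) → G = 0.5;
vertical leaves → K(0) → 0. The closed form is verified against direct
numerical integration of the projection kernel in the tests (≤ 2 % over
realistic angles; the fully erect limit is exact only to a few 1e-3 because
the mean-angle inversion is approximate there). A single diffuse-effective K
is defined as the value that reproduces the sky-vault-integrated interception
of a reference canopy of LAI 1; the dependence on the reference LAI is weak
and the convention is fixed.

## Diffuse sky and ray casting

The diffuse sky is a Uniform Overcast Sky vault discretized into 5 zenith
bands × 4 azimuths (20 sectors). Band weights follow uniform radiance,
w ∝ sin²θ₂ − sin²θ₁, and each band is represented by its upper boundary
zenith (18°, 36°, 54°, 72°, 90°); the 90° entry is replaced by the band's
flux-weighted mean zenith (~77°) because a horizontal ray never terminates in
a periodic scene. A band-centre convention is available as a switch.

Interception is first-order: organs are opaque, with no transmission or
scattering. This is a deliberate simplification of radiosity-style canopy
radiative transfer — scattering redistributes a modest fraction of PAR and is
out of scope; the quantity analysed is the intercepted fraction only. Per
sector, a stratified jittered grid of parallel rays is cast over the doubly
periodic footprint; each ray is attributed to the species of its first
intersected triangle or to soil, so the per-direction energy budget is an
exact counting measure (species + soil = 1). Implementation: a shear aligned
with the beam makes all rays vertical, after which the first interception is
the covering triangle of greatest sheared height at the ray's footprint
position; triangles are wrapped into the periodic cell by integer lattice
offsets. Cost scales with projected covered area, not rays × triangles
(~2 s per 20-sector, 1e5-ray-per-sector scene at early-stage density).
Monte-Carlo standard errors are propagated per species as weighted binomial
errors; they ignore the (variance-reducing) stratification and are therefore
slightly conservative.

## Plant mock-ups

**Pea.** Each cultivar is a parameter file (YAML under `lightshare/data/`)
holding: Schnute development parameters; a per-stage branching table (range of
branch counts and mean phytomers per branch); internode and stipule (and, for
leafy cultivars, leaflet) final-length profiles over normalized phytomer rank;
stipule/leaflet inclination dynamics over thermal time; organ-type
contributions to green area; and two calibrated scalars (below). A mock-up at
thermal time *t* is built phytomer by phytomer: the visible count is the
rounded Schnute curve value, rank *i* appears when the curve passes *i* − ½,
internodes elongate linearly over 75 DD, and leaf area expands linearly over a
per-cultivar window (150–900 DD; long-cycle cultivars expand longest) with
width fixed at the final profile length. Leaves are planar rhombi; stipules
insert as opposite pairs just off the stem (8 mm), leaflets ride a 40 mm
horizontal petiole — without the petiole offset, organs cluster unrealistically
around the stem axis and the sparse-stand share falls measurably below the
well-mixed prediction. Branch counts are drawn uniformly (seeded) from the
stage's observed range; branches reuse the main-stem profiles truncated to
their phytomer count and insert basally, except China whose branches insert at
ranks 12–14. Stems are staked upright (no lodging or curvature).

Organ-type shares of green area are matched exactly to the cultivar's
transcribed contributions by per-type width factors at build time, and a
single calibrated width factor sets the absolute area. Two scalars per
cultivar — the internode mean length and that width factor — were calibrated
once against the observed stand descriptors (heights and LAI at 300, 600,
1240, 1560 DD at 45 plants m⁻²) and frozen into the parameter files; with
them, simulated stand LAI tracks the observed values within ±20 % at every
stage and the area-weighted foliage inclination reproduces the observed
per-stage values (the inclination knots are solved for this exactly; a ±3°
zero-mean jitter decorates individual organs). 886/01 carries a steeper
stipule-length profile than the common triangular profile (longest stipules
at normalized ranks 0.6–0.8, ~50 mm): its late, many-phytomer development
cannot otherwise reconcile the 600 DD and 1240 DD stand areas.

**Wheat.** A dynamic wheat development model is out of scope. Each stage is a
target triple (stand LAI at 125 plants m⁻², height, foliage inclination); a
plant is a 3 mm-wide vertical culm of exactly the stage height carrying six
planar blades that arch downward from their insertions, sized so total green
area meets the target and jittered (zero-mean) around the stage inclination.
The culm counts toward green area; at 300 DD it is a non-trivial share of
wheat area, which is a model difference from a real tillering stand whose
"stem" is leaf sheaths.

## Scenes and descriptors

Mixtures use 17 cm rows with wheat and pea alternating within rows in
proportion to their densities (125 and 45 plants m⁻², i.e. half of each
sole-crop optimum), ≤ 2 cm placement jitter, seeded plant rotations, and a
doubly periodic plot emulating an infinite canopy (no border plants).
Descriptors follow the stand conventions: LAI = green organ area (leaves and
stems) per ground area; mean foliage inclination is green-area-weighted over
leaf organs only; plant height is the maximum organ vertex height, averaged
per species. Inclination is measured from the horizontal (erect wheat ≈ 65°).

## Experiments and analysis

`run_stage_experiment` builds, for each (cultivar, replicate seed), a fresh
mixture at the stage, ray casts the vault, and computes the theoretical share
from the scene's *own* descriptors (per-scene K from mean inclinations, p from
LAIs) — a per-point isoline comparison. All randomness fans out from the
replicate seed through a fixed counter scheme (`SeedSequence((seed, stream,
index))`), so records are bit-reproducible and adding replicates does not
perturb earlier ones. Computed share is regressed on theoretical share with a
free intercept by default; the origin-constrained variant (uncentered R²) is
reported alongside, since which of the two the original analysis used is not
stated. Deviations are related to the wheat/pea height ratio h by the
saturating form a(1 − e^(−b(h−1))) for h ≥ 1; the exact functional form behind
"exponentially related" is interpretive, and fits that do no better than a
constant are flagged non-saturating.

## What the synthetic stands do and do not show

The generator reproduces the *statistical* architecture of the measured
cultivars — development timing, branching ranges, organ-size profiles,
inclination dynamics, stand LAI/height trajectories — not individual digitized
plants. Organ shapes are planar polygons without curvature, tendrils, petiole
geometry beyond a rigid offset, or plastic responses to neighbours; azimuths
are uniform random. Consequently early-stage (sparse, well-mixed) results —
the regression of computed on theoretical share at 300 DD with slope ≈ 1,
R² ≥ 0.99 — are quantitative reproductions, while late-stage slopes depend on
the authors' specific digitized plants and are only qualitatively comparable
(dense-stand runs show the same height-driven departures from the isolines).
Passing tests certify the model chain, not field behaviour of real canopies.

## Numerical choices

- Schnute fits: Levenberg–Marquardt (scipy `least_squares`, method="lm") on
  (A, B, y_max) with t_max fixed to the last observation; positivity through
  |·| reparameterization; initialization A₀ = 2/t_max, B₀ = 0.5,
  y_max₀ = max(counts); < 5 observations or a constant series raise; rates use
  the closed form t* = −ln(B)/A for B < 1, otherwise the boundary is flagged;
  ties in a flat derivative resolve to the smallest t by construction.
- Ray budget default 1e5 per sector; horizontal path capped at 10 plot widths;
  grazing band represented by its flux-weighted mean zenith.
- Edge-on triangles (projected determinant < 1e-18) are skipped: they have
  zero projected area.
- Degenerate inputs: empty scenes intercept nothing (soil fraction 1); a
  zero-interception mixture has no defined share and raises; zero-length
  organs produce empty meshes, not errors.
- Stand-calibration simulations and tests use 8 seeded plants per cultivar
  and stage (matching the measured sample size); acceptance-scale experiments
  use a 0.51 × 0.51 m plot (3 rows, 33 wheat + 12 pea plants), six cultivars ×
  4 replicates.

## Known limitations

- No scattering: absolute interception is slightly underestimated relative to
  a radiosity computation, mostly cancelling in the species share.
- The diffuse-effective K convention compresses the inclination contrast
  between species (oblique sky sectors dominate); theoretical shares are
  correspondingly close to the LAI share for realistic inclinations.
- Wheat is stage-parametric, not developmental; its culm inflates early green
  area relative to a real tillering stand.
- Heights match the observed stands to ~±25 % (they are emergent, only
  indirectly calibrated); LAI is the calibrated quantity.
- The height-ratio curve is defined for wheat taller than pea (h ≥ 1); in
  these mixtures pea overtops wheat from 600 DD, so that analysis is mainly
  exercised on synthetic data.
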
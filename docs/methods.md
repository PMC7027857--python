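# Methods

## Coordinate conventions and geometry

All geometry lives in millimetres in a right-handed frame with the origin
at the intersection of the column axis and the soil surface; `z` is depth,
increasing downward, so the column occupies `z ∈ [0, 170]` and "deeper"
means larger `z`.  Roots are ordered polylines (proximal → distal) with a
single representative radius; macropores are finite vertical cylinders.

Growth direction at an arc position is the principal axis of a
total-least-squares 3D line fit (SVD of the centred points) over points
resampled at 0.5 mm within the requested arc window, oriented along growth.
The fit window is 20 mm by default; when a root offers less than 5 mm of
arc on the requested side the direction is declared indeterminate rather
than fitted — short windows near tips produce unstable fits, and events
that depend on them are excluded from change/no-change percentages but
still counted and reported.

Root–pore separation is surface-to-surface: the distance from centerline
to the solid cylinder (lateral surface, end caps and rim all handled) minus
the root radius, floored at zero.  The minimum over a root is found by
coarse arc sampling at 0.1 mm followed by local refinement at 5 μm around
every sample that could hide the minimum; because the distance field is
1-Lipschitz along the arc this brackets the true minimum to well below the
45 μm detection threshold.

## The mesocosm and its voxelization

`ColumnSpec` carries the full column parametrization (64 mm × 170 mm outer
column, 55 mm subsoil at 1.2 or 1.6 g cm⁻³ under 1.1 g cm⁻³ topsoil, 20 mm
inner guide column, nine 0.8 mm × 45 mm pores with a 10 mm soil cap, seeds
planted 20 mm deep).  The pore jig layout is not fully determined by the
column description beyond "equally spaced"; the package uses one axial
pore plus eight on a circle of radius 8 mm at 45° spacing, which keeps the
whole field under the 20 mm inner-column footprint through which roots are
funneled.  The layout is configurable and recorded in output metadata.
Pores run from 125 mm depth to the column base at 170 mm, as they are
formed by rods inserted through the base.

Label volumes assign each voxel the region containing its center, with
precedence root > pore > inner wall > soil layer, except for the pores:
at the default working voxel sizes (200–500 μm; the full column at the
45 μm scan resolution would be ~7.6×10⁹ voxels, so 45 μm is reserved for
ROI crops) the 0.8 mm pores are sub-voxel, and center labeling misstates
their volume by tens of percent depending on how the grid happens to align
with each pore axis.  Pores are therefore rasterized volume-preservingly:
voxel footprints are ranked by their analytic in-circle coverage and
exactly as many voxels are labeled per slice as match the true
cross-section area.  This keeps total pore volume correct to the rounding
of one voxel while remaining deterministic.

Grayscale phantoms give each label a mean intensity (air-filled pores
darkest at 0.05, roots 0.25, topsoil 0.55, subsoil scaled by its bulk
density relative to topsoil, PVC wall 0.9) plus seeded iid Gaussian noise.
No scanner physics (beam hardening, rings) is modelled; the phantom's role
is to exercise the segmentation path, not to imitate scan artifacts.

## The root simulator

The simulator is **event-driven**: the printed interaction statistics are
per-interaction probabilities, and root-number/angle parameters that would
let those rates emerge from blind growth are unknown.  So the number of
interactions per column is drawn first — Poisson with mean 1.78, redrawn
while above the observed maximum of 7 — and each interaction gets a root
constructed to realize its drawn outcome.  A purely geometric mode is
deliberately out of the acceptance path for the reason above.

Behavior profiles package the observed rates per treatment × genotype:
colonization 68.8 % / 12.5 % (compact/loose, combined), overall trajectory
change 76.0 % / 21.0 %; genotype-resolved colonization 80.0 / 62.5 %
(compact) and 7.7 / 15 % (loose), change 92.9 / 78.6 % (compact) and
20 / 25 % (loose).  Because colonization implies a trajectory change, the
conditional change probability for crossing events is derived as
`(p_change_overall − p_colonize) / (1 − p_colonize)`.

Geometric construction per event:

- **Colonizers** approach a pore mouth along a straight run tilted 3–8°
  from vertical, blend onto the pore axis within 3 mm (staying inside the
  0.4 mm pore radius), and follow the axis to 0.5 mm above the pore bottom
  with a bounded 0.05 mm wobble — colonizing roots never exit a pore, and
  their in-pore run (≈ 44.5 mm) always clears the 15 mm rule.
- **Crossers** touch the pore's lateral surface (centerline at exactly
  pore radius + root radius from the axis) at a depth 2–12 mm below the
  pore top, approached along a 25 mm straight run tilted 5–15° from
  vertical, then continue 25 mm deflected by an angle drawn from the
  change band (Uniform 8–45°) or the no-change band (Uniform 0–1.5°).
  The bands are configurable; their defaults deliberately avoid the 3°
  decision boundary so that classifier validation measures the pipeline,
  not boundary luck.

Per-step heading wobble (sd 0.4° per 0.5 mm step) is applied as an
independent perturbation around the persistent base heading rather than as
an accumulating random walk: an accumulating walk of that magnitude drifts
a few degrees between the two 20 mm fit windows, which would smear the
no-change population across the 3° threshold and make the truth labels
themselves ill-defined.  With independent wobble the fitted window
directions reproduce the base headings to well under a degree while the
centerline keeps visible tortuosity.

Every constructed root is checked to stay inside the column and at least
0.2 mm clear of every pore other than its target (so no accidental second
interactions corrupt the truth log); construction retries with fresh draws
up to 40 times.  Optional non-interacting filler roots descend between the
pores with ≥ 1 mm clearance.  The upper shaft connecting the seed position
(20 mm depth, within the inner column) to the approach run is a cubic
Bézier blend; only the final straight windows matter for classification.

Experiments assign one column per genotype × treatment × replicate slot
(default 2 × 2 × 10 = 40), with per-column seeds spawned from the master
seed and block labels (6 staggered days) assigned by a seeded shuffle of a
balanced block vector — the real block map was not published.

## Segmentation

The interactive region-growing workflow used on real scans is replaced by
a deterministic variant with explicit semantics: the region is the
26-connected set reachable from the seeds through voxels whose intensity
is within `tolerance` of the running mean of the region accepted so far,
expanded frontier-by-frontier (vectorized dilation), so results are exactly
reproducible.  Centerlines come from 3D topological thinning
(`skimage.morphology.skeletonize`), converted to a graph over 26-adjacent
skeleton voxels with Euclidean-distance-transform radii; each component's
centerline is its longest geodesic path (double Dijkstra sweep), ordered
shallowest-end first and smoothed by a ~1 mm moving average.  One
degenerate case is handled explicitly: thinning annihilates objects that
are perfectly symmetric on the voxel grid (no unique medial voxel); the
mask is then re-skeletonized after a one-voxel one-sided dilation, at the
cost of a half-voxel axis shift (within the one-voxel accuracy budget).
Pore cylinders are fitted per connected component from the (x, y) centroid,
z-extent and voxel count; components whose z-extent is under 3× their
lateral extent are flagged non-tubular and skipped.

Separating a root from the air-filled pore it occupies is the hardest step
on real grayscale data; synthetic label volumes keep the two materials
distinct, and the label-mode path is what the end-to-end tests exercise.

## Classification rules and boundary conventions

- Interaction: minimum surface separation ≤ 1 voxel (45 μm unless volume
  metadata overrides).  Contact episodes on the same pore separated by
  < 15 mm of arc are merged, keeping the first contact.
- Colonize: strictly more than 15 mm of contiguous centerline inside the
  pore (within the pore radius of its axis, within its z-extent), starting
  at or after contact, measured on a 0.1 mm resampling.  Exactly 15 mm is
  a cross.
- Trajectory: pre direction fitted over 20 mm before contact; post over
  20 mm after *leaving* the pore (contact arc + in-pore length); changed
  iff the angle strictly exceeds 3.0° (exactly 3.0° is unchanged).  The
  angle is measured in 3D.  Colonizers are changed by definition.
- Each (root, pore) pair yields its own event; interactions, not roots,
  are the counting unit throughout, including the change percentages.

## Statistics

Per-column counts are analysed as a randomized complete block two-factor
ANOVA via an OLS fit with sequential (type I) sums of squares — the block
stratum is removed first, as in a classical RBD analysis, and the
components add to the total SS exactly.  The least significant difference
is `t(1−α/2, df_resid) · sqrt(2·MSE/n)` at α = 0.05.  Shapiro–Wilk is
reported per response; count responses at n = 10 per cell can fail
normality, in which case a note is emitted and the ANOVA proceeds anyway,
mirroring how such datasets are analysed in practice.  Genotype-combined
percentages use interactions as the denominator, with indeterminate
events excluded from (but reported alongside) the changed/unchanged split.

## Problem sizes and numerical choices

Validation runs use 500 interactions per treatment arm for rate recovery,
a 400-column experiment for the interaction-rate mean (each within 3
binomial/Poisson standard errors of the generating parameter), and
phantoms at 100–500 μm voxels with tubes ≥ 5 voxels across for the
segmentation path.  Detection resamples centerlines at 0.05 mm, in-pore
measurement at 0.1 mm; ties and boundaries follow the strict-inequality
conventions above.  Known limitations: no branching architecture, no
mechanistic growth (impedance, water), no scanner artifacts, and the
grayscale root-in-pore separation is not exercised by the synthetic
acceptance path.
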
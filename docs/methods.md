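# Methods

## Coordinate and unit conventions

All lengths are micrometres, times minutes, angles degrees. The basal
plane is z = 0 at the basement membrane with apical positive; the image
plane is y-down with origin top-left (label-mask convention). Axial
(headless) orientations — division azimuths, long axes, polarity axes —
are reported modulo 180°.

## Division orientation and positional fate

The division elevation is measured between the two daughter-nucleus
centroids, Θ = arcsin(|Δz| / ‖Δ‖), at the first frame where both daughter
tracks exist as separate objects. Spindles rotate while chromatids are
still aligned at metaphase, so earlier frames are never used; the first
co-appearance frame is the telophase proxy. A mother track persisting past
its daughters' appearance is a lineage inconsistency and raises an error.

Categories use inclusive upper bounds: planar Θ ≤ 20°, oblique
20° < Θ ≤ 70°, perpendicular 70° < Θ ≤ 90°. Angles are stored at full
floating precision and categorised without rounding.

Fate is scored over a 90-minute window after the division frame (9 frames
at the default 10-minute interval; the window length and interval are both
parameters). A daughter is suprabasal when its nuclear z exceeds the basal
threshold; to count, the excursion must persist for ≥ 2 consecutive frames
within the window *and* hold at the window's final frame — a guard against
single-frame z jitter. Symmetric = both daughters basal; asymmetric =
exactly one suprabasal; both-suprabasal is flagged and excluded from the
dichotomy; missing frames give "indeterminate" with a reason.

The basal threshold is a parameter. When not supplied it is estimated as
the 75th percentile of the mother-population nuclear z plus one nuclear
radius (default 2.5 μm). Nuclear z position, rather than membrane context,
defines basal-layer membership throughout; the window is exclusive of the
division frame itself.

## Cell geometry

- **Area**: planimetric (shoelace) polygon area of the segmented outline;
  self-intersecting polygons are rejected.
- **Width** ("longest planar axis"): the maximum vertex-to-vertex chord of
  the outline — the literal reading, checked against an all-pairs brute
  force. A fitted-ellipse major axis is available as an option
  (`method="ellipse"`).
- **Height**: apical surface to basement membrane; H:W = height / width
  from the interphase frame just before mitotic rounding.
- **Elongation nematic**: from the area-normalised central second-moment
  tensor; magnitude = 100·(λ₁ − λ₂)/(λ₁ + λ₂), axis = major eigenvector.
  The ×100 scale puts moderately elongated cells in the tens (a 2:1
  ellipse scores exactly 60). Other tools print elongation in their own
  unspecified conventions, so cross-tool numeric comparison of elongation
  values is not supported — only directions and ratios.
- **Neighbour counts**: from shared Voronoi ridges in synthetic fields, or
  from shared polygon edges with a 0.1 μm snapping tolerance for segmented
  input.
- **Density**: centroid-in-bounds count normalised to a stated reference
  area (default 1200 μm², a common field-of-view convention).
- **Mitotic index**: mitotic cells as a percentage of all cells in the
  field.
- **Tissue thickness**: foreground area of a binary cross-section divided
  by its lateral foreground extent — mean thickness over the imaged
  length.

Cells touching the field boundary are excluded from shape statistics
(area, elongation, H:W, neighbour classes) because clipped polygons bias
shape metrics, but they still count toward density.

**Hertwig alignment** joins each division to its mother's interphase
shape and reports (i) Δxy, the axial difference between the planar
division axis and the longest planar axis, for planar divisions; (ii)
per-category H:W means; (iii) the one-sided Spearman rank correlation
between H:W and division angle (positive direction: taller/narrower cells
divide more perpendicularly).

## The restricted-range Kuiper test

Division elevations live on the bounded interval [0°, 90°], not a circle.
The two-sample statistic is therefore computed without circular
wrap-around:

    V = D⁺ + D⁻,  D⁺ = max(F̂₁ − F̂₂),  D⁻ = max(F̂₂ − F̂₁),

with right-continuous ECDFs evaluated at the pooled unique breakpoints and
ties pooled. V is a rank statistic, invariant under any common strictly
monotone transform; consequently the quadrupled-angle circular embedding
θ → 4θ (offered as `variant="circular_4x"` for sensitivity analysis)
yields the identical two-sample statistic, which the test suite asserts.
The exact form of restricted-range modification used historically with
this kind of data is not standardised; the bounded-interval V with
permutation inference was chosen because the permutation null is
exact-by-construction for any statistic, making the inference robust to
the variant choice.

Inference defaults to pooled-relabelling permutation with
p = (1 + #{V_perm ≥ V_obs}) / (1 + B), B = 10,000 by default and a
mandatory seed in the CLI. Because V is lattice-valued, ties between
observed and permuted statistics make the test mildly conservative
(measured null rejection ≈ 0.045 at α = 0.05 for n₁ = n₂ = 150). The
classical asymptotic tail

    p = 2 Σ_{j≥1} (4j²λ² − 1) e^(−2j²λ²),
    λ = V·(√Nₑ + 0.155 + 0.24/√Nₑ),  Nₑ = n₁n₂/(n₁+n₂),

is available for moderately large samples and is automatically replaced by
permutation (with a warning) when Nₑ < 10. Per-category comparisons across
replicate embryos use the standard unpaired Welch t-test on per-embryo
proportions — deliberately an off-the-shelf convenience, not a
contribution.

## Junctional polarity

Planar cell polarity signal enriches on opposite cell edges, so it is
treated as a nematic (period 180°). Per cell,
z = Σ I_k·e^(2iφ_k) / Σ I_k over boundary samples (φ = outward-normal
angle, I = intensity); magnitude = |z|, axis = arg(z)/2 mod 180°. A pure
1 + cos 2(φ − φ₀) modulation gives magnitude 1/2 and axis φ₀. Tissue
polarity averages per-cell nematics in the angle-doubled complex plane —
one vote per cell by default ("average direction of polarity"), with
intensity weighting as a flag, since published rose-plot averages rarely
state which is used. Orthogonal axes cancel exactly. Rose histograms bin
per-cell axes over [0°, 180°) with conserved total weight.

On irregular single cells the estimator couples weakly to cell-shape
anisotropy (the boundary-normal distribution is not uniform), adding
mean-zero scatter of order the cell's elongation to per-cell estimates;
it averages out at tissue level.

## The synthetic generator

The generator emulates a live-imaged basal layer with every parameter
explicit, so each analysis stage can be checked by parameter recovery.

**Packing.** Cell count = round(density × area) — the realised density
always matches the target. Packing is a Voronoi tessellation of uniform
points, relaxed by 2 Lloyd iterations (a centroidal-relaxed tessellation
reproduces realistic polygon-class distributions, mode 6, without a
mechanics engine) and clipped to the field rectangle via generator
mirroring. Defaults describe an E14.5-like wildtype layer: 0.86 cells per
100 μm² (≈116 μm² mean area), heights 7.9 ± 1.5 μm (truncated normal),
150 × 150 μm field, mitotic index 2.5%.

**Division angles.** Mixture mode draws the category from weights
(default 0.51/0.29/0.20) and the angle uniformly within the category
bounds; a sine-weighted ("isotropic") within-bin law exists for 3D-null
simulations, since no within-bin law is established. Hertwig mode divides
along the interphase 3D long axis of an ellipsoid-like cell: the longest
planar chord when the cell is wider than tall (elevation 0°), the
apical-basal axis when taller than wide (elevation 90°), plus wrapped
Gaussian noise (default SD 10°) reflected into [0°, 90°]. This binary
long-axis rule is what lets planar dividers have H:W < 1 and
perpendicular dividers H:W > 1 simultaneously; a prism-diagonal rule
(elevation = arctan(h/w)) would make planar divisions impossible for any
cell of positive height and was rejected.

**Fates and tracks.** True fate is drawn per category from
P(symmetric | category), default (0.94, 0.41, 0.11). Mother tracks end at
the division frame; daughters begin the next frame separated by
`daughter_separation` (default 6 μm — a plausible placeholder, no
published measurement exists) along the sampled 3D axis, so the analyser's
angle equals the sampled angle exactly on noise-free tracks. Suprabasal
daughters ramp to threshold + 5 μm within 3 frames and stay; basal
daughters relax to the basal nuclear level (5.0 ± 0.5 μm — placeholder).
The generator and analyser share one basal-threshold convention (default
10 μm nuclear z). Division frames whose fate window does not fit in the
movie are rejected. Track jitter defaults to zero (idealised tracks);
`xy_noise_sd` / `z_noise_sd` enable robustness studies, under which fate
error is monotone in noise.

**Edge intensities.** Sample intensity at boundary-normal angle φ is
baseline·(1 + 2m·cos 2(φ − φ_cell)) + Gaussian noise, clipped at 0, with
samples spaced ~1 μm along each junction. The factor 2 makes the per-cell
nematic estimator recover m in expectation; for m > 0.5 clipping makes
recovery saturate. Per-cell axes scatter about the tissue axis with SD
10° by default. Boundary-touching cells emit no samples: their clipped
rectangle edges are not junctions and their axis-aligned normals would
bias the tissue nematic. The ground truth records the *realised* tissue
nematic (the resultant of the drawn per-cell axes at magnitude m over
interior cells): axis scatter attenuates the true tissue magnitude by
e^(−2σ²) ≈ 0.94 at σ = 10°, and that attenuation is a property of the
tissue, not estimator error.

**Determinism.** All randomness flows from per-stage generators derived
from the single config seed; a fixed seed reproduces every output
byte-for-byte, and the pipeline report is byte-identical across runs.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the generator at the
sample sizes the underlying study design uses: ~300 divisions per
condition for category recovery (200 replicates), n = 284 for the
fate-orientation table, n = 310 vs 271 for the genotype-scale Kuiper
comparison, n = 72 for the long-axis experiment, n = 150/group for null
calibration (2000 replicates at B = 999 permutations) and n = 300/group
for power (500 replicates), and three pooled fields per polarity
replicate, matching rose-plot practice. The long-axis experiment uses a
crowded condition (3.0 cells per 100 μm², paper-scale heights) so that
both planar and perpendicular divisions occur — at wildtype density
nearly all cells are wider than tall and long-axis divisions are almost
exclusively planar.

## What passing tests do and do not show

The generator's cells are convex Voronoi polygons with independent
heights, tracks are piecewise-linear with optional Gaussian jitter, and
intensities are Gaussian about the cosine model. Real basal layers have
curved junctions, correlated shape/height fields, neighbour exchanges,
photobleaching and segmentation error — none of which are modelled.
Passing recovery tests therefore validates the *estimators and their
conventions* (angle measurement, fate rule, shape tensors, Kuiper
inference, nematic averaging), not robustness to microscopy artefacts.
Specifically out of scope: raw-fluorescence segmentation and nucleus
tracking, mitotic-phase classification from morphology, delamination
detection, cell-mechanical simulation, and vectorial (period-360°) PCP
estimation.
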
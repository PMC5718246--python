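# Methods

## Problem and model

A synaptic punctum in an immunofluorescence (IF) micrograph is a compact,
roughly isotropic bright spot, typically 0.4–4 μm across, riding on a diffuse
background. Simple global thresholding faces two opposing failure modes: a low
threshold merges neighboring puncta and admits background, while a high
threshold captures only each punctum's bright core and under-reports its area.
This package combines three fixed thresholds with a gradient-guided trace
refinement so that detection sensitivity and trace fidelity are decoupled.

The processing model per image:

1. intensities normalized to [0, 1] by the source bit depth (8- or 16-bit);
2. 3×3 median pre-filter (optional) — robust to shot noise, edge-preserving,
   which matters because the gradient templates below are edge images;
3. strict thresholding at 30/255, 70/255, 220/255 (configurable), giving
   nested binary masks (level 3 ⊆ level 2 ⊆ level 1);
4. per level: connected-component labeling (8-connectivity throughout);
   removal of ROIs whose mean Sobel-gradient magnitude does not exceed the
   background removal factor; watershed splitting; optional MAP2 correlation;
   inclusive size discrimination to [0.16, 6.25] μm²;
5. trace optimization (below) for levels 2 and 3;
6. cross-level deduplication: an ROI is discarded if it shares a pixel with
   any ROI of a higher level, so each punctum is represented once, by the
   highest threshold that detected it; a final size discrimination keeps
   optimized traces inside the physical band;
7. measurement via `skimage.measure.regionprops`: area = pixel count × pixel
   area, mean intensity = mean normalized value × 255 (one display scale for
   all bit depths keeps rounds comparable), centroid = unweighted pixel-center
   mean in μm.

## Trace optimization

Sobel gradient magnitudes are computed twice: `G1 = |∇I|` forms a single
bright ring around an isotropic punctum (for a Gaussian profile of width σ the
ring peaks at radius σ), and `G2 = |∇G1|` forms two rings, one inside and one
outside the first. Both are rescaled by their own maxima to [0, 1]; a flat
image yields all-zero templates.

For each threshold level the ROIs are grown by one shared integer dilation
radius. Phase 1 climbs the mean of `G1` over the trace (edge) pixels of the
dilated ROIs — the MIG — and stops at the first strict decrease (or the cap,
default 10 px ≈ 1 μm at 0.099 μm/px). Phase 2 continues outward from the
phase-1 argmax, climbing the mean of `G2` (the MIGG); because it starts at the
inner-ring optimum and only grows, the first MIGG maximum it meets is the
outer `G2` ring, which is where the footprint ends. Ties prefer the smaller
radius. Dilation uses nearest-seed label expansion, so two ROIs separated by
the watershed can never merge; contested pixels go to the nearer ROI.

Two deliberate interpretations:

* **Mean over trace pixels.** A formal whole-image average of
  `gradient × trace` would be dominated by the fixed number of zero pixels and
  would grow monotonically with trace length, leaving the loop without an
  interior maximum; the mean over trace pixels is the reading under which the
  optimization is well-posed. The whole-image variant remains available as
  `objective_mean_mode="all-pixels"` for comparison.
* **Shared radius per level.** One radius per threshold level per image (not
  per ROI) makes the trace optimal for the average-shaped punctum in the
  field; unusually large or small puncta are traded off (see Limitations).

All dilation is owned by the optimization stage: the loop starts at radius 0,
and the background filter always sees undilated cores, whose gradient means
are well defined. This removes the circularity of "dilate by the optimized
size" occurring before the optimizer has run.

## MAP2 correlation

Dendrites are segmented from the neurite channel by Otsu's method, implemented
as an exhaustive scan of all 256 bin edges of a fixed histogram over [0, 1]
(ties take the lowest maximizing edge; components under 4 px are discarded as
noise). Somata are the closed, hole-filled foreground regions that survive a
morphological opening of 2 μm radius and cover at least 80 μm² (≈ a 10 μm
cell body). The opening is essential: an area floor alone would classify any
large connected dendrite network as a soma. Only the largest soma's area is
reported, which keeps small spuriously segmented objects from biasing the
soma statistic.

The correlation region is the dendrite mask (minus soma pixels) dilated by
`round(margin / μm-per-px)` pixels — default margin 1.5 μm — unioned with the
somata when soma inclusion is on. A punctum is retained if any of its pixels
touches the region. Removing soma pixels before dilation is what makes soma
inclusion a real switch; with them left in, the dilated dendrite mask would
always cover the somata.

## Statistics

The unit of replication is the image; each round (condition folder)
contributes one value per image for the chosen parameter (count, mean area,
mean intensity, density per MAP2 area). The layer provides the classical
one-way ANOVA decomposition (group means ± SEM attached), Tukey–Kramer
all-pairs comparisons using the studentized-range distribution with the
Kramer `1/n_i + 1/n_j` correction for unequal group sizes, a pooled-variance
two-tailed t test, and a one-sample K-S test against a normal with the
sample's own moments. The K-S p value is the asymptotic one and is
conservative toward normality because the moments are estimated from the
sample (a Lilliefors-type composite null); a parametric-bootstrap p value is
available via `ks_normality(x, n_bootstrap=...)`.

## Synthetic fields

The generator emulates two-channel confocal fields of cultured neurons at
0.0992 μm/px (a 101.6 μm field at 1024 px; default fields are 256 px for
speed). The puncta channel is a sum of isotropic Gaussian spots over a flat
background (0.02) with additive Gaussian noise (sd 0.06; Poisson shot noise
optional); defaults are 30 puncta with σ = 2–5 px (footprint diameters
0.8–2.0 μm) and peaks 0.6–0.95 of full scale, i.e. SNR ≈ 10–16. The neurite
channel holds 2–3 smooth random-walk ribbons ~1 μm wide and a ~12 μm disk
soma with mild multiplicative texture; 85% of puncta are placed on ribbons.
Merged pairs (to exercise the watershed) are placed using the saddle-point
geometry of two equal-width Gaussians — separation between the fuse distances
of the lowest and middle thresholds — so each pair fuses at threshold 1,
stays separate at threshold 2, and keeps two intensity maxima.

What the simulator does *not* model: a realistic point-spread function and
its diffraction rings, intensity-dependent (Poisson-dominated) noise unless
enabled, non-circular or overlapping puncta, uneven illumination, and the
dim MAP2 signal often seen inside real cell bodies. Tests passing on these
fields therefore demonstrate the algorithm's correctness and calibration, not
its performance on any particular microscope's data.

Detection scoring matches detections to truth greedily by centroid distance
(one-to-one, default radius 0.5 μm) and reports recall, precision, and area
errors relative to the true 2σ-disk footprint π(2σ)².

## Numerical choices

* Thresholds compare strictly (`>`); 16-bit images use the same fractional
  thresholds as 8-bit ones.
* Watershed seeds are regional maxima of the 3×3-median-filtered intensity
  inside the mask; maxima closer than 2 px are merged into one seed, which
  mitigates plateau-driven over-segmentation. Components left unseeded (border
  plateaus) fall back to connected-component labels.
* The background filter compares strictly, so a flat field (zero gradient)
  retains nothing at any factor ≥ 0.
* Size bounds are inclusive. Margin-to-pixel conversion rounds to nearest.
* Degenerate inputs raise typed errors rather than returning silent zeros:
  constant images have no Otsu threshold, empty traces have no objective,
  zero MAP2 area flags density as undefined, constant samples have no K-S or
  t statistic.
* Batch processing quarantines per-image failures (recorded with the failing
  stage) and continues; nothing in the pipeline is random, so identical
  inputs and configuration give byte-identical CSVs.

## Problem sizes used in the checks

The automated checks run on 192–256 px synthetic fields (up to 24 images for
the six-round trend), 20 single-spot fields for the radius-search oracle, 100
random images for the Otsu oracle, and 2,000 simulations for the ANOVA
type-I calibration — sizes chosen so the whole suite completes in about a
minute on one core while keeping every statistical check's Monte-Carlo error
well below its acceptance band.

## Known limitations

* The optimized trace targets the outer second-gradient ring, which for a
  Gaussian profile sits at ≈ √3 σ; relative to a 2σ-disk reference footprint
  the recovered area is therefore systematically ~25% low even when the
  optimization works perfectly. This is inherent to the trace criterion (the
  outermost gradient ring excludes the dimmest tail pixels), and it is why
  mean absolute area error against that reference hovers near 0.25 in the
  reproduction script.
* Because the dilation radius is shared per level, fields mixing very wide,
  dim puncta with small, bright ones spread individual area errors well
  beyond the systematic offset (the widest, dimmest puncta can read ~45%
  low). Per-punctum radii would fix this at the cost of abandoning the
  average-shape optimization; we keep the shared radius.
* Soma segmentation assumes compact, Otsu-bright cell bodies; high-density
  cultures or dim somatic MAP2 will degrade it. It can be toggled off.
* The watershed can still over-split on noisy plateaus; disabling it trades
  that for under-splitting of apposed puncta.
* Only 2-D fields are processed; Z-stacks must be maximum-projected upstream,
  and the tool refuses them rather than guessing a projection.
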
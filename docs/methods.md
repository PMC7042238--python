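# Methods

This note records the models, conventions and design choices behind
`rgcmosaic`, in the spirit of a software methods section: what is
simulated, how each measurement is defined, which knobs matter, and
what the synthetic validation does and does not demonstrate.

## Synthetic retina model

The generator produces ground-truthed stand-ins for Brn3a-immunostained
retinal whole-mounts. It is a *benchmarking* model: rich enough to
exercise every stage of the quantification chain, deliberately not a
biophysical simulation.

**Mosaic.** RGC positions follow a hard-core point process sampled by
dart throwing (simple sequential inhibition): candidates are drawn
uniformly and rejected if closer than the exclusion distance to an
accepted point, until the expected count n = density × area is reached
or 200·n attempts are exhausted (then an error reports achieved versus
requested density — the process jams near coverage ~0.55). Points are
generated in a guard band two exclusion distances beyond the field and
cropped back, so edge densities are unbiased. With exclusion 0 this
reduces to binomial (Poisson-like) sampling whose regularity index
converges to √(π/(4−π)); the exclusion distance tunes regularity
upward, spanning the range reported for real RGC mosaics.

**Degeneration.** Each cell survives an independent Bernoulli draw with
its quadrant's survival probability. This models sector-dependent loss
(primary superior loss after a dorsal nerve cut, milder diffuse
inferior loss) while preserving the hard-core property of the
survivors, since thinning a hard-core pattern cannot create close
pairs. Real secondary degeneration is spatially correlated
(clustered); independent thinning is the simplest model that produces
the quadrant-wise density signal the pipeline measures, and tests on
it say nothing about clustered-loss recovery.

**Rendering.** Somas are isotropic flat-topped blobs — sixth-order
super-Gaussians amp·exp(−ln2·(2r/d)⁶) whose full width at half maximum
equals the soma diameter d — because stained nuclei in maximum
intensity projections image as plateaus with steep edges; a plain
Gaussian profile was rejected since its footprint above any fixed
threshold is only ~0.6·d, which systematically mis-sizes somas against
a physical size gate. Blob amplitude is soma_peak − background_level
above the *local* background; overlapping somas and vessels combine by
per-pixel maximum (saturating stain rather than additive photons).
The background is a level plus a diagonal linear ramp (uneven
illumination); vessels are straight ribbons of the soma amplitude at
random angles; i.i.d. Gaussian noise is added last and the image is
clipped to 8 bits. No optical PSF, z-structure or multi-channel
content is modelled.

**Defaults** (plausible-regime choices for an adult rat retina, not
measurements): density 2000 cells/mm², exclusion 10 µm, soma diameter
14 ± 2 µm truncated positive, peak 200 / background 20 / gradient 30 /
noise SD 5 on the 8-bit scale, 1 µm/px over a 1 × 1 mm field. One
`numpy` PCG64 stream per scene, seeded from the scene spec, consumed in
the documented order (mosaic, thinning, diameters, vessels, noise), so
a scene is a pure function of its spec.

## Detection chain conventions

The chain mirrors the ImageJ particle-analysis recipe; every
convention the original leaves implicit is fixed here:

- **8-bit conversion**: linear min–max rescale, round half-up;
  constant images map to zero. Not display-range dependent.
- **High pass**: the background is a grey opening — minimum then
  maximum filter over a square window of half-width 50 µm (default) on
  a σ = 2 px smoothed copy — subtracted and clamped at zero. A
  subtracted Gaussian blur was rejected: at study densities the somas'
  own integrated intensity lifts a mean-based background estimate by
  tens of grey levels, dragging blob peaks below the fixed threshold,
  whereas the opening sits under the blobs (this is also the behaviour
  of the rolling-ball background subtraction the ImageJ lineage uses).
  The window must exceed the largest soma; 50 µm leaves a wide margin.
- **Threshold**: foreground where intensity ≥ 130 (inclusive lower
  bound, the ImageJ convention).
- **Watershed**: Euclidean distance transform (outside the frame is
  background, so border-cut objects end in caps), markers = regional
  maxima deeper than 1 px (h-maxima) merged within ~0.7 of the minimum
  soma diameter. The 1 px depth keeps ribbon ridges — including the
  slightly deeper maxima where thin ribbons cross — markerless, so
  vessels stay single elongated particles instead of being chopped
  into soma-sized rounds, while soma–soma saddles at the mosaic's
  packing floor (~3 px deep) still split. No watershed lines are
  discarded: per-label pixel counts sum exactly to the foreground
  count.
- **Measurement**: 8-connected labels; area = pixel count × px²;
  perimeter by the weighted chain-code estimator
  (`skimage.measure.perimeter`), under which a large rasterized square
  measures 4s (circularity → π/4) and a large disk lands in
  [0.90, 0.95]; circularity clamped at 1 (small rasterized disks
  overshoot); centroid is the unweighted pixel mean; mean grey value
  over member pixels.
- **Gates**: size applies to the area-equivalent diameter by default
  (the 7–21 µm band is a length); an area-units mode interprets the
  same bounds as µm². Circularity is strictly > 0.7. Rejected
  particles are returned with reasons for audit.

## Mosaic statistics

NND uses a KD-tree, verified exactly against the O(n²) scan; no edge
correction is applied (the classic macros apply none; the inward bias
of mean NND is <2% at the densities and field sizes used, and the
Poisson-limit test passes within its band with the bias included). RI
uses the sample (n−1) SD by default with a population-SD switch, since
the original macro's choice is unknowable; RI on a degenerate
(zero-variance) pattern is an explicit error. Density is count over
the supplied reference area.

## Partition and attribution

Quadrants are 90° half-open wedges centred on the dorsal and ventral
axes about the optic-disc position: with θ the counter-clockwise angle
from the dorsal axis, superior is [−45°, 45°), nasal [45°, 135°),
inferior [135°, 225°), temporal [225°, 315°). The half-open bins fix
boundary ties; a point on the disc centre is superior by convention.
The tissue mask is Otsu on a blurred copy (largest component, holes
filled), with a wall-to-wall fallback when the Otsu split separates
the classes by under 10 grey levels — Otsu always splits something,
even pure noise on a full-frame mount. The disc centre defaults to the
mask centroid when not supplied. Per-quadrant NND is computed within
the region by default (a region-aggregated global-neighbour switch
exists; the original macro's choice is not recoverable). Relative loss
is 1 − density/reference with the naive-group mean as reference.

## DARC normalization

Observer counts are averaged (median switch available) into DC;
DC% = 100·(DC − D̄C_C)/(D̄C_P − D̄C_C) with group means computed once
per experiment — not leave-one-out — so the normalized group means of
the lesion-only and naive groups are exactly 100 and 0. The ratio is
computed before scaling by 100 so the endpoints are floating-point
exact. Values outside [0, 100] are legitimate for extreme animals;
equal group means raise an explicit degenerate-normalization error.

## Group inference

Classical fixed-effects one-way ANOVA (between/within sums of squares,
F = MSB/MSW, p from the F distribution). Post-hoc comparisons are
two-sample pooled-variance Student t-tests — each pair pools its own
two groups, matching the classical Bonferroni post-test — with p
multiplied by the family size m and capped at 1. The family is
configurable: explicit pairs, all pairs against a named control, or
all pairs; m is always reported, since the multiplicity depends on it.

## Validation scope and limitations

The acceptance-grade checks (detection recall/precision ≥ 0.95,
density recovery within 5% at 1000–3000 cells/mm², survival-fraction
recovery within 3 binomial SDs, zero vessel-derived acceptances) hold
on the synthetic model at the stated problem sizes: 1 mm² fields at
1 µm/px, 10–20 seeds per claim. They demonstrate internal consistency
of the chain, not performance on real micrographs, which add optical
blur, staining heterogeneity, soma-size gradients across eccentricity,
tissue tears and mounting artifacts. The quadrant attribution analyses
a single endpoint; longitudinal primary/secondary decomposition is out
of scope. Melanopsin-positive RGCs (not labelled by Brn3a) are neither
simulated nor claimed.
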
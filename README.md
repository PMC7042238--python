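# rgcmosaic

Quantification machinery for retinal ganglion cell (RGC) survival
studies on whole-mounted retinas: automated Brn3a⁺ soma detection in
fluorescence images, mosaic spatial statistics, quadrant-based
attribution of primary versus secondary degeneration, normalized DARC
(Detection of Apoptosing Retinal Cells) counts, and the accompanying
group statistics — all exercisable end-to-end on a ground-truthed
synthetic retina generator, so every stage can be validated without
animal data.

## Who this is for

Vision scientists quantifying RGC loss after optic-nerve injury (e.g.
partial optic nerve transection, pONT, which cuts only dorsal axons so
the superior retina suffers primary injury while the inferior retina
degenerates secondarily), and anyone who needs a reproducible,
scriptable replacement for the classic ImageJ particle-counting recipe.

## The methods at the core

**Soma detection.** The 8-bit Brn3a channel is background-flattened
with a high-pass (rolling-ball style) filter, thresholded at intensity
130, split with a distance-transform watershed, and measured per
particle. Particles are accepted as RGC somas iff their area-equivalent
diameter 2√(A/π) lies in the 7–21 µm band **and** circularity
4πA/P² > 0.7 — the circularity gate rejects brightly stained but
elongated blood vessels.

**Mosaic statistics.** For the accepted centroid set:
density = n/area (cells/mm²); nearest-neighbour distance
NND_i = min_{j≠i} ‖x_i − x_j‖; regularity index
RI = mean(NND)/SD(NND). A random (Poisson) mosaic has
RI = √(π/(4−π)) ≈ 1.913; healthy RGC mosaics are more regular
(larger RI), and degeneration pushes RI down toward — and below — the
Poisson value.

**Quadrant attribution.** The whole-mount is segmented into four 90°
wedges (superior, nasal, inferior, temporal) about the optic-disc
centre, oriented by the dorsal axis; per-quadrant densities against a
naive reference attribute loss to primary (superior) or secondary
(inferior) degeneration.

**Normalized DARC count.** Per-animal apoptotic-spot counts from
masked observers are averaged into DC and expressed as

    DC% = 100 · (DC − D̄C_C) / (D̄C_P − D̄C_C)

where D̄C_P and D̄C_C are the lesion-only and naive group means, so the
scale is pinned at 0 (naive mean) and 100 (lesion mean).

**Inference.** Means ± SEM, pooled-variance Student t-tests, and
classical one-way ANOVA with Bonferroni post-tests against control
groups.

## Worked example

Simulate a six-animal experiment — three naive retinas and three with
superior-dominant loss (survival: superior 0.35, inferior 0.75,
nasal/temporal 0.9) at 2000 cells/mm² — then detect, partition and
compare:

```python
import rgcmosaic as rm
from rgcmosaic.pipeline import ImageEntry, RunConfig, summarize_groups

lesion = {"superior": 0.35, "inferior": 0.75, "nasal": 0.9, "temporal": 0.9}
images = []
for i in range(3):
    images.append(ImageEntry(f"naive_{i}", "naive", scene=rm.SceneSpec(
        field_width_um=800, field_height_um=800,
        target_density_cells_per_mm2=2000, seed=100 + i)))
    images.append(ImageEntry(f"pont_{i}", "pONT", scene=rm.SceneSpec(
        field_width_um=800, field_height_um=800,
        target_density_cells_per_mm2=2000,
        survival_by_quadrant=lesion, seed=200 + i)))

bundle = rm.run_pipeline(RunConfig(images=images), write=False)
print(summarize_groups(bundle.whole_mount_stats, "density"))
print(bundle.region_stats.groupby(["group", "region"])["density"].mean())
```

which prints (seeds as above):

```
group  metric        mean       sem  n
naive density 1958.854167  5.437660  3
 pONT density 1429.687500 14.518083  3

naive  inferior    2001.0
       nasal       1929.0
       superior    1955.0
       temporal    1951.0
pONT   inferior    1455.0
       nasal       1802.0
       superior     693.0
       temporal    1767.0
```

Detected naive density sits within ~2% of the simulated 2000 cells/mm²,
and the per-quadrant table recovers the imposed pattern: superior
density collapses to ~35% of naive (primary loss) while inferior
retains ~73% (secondary loss). The density ANOVA for these two groups
gives F = 1165 and a Bonferroni-adjusted p ≈ 4·10⁻⁶ (***).

The same pipeline runs from the shell: `rgcmosaic synth` writes
ground-truthed TIFF scenes, `rgcmosaic detect` emits a particle CSV
from any single-channel TIFF, and `rgcmosaic run config.yaml` executes
a full configured experiment. See `rgcmosaic --help`.

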
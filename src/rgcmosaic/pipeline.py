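"""End-to-end orchestration: synthesize or load whole-mount images,
detect somas, partition into quadrants, compute mosaic statistics and
run the group-level ANOVA, writing a reproducible result bundle.

A run is described by a declarative config (YAML or an in-memory
:class:`RunConfig`).  Outputs are plain CSV/JSON; identical config and
seed give identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detection import DetectionParams, RawImage, detect_somas
from .inference import one_way_anova, sem_summary
from .mosaic import PointSet, mosaic_stats
from .partition import QUADRANTS, estimate_retina_mask, per_region_stats, quadrant_areas_mm2
from .synthetic import SceneSpec, make_scene

log = logging.getLogger("rgcmosaic")

__all__ = ["ImageEntry", "RunConfig", "ResultBundle", "validate_config", "run_pipeline", "load_config"]


@dataclass
class ImageEntry:
    """One retina in the run: either a TIFF path or a synthetic spec."""

    animal_id: str
    group: str
    path: str | None = None
    scene: SceneSpec | None = None
    pixel_size_um: float | None = None
    disc_center_xy_um: tuple[float, float] | None = None
    dorsal_axis_deg: float = 90.0


@dataclass
class RunConfig:
    images: list[ImageEntry]
    detection: DetectionParams = field(default_factory=DetectionParams)
    reference_group: str = "naive"
    output_dir: str = "rgcmosaic_out"
    seed: int = 0
    within_region_nnd: bool = True


@dataclass
class ResultBundle:
    particles: dict[str, pd.DataFrame]
    whole_mount_stats: pd.DataFrame
    region_stats: pd.DataFrame
    anova: pd.DataFrame
    skipped: dict[str, str]
    run_log: dict


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; synthetic entries carry a ``scene``
    mapping of SceneSpec fields."""
    raw = yaml.safe_load(Path(path).read_text())
    images = []
    for e in raw.get("images", []):
        scene = e.pop("scene", None)
        if scene is not None:
            if "survival_by_quadrant" in scene:
                scene["survival_by_quadrant"] = dict(scene["survival_by_quadrant"])
            if "disc_center_xy_um" in scene and scene["disc_center_xy_um"] is not None:
                scene["disc_center_xy_um"] = tuple(scene["disc_center_xy_um"])
            scene = SceneSpec(**scene)
        if e.get("disc_center_xy_um") is not None:
            e["disc_center_xy_um"] = tuple(e["disc_center_xy_um"])
        images.append(ImageEntry(scene=scene, **e))
    det = DetectionParams(**raw.get("detection", {}))
    return RunConfig(
        images=images,
        detection=det,
        reference_group=raw.get("reference_group", "naive"),
        output_dir=raw.get("output_dir", "rgcmosaic_out"),
        seed=int(raw.get("seed", 0)),
        within_region_nnd=bool(raw.get("within_region_nnd", True)),
    )


def validate_config(config: RunConfig) -> list[str]:
    """Report-only validation: missing files, bad parameter ranges,
    duplicate animal ids.  An empty list means the config is usable."""
    problems = []
    seen = set()
    for e in config.images:
        if e.animal_id in seen:
            problems.append(f"duplicate animal_id {e.animal_id!r}")
        seen.add(e.animal_id)
        if e.path is None and e.scene is None:
            problems.append(f"{e.animal_id}: neither image path nor synthetic scene")
        if e.path is not None and not Path(e.path).exists():
            problems.append(f"{e.animal_id}: missing image file {e.path}")
        if e.path is not None and e.pixel_size_um is not None and e.pixel_size_um <= 0:
            problems.append(f"{e.animal_id}: pixel_size_um must be > 0")
    d = config.detection
    if not 0 < d.min_diam_um < d.max_diam_um:
        problems.append("detection: need 0 < min_diam_um < max_diam_um")
    groups = {e.group for e in config.images}
    if config.images and config.reference_group not in groups:
        problems.append(f"reference group {config.reference_group!r} has no images")
    return problems


def _particle_table(result) -> pd.DataFrame:
    rows = []
    for p, acc in [(p, True) for p in result.accepted] + [
        (p, False) for p in result.rejected
    ]:
        rows.append(
            {
                "label": p.label_id,
                "x_um": p.centroid_xy_um[0],
                "y_um": p.centroid_xy_um[1],
                "area_um2": p.area_um2,
                "equiv_diam_um": p.equiv_diam_um,
                "perimeter_um": p.perimeter_um,
                "circularity": p.circularity,
                "mean_intensity": p.mean_intensity,
                "accepted": acc,
                "reject_reason": result.reject_reasons.get(p.label_id, ""),
            }
        )
    return pd.DataFrame(rows).sort_values("label").reset_index(drop=True) if rows else pd.DataFrame(
        columns=["label", "x_um", "y_um", "area_um2", "equiv_diam_um",
                 "perimeter_um", "circularity", "mean_intensity", "accepted", "reject_reason"]
    )


def _load_entry(entry: ImageEntry) -> tuple[RawImage, SceneSpec | None]:
    if entry.scene is not None:
        scene = make_scene(entry.scene)
        return RawImage(scene.pixels, entry.scene.pixel_size_um), entry.scene
    pixels = tifffile.imread(entry.path)
    if entry.pixel_size_um is None:
        raise ValueError(f"{entry.animal_id}: pixel_size_um required for file input")
    return RawImage(pixels, entry.pixel_size_um), None


def run_pipeline(config: RunConfig, write: bool = True) -> ResultBundle:
    """Process every image through detection, partition and statistics,
    then ANOVA per metric across groups; failures on single images are
    logged and skipped."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    if not config.images:
        log.warning("config lists no images; producing an empty bundle")

    particles: dict[str, pd.DataFrame] = {}
    wm_rows, region_rows = [], []
    skipped: dict[str, str] = {}
    for entry in config.images:
        try:
            img, scene = _load_entry(entry)
            result = detect_somas(img, config.detection)
            table = _particle_table(result)
            particles[entry.animal_id] = table
            pts = np.array([p.centroid_xy_um for p in result.accepted]).reshape(-1, 2)
            if scene is not None:
                area_mm2 = scene.area_mm2
                disc = scene.disc_center
                dorsal = scene.dorsal_axis_deg
                h, w = scene.shape_px
                px = scene.pixel_size_um
                qareas = _rect_quadrant_areas(w, h, px, disc, dorsal)
            else:
                retina = estimate_retina_mask(
                    img.pixels, img.pixel_size_um,
                    entry.disc_center_xy_um, entry.dorsal_axis_deg,
                )
                area_mm2 = retina.area_mm2
                disc = retina.disc_center_xy_um
                dorsal = retina.dorsal_axis_deg
                qareas = quadrant_areas_mm2(retina)
            ms = mosaic_stats(PointSet(pts, area_mm2))
            wm_rows.append(
                {
                    "animal_id": entry.animal_id,
                    "group": entry.group,
                    "n": ms.n,
                    "area_mm2": area_mm2,
                    "density": ms.density_cells_per_mm2,
                    "mean_nnd": ms.mean_nnd_um,
                    "sd_nnd": ms.sd_nnd_um,
                    "ri": ms.regularity_index,
                }
            )
            for rs in per_region_stats(
                pts, disc, qareas, dorsal, within_region_nnd=config.within_region_nnd
            ):
                region_rows.append(
                    {
                        "animal_id": entry.animal_id,
                        "group": entry.group,
                        "region": rs.region,
                        "n": rs.n,
                        "area_mm2": rs.area_mm2,
                        "density": rs.density_cells_per_mm2,
                        "mean_nnd": rs.mean_nnd_um,
                        "sd_nnd": rs.sd_nnd_um,
                        "ri": rs.regularity_index,
                    }
                )
        except Exception as exc:  # per-image isolation
            log.error("skipping %s: %s", entry.animal_id, exc)
            skipped[entry.animal_id] = str(exc)

    wm = pd.DataFrame(wm_rows)
    regions = pd.DataFrame(region_rows)
    anova = _group_anova(wm, config.reference_group)
    bundle = ResultBundle(
        particles, wm, regions, anova, skipped,
        run_log={
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_images": len(config.images),
            "n_skipped": len(skipped),
        },
    )
    if write:
        _write_bundle(bundle, config)
    return bundle


def _rect_quadrant_areas(w_px, h_px, pixel_size_um, disc, dorsal) -> dict[str, float]:
    """Exact pixel partition of a full rectangular field (synthetic
    scenes have no tissue boundary, so the field is the mask)."""
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    from .partition import assign_quadrants

    pts = np.column_stack([xx.ravel() * pixel_size_um, yy.ravel() * pixel_size_um])
    labels = assign_quadrants(pts, disc, dorsal)
    px_area = pixel_size_um**2 * 1e-6
    return {q: float(np.sum(labels == q)) * px_area for q in QUADRANTS}


def _group_anova(wm: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    rows = []
    if wm.empty:
        return pd.DataFrame(columns=["metric", "f", "df_between", "df_within", "p", "pair", "raw_p", "bonferroni_p", "stars"])
    for metric in ("density", "mean_nnd", "ri"):
        data = {
            g: sub[metric].dropna().to_numpy()
            for g, sub in wm.groupby("group")
        }
        data = {g: v for g, v in data.items() if len(v) >= 2}
        if len(data) < 2:
            continue
        try:
            res = one_way_anova(data, control=None)
        except ValueError as exc:
            log.warning("ANOVA on %s failed: %s", metric, exc)
            continue
        for cmp in res.posthoc:
            rows.append(
                {
                    "metric": metric,
                    "f": res.f,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p": res.p_value,
                    "pair": "|".join(cmp.pair),
                    "raw_p": cmp.raw_p,
                    "bonferroni_p": cmp.bonferroni_p,
                    "stars": cmp.stars,
                }
            )
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_bundle(bundle: ResultBundle, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for animal, table in bundle.particles.items():
        table.to_csv(out / f"particles_{animal}.csv", index=False)
    bundle.whole_mount_stats.to_csv(out / "whole_mount_stats.csv", index=False)
    bundle.region_stats.to_csv(out / "region_stats.csv", index=False)
    bundle.anova.to_csv(out / "anova.csv", index=False)
    (out / "run_log.json").write_text(json.dumps(bundle.run_log, indent=2))
    if bundle.skipped:
        (out / "skipped.json").write_text(json.dumps(bundle.skipped, indent=2))


def summarize_groups(wm: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean +/- SEM of a metric per group (the bar-chart numbers)."""
    rows = []
    for g, sub in wm.groupby("group"):
        vals = sub[metric].dropna().to_numpy()
        if len(vals) >= 2:
            mean, sem = sem_summary(vals)
        else:
            mean, sem = (float(vals[0]) if len(vals) else np.nan), np.nan
        rows.append({"group": g, "metric": metric, "mean": mean, "sem": sem, "n": len(vals)})
    return pd.DataFrame(rows)
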
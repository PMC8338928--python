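"""End-to-end orchestration with a reproducible run manifest.

The stage order is: clean → daily metrics → Moving-Day threshold →
residence-area segmentation (per bird × Oct–Dec year) → kernel home ranges →
NDWI phase sampling → paired designs → mixed-model fits.  Each stage writes
its own files; the manifest records the config hash, the seed, per-stage
record counts and a SHA-256 of every output, so two runs of the same config
can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .homerange import annual_ranges, range_summary
from .movement import daily_movements, fit_moving_threshold
from .projection import LocalProjection
from .rasters import Raster
from .response import build_design, fit_water_model
from .segmentation import SegmentationResult, areas_to_geojson, segment_areas, stay_durations
from .simulate import Bundle, end_to_end_fixture
from .tracking import assign_age_windows, filter_speed_outliers, read_fixes, write_fixes
from .water import phase_samples, samples_to_frame


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str
    fixes_csv: str | None = None
    raster_dir: str | None = None
    simulate_preset: str | None = None  # simulate inputs instead of reading
    seed: int = 0
    analysis_years: tuple[int, ...] | None = None
    window_month_day: tuple[tuple[int, int], tuple[int, int]] = ((10, 1), (12, 31))
    max_speed_kmh: float = 150.0
    threshold_level: float = 0.80
    threshold_rounding_km: float = 1.0
    kde_cell_m: float = 500.0
    kde_min_fixes: int = 30
    models: tuple[str, ...] = ("a", "b")
    tagging_class: str = "adult"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def save_composite_dir(composites, raster_dir) -> None:
    """Write NDWI composites as ``ndwi_<start>.tif`` (+ JSON sidecars)."""
    from .water import NdwiComposite  # noqa: F401 - documented return type

    d = Path(raster_dir)
    d.mkdir(parents=True, exist_ok=True)
    index = []
    for comp in composites:
        name = f"ndwi_{comp.window_start.isoformat()}.tif"
        comp.raster.to_file(d / name)
        index.append(
            {
                "file": name,
                "window_start": comp.window_start.isoformat(),
                "frac_good": comp.frac_good,
                "frac_unclassified": comp.frac_unclassified,
            }
        )
    _write_json(d / "composites.json", index)


def load_composite_dir(raster_dir):
    """Inverse of :func:`save_composite_dir`."""
    from .water import NdwiComposite

    d = Path(raster_dir)
    index = json.loads((d / "composites.json").read_text())
    composites = []
    for entry in index:
        composites.append(
            NdwiComposite(
                window_start=date.fromisoformat(entry["window_start"]),
                raster=Raster.from_file(d / entry["file"]),
                frac_good=entry["frac_good"],
                frac_unclassified=entry["frac_unclassified"],
            )
        )
    return composites


def analyze_bundle(
    bundle: Bundle,
    threshold_level: float = 0.80,
    threshold_rounding_km: float = 1.0,
    models: tuple[str, ...] = ("a", "b"),
    fit_kwargs: dict | None = None,
) -> dict:
    """In-memory pipeline on a simulated bundle (no file IO).

    Returns a dict with daily metrics, the fitted threshold, per-bird-year
    segmentations, phase samples, paired designs and model fits.
    """
    cfg = bundle.config
    daily_frames = [daily_movements(t) for t in bundle.trajectories]
    daily = pd.concat(daily_frames, ignore_index=True)
    threshold = fit_moving_threshold(daily, level=threshold_level, rounding_km=threshold_rounding_km)

    segmentations: list[SegmentationResult] = []
    samples = []
    skipped: list[dict] = []
    for traj in bundle.trajectories:
        for year in cfg.years:
            window = (
                date(year, *cfg.window_start_month_day),
                date(year, *cfg.window_end_month_day),
            )
            seg = segment_areas(daily, traj, threshold, window,
                                projection=bundle.truth.projection)
            segmentations.append(seg)
            for area in seg.areas:
                samples.extend(
                    phase_samples(area, bundle.composites, bundle.truth.projection,
                                  skipped=skipped)
                )
    sample_df = samples_to_frame(samples)

    designs = {}
    fits = {}
    for model in models:
        design = build_design(sample_df, model)
        designs[model] = design
        if not design.empty and design["response"].nunique() == 2:
            fits[model] = fit_water_model(design, model, **(fit_kwargs or {}))
    return {
        "daily": daily,
        "threshold": threshold,
        "segmentations": segmentations,
        "samples": sample_df,
        "skipped_samples": skipped,
        "designs": designs,
        "fits": fits,
    }


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Any stage failure raises :class:`StageError` naming the stage and a
    machine-readable code.  The manifest (also written to
    ``<output_dir>/manifest.json``) contains no timestamps so reruns of the
    same config are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    # --- inputs ----------------------------------------------------------
    if config.simulate_preset is not None:
        bundle = end_to_end_fixture(config.simulate_preset, seed=config.seed)
        trajectories, composites = bundle.trajectories, bundle.composites
        projection = bundle.truth.projection
        years = config.analysis_years or bundle.config.years
        write_fixes(trajectories, out / "fixes.csv")
        manifest["stages"]["simulate"] = {
            "n_birds": len(trajectories),
            "n_fixes": int(sum(len(t) for t in trajectories)),
            "n_composites": len(composites),
            "n_true_areas": len(bundle.truth.areas),
        }
    else:
        if config.fixes_csv is None:
            raise StageError("clean", "no_input", "neither fixes_csv nor simulate_preset given")
        if not Path(config.fixes_csv).exists():
            raise StageError("clean", "missing_path", f"fixes file not found: {config.fixes_csv}")
        trajectories, _ = read_fixes(config.fixes_csv)
        if config.raster_dir is None or not Path(config.raster_dir).is_dir():
            raise StageError(
                "sample", "missing_path", f"raster directory not found: {config.raster_dir}"
            )
        composites = load_composite_dir(config.raster_dir)
        all_fixes = pd.concat([t.fixes for t in trajectories], ignore_index=True)
        projection = LocalProjection.for_points(
            all_fixes["lon"].to_numpy(), all_fixes["lat"].to_numpy()
        )
        if config.analysis_years is None:
            raise StageError("segment", "no_years", "analysis_years required for file inputs")
        years = config.analysis_years

    # --- clean ------------------------------------------------------------
    cleaned = []
    n_removed = 0
    for traj in trajectories:
        t2, removed = filter_speed_outliers(traj, max_kmh=config.max_speed_kmh)
        n_removed += len(removed)
        cleaned.append(t2)
    write_fixes(cleaned, out / "fixes_clean.csv")
    manifest["stages"]["clean"] = {
        "n_fixes": int(sum(len(t) for t in cleaned)),
        "n_removed_speed": n_removed,
    }

    windows_by_bird = {
        t.bird_id: assign_age_windows(t, t.start_date, config.tagging_class)  # type: ignore[arg-type]
        for t in cleaned
    }

    # --- metrics + threshold ---------------------------------------------
    daily = pd.concat([daily_movements(t) for t in cleaned], ignore_index=True)
    daily_out = daily.copy()
    daily_out["date"] = daily_out["date"].map(lambda d: d.isoformat())
    daily_out.to_csv(out / "daily_movements.csv", index=False, float_format="%.10g")
    threshold = fit_moving_threshold(
        daily, level=config.threshold_level, rounding_km=config.threshold_rounding_km
    )
    _write_json(
        out / "moving_threshold.json",
        {
            "quantile_level": threshold.quantile_level,
            "threshold_km": threshold.threshold_km,
            "achieved_coverage": threshold.achieved_coverage,
            "n_days": threshold.n_days,
        },
    )
    manifest["stages"]["metrics"] = {"n_days": len(daily)}
    manifest["stages"]["threshold"] = {
        "threshold_km": threshold.threshold_km,
        "achieved_coverage": threshold.achieved_coverage,
    }

    # --- segmentation -----------------------------------------------------
    segmentations = []
    for traj in cleaned:
        for year in years:
            window = (
                date(year, *config.window_month_day[0]),
                date(year, *config.window_month_day[1]),
            )
            segmentations.append(
                segment_areas(daily, traj, threshold, window, projection=projection)
            )
    _write_json(out / "areas.geojson", areas_to_geojson(segmentations))
    stay_durations(segmentations, windows_by_bird).to_csv(
        out / "stay_durations.csv", index=False, float_format="%.10g"
    )
    n_areas = int(sum(len(s.areas) for s in segmentations))
    manifest["stages"]["segment"] = {
        "n_areas": n_areas,
        "n_moving_days": int(sum(len(s.moving_days) for s in segmentations)),
    }

    # --- home ranges ------------------------------------------------------
    ranges = []
    for traj in cleaned:
        ranges.extend(
            annual_ranges(
                traj,
                windows_by_bird[traj.bird_id],
                cell_m=config.kde_cell_m,
                min_fixes=config.kde_min_fixes,
            )
        )
    pd.DataFrame(
        [
            {
                "bird_id": r.bird_id,
                "season": r.season,
                "age_class": r.age_class,
                "n_fixes": r.n_fixes,
                "bandwidth_m": r.bandwidth_m,
                "area_km2_95": r.area_km2_95,
                "area_km2_50": r.area_km2_50,
            }
            for r in ranges
        ]
    ).to_csv(out / "home_ranges.csv", index=False, float_format="%.10g")
    if ranges:
        range_summary(ranges).to_csv(
            out / "home_range_summary.csv", index=False, float_format="%.10g"
        )
    manifest["stages"]["homerange"] = {"n_ranges": len(ranges)}

    # --- NDWI sampling ----------------------------------------------------
    skipped: list[dict] = []
    samples = []
    for seg in segmentations:
        for area in seg.areas:
            samples.extend(phase_samples(area, composites, projection, skipped=skipped))
    sample_df = samples_to_frame(samples)
    sample_out = sample_df.copy()
    sample_out["date"] = sample_out["date"].map(lambda d: d.isoformat())
    sample_out.to_csv(out / "ndwi_samples.csv", index=False, float_format="%.10g")
    manifest["stages"]["sample"] = {"n_samples": len(sample_df), "n_skipped": len(skipped)}

    # --- models -----------------------------------------------------------
    reports = {}
    for model in config.models:
        design = build_design(sample_df, model)
        design_out = design.copy()
        design_out["date"] = design_out["date"].map(lambda d: d.isoformat())
        design_out.to_csv(out / f"design_{model}.csv", index=False, float_format="%.10g")
        if design.empty or design["response"].nunique() < 2:
            reports[model] = {"model": model, "skipped": "insufficient design"}
            continue
        result = fit_water_model(design, model)
        reports[model] = result.report()
        manifest["stages"][f"fit_{model}"] = {
            "n_obs": result.fit.n_obs,
            "marginal_r2": round(result.fit.marginal_r2, 6),
            "conditional_r2": round(result.fit.conditional_r2, 6),
        }
    _write_json(out / "model_reports.json", reports)

    # --- manifest ---------------------------------------------------------
    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    _write_json(out / "manifest.json", manifest)
    return manifest
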
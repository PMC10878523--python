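"""End-to-end orchestration: stages, run directories, truth evaluation.

A run executes the enabled stages in dependency order --

    simulate -> composite -> basemap -> breaks -> detect -> history -> stats

-- writing every intermediate product and a manifest (config hash, seed,
per-stage counts) into one run directory.  Stages can also be run one at a
time against an existing directory; a stage whose inputs are missing fails
naming the missing product.  ``evaluate_against_truth`` scores a run
against the synthetic generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breaks import TrendBreak
from .classify import forest_base_map
from .detect import (FireEvent, detect_breaks_grid, detect_fires,
                     events_to_csv, events_to_geojson)
from .history import NEVER, accumulate_history, summarize, time_since_fire
from .indices import compute_index, dnbr_stack
from .raster import RasterGrid, RasterStack, read_stack, index_to_ym
from .stats import (dunn_posthoc, filter_and_attach, fit_structure_model,
                    kruskal_wallis, recovery_assessment)
from .synthetic import (SceneConfig, FireSpec, SceneTruth, generate_landscape,
                        simulate_archive, simulate_footprints, write_archive)

__all__ = ["PipelineConfig", "PipelineError", "run", "evaluate_against_truth",
           "STAGES", "run_stage", "load_config"]

log = logging.getLogger("firehist")

STAGES = ("simulate", "composite", "basemap", "breaks", "detect",
          "history", "stats")

_REQUIRES = {
    "simulate": (),
    "composite": ("bands",),
    "basemap": ("bands", "truth"),
    "breaks": ("ndvi", "forest_mask"),
    "detect": ("ndvi", "dnbr", "forest_mask", "breaks"),
    "history": ("events", "forest_mask"),
    "stats": ("footprints", "history", "forest_mask"),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; the scene block configures the generator."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    dnbr_threshold: float = 0.2
    min_area_ha: float = 5.0
    connectivity: int = 1
    refine: bool = True

    harmonic_order: int = 2
    min_segment: float = 8
    max_breaks: int = 4
    criterion: str = "bic"
    ci_level: float = 0.95

    basemap_segments: int = 400
    basemap_label_fraction: float = 0.2
    basemap_classifier: str = "mlp"
    use_truth_basemap: bool = False

    include_unburned: bool = False
    stats_alpha: float = 0.05

    def validate(self) -> None:
        if self.dnbr_threshold < 0 or self.min_area_ha < 0:
            raise ValueError("threshold and minimum area must be non-negative")
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must be in (0, 1)")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.scene.validate()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["scene"]["fires"] = [dataclasses.asdict(f) for f in self.scene.fires]
        return json.dumps(d, indent=2, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from its JSON form."""
    d = json.loads(Path(path).read_text())
    scene_d = d.pop("scene", {})
    fires = scene_d.pop("fires", None)
    for key in ("start", "end"):
        if key in scene_d:
            scene_d[key] = tuple(scene_d[key])
    if "footprint_window" in scene_d:
        scene_d["footprint_window"] = tuple(
            tuple(x) for x in scene_d["footprint_window"])
    scene = SceneConfig(**scene_d)
    if fires is not None:
        scene.fires = tuple(FireSpec(**f) for f in fires)
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    return PipelineConfig(scene=scene, **d)


# ---------------------------------------------------------------------------
# stage implementations (operate on a context dict, write products)
# ---------------------------------------------------------------------------

def _stage_simulate(ctx, cfg: PipelineConfig, out: Path | None):
    landscape = generate_landscape(cfg.scene)
    bands, truth = simulate_archive(cfg.scene, landscape)
    footprints = simulate_footprints(cfg.scene, truth)
    ctx.update(bands=bands, truth=truth, footprints=footprints)
    if out:
        write_archive(bands, out / "archive")
        truth.write(out / "truth")
        footprints.to_csv(out / "footprints.csv", index=False)
    return {"n_months": cfg.scene.n_months,
            "grid": [cfg.scene.rows, cfg.scene.cols],
            "truth_fires": len(truth.fires),
            "footprints": len(footprints)}


def _stage_composite(ctx, cfg: PipelineConfig, out: Path | None):
    bands = ctx["bands"]
    red, nir, swir2 = bands["red"], bands["nir"], bands["swir2"]
    T = red.shape[0]
    ndvi_vals = np.empty(red.values.shape, dtype=np.float32)
    nbr_vals = np.empty_like(ndvi_vals)
    for t in range(T):
        nd = compute_index(red.grid(t), nir.grid(t), which="NDVI")
        nb = compute_index(red.grid(t), nir.grid(t), swir2.grid(t), which="NBR")
        ndvi_vals[t] = nd.filled(np.nan)
        nbr_vals[t] = nb.filled(np.nan)
    ndvi = RasterStack(ndvi_vals, ~np.isfinite(ndvi_vals), red.months,
                       red.epoch, "NDVI", red.georef)
    nbr = RasterStack(nbr_vals, ~np.isfinite(nbr_vals), red.months,
                      red.epoch, "NBR", red.georef)
    dnb = dnbr_stack(nbr)
    ctx.update(ndvi=ndvi, nbr=nbr, dnbr=dnb)
    if out:
        (out / "indices").mkdir(exist_ok=True)
        ndvi.write(out / "indices" / "ndvi.tif")
        nbr.write(out / "indices" / "nbr.tif")
        dnb.write(out / "indices" / "dnbr.tif")
    return {"months": int(T)}


def _stage_basemap(ctx, cfg: PipelineConfig, out: Path | None):
    truth: SceneTruth = ctx["truth"]
    if cfg.use_truth_basemap:
        mask = truth.land_cover == 1
    else:
        mask = forest_base_map(
            ctx["bands"], truth.land_cover,
            n_segments=cfg.basemap_segments,
            label_fraction=cfg.basemap_label_fraction,
            classifier=cfg.basemap_classifier, seed=cfg.seed)
    ctx["forest_mask"] = mask
    if out:
        RasterGrid(mask.astype(float), band="forest",
                   georef=truth.georef).write(out / "basemap.tif")
    return {"forest_pixels": int(mask.sum()),
            "forest_area_ha": float(mask.sum() * truth.georef.pixel_area_ha)}


def _stage_breaks(ctx, cfg: PipelineConfig, out: Path | None):
    breaks = detect_breaks_grid(
        ctx["ndvi"], ctx["forest_mask"], harmonic_order=cfg.harmonic_order,
        min_segment=cfg.min_segment, max_breaks=cfg.max_breaks,
        criterion=cfg.criterion, level=cfg.ci_level)
    ctx["breaks"] = breaks
    if out:
        rows = []
        for (r, c), brks in sorted(breaks.items()):
            for b in brks:
                rows.append({"row": r, "col": c, "month_index": b.month,
                             "magnitude": b.magnitude, "ci_lo": b.ci[0],
                             "ci_hi": b.ci[1], "obs_index": b.obs_index,
                             "rss": b.rss, "n_segments": b.n_segments})
        pd.DataFrame(rows, columns=["row", "col", "month_index", "magnitude",
                                    "ci_lo", "ci_hi", "obs_index", "rss",
                                    "n_segments"]).to_csv(
            out / "breaks.csv", index=False)
    n_breaks = sum(len(v) for v in breaks.values())
    return {"pixels_with_breaks": len(breaks), "n_breaks": n_breaks}


def _stage_detect(ctx, cfg: PipelineConfig, out: Path | None):
    events, candidates = detect_fires(
        ctx["ndvi"], ctx["dnbr"], ctx["forest_mask"],
        threshold=cfg.dnbr_threshold, min_area_ha=cfg.min_area_ha,
        connectivity=cfg.connectivity, refine=cfg.refine,
        breaks_by_pixel=ctx["breaks"], seed=cfg.seed)
    ctx.update(events=events, candidates=candidates)
    if out:
        epoch = ctx["ndvi"].epoch
        events_to_geojson(events, epoch, out / "events.geojson")
        events_to_csv(events, epoch, out / "events.csv")
        if events:
            import tifffile
            masks = np.stack([e.pixel_mask for e in events]).astype(np.uint8)
            tifffile.imwrite(out / "event_masks.tif", masks, description=json.dumps(
                {"months": [e.month for e in events],
                 "epoch": list(epoch)}))
    return {"n_candidates": len(candidates), "n_events": len(events),
            "event_area_ha": [round(e.area_ha, 2) for e in events]}


def _stage_history(ctx, cfg: PipelineConfig, out: Path | None):
    mask = ctx["forest_mask"]
    pa = ctx["truth"].georef.pixel_area_ha if "truth" in ctx else \
        cfg.scene.pixel_area_ha
    hist = accumulate_history(ctx["events"], mask, pixel_area_ha=pa)
    summaries = summarize(hist, ctx["events"])
    ref = int(ctx["ndvi"].months[-1]) if "ndvi" in ctx else \
        int(max((e.month for e in ctx["events"]), default=0))
    tsf = time_since_fire(hist, ref)
    ctx.update(history=hist, summaries=summaries, months_since=tsf)
    if out:
        geo = ctx["truth"].georef if "truth" in ctx else None
        if geo is not None:
            RasterGrid(hist.burn_counts.astype(float), band="burn_count",
                       georef=geo).write(out / "burn_counts.tif")
            RasterGrid(tsf.astype(float), band="months_since",
                       georef=geo).write(out / "months_since.tif")
            RasterGrid(hist.max_severity, band="max_dnbr",
                       georef=geo).write(out / "max_dnbr.tif")
        (out / "summaries").mkdir(exist_ok=True)
        for name, df in summaries.items():
            df.to_csv(out / "summaries" / f"{name}.csv", index=False)
    burned = hist.burn_counts[mask]
    return {"burned_pixels": int((burned > 0).sum()),
            "max_burn_count": int(burned.max()) if burned.size else 0}


def _stage_stats(ctx, cfg: PipelineConfig, out: Path | None):
    truth = ctx.get("truth")
    table = filter_and_attach(
        ctx["footprints"], ctx["history"], ctx["forest_mask"],
        zone_map=truth.zones if truth is not None else None,
        zone_names=truth.zone_names if truth is not None else None)
    results = {"kruskal_wallis": {}, "dunn": {}, "models": {}}
    groups_by = table.groupby("n_fires")
    labels = sorted(table["n_fires"].unique())
    models = {}
    for resp in ("pai", "cc", "ch"):
        gs = [groups_by.get_group(k)[resp].to_numpy() for k in labels]
        if len(gs) >= 2:
            h, p = kruskal_wallis(gs)
            results["kruskal_wallis"][resp] = {"H": h, "p": p}
            results["dunn"][resp] = dunn_posthoc(gs, labels=labels).to_dict("records")
        try:
            m = fit_structure_model(table, resp,
                                    include_unburned=cfg.include_unburned)
            models[resp] = m
            results["models"][resp] = {
                "coefficients": m.coefficients,
                "variance_components": m.variance_components,
                "residual_variance": m.residual_variance,
                "n_obs": m.n_obs, "converged": m.converged,
                "singular": m.singular,
            }
        except ValueError as exc:
            results["models"][resp] = {"error": str(exc)}
    try:
        recovery = recovery_assessment(table, alpha=cfg.stats_alpha,
                                       include_unburned=cfg.include_unburned)
    except ValueError as exc:  # e.g. no burned footprints to model
        recovery = pd.DataFrame()
        results["recovery_error"] = str(exc)
    ctx.update(analysis_table=table, stats_results=results, models=models,
               recovery=recovery)
    if out:
        (out / "stats").mkdir(exist_ok=True)
        table.to_csv(out / "stats" / "analysis_table.csv", index=False)
        (out / "stats" / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True))
        recovery.to_csv(out / "stats" / "recovery.csv", index=False)
    return {"analysis_rows": len(table),
            "responses": list(results["models"].keys())}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "composite": _stage_composite,
    "basemap": _stage_basemap,
    "breaks": _stage_breaks,
    "detect": _stage_detect,
    "history": _stage_history,
    "stats": _stage_stats,
}


def run_stage(name: str, ctx: dict, cfg: PipelineConfig,
              out: Path | None = None) -> dict:
    """Run one stage against a context, checking its inputs first."""
    for req in _REQUIRES[name]:
        if req not in ctx:
            raise PipelineError(
                f"stage {name!r} requires missing product {req!r}; "
                f"run the stage that produces it first")
    t0 = time.perf_counter()
    counts = _STAGE_FN[name](ctx, cfg, out)
    log.info("stage %s done in %.2fs: %s", name, time.perf_counter() - t0, counts)
    return counts


def run(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order; return the run context.

    The context maps product names to in-memory objects and carries the
    manifest under ``"manifest"``.  When ``outdir`` is given every product
    and the manifest are written there; an existing manifest in the
    directory is refused (one run directory per invocation).
    """
    config.validate()
    out = None
    if outdir is not None:
        out = Path(outdir)
        if (out / "manifest.json").exists():
            raise PipelineError(f"run directory {out} already holds a run")
        out.mkdir(parents=True, exist_ok=True)

    ctx: dict = {}
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "version": __version__, "stages": {}}
    ordered = [s for s in STAGES if s in config.stages]
    for name in ordered:
        manifest["stages"][name] = run_stage(name, ctx, config, out)
    ctx["manifest"] = manifest
    if out:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        (out / "config.json").write_text(config.to_json())
    return ctx


# ---------------------------------------------------------------------------
# evaluation against synthetic truth
# ---------------------------------------------------------------------------

def evaluate_against_truth(ctx: dict, truth: SceneTruth | None = None,
                           month_tolerance: int = 1,
                           iou_threshold: float = 0.5) -> dict:
    """Score a run of a synthetic scene against its ground truth.

    Event-level precision/recall (an event matches a truth fire when its
    month is within ``month_tolerance`` and pixel IoU >= threshold),
    per-match month errors, the burn-count confusion matrix over the
    forest mask, and mixed-model coefficient recovery when the stats stage
    ran.  With zero truth fires and zero detections both precision and
    recall are reported as 1.0 by convention (noted in the output).
    """
    truth = truth if truth is not None else ctx["truth"]
    events: list[FireEvent] = ctx.get("events", [])
    notes = []

    matches = []
    used = set()
    for tf in truth.fires:
        best = (None, 0.0)
        for ev in events:
            if ev.event_id in used or abs(ev.month - tf.month_index) > month_tolerance:
                continue
            inter = np.logical_and(ev.pixel_mask, tf.mask).sum()
            union = np.logical_or(ev.pixel_mask, tf.mask).sum()
            iou = inter / union if union else 0.0
            if iou > best[1]:
                best = (ev, iou)
        if best[0] is not None and best[1] >= iou_threshold:
            matches.append((tf, best[0], best[1]))
            used.add(best[0].event_id)

    n_truth, n_det = len(truth.fires), len(events)
    if n_truth == 0 and n_det == 0:
        precision = recall = 1.0
        notes.append("no truth fires and no detections: vacuous 1.0 by convention")
    else:
        precision = len(matches) / n_det if n_det else 0.0
        recall = len(matches) / n_truth if n_truth else 0.0
    month_errors = [ev.month - tf.month_index for tf, ev, _ in matches]

    out = {
        "n_truth_fires": n_truth,
        "n_detected_events": n_det,
        "n_matched": len(matches),
        "precision": precision,
        "recall": recall,
        "month_errors": month_errors,
        "mean_abs_month_error": float(np.mean(np.abs(month_errors)))
        if month_errors else 0.0,
        "mean_iou": float(np.mean([i for *_, i in matches])) if matches else None,
        "notes": notes,
    }

    if "history" in ctx:
        hist = ctx["history"]
        mask = ctx.get("forest_mask", np.ones_like(truth.land_cover, dtype=bool))
        t_counts = truth.burn_counts[mask]
        d_counts = hist.burn_counts[mask]
        kmax = int(max(t_counts.max(initial=0), d_counts.max(initial=0)))
        conf = np.zeros((kmax + 1, kmax + 1), dtype=int)
        for tt, dd in zip(t_counts.ravel(), d_counts.ravel()):
            conf[tt, dd] += 1
        out["burn_count_confusion"] = conf.tolist()
        out["burn_count_accuracy"] = float(np.trace(conf) / conf.sum())

    if "models" in ctx and truth.coefficients:
        rec = []
        for resp, model in ctx["models"].items():
            true_c = truth.coefficients.get("coef_nfires", {}).get(resp)
            true_m = truth.coefficients.get("coef_months", {}).get(resp)
            row = {"response": resp}
            if true_c is not None and "n_fires" in model.coefficients:
                c = model.coefficients["n_fires"]
                row.update(nfires_true=true_c, nfires_est=c["estimate"],
                           nfires_se=c["se"],
                           nfires_within_2se=abs(c["estimate"] - true_c) <= 2 * c["se"])
            if true_m is not None and "n_months" in model.coefficients:
                c = model.coefficients["n_months"]
                row.update(nmonths_true=true_m, nmonths_est=c["estimate"],
                           nmonths_se=c["se"],
                           nmonths_within_2se=abs(c["estimate"] - true_m) <= 2 * c["se"])
            rec.append(row)
        out["coefficient_recovery"] = rec
    return out
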
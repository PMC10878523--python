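"""Fire detection: the break x dNBR rule, grouping, filtering, refinement.

A pixel is a fire candidate when its NDVI trend shows a *negative* break
and the monthly dNBR series reaches at least the burn threshold (default
0.2) within the 95% confidence interval of that break; the fire month is
the month of maximum dNBR inside the CI (earliest on ties).  Candidates
are binned by fire month, grouped into connected components (rook
connectivity by default), filtered by a 5-ha minimum mapping unit, and
optionally refined by object-based classification of the differenced NDVI
image bracketing the fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import mapping

from .breaks import (PixelSeries, TrendBreak, detect_breaks, fit_season_trend)
from .classify import slic_segment, train_and_classify
from .raster import GeoRef, RasterGrid, RasterStack
from .synthetic import _mask_to_polygon

__all__ = [
    "FireCandidate",
    "FireEvent",
    "match_break_with_dnbr",
    "group_to_polygons",
    "filter_min_area",
    "refine_perimeter",
    "detect_breaks_grid",
    "detect_fires",
    "events_to_geojson",
    "events_to_csv",
]

DNBR_THRESHOLD = 0.2
MIN_AREA_HA = 5.0

PROV_RULE = 1       # pixel passed the break x dNBR rule
PROV_REFINED = 2    # pixel added by supervised perimeter refinement


@dataclass
class FireCandidate:
    """One pixel that satisfied the fire rule."""

    pixel: tuple[int, int]
    brk: TrendBreak
    fire_month: int
    max_dnbr: float

    def __post_init__(self) -> None:
        if self.brk.sign >= 0:
            raise ValueError("fire candidates require a negative break")
        if not self.brk.ci[0] <= self.fire_month <= self.brk.ci[1]:
            raise ValueError("fire month must lie within the break CI")


@dataclass
class FireEvent:
    """A dated burn: one connected pixel set with severity."""

    event_id: int
    month: int                       # month index
    pixel_mask: np.ndarray           # (H, W) bool
    georef: GeoRef
    max_dnbr: np.ndarray | None = None   # per-pixel max dNBR (NaN outside)
    provenance: np.ndarray | None = None  # uint8 per pixel (0 outside)
    date: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = np.where(self.pixel_mask, PROV_RULE, 0).astype(np.uint8)

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_mask.sum())

    @property
    def area_ha(self) -> float:
        return self.n_pixels * self.georef.pixel_area_ha

    @property
    def polygon(self):
        return _mask_to_polygon(self.pixel_mask, self.georef)

    def mean_max_dnbr(self) -> float:
        if self.max_dnbr is None:
            return float("nan")
        vals = self.max_dnbr[self.pixel_mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else float("nan")


# ---------------------------------------------------------------------------
# the fire rule
# ---------------------------------------------------------------------------

def match_break_with_dnbr(brk: TrendBreak, dnbr_series: PixelSeries,
                          threshold: float = DNBR_THRESHOLD,
                          bridge_months: np.ndarray | None = None) -> FireCandidate | None:
    """Apply the fire rule to one break of one pixel.

    Candidate iff the break is negative and max dNBR within the break's CI
    reaches ``threshold``; the fire month is the argmax month (earliest on
    ties).  When ``bridge_months`` gives the pre-fire observation month each
    difference was taken against (gap bridging), a spike observed after a
    cloud gap is dated to the earliest gap month consistent with the CI.
    Raises when the CI lies entirely outside the dNBR series span.
    """
    lo, hi = brk.ci
    months = dnbr_series.months
    if len(months) == 0 or hi < months[0] or lo > months[-1]:
        raise ValueError("break CI entirely outside the dNBR series span")
    if brk.sign >= 0:
        return None
    sel = (months >= lo) & (months <= hi)
    if not np.any(sel):
        return None
    vals = dnbr_series.values[sel]
    mths = months[sel]
    best = int(np.argmax(vals))  # argmax returns the first (earliest) maximum
    if vals[best] < threshold:
        return None
    fire_month = int(mths[best])
    if bridge_months is not None:
        gap_start = int(np.asarray(bridge_months)[sel][best]) + 1
        fire_month = min(fire_month, max(gap_start, lo))
    return FireCandidate(pixel=dnbr_series.location or (0, 0), brk=brk,
                         fire_month=fire_month, max_dnbr=float(vals[best]))


# ---------------------------------------------------------------------------
# grouping and filtering
# ---------------------------------------------------------------------------

def group_to_polygons(candidates: list[FireCandidate], grid_shape: tuple[int, int],
                      georef: GeoRef, connectivity: int = 1,
                      dnbr_stack: RasterStack | None = None,
                      start_id: int = 0, bridge_px: int = 0) -> list[FireEvent]:
    """Group candidates into per-month connected components.

    Candidates are binned by fire month; within each month bin, connected
    components under the declared connectivity (1 = rook/4-neighbour,
    2 = queen/8-neighbour) become separate events.  ``bridge_px`` > 0
    additionally joins components separated by at most that many missing
    pixels (cloud dropouts punch one-pixel holes in real scars); the
    events' pixel sets themselves are never grown.
    """
    by_month: dict[int, list[FireCandidate]] = {}
    for c in candidates:
        by_month.setdefault(c.fire_month, []).append(c)
    events: list[FireEvent] = []
    next_id = start_id
    structure = ndimage.generate_binary_structure(2, connectivity)
    for month in sorted(by_month):
        mask = np.zeros(grid_shape, dtype=bool)
        dnbr_vals = np.full(grid_shape, np.nan)
        for c in by_month[month]:
            mask[c.pixel] = True
            dnbr_vals[c.pixel] = c.max_dnbr
        if bridge_px > 0:
            closed = ndimage.binary_dilation(mask, structure=structure,
                                             iterations=bridge_px)
            labeled, n = ndimage.label(closed, structure=structure)
            labeled[~mask] = 0
        else:
            labeled, n = ndimage.label(mask, structure=structure)
        for comp in range(1, n + 1):
            comp_mask = labeled == comp
            sev = np.where(comp_mask, dnbr_vals, np.nan)
            events.append(FireEvent(
                event_id=next_id, month=month, pixel_mask=comp_mask,
                georef=georef, max_dnbr=sev))
            next_id += 1
    return events


def filter_min_area(events: list[FireEvent],
                    min_area_ha: float = MIN_AREA_HA) -> list[FireEvent]:
    """Drop events below the minimum mapping unit (5 ha by default)."""
    return [e for e in events if e.area_ha >= min_area_ha]


# ---------------------------------------------------------------------------
# supervised perimeter refinement
# ---------------------------------------------------------------------------

def refine_perimeter(event: FireEvent, ndvi_pre: RasterGrid, ndvi_post: RasterGrid,
                     margin: int = 10, px_per_segment: int = 16,
                     min_contrast: float = 0.1, classifier: str = "logistic",
                     seed: int = 0) -> FireEvent | None:
    """Refine an event's perimeter on the bracketing differenced-NDVI image.

    The pre-minus-post NDVI difference around the event is segmented
    (SLIC); segments dominated by the candidate set and segments fully
    outside its dilation provide burn / non-burn training labels; all
    segments are then classified and painted back.  Pixels in segments
    straddling the boundary are resolved individually to the nearer class
    mean.  When the burn/surround contrast in differenced NDVI is below
    ``min_contrast`` the candidate is judged a non-fire artefact and the
    event is dropped (returns None) -- the automated stand-in for manual
    image confirmation.
    """
    if not ndvi_pre.congruent(ndvi_post):
        raise ValueError("pre/post NDVI grids are not congruent")
    H, W = event.pixel_mask.shape
    rows, cols = np.nonzero(event.pixel_mask)
    r0, r1 = max(0, rows.min() - margin), min(H, rows.max() + margin + 1)
    c0, c1 = max(0, cols.min() - margin), min(W, cols.max() + margin + 1)
    win = (slice(r0, r1), slice(c0, c1))

    d = ndvi_pre.filled(np.nan)[win] - ndvi_post.filled(np.nan)[win]
    cand = event.pixel_mask[win]
    dgrid = RasterGrid(d, band="dNDVI", georef=event.georef)

    # burn/surround contrast gate on the pixels themselves; the background
    # level is the upper quartile of the surround so that a cover class far
    # below the burn signal (e.g. strongly seasonal savanna) cannot drag
    # the burn threshold beneath unburned forest
    dil = ndimage.binary_dilation(cand, iterations=2)
    with np.errstate(all="ignore"):
        mu_burn = float(np.nanmean(d[cand]))
        mu_non = float(np.nanpercentile(d[~dil], 75)) if np.any(~dil) \
            else float(np.nanmean(d))
    if not np.isfinite(mu_burn) or not np.isfinite(mu_non) \
            or abs(mu_burn - mu_non) < min_contrast:
        return None  # uniform dNDVI: no burn signal, drop the event

    n_seg = max(4, d.size // px_per_segment)
    segments = slic_segment(dgrid, n_segments=n_seg)
    labels = segments.labels
    ids = segments.features.index.to_numpy()
    inside_frac = ndimage.mean(cand.astype(float), labels=labels, index=ids)
    outside_frac = ndimage.mean((~dil).astype(float), labels=labels, index=ids)
    dmean = segments.features["mean_dNDVI"].to_numpy()

    # asymmetric burn threshold: within one scar the dNDVI step shrinks on
    # re-burned ground, so the cut sits much nearer the unburned level than
    # the midpoint between class means
    thr = mu_non + max(0.5 * min_contrast, 0.25 * (mu_burn - mu_non))
    closer_burn_seg = dmean >= thr
    burn_train = ids[(inside_frac >= 0.5) & closer_burn_seg]
    nonburn_train = ids[(outside_frac >= 0.9) & ~closer_burn_seg]
    if len(burn_train) and len(nonburn_train):
        training = pd.DataFrame({
            "segment_id": np.concatenate([burn_train, nonburn_train]),
            "class": ["burn"] * len(burn_train) + ["nonburn"] * len(nonburn_train),
        })
        _, seg_classes = train_and_classify(
            segments, training, classifier=classifier, seed=seed,
            feature_columns=["mean_dNDVI"])
        clf_burn = (seg_classes == "burn").to_numpy()
    else:
        clf_burn = closer_burn_seg
    # the dNDVI threshold is authoritative: the classifier cannot claim a
    # segment below it, and a segment far above it is burn regardless
    seg_burn = (clf_burn & closer_burn_seg) | (dmean >= thr + 0.5 * (mu_burn - thr))
    lut = dict(zip(ids, seg_burn))
    refined_win = np.vectorize(lut.get)(labels).astype(bool)

    # per-pixel cleanup: pixels in boundary-straddling (high-sd) segments
    # are re-decided individually, and a pixel observed below the burn
    # threshold is never kept regardless of its segment's label (pixels
    # with no observation keep the segment's call)
    finite = np.isfinite(d)
    sd = segments.features["sd_dNDVI"]
    mixed_ids = sd.index[sd > 0.15 * abs(mu_burn - mu_non)].to_numpy()
    if len(mixed_ids):
        mixed_px = np.isin(labels, mixed_ids)
        refined_win[mixed_px & finite] = d[mixed_px & finite] >= thr
    refined_win &= ~finite | (d >= thr)

    # keep components substantially supported by the original candidates;
    # a one-pixel bridge closes small gaps left by cloud dropouts
    closed = ndimage.binary_dilation(refined_win)
    labeled, n = ndimage.label(closed)
    labeled[~refined_win] = 0
    keep = np.zeros_like(refined_win)
    min_support = max(5, min(25, int(0.1 * cand.sum())))
    for comp in range(1, n + 1):
        comp_mask = labeled == comp
        if int((comp_mask & cand).sum()) >= min_support:
            keep |= comp_mask
    if not keep.any():
        return None

    refined = np.zeros((H, W), dtype=bool)
    refined[win] = keep
    provenance = np.zeros((H, W), dtype=np.uint8)
    provenance[refined & event.pixel_mask] = PROV_RULE
    provenance[refined & ~event.pixel_mask] = PROV_REFINED
    sev = event.max_dnbr
    if sev is not None:
        sev = np.where(refined, np.where(np.isfinite(sev), sev, np.nan), np.nan)
    return FireEvent(event_id=event.event_id, month=event.month,
                     pixel_mask=refined, georef=event.georef,
                     max_dnbr=sev, provenance=provenance)


# ---------------------------------------------------------------------------
# grid-level orchestration
# ---------------------------------------------------------------------------

def detect_breaks_grid(ndvi: RasterStack, forest_mask: np.ndarray,
                       harmonic_order: int = 2, min_segment: float = 8,
                       max_breaks: int = 4, criterion: str = "bic",
                       level: float = 0.95,
                       min_observations: int | None = None) -> dict:
    """Negative-break detection for every forest pixel of an NDVI stack.

    Returns ``{(row, col): [TrendBreak, ...]}`` for pixels with at least
    one break; pixels with too few observations are skipped.
    """
    from .breaks import MIN_OBSERVATIONS
    min_obs = min_observations or MIN_OBSERVATIONS
    out: dict[tuple[int, int], list[TrendBreak]] = {}
    months = ndvi.months
    vals = ndvi.values
    mask = ndvi.mask
    for r, c in zip(*np.nonzero(forest_mask)):
        ok = ~mask[:, r, c]
        if ok.sum() < min_obs:
            continue
        series = PixelSeries(months[ok], vals[ok, r, c].astype(float),
                             index_name="NDVI", location=(int(r), int(c)))
        fit = fit_season_trend(series, harmonic_order=harmonic_order,
                               min_segment_fraction=min_segment,
                               max_breaks=max_breaks, criterion=criterion)
        brks = detect_breaks(fit, level=level)
        if brks:
            out[(int(r), int(c))] = brks
    return out


def detect_fires(ndvi: RasterStack, dnbr: RasterStack, forest_mask: np.ndarray,
                 threshold: float = DNBR_THRESHOLD, min_area_ha: float = MIN_AREA_HA,
                 connectivity: int = 1, refine: bool = True,
                 breaks_by_pixel: dict | None = None, bridge_px: int = 1,
                 seed: int = 0, **break_kwargs) -> tuple[list[FireEvent], list[FireCandidate]]:
    """Full unsupervised + refined fire detection on index stacks.

    Runs break detection (unless ``breaks_by_pixel`` is supplied), applies
    the fire rule per pixel, groups candidates by month into events,
    enforces the minimum mapping unit, and optionally refines each
    surviving event's perimeter on the bracketing NDVI composites.
    """
    if breaks_by_pixel is None:
        breaks_by_pixel = detect_breaks_grid(ndvi, forest_mask, **break_kwargs)
    candidates: list[FireCandidate] = []
    months = dnbr.months
    bridge_all = getattr(dnbr, "bridge_months", None)
    for (r, c), brks in breaks_by_pixel.items():
        ok = ~dnbr.mask[:, r, c]
        if not ok.any():
            continue
        series = PixelSeries(months[ok], dnbr.values[ok, r, c].astype(float),
                             index_name="dNBR", location=(r, c))
        bridge = bridge_all[ok, r, c] if bridge_all is not None else None
        for brk in brks:
            if brk.sign >= 0:
                continue
            lo, hi = brk.ci
            if hi < series.months[0] or lo > series.months[-1]:
                continue
            cand = match_break_with_dnbr(brk, series, threshold=threshold,
                                         bridge_months=bridge)
            if cand is not None:
                candidates.append(cand)

    events = group_to_polygons(candidates, forest_mask.shape, ndvi.georef,
                               connectivity=connectivity, dnbr_stack=dnbr,
                               bridge_px=bridge_px)
    events = filter_min_area(events, min_area_ha)

    if refine:
        refined_events = []
        for ev in events:
            pre, post = _bracketing_composites(ndvi, ev.month)
            if pre is None or post is None:
                refined_events.append(ev)
                continue
            out = refine_perimeter(ev, pre, post, seed=seed)
            if out is not None:
                refined_events.append(out)
        # refinement can regrow fragments of one scar into overlapping
        # perimeters: merge same-month events that touch
        events = _merge_same_month(refined_events, connectivity)

    for i, ev in enumerate(events):
        ev.event_id = i
        ev.date = None
    return events, candidates


def _merge_same_month(events: list[FireEvent], connectivity: int = 1) -> list[FireEvent]:
    by_month: dict[int, list[FireEvent]] = {}
    for ev in events:
        by_month.setdefault(ev.month, []).append(ev)
    merged: list[FireEvent] = []
    structure = ndimage.generate_binary_structure(2, connectivity)
    for month in sorted(by_month):
        evs = by_month[month]
        if len(evs) == 1:
            merged.append(evs[0])
            continue
        union = np.zeros_like(evs[0].pixel_mask)
        for ev in evs:
            union |= ev.pixel_mask
        closed = ndimage.binary_dilation(union, structure=structure)
        labeled, n = ndimage.label(closed, structure=structure)
        labeled[~union] = 0
        for comp in range(1, n + 1):
            comp_mask = labeled == comp
            sev = np.full(comp_mask.shape, np.nan)
            prov = np.zeros(comp_mask.shape, dtype=np.uint8)
            for ev in evs:
                if not np.any(ev.pixel_mask & comp_mask):
                    continue
                if ev.max_dnbr is not None:
                    take = comp_mask & np.isfinite(ev.max_dnbr)
                    sev[take] = np.fmax(np.where(np.isfinite(sev[take]),
                                                 sev[take], -np.inf),
                                        ev.max_dnbr[take])
                prov[comp_mask] = np.maximum(prov[comp_mask],
                                             ev.provenance[comp_mask])
            sev[~np.isfinite(sev)] = np.nan
            merged.append(FireEvent(event_id=len(merged), month=month,
                                    pixel_mask=comp_mask, georef=evs[0].georef,
                                    max_dnbr=sev, provenance=prov))
    return merged


def _bracketing_composites(ndvi: RasterStack, month: int,
                           max_lag: int = 3) -> tuple[RasterGrid | None, RasterGrid | None]:
    """Mean NDVI over the months just before / from the fire month.

    Averaging the short bracketing windows (fire signals persist; the
    pre-fire surface is stable) suppresses single-composite noise before
    the perimeter is refined on the difference image.
    """
    months = ndvi.months

    def _mean_grid(pos):
        import warnings as _w
        data = np.stack([ndvi.grid(int(t)).filled(np.nan) for t in pos])
        with np.errstate(all="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(data, axis=0)
        g = ndvi.grid(int(pos[-1]))
        return RasterGrid(vals, band=g.band, date=g.date, georef=g.georef)

    pre_pos = np.flatnonzero((months < month) & (months >= month - max_lag))
    post_pos = np.flatnonzero((months >= month) & (months <= month + max_lag))
    pre = _mean_grid(pre_pos) if len(pre_pos) else None
    post = _mean_grid(post_pos) if len(post_pos) else None
    return pre, post


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def events_to_geojson(events: list[FireEvent], epoch: tuple[int, int],
                      path: str | Path) -> None:
    from .raster import index_to_ym
    features = []
    for ev in events:
        y, m = index_to_ym(ev.month, epoch)
        features.append({
            "type": "Feature",
            "geometry": mapping(ev.polygon),
            "properties": {
                "event_id": ev.event_id, "year": y, "month": m,
                "area_ha": round(ev.area_ha, 4),
                "mean_max_dnbr": round(ev.mean_max_dnbr(), 4),
            },
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def events_to_csv(events: list[FireEvent], epoch: tuple[int, int],
                  path: str | Path) -> pd.DataFrame:
    from .raster import index_to_ym
    rows = []
    for ev in events:
        y, m = index_to_ym(ev.month, epoch)
        rows.append({"event_id": ev.event_id, "year": y, "month": m,
                     "month_index": ev.month, "n_pixels": ev.n_pixels,
                     "area_ha": ev.area_ha, "mean_max_dnbr": ev.mean_max_dnbr()})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
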
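"""Spectral indices, monthly median composites, and burn-ratio severity.

NDVI = (NIR - Red) / (NIR + Red); NBR = (NIR - SWIR2) / (NIR + SWIR2).
dNBR follows the pre-minus-post convention, so vegetation loss from fire is
a *positive* dNBR.  Pixels where any input is missing, or where a ratio
denominator is zero, are masked rather than clamped.
"""

from __future__ import annotations

import numpy as np

from .raster import RasterGrid, RasterStack

__all__ = [
    "compute_index",
    "monthly_median_composite",
    "dnbr",
    "dnbr_stack",
    "max_severity",
]


def _ratio(num_a: RasterGrid, num_b: RasterGrid, band: str) -> RasterGrid:
    if not num_a.congruent(num_b):
        raise ValueError("input grids are not congruent")
    if num_a.date != num_b.date:
        raise ValueError("input grids must share an acquisition date")
    a, b = num_a.values, num_b.values
    denom = a + b
    bad = num_a.mask | num_b.mask | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out[bad] = np.nan
    return RasterGrid(out, band=band, date=num_a.date, georef=num_a.georef, mask=bad)


def compute_index(
    red: RasterGrid, nir: RasterGrid, swir2: RasterGrid | None = None, which: str = "NDVI"
) -> RasterGrid:
    """Compute NDVI or NBR from congruent same-date reflectance grids.

    Outputs lie in [-1, 1] wherever defined; masked where any input is
    masked or the denominator vanishes.
    """
    which = which.upper()
    if which == "NDVI":
        return _ratio(nir, red, "NDVI")
    if which == "NBR":
        if swir2 is None:
            raise ValueError("NBR requires the SWIR2 band")
        return _ratio(nir, swir2, "NBR")
    raise ValueError(f"unknown index {which!r}")


def monthly_median_composite(stack: list[RasterGrid], month: tuple[int, int] | None = None) -> RasterGrid:
    """Per-pixel median over the unmasked observations of one month.

    ``stack`` holds the grids acquired within the month (optionally checked
    against ``month``); a pixel with no unmasked observation stays masked.
    """
    if not stack:
        raise ValueError("empty stack")
    first = stack[0]
    for g in stack[1:]:
        if not g.congruent(first):
            raise ValueError("grids in stack are not congruent")
    if month is not None:
        for g in stack:
            if g.date != tuple(month):
                raise ValueError(f"grid dated {g.date} not in month {tuple(month)}")
    data = np.stack([g.filled(np.nan) for g in stack])
    with np.errstate(all="ignore"):
        med = np.nanmedian(data, axis=0)
    mask = np.all(np.stack([g.mask for g in stack]), axis=0)
    med[mask] = np.nan
    return RasterGrid(med, band=first.band, date=month or first.date,
                      georef=first.georef, mask=mask)


def dnbr(nbr_pre: RasterGrid, nbr_post: RasterGrid) -> RasterGrid:
    """Differenced NBR, pre minus post; positive where vegetation was lost."""
    if not nbr_pre.congruent(nbr_post):
        raise ValueError("input grids are not congruent")
    if nbr_pre.date is not None and nbr_post.date is not None and not nbr_pre.date < nbr_post.date:
        raise ValueError("pre-fire grid must predate post-fire grid")
    mask = nbr_pre.mask | nbr_post.mask
    out = nbr_pre.values - nbr_post.values
    out[mask] = np.nan
    return RasterGrid(out, band="dNBR", date=nbr_post.date,
                      georef=nbr_post.georef, mask=mask)


def dnbr_stack(nbr: RasterStack, max_gap: int = 3) -> RasterStack:
    """Monthly dNBR series from a monthly NBR stack.

    dNBR at month m is NBR at the most recent unmasked prior month (within
    ``max_gap`` months) minus NBR at m, per pixel; masked when month m or
    every admissible prior month is masked.  Bridging short gaps keeps a
    cloud-hidden pre-fire month from erasing the fire-month spike.
    """
    T, H, W = nbr.shape
    vals = np.full((T, H, W), np.nan, dtype=np.float32)
    bridge = np.full((T, H, W), -(10**9), dtype=np.int64)
    prev_val = np.full((H, W), np.nan, dtype=np.float32)
    prev_month = np.full((H, W), -(10**9), dtype=np.int64)
    months = nbr.months
    filled = nbr.values.copy()
    filled[nbr.mask] = np.nan
    for t in range(T):
        cur = filled[t]
        ok = ~nbr.mask[t] & (months[t] - prev_month <= max_gap)
        vals[t][ok] = prev_val[ok] - cur[ok]
        bridge[t][ok] = prev_month[ok]
        upd = ~nbr.mask[t]
        prev_val[upd] = cur[upd]
        prev_month[upd] = months[t]
    out = RasterStack(values=vals, mask=~np.isfinite(vals), months=months,
                      epoch=nbr.epoch, band="dNBR", georef=nbr.georef)
    # month of the pre-fire observation each difference was taken against;
    # lets a spike observed after a gap be dated to the earliest gap month
    out.bridge_months = bridge
    return out


def max_severity(event, dnbr_grids: list[RasterGrid] | RasterStack, epoch=None) -> np.ndarray:
    """Per-pixel maximum dNBR over the event month's observations.

    ``event`` needs ``month`` (month index) and ``pixel_mask`` attributes
    (see :class:`firehist.detect.FireEvent`).  Returns a float grid that is
    NaN outside the event and where every observation is masked.
    """
    _mi = getattr(event, "month_index", None)
    ev_month = int(_mi) if _mi is not None else int(event.month)
    if isinstance(dnbr_grids, RasterStack):
        months = dnbr_grids.months
        if ev_month < months.min() or ev_month > months.max():
            raise ValueError("event month outside stack span")
        sel = np.flatnonzero(months == ev_month)
        layers = [dnbr_grids.grid(int(t)) for t in sel]
    else:
        layers = [
            g for g in dnbr_grids
            if epoch is None or g.date is None
            or (g.date[0] - epoch[0]) * 12 + g.date[1] - epoch[1] == ev_month
        ]
    if not layers:
        raise ValueError("no dNBR observations in the event month")
    data = np.stack([g.filled(np.nan) for g in layers])
    with np.errstate(all="ignore"):
        out = np.nanmax(data, axis=0)
    out[~event.pixel_mask] = np.nan
    return out
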
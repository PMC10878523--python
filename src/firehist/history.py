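"""Per-pixel fire history layers and landscape burn summaries.

Events are accumulated chronologically into a burn-count raster, ordered
per-pixel burn dates, and a per-pixel severity raster.  Summaries follow
the descriptive statistics of a fire-regime analysis: per-event area and
previously burned fraction (with a configurable recency window), landscape
area shares by final burn count, and the severity distribution by burn
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FireHistoryMap", "accumulate_history", "time_since_fire", "summarize"]

NEVER = -1  # sentinel for pixels with no burn history


@dataclass
class FireHistoryMap:
    """Accumulated fire history on the forest grid.

    ``burn_months[k]`` is the month index of a pixel's (k+1)-th burn, or
    -1; ``severity[k]`` the max dNBR of that burn.  Pixels outside the
    forest mask carry no history.
    """

    burn_months: np.ndarray           # (max_burns, H, W) int
    severity: np.ndarray              # (max_burns, H, W) float, NaN = none
    forest_mask: np.ndarray           # (H, W) bool
    pixel_area_ha: float
    event_ids: np.ndarray = None      # (max_burns, H, W) int, -1 = none

    @property
    def burn_counts(self) -> np.ndarray:
        return (self.burn_months >= 0).sum(axis=0)

    @property
    def max_severity(self) -> np.ndarray:
        """Per-pixel maximum dNBR across all burns (NaN where unburned)."""
        with np.errstate(all="ignore"):
            return np.nanmax(np.where(self.burn_months >= 0, self.severity, np.nan),
                             axis=0)

    def validate(self) -> None:
        counts = self.burn_counts
        if np.any(counts[~self.forest_mask] > 0):
            raise AssertionError("history recorded outside the forest mask")
        act = self.burn_months >= 0
        for k in range(1, self.burn_months.shape[0]):
            both = act[k] & act[k - 1]
            if np.any(self.burn_months[k][both] <= self.burn_months[k - 1][both]):
                raise AssertionError("per-pixel burn dates not strictly increasing")
        # slots fill from the bottom: count equals number of stored dates
        if np.any(act[1:] & ~act[:-1]):
            raise AssertionError("burn-date slots must fill chronologically")

    def n_fires_at(self, row: int, col: int, month_index: int) -> int:
        bm = self.burn_months[:, row, col]
        return int(np.sum((bm >= 0) & (bm <= month_index)))

    def months_since_at(self, row: int, col: int, month_index: int) -> int:
        bm = self.burn_months[:, row, col]
        past = bm[(bm >= 0) & (bm <= month_index)]
        return int(month_index - past.max()) if len(past) else NEVER


def accumulate_history(events: list, forest_mask: np.ndarray,
                       pixel_area_ha: float = 0.09) -> FireHistoryMap:
    """Accumulate dated events chronologically into a history map.

    ``events`` need ``month``, ``pixel_mask`` and optionally ``max_dnbr``
    and ``event_id`` attributes (:class:`firehist.detect.FireEvent` or the
    generator's truth records both qualify).
    """
    def _month_of(e):
        mi = getattr(e, "month_index", None)
        return int(mi) if mi is not None else int(e.month)

    H, W = forest_mask.shape
    ordered = sorted(events, key=_month_of)
    max_burns = max(1, _max_overlap(ordered, (H, W)))
    burn_months = np.full((max_burns, H, W), NEVER, dtype=int)
    severity = np.full((max_burns, H, W), np.nan)
    event_ids = np.full((max_burns, H, W), -1, dtype=int)
    counter = np.zeros((H, W), dtype=int)
    for ev in ordered:
        m = ev.pixel_mask & forest_mask
        rows, cols = np.nonzero(m)
        slots = counter[rows, cols]
        burn_months[slots, rows, cols] = _month_of(ev)
        sev = getattr(ev, "max_dnbr", None)
        if sev is not None:
            severity[slots, rows, cols] = np.asarray(sev)[rows, cols]
        event_ids[slots, rows, cols] = getattr(ev, "event_id", -1)
        counter[rows, cols] += 1
    hist = FireHistoryMap(burn_months=burn_months, severity=severity,
                          forest_mask=forest_mask, pixel_area_ha=pixel_area_ha,
                          event_ids=event_ids)
    hist.validate()
    return hist


def _max_overlap(events: list, shape: tuple[int, int]) -> int:
    count = np.zeros(shape, dtype=int)
    for ev in events:
        count += ev.pixel_mask
    return int(count.max()) if count.size else 0


def time_since_fire(history: FireHistoryMap, reference_month: int) -> np.ndarray:
    """Months between each pixel's last burn and a reference month.

    Unburned pixels carry the sentinel -1 (``NEVER``), distinct from 0
    (burned in the reference month itself).  Raises when the reference
    predates a recorded burn.
    """
    bm = history.burn_months
    if np.any((bm >= 0) & (bm > reference_month)):
        raise ValueError("reference month predates recorded burns")
    with np.errstate(all="ignore"):
        last = np.max(np.where(bm >= 0, bm, NEVER), axis=0)
    out = np.where(last >= 0, reference_month - last, NEVER)
    return out.astype(int)


def summarize(history: FireHistoryMap, events: list,
              recent_window_months: tuple[int, int] = (1, 60)) -> dict:
    """Landscape and per-event burn summaries.

    Returns a dict of DataFrames:

    ``landscape``  area (ha) and share of the forest mask per final burn
                   count (class 0 = never burned included, so areas sum to
                   the forest area exactly);
    ``per_event``  per event: area, previously burned area and fraction,
                   the fraction previously burned within the recency
                   window (months), and a breakdown by prior burn count;
    ``severity``   per-pixel max dNBR by the burn number that produced it
                   (the k-th burn of a pixel contributes to class k).
    """
    pa = history.pixel_area_ha
    counts = history.burn_counts
    forest = history.forest_mask

    classes = np.arange(0, counts.max() + 1)
    area = np.array([(forest & (counts == k)).sum() * pa for k in classes])
    forest_area = forest.sum() * pa
    landscape = pd.DataFrame({
        "burn_count": classes,
        "area_ha": area,
        "share": area / forest_area if forest_area > 0 else np.nan,
    })

    def _month_of(e):
        mi = getattr(e, "month_index", None)
        return int(mi) if mi is not None else int(e.month)

    lo, hi = recent_window_months
    ordered = sorted(events, key=_month_of)
    rows = []
    for ev in ordered:
        ev_month = _month_of(ev)
        m = ev.pixel_mask & forest
        n_px = int(m.sum())
        bm = history.burn_months
        prior = (bm >= 0) & (bm < ev_month)
        prior_count = prior.sum(axis=0)
        with np.errstate(all="ignore"):
            last_prior = np.max(np.where(prior, bm, NEVER), axis=0)
        prev_burned = m & (prior_count > 0)
        lag = ev_month - last_prior
        recent = prev_burned & (lag >= lo) & (lag <= hi)
        breakdown = {f"prior_{k}_ha": float((m & (prior_count == k)).sum() * pa)
                     for k in range(0, int(prior_count[m].max()) + 1 if n_px else 1)}
        rows.append({
            "event_id": getattr(ev, "event_id", -1),
            "month_index": ev_month,
            "area_ha": n_px * pa,
            "prev_burned_ha": float(prev_burned.sum() * pa),
            "prev_burned_frac": float(prev_burned.sum() / n_px) if n_px else np.nan,
            "prev_burned_recent_frac": float(recent.sum() / max(prev_burned.sum(), 1))
            if prev_burned.sum() else 0.0,
            **breakdown,
        })
    per_event = pd.DataFrame(rows)

    sev_rows = []
    act = history.burn_months >= 0
    for k in range(history.burn_months.shape[0]):
        vals = history.severity[k][act[k] & np.isfinite(history.severity[k])]
        for v in vals:
            sev_rows.append({"burn_number": k + 1, "max_dnbr": float(v)})
    severity = pd.DataFrame(sev_rows, columns=["burn_number", "max_dnbr"])

    return {"landscape": landscape, "per_event": per_event, "severity": severity}
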
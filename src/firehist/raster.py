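"""Georeferenced raster containers and TIFF-backed IO.

The analysis operates on modest scene extents (thousands of hectares at
30 m), so rasters are held fully in memory as 2-D arrays with an explicit
missing-data mask.  A :class:`RasterGrid` is one band at one date; a
:class:`RasterStack` is the same band observed at a sequence of months.

Time is handled at monthly resolution throughout: a date is a
``(year, month)`` pair and a *month index* counts months from a stack's
epoch.  Files are written as (multipage) TIFF with the georeference and
acquisition dates stored as JSON in the image-description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "GeoRef",
    "RasterGrid",
    "RasterStack",
    "ym_to_index",
    "index_to_ym",
    "month_of",
    "read_grid",
    "read_stack",
]


# ---------------------------------------------------------------------------
# calendar helpers (monthly resolution)
# ---------------------------------------------------------------------------

def ym_to_index(year: int, month: int, epoch: tuple[int, int]) -> int:
    """Month index of (year, month) relative to an epoch ``(year, month)``."""
    return (year - epoch[0]) * 12 + (month - epoch[1])


def index_to_ym(idx: int, epoch: tuple[int, int]) -> tuple[int, int]:
    """Inverse of :func:`ym_to_index`."""
    total = epoch[0] * 12 + (epoch[1] - 1) + idx
    return total // 12, total % 12 + 1


def month_of(idx: int, epoch: tuple[int, int]) -> int:
    """Calendar month (1..12) of a month index."""
    return index_to_ym(idx, epoch)[1]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoRef:
    """North-up affine georeference: upper-left origin and square pixels.

    ``pixel_size`` is in metres; pixel (row, col) covers the square with
    upper-left corner ``(x0 + col*s, y0 - row*s)``.
    """

    x0: float = 0.0
    y0: float = 0.0
    pixel_size: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.pixel_size
        return self.x0 + (col + 0.5) * s, self.y0 - (row + 0.5) * s

    def to_json(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "pixel_size": self.pixel_size}

    @classmethod
    def from_json(cls, d: dict) -> "GeoRef":
        return cls(**d)


@dataclass
class RasterGrid:
    """One band of one acquisition: 2-D values plus a missing-data mask.

    ``mask`` is True where the value is missing (cloud, gap, divide-by-zero).
    """

    values: np.ndarray
    band: str = ""
    date: tuple[int, int] | None = None  # (year, month)
    georef: GeoRef = field(default_factory=GeoRef)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must be congruent")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def congruent(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.georef == other.georef

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def copy_with(self, **kw) -> "RasterGrid":
        return replace(self, **kw)

    # -- IO -----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        meta = {
            "band": self.band,
            "date": list(self.date) if self.date else None,
            "georef": self.georef.to_json(),
        }
        data = self.values.astype(np.float32).copy()
        data[self.mask] = np.nan
        tifffile.imwrite(path, data, description=json.dumps(meta))


@dataclass
class RasterStack:
    """A band observed at a strictly increasing sequence of month indices."""

    values: np.ndarray  # (T, H, W) float
    mask: np.ndarray    # (T, H, W) bool, True = missing
    months: np.ndarray  # (T,) int month indices relative to epoch
    epoch: tuple[int, int]
    band: str = ""
    georef: GeoRef = field(default_factory=GeoRef)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.months = np.asarray(self.months, dtype=int)
        if self.values.shape != self.mask.shape or self.values.ndim != 3:
            raise ValueError("values/mask must be congruent 3-D arrays")
        if len(self.months) != self.values.shape[0]:
            raise ValueError("months must match the leading axis")
        if np.any(np.diff(self.months) <= 0):
            raise ValueError("months must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def grid(self, t: int) -> RasterGrid:
        return RasterGrid(
            values=self.values[t].astype(float),
            band=self.band,
            date=index_to_ym(int(self.months[t]), self.epoch),
            georef=self.georef,
            mask=self.mask[t].copy(),
        )

    def at_month(self, month_idx: int) -> RasterGrid:
        pos = np.flatnonzero(self.months == month_idx)
        if len(pos) == 0:
            raise KeyError(f"month index {month_idx} not in stack")
        return self.grid(int(pos[0]))

    def grids(self) -> Iterable[RasterGrid]:
        for t in range(self.shape[0]):
            yield self.grid(t)

    @classmethod
    def from_grids(cls, grids: Sequence[RasterGrid], epoch: tuple[int, int]) -> "RasterStack":
        if not grids:
            raise ValueError("empty grid sequence")
        months = [ym_to_index(*g.date, epoch) for g in grids]
        order = np.argsort(months)
        g0 = grids[0]
        return cls(
            values=np.stack([grids[i].values for i in order]),
            mask=np.stack([grids[i].mask for i in order]),
            months=np.asarray(months)[order],
            epoch=epoch,
            band=g0.band,
            georef=g0.georef,
        )

    # -- IO -----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        meta = {
            "band": self.band,
            "epoch": list(self.epoch),
            "months": self.months.tolist(),
            "georef": self.georef.to_json(),
        }
        data = self.values.astype(np.float32).copy()
        data[self.mask] = np.nan
        tifffile.imwrite(path, data, description=json.dumps(meta))


def _read_meta(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description
    return json.loads(desc) if desc else {}


def read_grid(path: str | Path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        meta = _read_meta(tif)
    return RasterGrid(
        values=data,
        band=meta.get("band", ""),
        date=tuple(meta["date"]) if meta.get("date") else None,
        georef=GeoRef.from_json(meta.get("georef", {})),
    )


def read_stack(path: str | Path) -> RasterStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float32)
        meta = _read_meta(tif)
    if data.ndim == 2:
        data = data[None]
    return RasterStack(
        values=data,
        mask=~np.isfinite(data),
        months=np.asarray(meta["months"]),
        epoch=tuple(meta["epoch"]),
        band=meta.get("band", ""),
        georef=GeoRef.from_json(meta.get("georef", {})),
    )
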
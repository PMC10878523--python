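"""Synthetic fire-scene generator with known ground truth.

Emulates the inputs of a multidecadal burned-area study of a dry
forest/savanna mosaic: a monthly surface-reflectance archive (Red, NIR,
SWIR2 at 30 m) spanning ~37 years, a five-zone management map, a schedule
of late-dry-season fires that step NDVI down with (by default) zero
recovery and spike dNBR at the fire month, and GEDI-like lidar footprints
whose structure metrics (PAI, canopy cover, canopy height) respond linearly
to burn count and months since fire.

Everything is seeded and the generator returns a :class:`SceneTruth`
holding the exact burned pixel sets, burn dates and coefficients used, so
every downstream stage can be tested against a known answer.

Reflectance is simulated directly on the surface-reflectance scale; the
spectral bands are back-solved from target NDVI/NBR series so that the
index values recovered downstream equal the simulated ones exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import heapq
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import mapping

from .raster import GeoRef, RasterStack, index_to_ym, ym_to_index

__all__ = [
    "FireSpec",
    "SceneConfig",
    "SceneTruth",
    "TruthFire",
    "generate_landscape",
    "simulate_archive",
    "simulate_footprints",
    "generate_scene",
    "DRY_SEASON_MONTHS",
]

# Dry season May-October: the only window in which fires are scheduled and
# the season label used for footprints.
DRY_SEASON_MONTHS = frozenset(range(5, 11))

FOREST, SAVANNA = 1, 0
ZONE_NAMES = ("peripheral", "service", "buffer", "community", "core")


@dataclass(frozen=True)
class FireSpec:
    """One scheduled fire: date, target size and placement behaviour.

    ``overlap`` in [0, 1] biases both the ignition point and the growth of
    the burn scar toward previously burned forest, which is how escalating
    re-burn histories are produced.
    """

    year: int
    month: int
    area_ha: float
    overlap: float = 0.0


def _default_fire_schedule() -> tuple[FireSpec, ...]:
    # Escalating late-dry-season schedule: two minor early fires, then
    # successively larger events re-burning earlier scars.
    return (
        FireSpec(2014, 9, 8.0),
        FireSpec(2014, 10, 10.0),
        FireSpec(2017, 10, 50.0, overlap=0.2),
        FireSpec(2018, 9, 25.0, overlap=0.3),
        FireSpec(2019, 10, 120.0, overlap=0.6),
        FireSpec(2021, 10, 250.0, overlap=0.6),
    )


@dataclass
class SceneConfig:
    """Full parameterisation of the synthetic scene.

    Seasonal index parameters are (annual mean, seasonal amplitude, phase
    month of the peak) per cover class on the index scale; noise and fire
    effects are also on the index scale.  All spatial sizes are in pixels
    of ``pixel_size`` metres (0.09 ha at the 30 m default).
    """

    rows: int = 100
    cols: int = 100
    pixel_size: float = 30.0
    start: tuple[int, int] = (1985, 1)
    end: tuple[int, int] = (2022, 12)

    forest_fraction: float = 0.7
    savanna_fraction: float | None = None  # default: remainder
    patch_scale_px: float = 8.0            # Gaussian-field correlation length
    peripheral_width_frac: float = 0.10    # outer ring of the zone map

    # (mean, amplitude, peak month) per class, index scale
    ndvi_seasonal: dict = field(default_factory=lambda: {
        "forest": (0.70, 0.06, 2.0), "savanna": (0.35, 0.22, 2.0)})
    nbr_seasonal: dict = field(default_factory=lambda: {
        "forest": (0.55, 0.04, 2.0), "savanna": (0.30, 0.15, 2.0)})
    red_reflectance: float = 0.08

    noise_sd: float = 0.05
    missing_prob: float = 0.10

    fires: tuple[FireSpec, ...] = field(default_factory=_default_fire_schedule)
    ndvi_drop_first: float = 0.35
    ndvi_drop_repeat: float = 0.15
    dnbr_first: float = 0.45
    dnbr_increment: float = 0.10        # added per prior burn
    recovery_rate: float = 0.0          # NDVI deficit removed per month
    char_fade_rate: float = 0.15        # burn-scar NBR relaxation per month
    nbr_perm_step: float = 0.05         # permanent NBR loss per burn

    # lidar-like footprints
    n_footprints: int = 1500
    footprint_window: tuple[tuple[int, int], tuple[int, int]] = ((2019, 1), (2022, 12))
    n_orbits: int = 8
    fp_baselines: dict = field(default_factory=lambda: {
        "forest": {"pai": 3.2, "cc": 0.78, "ch": 18.0},
        "savanna": {"pai": 0.6, "cc": 0.25, "ch": 4.0}})
    fp_coef_nfires: dict = field(default_factory=lambda: {
        "pai": -0.2, "cc": -0.071, "ch": -0.114})
    fp_coef_months: dict = field(default_factory=lambda: {
        "pai": 0.0, "cc": 0.0, "ch": -0.041})
    fp_noise_sd: dict = field(default_factory=lambda: {
        "pai": 0.5, "cc": 0.07, "ch": 0.45})
    fp_zone_sd: dict = field(default_factory=lambda: {
        "pai": 0.05, "cc": 0.01, "ch": 0.2})
    fp_season_sd: dict = field(default_factory=lambda: {
        "pai": 0.05, "cc": 0.01, "ch": 0.2})
    fp_quality_fail_rate: float = 0.05

    seed: int = 0

    # -- derived ------------------------------------------------------------

    @property
    def epoch(self) -> tuple[int, int]:
        return self.start

    @property
    def n_months(self) -> int:
        return ym_to_index(*self.end, self.start) + 1

    @property
    def georef(self) -> GeoRef:
        return GeoRef(0.0, self.rows * self.pixel_size, self.pixel_size)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0

    def validate(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        sav = self.savanna_fraction
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise ValueError("forest fraction must be in [0, 1]")
        if sav is not None and (sav < 0 or self.forest_fraction + sav > 1.0 + 1e-9):
            raise ValueError("cover fractions must be in [0,1] and sum to <= 1")
        for f in self.fires:
            if f.month not in DRY_SEASON_MONTHS:
                raise ValueError(
                    f"fire {f.year}-{f.month:02d} outside the May-October dry season")
            idx = ym_to_index(f.year, f.month, self.start)
            if not 0 <= idx < self.n_months:
                raise ValueError(f"fire {f.year}-{f.month:02d} outside the time span")
        for name in ("noise_sd", "missing_prob", "char_fade_rate", "recovery_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for d in (self.fp_noise_sd, self.fp_zone_sd, self.fp_season_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("footprint noise sds must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stage of the simulation."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TruthFire:
    """One ground-truth fire event."""

    event_id: int
    year: int
    month: int
    month_index: int
    mask: np.ndarray  # (H, W) bool
    area_ha: float

    def polygon(self, georef: GeoRef):
        return _mask_to_polygon(self.mask, georef)

    # duck-type compatibility with detection events (same pixel-set protocol;
    # note ``month`` here is the calendar month -- consumers that need the
    # series position read ``month_index`` first)
    @property
    def pixel_mask(self) -> np.ndarray:
        return self.mask


@dataclass
class SceneTruth:
    """Ground truth of a generated scene: the oracle for every later stage."""

    land_cover: np.ndarray        # (H, W) int: 1 forest, 0 savanna
    zones: np.ndarray             # (H, W) int index into zone_names
    zone_names: tuple[str, ...]
    fires: list
    burn_months: np.ndarray       # (max_burns, H, W) int month index, -1 = none
    epoch: tuple[int, int]
    georef: GeoRef
    coefficients: dict = field(default_factory=dict)

    @property
    def burn_counts(self) -> np.ndarray:
        return (self.burn_months >= 0).sum(axis=0)

    def validate(self) -> None:
        H, W = self.land_cover.shape
        for f in self.fires:
            if f.mask.shape != (H, W):
                raise AssertionError("fire mask incongruent with grid")
            if abs(f.mask.sum() * self.georef.pixel_area_ha - f.area_ha) > 1e-6:
                raise AssertionError("catalog area does not match pixel set")
        bm = self.burn_months
        active = bm >= 0
        # per-pixel dates strictly increasing where present
        for k in range(1, bm.shape[0]):
            both = active[k] & active[k - 1]
            if np.any(bm[k][both] <= bm[k - 1][both]):
                raise AssertionError("per-pixel burn dates not strictly increasing")
        # counts agree with catalog membership
        from_events = np.zeros((H, W), dtype=int)
        for f in self.fires:
            from_events += f.mask
        if not np.array_equal(from_events, self.burn_counts):
            raise AssertionError("burn counts disagree with catalog membership")

    def n_fires_at(self, row: int, col: int, month_index: int) -> int:
        """Number of catalogued burns at a pixel on/before a month."""
        bm = self.burn_months[:, row, col]
        return int(np.sum((bm >= 0) & (bm <= month_index)))

    def months_since_at(self, row: int, col: int, month_index: int) -> int | None:
        bm = self.burn_months[:, row, col]
        past = bm[(bm >= 0) & (bm <= month_index)]
        return int(month_index - past.max()) if len(past) else None

    # -- export -------------------------------------------------------------

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        features = []
        for f in self.fires:
            features.append({
                "type": "Feature",
                "geometry": mapping(f.polygon(self.georef)),
                "properties": {
                    "event_id": f.event_id, "year": f.year, "month": f.month,
                    "area_ha": round(f.area_ha, 4),
                },
            })
        (directory / "truth_fires.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features}))
        meta = {
            "epoch": list(self.epoch),
            "zone_names": list(self.zone_names),
            "coefficients": self.coefficients,
            "n_fires": len(self.fires),
        }
        (directory / "truth_meta.json").write_text(json.dumps(meta, indent=2))
        np.savetxt(directory / "truth_burn_counts.csv",
                   self.burn_counts, fmt="%d", delimiter=",")


def _mask_to_polygon(mask: np.ndarray, georef: GeoRef):
    rows, cols = np.nonzero(mask)
    s = georef.pixel_size
    boxes = shapely.box(
        georef.x0 + cols * s,
        georef.y0 - (rows + 1) * s,
        georef.x0 + (cols + 1) * s,
        georef.y0 - rows * s,
    )
    return shapely.union_all(boxes)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def generate_landscape(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Land-cover and zone maps.

    Forest is a thresholded smoothed Gaussian random field, giving
    contiguous patches whose areal share matches ``forest_fraction``
    exactly up to ties.  The zone map is an outer peripheral ring with the
    interior split into service/buffer/community/core strips.
    """
    config.validate()
    H, W = config.rows, config.cols
    rng = config.rng(1)

    if config.forest_fraction >= 1.0:
        land = np.full((H, W), FOREST, dtype=np.int8)
    elif config.forest_fraction <= 0.0:
        land = np.full((H, W), SAVANNA, dtype=np.int8)
    else:
        f = gaussian_filter(rng.standard_normal((H, W)), config.patch_scale_px)
        thr = np.quantile(f, 1.0 - config.forest_fraction)
        land = np.where(f >= thr, FOREST, SAVANNA).astype(np.int8)

    zones = np.full((H, W), ZONE_NAMES.index("core"), dtype=np.int8)
    ring = max(1, int(round(config.peripheral_width_frac * min(H, W))))
    if min(H, W) <= 2 * ring:
        ring = 0
    inner_cols = W - 2 * ring
    edges = [ring + int(round(inner_cols * q)) for q in (0.25, 0.5, 0.75)]
    for name, lo, hi in (
        ("service", ring, edges[0]),
        ("buffer", edges[0], edges[1]),
        ("community", edges[1], edges[2]),
        ("core", edges[2], W - ring),
    ):
        zones[ring:H - ring if ring else H, lo:hi] = ZONE_NAMES.index(name)
    if ring:
        per = ZONE_NAMES.index("peripheral")
        zones[:ring, :] = per
        zones[-ring:, :] = per
        zones[:, :ring] = per
        zones[:, -ring:] = per
    return land, zones


# ---------------------------------------------------------------------------
# fire placement
# ---------------------------------------------------------------------------

def _grow_scar(rng, eligible: np.ndarray, prior: np.ndarray, n_px: int,
               overlap: float) -> np.ndarray:
    """Grow a connected burn scar of ``n_px`` pixels inside ``eligible``.

    Randomised Prim growth: frontier pixels carry random keys, shrunk for
    previously burned pixels in proportion to ``overlap`` so the scar
    preferentially re-covers old burns.  Falls back to a fresh ignition in
    the remaining eligible area if a forest patch is exhausted.
    """
    H, W = eligible.shape
    avail = eligible.copy()
    if avail.sum() < n_px:
        raise ValueError("target fire area exceeds available forest")
    scar = np.zeros((H, W), dtype=bool)

    def key_for(r, c):
        k = rng.random()
        if overlap > 0 and prior[r, c]:
            k *= 1.0 - 0.85 * overlap
        return k

    def seed_pixel():
        pool = avail & prior if (overlap > 0 and rng.random() < overlap
                                 and (avail & prior).any()) else avail
        rows, cols = np.nonzero(pool)
        i = rng.integers(len(rows))
        return int(rows[i]), int(cols[i])

    heap: list[tuple[float, int, int]] = []
    r0, c0 = seed_pixel()
    heapq.heappush(heap, (0.0, r0, c0))
    count = 0
    while count < n_px:
        if not heap:
            rr, cc = seed_pixel()
            heapq.heappush(heap, (0.0, rr, cc))
        _, r, c = heapq.heappop(heap)
        if scar[r, c] or not avail[r, c]:
            continue
        scar[r, c] = True
        avail[r, c] = False
        count += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and avail[rr, cc] and not scar[rr, cc]:
                heapq.heappush(heap, (key_for(rr, cc), rr, cc))
    return scar


def _build_fire_catalog(config: SceneConfig, land: np.ndarray) -> list:
    rng = config.rng(2)
    pa = config.pixel_area_ha
    burned_ever = np.zeros_like(land, dtype=bool)
    fires: list[TruthFire] = []
    for i, spec in enumerate(sorted(config.fires, key=lambda f: (f.year, f.month))):
        n_px = max(1, int(round(spec.area_ha / pa)))
        scar = _grow_scar(rng, land == FOREST, burned_ever, n_px, spec.overlap)
        burned_ever |= scar
        fires.append(TruthFire(
            event_id=i, year=spec.year, month=spec.month,
            month_index=ym_to_index(spec.year, spec.month, config.start),
            mask=scar, area_ha=scar.sum() * pa,
        ))
    return fires


# ---------------------------------------------------------------------------
# reflectance archive
# ---------------------------------------------------------------------------

def _seasonal_series(params: dict, land: np.ndarray, cal_months: np.ndarray) -> np.ndarray:
    """(T, H, W) seasonal index values from per-class (mean, amp, peak)."""
    T = len(cal_months)
    out = np.empty((T,) + land.shape, dtype=np.float64)
    for cls, code in (("forest", FOREST), ("savanna", SAVANNA)):
        mean, amp, peak = params[cls]
        series = mean + amp * np.cos(2 * np.pi * (cal_months - peak) / 12.0)
        sel = land == code
        out[:, sel] = series[:, None]
    return out


def simulate_archive(config: SceneConfig, landscape=None):
    """Simulate the monthly Red/NIR/SWIR2 archive and its ground truth.

    Returns ``(bands, truth)`` where ``bands`` maps band name to a
    :class:`RasterStack`.  Fires step NDVI down with no recovery (by
    default) and drop NBR at the fire month by exactly the configured dNBR
    magnitude relative to the previous month, after which the scar signal
    fades toward a permanently lowered level.
    """
    config.validate()
    if landscape is None:
        landscape = generate_landscape(config)
    land, zones = landscape
    H, W = land.shape
    T = config.n_months
    months = np.arange(T)
    cal = np.array([index_to_ym(m, config.start)[1] for m in months], dtype=float)

    fires = _build_fire_catalog(config, land)
    burns_at: dict[int, list[TruthFire]] = {}
    for f in fires:
        burns_at.setdefault(f.month_index, []).append(f)

    base_ndvi = _seasonal_series(config.ndvi_seasonal, land, cal)
    base_nbr = _seasonal_series(config.nbr_seasonal, land, cal)

    ndvi = np.empty_like(base_ndvi)
    nbr = np.empty_like(base_nbr)
    deficit = np.zeros((H, W))      # NDVI loss carried forward
    char = np.zeros((H, W))         # fading burn-scar NBR depression
    perm = np.zeros((H, W))         # permanent NBR depression
    nburn = np.zeros((H, W), dtype=int)
    prev_nbr = base_nbr[0]
    for t in range(T):
        if config.recovery_rate > 0:
            deficit = np.maximum(0.0, deficit - config.recovery_rate)
        char *= 1.0 - config.char_fade_rate
        for f in burns_at.get(t, ()):
            m = f.mask
            k = nburn[m]  # prior burns per pixel
            deficit[m] += np.where(k == 0, config.ndvi_drop_first,
                                   config.ndvi_drop_repeat)
            d = config.dnbr_first + config.dnbr_increment * k
            target = prev_nbr[m] - d
            perm[m] = np.minimum(perm[m] + config.nbr_perm_step, 0.4)
            char[m] = np.maximum(base_nbr[t][m] - perm[m] - target, 0.0)
            nburn[m] += 1
        ndvi[t] = np.clip(base_ndvi[t] - deficit, 0.02, 0.98)
        nbr[t] = np.clip(base_nbr[t] - perm - char, -0.95, 0.98)
        prev_nbr = nbr[t]

    rng = config.rng(3)
    if config.noise_sd > 0:
        ndvi = np.clip(ndvi + rng.normal(0, config.noise_sd, ndvi.shape), -0.98, 0.98)
        nbr = np.clip(nbr + rng.normal(0, config.noise_sd, nbr.shape), -0.98, 0.98)
    miss = (rng.random((T, H, W)) < config.missing_prob) if config.missing_prob > 0 \
        else np.zeros((T, H, W), dtype=bool)

    red = np.full((T, H, W), config.red_reflectance)
    nir = red * (1 + ndvi) / (1 - ndvi)
    swir2 = nir * (1 - nbr) / (1 + nbr)

    bands = {}
    for name, data in (("red", red), ("nir", nir), ("swir2", swir2)):
        vals = data.astype(np.float32)
        vals[miss] = np.nan
        bands[name] = RasterStack(values=vals, mask=miss.copy(), months=months,
                                  epoch=config.start, band=name, georef=config.georef)

    max_burns = max((int(nburn.max()), 1))
    burn_months = np.full((max_burns, H, W), -1, dtype=int)
    counter = np.zeros((H, W), dtype=int)
    for f in fires:
        rows_m, cols_m = np.nonzero(f.mask)
        burn_months[counter[f.mask], rows_m, cols_m] = f.month_index
        counter[f.mask] += 1

    truth = SceneTruth(
        land_cover=land, zones=zones, zone_names=ZONE_NAMES, fires=fires,
        burn_months=burn_months, epoch=config.start, georef=config.georef,
        coefficients={
            "ndvi_drop_first": config.ndvi_drop_first,
            "ndvi_drop_repeat": config.ndvi_drop_repeat,
            "dnbr_first": config.dnbr_first,
            "dnbr_increment": config.dnbr_increment,
            "coef_nfires": dict(config.fp_coef_nfires),
            "coef_months": dict(config.fp_coef_months),
        },
    )
    truth.validate()
    return bands, truth


# ---------------------------------------------------------------------------
# lidar-like footprints
# ---------------------------------------------------------------------------

def simulate_footprints(config: SceneConfig, truth: SceneTruth,
                        seed: int | None = None) -> pd.DataFrame:
    """Draw GEDI-like footprints over the scene.

    Each footprint is one ~25 m sample at a forest pixel with an
    acquisition month in the configured window; PAI/CC/CH are the class
    baseline plus fixed effects of burn count and months since fire, plus
    zone and season random intercepts and observation noise.  Columns
    ``n_fires_true``/``months_since_true`` carry the generator's own
    covariates for oracle comparisons (months since is -1 for never
    burned).
    """
    if config.n_footprints <= 0:
        raise ValueError("at least one footprint must be requested")
    rng = config.rng(4) if seed is None else np.random.default_rng(
        np.random.SeedSequence([int(seed), 4]))

    H, W = truth.land_cover.shape
    rows_f, cols_f = np.nonzero(truth.land_cover == FOREST)
    if len(rows_f) == 0:
        rows_f, cols_f = np.nonzero(np.ones((H, W), dtype=bool))
    n = config.n_footprints
    pick = rng.integers(len(rows_f), size=n)
    rows, cols = rows_f[pick], cols_f[pick]

    lo = ym_to_index(*config.footprint_window[0], truth.epoch)
    hi = ym_to_index(*config.footprint_window[1], truth.epoch)
    acq = rng.integers(lo, hi + 1, size=n)
    cal_month = np.array([index_to_ym(int(m), truth.epoch)[1] for m in acq])
    season = np.where(np.isin(cal_month, list(DRY_SEASON_MONTHS)), "dry", "wet")
    orbit = rng.integers(config.n_orbits, size=n)

    zone_idx = truth.zones[rows, cols]
    zone = np.asarray(truth.zone_names)[zone_idx]
    nf = np.empty(n, dtype=int)
    msf = np.empty(n, dtype=int)
    for i in range(n):
        nf[i] = truth.n_fires_at(rows[i], cols[i], int(acq[i]))
        ms = truth.months_since_at(rows[i], cols[i], int(acq[i]))
        msf[i] = -1 if ms is None else ms

    zone_off = {m: dict(zip(truth.zone_names,
                            rng.normal(0, config.fp_zone_sd[m], len(truth.zone_names))))
                for m in ("pai", "cc", "ch")}
    season_off = {m: dict(zip(("dry", "wet"), rng.normal(0, config.fp_season_sd[m], 2)))
                  for m in ("pai", "cc", "ch")}

    cover = np.where(truth.land_cover[rows, cols] == FOREST, "forest", "savanna")
    months_cov = np.where(msf >= 0, msf, 0)
    out = {}
    for m in ("pai", "cc", "ch"):
        base = np.array([config.fp_baselines[c][m] for c in cover])
        z = np.array([zone_off[m][zn] for zn in zone])
        s = np.array([season_off[m][sn] for sn in season])
        vals = (base + config.fp_coef_nfires[m] * nf
                + config.fp_coef_months[m] * months_cov + z + s
                + rng.normal(0, config.fp_noise_sd[m], n))
        if m == "cc":
            vals = np.clip(vals, 0.0, 1.0)
        else:
            vals = np.maximum(vals, 0.0)
        out[m] = vals

    x, y = zip(*(truth.georef.pixel_center(int(r), int(c)) for r, c in zip(rows, cols)))
    years = [index_to_ym(int(m), truth.epoch)[0] for m in acq]
    cals = [index_to_ym(int(m), truth.epoch)[1] for m in acq]
    return pd.DataFrame({
        "row": rows, "col": cols, "x": x, "y": y,
        "year": years, "month": cals, "month_index": acq,
        "orbit": orbit,
        "quality_ok": rng.random(n) >= config.fp_quality_fail_rate,
        "season": season, "zone": zone, "cover": cover,
        "pai": out["pai"], "cc": out["cc"], "ch": out["ch"],
        "n_fires_true": nf, "months_since_true": msf,
    })


def generate_scene(config: SceneConfig):
    """Convenience wrapper: landscape + archive + truth + footprints."""
    landscape = generate_landscape(config)
    bands, truth = simulate_archive(config, landscape)
    footprints = simulate_footprints(config, truth)
    return bands, truth, footprints


def write_archive(bands: dict, directory: str | Path) -> None:
    """Write each band stack as a multipage TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, stack in bands.items():
        stack.write(directory / f"{name}.tif")


def config_to_json(config: SceneConfig) -> str:
    d = asdict(config)
    d["fires"] = [asdict(f) for f in config.fires]
    return json.dumps(d, indent=2, default=str)
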
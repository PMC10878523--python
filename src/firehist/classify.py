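"""Object-based classification: SLIC segmentation + supervised labelling.

Used twice in the pipeline: to derive the forest base map from the start
of the archive, and to refine fire perimeters on differenced-NDVI images.
Segmentation is Simple Linear Iterative Clustering (localized k-means over
joint spatial/spectral space); segments are then classified from training
labels by a pluggable classifier, by default a small feed-forward network,
and segment labels are painted back to pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.segmentation import slic as _skimage_slic
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .indices import compute_index, monthly_median_composite
from .raster import RasterGrid

__all__ = [
    "SegmentSet",
    "slic_segment",
    "train_and_classify",
    "forest_base_map",
]


@dataclass
class SegmentSet:
    """A segment-id raster and per-segment spectral/shape features.

    Labels partition the unmasked pixels (masked pixels carry -1); the
    feature table is indexed by segment id with columns ``mean_<band>``,
    ``sd_<band>``, ``size`` and centroid row/col.
    """

    labels: np.ndarray
    features: pd.DataFrame
    band_names: tuple[str, ...]

    @property
    def n_segments(self) -> int:
        return len(self.features)

    def validate(self) -> None:
        unmasked = self.labels >= 0
        ids = np.unique(self.labels[unmasked])
        if not np.array_equal(np.sort(ids), np.sort(self.features.index.to_numpy())):
            raise AssertionError("feature table does not match label raster")
        if not np.all(np.isfinite(self.features.to_numpy(dtype=float))):
            raise AssertionError("non-finite segment features")


def slic_segment(images: RasterGrid | list[RasterGrid], n_segments: int,
                 compactness: float = 0.05) -> SegmentSet:
    """Segment one or more congruent bands with SLIC.

    ``compactness`` trades spatial regularity against spectral homogeneity
    exactly as in scikit-image; the default suits index-scale values of
    order 0.1-1.  Segment count may differ from the request by up to about
    a factor of two (connectivity enforcement merges/splits).
    """
    grids = [images] if isinstance(images, RasterGrid) else list(images)
    if not grids:
        raise ValueError("no input image")
    first = grids[0]
    for g in grids[1:]:
        if not g.congruent(first):
            raise ValueError("input grids are not congruent")
    n_px = first.values.size
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > n_px:
        raise ValueError("n_segments exceeds pixel count")

    data = np.stack([g.filled(np.nan) for g in grids], axis=-1)
    # SLIC needs finite values everywhere; fill gaps with the band mean
    for b in range(data.shape[-1]):
        band = data[..., b]
        fill = np.nanmean(band) if np.any(np.isfinite(band)) else 0.0
        band[~np.isfinite(band)] = fill
    if n_segments == 1:
        labels = np.zeros(first.shape, dtype=int)
    else:
        labels = _skimage_slic(
            data, n_segments=n_segments, compactness=compactness,
            start_label=0, channel_axis=-1, enforce_connectivity=True)
    labels = labels.astype(int)

    names = tuple(g.band or f"b{i}" for i, g in enumerate(grids))
    feats = _segment_features(labels, data, names)
    return SegmentSet(labels=labels, features=feats, band_names=names)


def _segment_features(labels: np.ndarray, data: np.ndarray,
                      names: tuple[str, ...]) -> pd.DataFrame:
    ids = np.unique(labels[labels >= 0])
    H, W = labels.shape
    rows, cols = np.indices((H, W))
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    bounds = np.searchsorted(sorted_labels, np.append(ids, ids[-1] + 1))
    rec = {}
    r_flat, c_flat = rows.ravel()[order], cols.ravel()[order]
    sizes, cent_r, cent_c = [], [], []
    per_band = {f: [] for name in names for f in (f"mean_{name}", f"sd_{name}")}
    band_flat = [data[..., b].ravel()[order] for b in range(data.shape[-1])]
    for i, sid in enumerate(ids):
        sl = slice(bounds[i], bounds[i + 1])
        sizes.append(sl.stop - sl.start)
        cent_r.append(float(r_flat[sl].mean()))
        cent_c.append(float(c_flat[sl].mean()))
        for b, name in enumerate(names):
            vals = band_flat[b][sl]
            per_band[f"mean_{name}"].append(float(vals.mean()))
            per_band[f"sd_{name}"].append(float(vals.std()))
    rec.update(per_band)
    rec["size"] = sizes
    rec["centroid_row"] = cent_r
    rec["centroid_col"] = cent_c
    return pd.DataFrame(rec, index=pd.Index(ids, name="segment_id"))


def _make_classifier(kind: str, seed: int):
    if kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=3000,
                             random_state=seed)
    if kind == "logistic":
        return LogisticRegression(max_iter=2000)
    raise ValueError(f"unknown classifier {kind!r}")


def train_and_classify(segments: SegmentSet, labels: pd.DataFrame,
                       classifier: str = "mlp", seed: int = 0,
                       feature_columns: list[str] | None = None):
    """Train on labelled segments and classify every segment.

    ``labels`` needs columns ``segment_id`` and ``class``.  Returns
    ``(class_map, segment_classes)``: a per-pixel array obtained by painting
    segment labels (-1 outside the partition when present) represented as an
    object array of class labels, and a Series of per-segment classes.
    """
    if labels["class"].nunique() < 1:
        raise ValueError("training labels required")
    feats = segments.features
    cols = feature_columns or [c for c in feats.columns
                               if c.startswith(("mean_", "sd_"))] + ["size"]
    X = feats.loc[:, cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain missing values")
    train = labels.drop_duplicates("segment_id")
    Xtr = feats.loc[train["segment_id"], cols].to_numpy(dtype=float)
    ytr = train["class"].to_numpy()

    if len(np.unique(ytr)) == 1:
        pred = np.full(len(feats), ytr[0], dtype=object)
    else:
        model = make_pipeline(StandardScaler(),
                              _make_classifier(classifier, seed))
        model.fit(Xtr, ytr)
        pred = model.predict(X)
    seg_classes = pd.Series(pred, index=feats.index, name="class")

    lut = dict(zip(feats.index.to_numpy(), pred))
    class_map = np.empty(segments.labels.shape, dtype=object)
    class_map.fill(None)
    for sid, cls in lut.items():
        class_map[segments.labels == sid] = cls
    return class_map, seg_classes


def forest_base_map(bands: dict, truth_labels: np.ndarray,
                    n_segments: int = 400, label_fraction: float = 0.2,
                    classifier: str = "mlp", seed: int = 0,
                    n_months: int = 24, compactness: float = 0.1) -> np.ndarray:
    """Binary forest mask from the start of the archive.

    Builds annual feature layers (mean/percentile NDVI and mean NBR over
    the first ``n_months`` months), segments them, trains on a fraction of
    segments labelled from ``truth_labels`` (1 = forest reference data,
    e.g. a digitised aerial survey), and paints the classification.
    """
    red, nir, swir2 = bands["red"], bands["nir"], bands["swir2"]
    T = min(n_months, red.shape[0])
    ndvi_layers, nbr_layers = [], []
    for t in range(T):
        ndvi_layers.append(compute_index(red.grid(t), nir.grid(t), which="NDVI"))
        nbr_layers.append(compute_index(red.grid(t), nir.grid(t), swir2.grid(t),
                                        which="NBR"))

    def stat_grid(layers, fn, band):
        data = np.stack([g.filled(np.nan) for g in layers])
        with np.errstate(all="ignore"):
            vals = fn(data)
        return RasterGrid(vals, band=band, date=layers[-1].date,
                          georef=layers[0].georef)

    feat_grids = [
        stat_grid(ndvi_layers, lambda d: np.nanmean(d, axis=0), "ndvi_mean"),
        stat_grid(ndvi_layers, lambda d: np.nanpercentile(d, 10, axis=0), "ndvi_p10"),
        stat_grid(ndvi_layers,
                  lambda d: np.nanpercentile(d, 90, axis=0)
                  - np.nanpercentile(d, 10, axis=0), "ndvi_range"),
        stat_grid(nbr_layers, lambda d: np.nanmean(d, axis=0), "nbr_mean"),
    ]
    segments = slic_segment(feat_grids, n_segments=n_segments,
                            compactness=compactness)

    rng = np.random.default_rng(seed)
    ids = segments.features.index.to_numpy()
    n_train = max(2, int(round(label_fraction * len(ids))))
    chosen = rng.choice(ids, size=min(n_train, len(ids)), replace=False)
    rows = []
    for sid in chosen:
        sel = segments.labels == sid
        frac_forest = float(np.mean(truth_labels[sel] == 1))
        rows.append({"segment_id": sid,
                     "class": "forest" if frac_forest >= 0.5 else "nonforest"})
    training = pd.DataFrame(rows)
    if training["class"].nunique() < 2:
        # degenerate draw: label everything by majority
        return np.full(truth_labels.shape, training["class"].iloc[0] == "forest")
    class_map, seg_classes = train_and_classify(segments, training,
                                                classifier=classifier, seed=seed)
    mask = class_map == "forest"

    # pixel-level cleanup in boundary-straddling segments: mean NDVI
    # separates the cover classes by a wide margin, so pixels of mixed
    # segments are reassigned to the nearer class level
    feat = feat_grids[0].values
    if mask.any() and (~mask).any():
        mu_f, mu_n = float(np.nanmean(feat[mask])), float(np.nanmean(feat[~mask]))
        sd = segments.features["sd_ndvi_mean"]
        mixed = sd.index[sd > 0.15 * abs(mu_f - mu_n)].to_numpy()
        if len(mixed):
            px = np.isin(segments.labels, mixed) & np.isfinite(feat)
            mask[px] = np.abs(feat[px] - mu_f) < np.abs(feat[px] - mu_n)
    return mask
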
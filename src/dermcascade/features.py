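"""Hand-crafted features of irregular pigment-network masks.

Given an RGB image, a binary lesion mask, and a binary network mask (usually
predicted), the extractor produces a fixed, ordered 36-value vector:

* 18 color features — pooled mean and population SD per CIELAB plane (sRGB,
  D65) over three pixel regions: pixels of network objects lying (by majority
  vote) inside the lesion, pixels of objects outside the lesion, and skin
  (everything outside both lesion and network);
* 4 counts — total objects, objects inside/outside the lesion, and objects
  surviving erosion by a discrete disk of radius 3 (thick-structure count);
* 12 shape aggregates — mean, SD, max of object area, eccentricity, length
  (major axis of the inertia-equivalent ellipse) and width (maximum
  inscribed-disk diameter, 2 x max Euclidean distance to the object's
  complement);
* 2 densities — network pixels inside (resp. outside) the lesion divided by
  the lesion area.

Objects are 8-connected components of the network mask. Aggregates over an
empty object set, and statistics of an empty region, are 0.0 sentinels so
downstream classifier rows stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.color import rgb2lab
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, erosion

__all__ = [
    "FEATURE_NAMES",
    "RegionObject",
    "label_objects",
    "object_width",
    "erosion_survivor_count",
    "rgb_to_lab",
    "color_region_stats",
    "extract_feature_vector",
    "extract_features_table",
    "MaskFeatureExtractor",
]

_COLOR_REGIONS = ("obj_inside", "obj_outside", "skin")
_PLANES = ("L", "A", "B")
_SHAPE_PROPS = ("area", "eccentricity", "length", "width")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{region}_{plane}_{stat}"
     for region in _COLOR_REGIONS for plane in _PLANES
     for stat in ("mean", "sd")]
    + ["n_objects", "n_objects_inside", "n_objects_outside",
       "n_objects_eroded"]
    + [f"{prop}_{stat}" for prop in _SHAPE_PROPS
       for stat in ("mean", "sd", "max")]
    + ["density_inside", "density_outside"]
)
assert len(FEATURE_NAMES) == 36


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return m
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0,1}})")
    return m.astype(bool)


@dataclass
class RegionObject:
    """One 8-connected component of the network mask."""

    coords: np.ndarray          # (n, 2) pixel coordinates
    area: int
    eccentricity: float
    length: float
    width: float
    inside_lesion: bool


def object_width(pixel_mask: np.ndarray) -> float:
    """Maximum inscribed-disk diameter of a single object.

    2 x the maximum Euclidean distance from an object pixel to the object's
    complement; an isolated pixel has distance 1 to background (width 2).
    """
    m = _as_binary(pixel_mask, "object mask")
    if not m.any():
        raise ValueError("object pixel set must be nonempty")
    padded = np.pad(m, 1)  # enforce background beyond the crop border
    return 2.0 * float(distance_transform_edt(padded).max())


def label_objects(network_mask: np.ndarray,
                  lesion_mask: np.ndarray | None = None) -> list[RegionObject]:
    """8-connected components of the network mask with shape descriptors.

    ``inside_lesion`` is decided by pixel-majority vote against the lesion
    mask (objects may straddle the border); with no lesion mask all objects
    are flagged outside.
    """
    m = _as_binary(network_mask, "network_mask")
    lesion = (_as_binary(lesion_mask, "lesion_mask")
              if lesion_mask is not None else None)
    if lesion is not None and lesion.shape != m.shape:
        raise ValueError("lesion_mask shape must match network_mask")
    labels = cc_label(m, connectivity=2)
    objects: list[RegionObject] = []
    for prop in regionprops(labels):
        sub = labels[prop.slice] == prop.label
        width = object_width(sub)
        if lesion is not None:
            inside = lesion[prop.slice][sub].sum() > prop.area / 2.0
        else:
            inside = False
        objects.append(RegionObject(
            coords=prop.coords,
            area=int(prop.area),
            eccentricity=float(prop.eccentricity),
            length=float(prop.axis_major_length),
            width=width,
            inside_lesion=bool(inside),
        ))
    return objects


def erosion_survivor_count(network_mask: np.ndarray, radius: int = 3) -> int:
    """Objects remaining after erosion by a discrete disk of ``radius``."""
    m = _as_binary(network_mask, "network_mask")
    eroded = erosion(m, disk(radius))
    return int(cc_label(eroded, connectivity=2).max())


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """8-bit sRGB to CIE L*a*b* (D65); L in [0, 100]."""
    return rgb2lab(np.asarray(image, dtype=np.uint8))


def color_region_stats(lab_image: np.ndarray,
                       region_mask: np.ndarray) -> np.ndarray:
    """Pooled per-plane (mean, sd) over the region's pixels.

    Population (divide-by-n) SD; an empty region returns the documented
    all-zero sentinel. Returns (mean_L, sd_L, mean_A, sd_A, mean_B, sd_B).
    """
    m = _as_binary(region_mask, "region_mask")
    if m.shape != lab_image.shape[:2]:
        raise ValueError("region_mask shape must match image")
    if not m.any():
        return np.zeros(6)
    px = lab_image[m]  # (n, 3)
    out = np.empty(6)
    out[0::2] = px.mean(axis=0)
    out[1::2] = px.std(axis=0)  # ddof=0
    return out


def _aggregate(values: list[float]) -> tuple[float, float, float]:
    if not values:
        return 0.0, 0.0, 0.0
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std()), float(v.max())


def extract_feature_vector(record, predicted_network_mask: np.ndarray,
                           erosion_radius: int = 3) -> pd.Series:
    """The full 36-value feature vector for one record.

    ``record`` needs ``image`` and a nonempty ``lesion_mask``; the network
    mask is passed separately because it is usually the segmenter's
    prediction, not ground truth.
    """
    lesion = _as_binary(record.lesion_mask, "lesion_mask")
    network = _as_binary(predicted_network_mask, "network_mask")
    if lesion.shape != network.shape:
        raise ValueError("mask shapes must match")
    if not lesion.any():
        raise ValueError("lesion mask is empty; densities are undefined")

    lab = rgb_to_lab(record.image)
    objects = label_objects(network, lesion)

    shape = lesion.shape
    inside_px = np.zeros(shape, dtype=bool)
    outside_px = np.zeros(shape, dtype=bool)
    for obj in objects:
        target = inside_px if obj.inside_lesion else outside_px
        target[obj.coords[:, 0], obj.coords[:, 1]] = True
    skin = ~(lesion | network)

    values: list[float] = []
    for region_mask in (inside_px, outside_px, skin):
        values.extend(color_region_stats(lab, region_mask))

    n_inside = sum(o.inside_lesion for o in objects)
    values.extend([
        float(len(objects)),
        float(n_inside),
        float(len(objects) - n_inside),
        float(erosion_survivor_count(network, erosion_radius)),
    ])

    for prop in _SHAPE_PROPS:
        values.extend(_aggregate([getattr(o, prop) for o in objects]))

    lesion_area = float(lesion.sum())
    values.append(float((network & lesion).sum()) / lesion_area)
    values.append(float((network & ~lesion).sum()) / lesion_area)

    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def extract_features_table(records, network_masks=None,
                           erosion_radius: int = 3) -> pd.DataFrame:
    """Feature rows for a list of records, indexed by image_id.

    ``network_masks`` defaults to each record's own (ground-truth) mask; pass
    predicted masks in record order to use segmenter output. The returned
    frame carries the 36 feature columns plus lesion_id and label.
    """
    rows = {}
    meta = {}
    for i, rec in enumerate(records):
        mask = (network_masks[i] if network_masks is not None
                else rec.network_mask)
        rows[rec.image_id] = extract_feature_vector(rec, mask, erosion_radius)
        meta[rec.image_id] = (rec.lesion_id, rec.label)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[list(FEATURE_NAMES)]
    df.index.name = "image_id"
    df["lesion_id"] = [meta[i][0] for i in df.index]
    df["label"] = [meta[i][1] for i in df.index]
    return df


class MaskFeatureExtractor:
    """Transformer-style wrapper: records (+ optional masks) -> feature table.

    Stateless; ``fit`` exists for pipeline compatibility.
    """

    def __init__(self, erosion_radius: int = 3):
        self.erosion_radius = erosion_radius

    def fit(self, records, y=None) -> "MaskFeatureExtractor":
        return self

    def transform(self, records, network_masks=None) -> pd.DataFrame:
        return extract_features_table(records, network_masks,
                                      self.erosion_radius)

    def get_params(self, deep: bool = True) -> dict:
        return {"erosion_radius": self.erosion_radius}

    def set_params(self, **params) -> "MaskFeatureExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self
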
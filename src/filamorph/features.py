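"""Per-object morphometric features.

Every segmented structure is characterized by 74 measures:

* 10 planar region properties (Area, ConvexArea, Eccentricity,
  EquivDiameter, Extent, FilledArea, MajorAxisLength, MinorAxisLength,
  Perimeter, Solidity);
* 4 context measures: mean and standard deviation of the minimal distance
  from the object's boundary points to the nearest neighboring object,
  and mean and standard deviation of the intensity inside the object;
* 30 amplitudes of the complex Fourier series of the boundary, taken as
  ``z = x + iy`` on an arc-length-uniform resampling — the moduli are
  invariant to rotation (a rotation multiplies every coefficient by a
  unit phase) and, with the translation mode discarded, to translation;
* 30 amplitudes of the real Fourier series of the boundary-to-neighbor
  distance profile sampled at the same resampled points.

Objects whose truncated-series boundary reconstruction misses the
resampled boundary by more than 0.1 px on average are flagged
``excluded`` and dropped from clustering.

Ellipse-equivalent axes use the unit-pixel-square convention (second
central moments plus 1/12), so a single pixel has Major = Minor =
2/sqrt(3) and eccentricity 0, and eccentricity stays strictly below 1
for 1-px-wide lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .segmentation import ImageFrame, StructureObject, boundary_length

logger = logging.getLogger("filamorph.features")

REGION_FEATURES = [
    "Area", "ConvexArea", "Eccentricity", "EquivDiameter", "Extent",
    "FilledArea", "MajorAxisLength", "MinorAxisLength", "Perimeter",
    "Solidity",
]
CONTEXT_FEATURES = [
    "NeighborDistMean", "NeighborDistSD", "IntensityMean", "IntensitySD",
]


def shape_feature_names(n_modes: int = 30) -> List[str]:
    names = []
    for k in range(1, n_modes // 2 + 1):
        names += [f"Shape_p{k}", f"Shape_m{k}"]
    return names[:n_modes]


def dist_feature_names(n_modes: int = 30) -> List[str]:
    return [f"Dist_{k:02d}" for k in range(n_modes)]


def feature_names(n_shape_modes: int = 30, n_dist_modes: int = 30) -> List[str]:
    return (REGION_FEATURES + CONTEXT_FEATURES
            + shape_feature_names(n_shape_modes)
            + dist_feature_names(n_dist_modes))


# ---------------------------------------------------------------------------
# region block
# ---------------------------------------------------------------------------

def region_features(obj: StructureObject) -> Dict[str, float]:
    """The ten standard planar region properties of the pixel set."""
    pix = np.asarray(obj.pixels)
    if pix.shape[0] == 0:
        raise ValueError("empty object")
    area = float(pix.shape[0])

    rmin, cmin = pix.min(axis=0)
    local = pix - [rmin, cmin]
    mask = np.zeros(tuple(local.max(axis=0) + 1), dtype=np.uint8)
    mask[local[:, 0], local[:, 1]] = 1
    props = regionprops(mask)[0]
    convex_area = float(props.area_convex)
    filled_area = float(props.area_filled)
    extent = area / float(mask.shape[0] * mask.shape[1])

    # ellipse-equivalent axes, unit-pixel-square (+1/12) convention
    r = pix[:, 0].astype(float)
    c = pix[:, 1].astype(float)
    mu_rr = r.var() + 1.0 / 12.0
    mu_cc = c.var() + 1.0 / 12.0
    mu_rc = ((r - r.mean()) * (c - c.mean())).mean()
    common = np.sqrt((mu_rr - mu_cc) ** 2 + 4.0 * mu_rc ** 2)
    major = 2.0 * np.sqrt(2.0) * np.sqrt(mu_rr + mu_cc + common)
    minor = 2.0 * np.sqrt(2.0) * np.sqrt(max(mu_rr + mu_cc - common, 0.0))
    ecc = np.sqrt(max(1.0 - (minor / major) ** 2, 0.0)) if major > 0 else 0.0

    return {
        "Area": area,
        "ConvexArea": convex_area,
        "Eccentricity": float(ecc),
        "EquivDiameter": float(2.0 * np.sqrt(area / np.pi)),
        "Extent": float(extent),
        "FilledArea": filled_area,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Perimeter": boundary_length(obj.boundary),
        "Solidity": area / convex_area,
    }


# ---------------------------------------------------------------------------
# neighbor distances and intensity
# ---------------------------------------------------------------------------

def neighbor_distance_map(objects: Sequence[StructureObject], index: int,
                          shape: Tuple[int, int]) -> Tuple[np.ndarray, bool]:
    """Distance (px) from every pixel to the nearest pixel of any *other*
    object.

    Returns ``(distance_map, lone)``.  For a frame with a single object
    the map is the documented sentinel (the image diagonal) everywhere
    and ``lone`` is True.
    """
    other = np.zeros(shape, dtype=bool)
    for j, o in enumerate(objects):
        if j != index:
            other[o.pixels[:, 0], o.pixels[:, 1]] = True
    if not other.any():
        sentinel = float(np.hypot(*shape))
        return np.full(shape, sentinel), True
    return ndimage.distance_transform_edt(~other), False


def neighbor_distance_features(obj: StructureObject,
                               objects: Sequence[StructureObject],
                               shape: Tuple[int, int],
                               dist_map: Optional[np.ndarray] = None,
                               ) -> Dict[str, float]:
    """Mean/SD of boundary-to-nearest-neighbor distance and of intensity.

    ``dist_map`` may be passed to reuse a precomputed map from
    :func:`neighbor_distance_map`.
    """
    if dist_map is None:
        index = next(i for i, o in enumerate(objects) if o is obj)
        dist_map, lone = neighbor_distance_map(objects, index, shape)
        if lone:
            logger.info("lone object %s: sentinel neighbor distance",
                        obj.object_id)
    b = np.asarray(obj.boundary)
    profile = ndimage.map_coordinates(dist_map, [b[:, 0], b[:, 1]],
                                      order=1, mode="nearest")
    inten = obj.intensities if obj.intensities is not None else np.zeros(1)
    return {
        "NeighborDistMean": float(profile.mean()),
        "NeighborDistSD": float(profile.std()),
        "IntensityMean": float(np.mean(inten)),
        "IntensitySD": float(np.std(inten)),
    }


# ---------------------------------------------------------------------------
# Fourier descriptors
# ---------------------------------------------------------------------------

def resample_boundary(boundary: np.ndarray, n_points: int = 128) -> np.ndarray:
    """Resample a closed boundary to ``n_points`` arc-length-uniform points.

    The traversal is rolled to start at the vertex farthest from the
    centroid, a rotation-covariant anchor: exact lattice rotations of an
    object then yield exactly rotated sample points, which is what makes
    the Fourier amplitude moduli invariant to machine precision.
    """
    b = np.asarray(boundary, dtype=float)
    if b.shape[0] == 1:
        return np.repeat(b, n_points, axis=0)
    centroid = b.mean(axis=0)
    anchor = int(np.argmax(np.round(
        np.hypot(*(b - centroid).T), 9)))
    b = np.roll(b, -anchor, axis=0)
    closed = np.vstack([b, b[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(b[:1], n_points, axis=0)
    target = np.arange(n_points) * total / n_points
    rows = np.interp(target, s, closed[:, 0])
    cols = np.interp(target, s, closed[:, 1])
    return np.column_stack([rows, cols])


def fourier_shape_features(boundary: np.ndarray, n_modes: int = 30,
                           n_points: int = 128,
                           ) -> Tuple[np.ndarray, float]:
    """Rotation-invariant boundary-shape amplitudes and reconstruction error.

    The boundary is resampled to ``n_points`` equally spaced points, read
    as the complex signal ``z = x + iy``, and Fourier transformed.  The
    translation mode ``c0`` is discarded; the returned amplitudes are
    ``|c_{+1}|, |c_{-1}|, |c_{+2}|, ...`` for the ``n_modes`` lowest
    frequencies.  The error is the mean distance between the resampled
    points and their truncated-series reconstruction.
    """
    b = np.asarray(boundary, dtype=float)
    n_half = n_modes // 2
    if b.shape[0] < 8:
        # degenerate boundary: report what the few available modes allow
        amps = np.zeros(n_modes)
        m = b.shape[0]
        if m >= 3:
            z = b[:, 1] + 1j * b[:, 0]
            c = np.fft.fft(z) / m
            for k in range(1, min(n_half, (m - 1) // 2) + 1):
                amps[2 * (k - 1)] = np.abs(c[k])
                amps[2 * k - 1] = np.abs(c[m - k])
        return amps, 0.0

    pts = resample_boundary(b, n_points)
    z = pts[:, 1] + 1j * pts[:, 0]
    c = np.fft.fft(z) / n_points
    amps = np.empty(n_modes)
    kept = np.zeros(n_points, dtype=bool)
    kept[0] = True                      # c0 used for reconstruction only
    for k in range(1, n_half + 1):
        amps[2 * (k - 1)] = np.abs(c[k])
        amps[2 * k - 1] = np.abs(c[n_points - k])
        kept[k] = True
        kept[n_points - k] = True
    z_rec = np.fft.ifft(np.where(kept, c, 0.0) * n_points)
    err = float(np.mean(np.abs(z - z_rec)))
    return amps, err


def fourier_distance_features(profile: np.ndarray, n_modes: int = 30,
                              ) -> np.ndarray:
    """One-sided real-DFT amplitudes of a periodic boundary profile.

    ``|d_0|`` equals the profile mean; a constant profile has all higher
    amplitudes zero.
    """
    p = np.asarray(profile, dtype=float)
    n = p.size
    d = np.fft.fft(p) / n
    amps = np.zeros(n_modes)
    m = min(n_modes, n)
    amps[:m] = np.abs(d[:m])
    return amps


# ---------------------------------------------------------------------------
# assembly and standardization
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Objects x named-features table with provenance and scaling state."""

    features: pd.DataFrame            # numeric feature columns
    meta: pd.DataFrame                # image_id, object_id, area, excluded...
    means: Optional[pd.Series] = None
    sds: Optional[pd.Series] = None

    @property
    def standardized(self) -> bool:
        return self.means is not None

    def __len__(self) -> int:
        return len(self.features)


def compute_frame_features(objects: Sequence[StructureObject],
                           frame: ImageFrame, image_id: str = "image_0",
                           n_shape_modes: int = 30, n_dist_modes: int = 30,
                           n_boundary_points: int = 128,
                           boundary_err_max: float = 0.1) -> FeatureMatrix:
    """All 74 measures for every object of one frame.

    ``frame`` is the image the objects were segmented on (the
    background-subtracted frame by default), used for the intensity
    statistics.
    """
    shape = frame.pixels.shape
    rows, meta_rows = [], []
    for i, obj in enumerate(objects):
        dist_map, lone = neighbor_distance_map(objects, i, shape)
        rec = region_features(obj)
        rec.update(neighbor_distance_features(obj, objects, shape,
                                              dist_map=dist_map))
        shape_amps, err = fourier_shape_features(
            obj.boundary, n_shape_modes, n_boundary_points)
        rec.update(dict(zip(shape_feature_names(n_shape_modes), shape_amps)))
        pts = resample_boundary(obj.boundary, n_boundary_points)
        profile = ndimage.map_coordinates(dist_map, [pts[:, 0], pts[:, 1]],
                                          order=1, mode="nearest")
        dist_amps = fourier_distance_features(profile, n_dist_modes)
        rec.update(dict(zip(dist_feature_names(n_dist_modes), dist_amps)))
        rows.append(rec)
        meta_rows.append({
            "image_id": image_id, "object_id": obj.object_id,
            "area": obj.area, "boundary_err": err,
            "excluded": err > boundary_err_max, "lone": lone,
            "centroid_row": obj.centroid[0], "centroid_col": obj.centroid[1],
        })
    cols = feature_names(n_shape_modes, n_dist_modes)
    features = pd.DataFrame(rows, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=[
        "image_id", "object_id", "area", "boundary_err", "excluded", "lone",
        "centroid_row", "centroid_col"])
    return FeatureMatrix(features=features, meta=meta)


def concat_feature_matrices(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    feats = pd.concat([p.features for p in parts], ignore_index=True)
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return FeatureMatrix(features=feats, meta=meta)


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scoring; zero-variance columns are dropped.

    The scaling parameters are stored on the result so held-out objects
    can be projected with :func:`apply_standardization`.
    """
    if len(fm) < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = fm.features.mean()
    sds = fm.features.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        logger.warning("dropping %d zero-variance feature columns: %s",
                       len(constant), constant[:5])
    keep = sds[sds > 0].index
    z = (fm.features[keep] - means[keep]) / sds[keep]
    return FeatureMatrix(features=z, meta=fm.meta.copy(),
                         means=means[keep], sds=sds[keep])


def apply_standardization(fm: FeatureMatrix, means: pd.Series,
                          sds: pd.Series) -> FeatureMatrix:
    """Apply previously fit scaling parameters to another matrix."""
    z = (fm.features[means.index] - means) / sds
    return FeatureMatrix(features=z, meta=fm.meta.copy(),
                         means=means, sds=sds)
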
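"""Clustering of structures into morphology classes.

The standardized feature matrix is reduced with PCA to the smallest
number of components explaining 90% of the variance, clustered with
DBSCAN (eps = 2, min_pts = 3 by default; points unreachable from any
core are noise, label -1), optionally refined by splitting large-object
classes along their most bimodal principal component, and finally merged
into a small number of interpretable classes (three by default:
dots/small clusters, fragments, and filaments/aggregates for septin or
rings for Cdc42ep1).  Images are summarized by the area fraction of each
merged class: the total area of its objects divided by the total area of
all classified objects in the image.

The bimodality screen uses the sample bimodality coefficient
``b = (skewness^2 + 1) / kurtosis`` with the 5/9 cutoff (a Gaussian has
b = 1/3; a balanced two-point mixture approaches 1).  The split itself
uses a two-component Gaussian mixture for the two most populated
candidate classes and Otsu thresholding of the PC values for the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors
from skimage.filters import threshold_otsu

logger = logging.getLogger("filamorph.classify")

NOISE = -1
BIMODALITY_CUTOFF = 5.0 / 9.0
MIN_SPLIT_MEMBERS = 6


@dataclass
class PcaBasis:
    """Principal-component basis kept to reach the variance target."""

    components: np.ndarray            # (n_kept, n_features)
    explained_variance_ratio: np.ndarray   # all components, non-increasing
    n_kept: int
    mean: np.ndarray = field(default=None, repr=False)


@dataclass
class ClassProfile:
    """Per-image area fractions over merged classes.

    ``fractions`` sums to 1 over classified objects; ``noise_fraction``
    is the area share of unclassified (DBSCAN noise) objects in the
    total object area, reported separately.  ``defined`` is False for
    images without a single classified object.
    """

    image_id: str
    fractions: Dict[int, float]
    noise_fraction: float
    defined: bool = True


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, var_target: float = 0.90,
            ) -> Tuple[PcaBasis, np.ndarray]:
    """Fit PCA and keep the smallest basis reaching ``var_target``.

    Returns the basis and the projections of all rows onto the kept
    components.
    """
    if not (0.0 < var_target <= 1.0):
        raise ValueError("var_target must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    pca = PCA(svd_solver="full")
    Z = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    # ignore numerically void trailing components when var_target == 1
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * max(
        pca.explained_variance_[0], 1.0)))
    n_kept = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    n_kept = min(max(n_kept, 1), rank)
    basis = PcaBasis(components=pca.components_[:n_kept],
                     explained_variance_ratio=evr, n_kept=n_kept,
                     mean=pca.mean_)
    return basis, Z[:, :n_kept]


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

def estimate_eps(Z: np.ndarray, min_pts: int = 3) -> float:
    """k-distance heuristic for the DBSCAN radius.

    Takes the distance of every point to its ``min_pts``-th nearest
    neighbor (self included), sorts the curve, and returns the value at
    its knee (the point of maximum distance to the chord joining the
    curve's endpoints).  Deterministic.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = Z.shape[0]
    k = min(min_pts, n)
    nn = NearestNeighbors(n_neighbors=k).fit(Z)
    kdist = np.sort(nn.kneighbors(Z)[0][:, -1])
    if kdist[-1] == kdist[0]:
        return float(max(kdist[-1], 1e-12))
    x = np.arange(n, dtype=float)
    # distance from each curve point to the endpoint chord
    dx, dy = n - 1.0, kdist[-1] - kdist[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * x - dx * (kdist - kdist[0])) / norm
    knee = int(np.argmax(dist))
    return float(max(kdist[knee], 1e-12))


def cluster_dbscan(Z: np.ndarray, eps: Union[float, str] = 2.0,
                   min_pts: int = 3) -> np.ndarray:
    """Standard DBSCAN in the projected feature space.

    A core point has at least ``min_pts`` neighbors within ``eps``
    (itself included); clusters are the density-reachable sets; points
    unreachable from any core are labeled -1.  ``eps='auto'`` uses
    :func:`estimate_eps`.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if isinstance(eps, str):
        if eps != "auto":
            raise ValueError("eps must be positive or 'auto'")
        eps = estimate_eps(Z, min_pts)
        logger.info("estimated DBSCAN eps = %.3f", eps)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(Z)


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def bimodality_coefficient(x: np.ndarray) -> float:
    """Sample bimodality coefficient ``(skewness^2 + 1) / kurtosis``.

    Kurtosis is the non-excess (Pearson) moment ratio ``m4 / m2^2``, so
    a Gaussian scores 1/3; values above 5/9 suggest bimodality.
    """
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    skew = m3 / m2 ** 1.5
    kurt = m4 / m2 ** 2
    return float((skew ** 2 + 1.0) / kurt)


def refine_classes(labels: np.ndarray, Z: np.ndarray, areas: np.ndarray,
                   refine_top_k: int = 5, seed: int = 0,
                   bimod_cutoff: float = BIMODALITY_CUTOFF) -> np.ndarray:
    """Split large-object classes along their most bimodal PC.

    The ``refine_top_k`` classes with the largest mean object area are
    screened; for each, the principal component with the largest
    bimodality coefficient is selected.  Classes whose best coefficient
    stays below the cutoff, or with fewer than 6 members, are left
    intact.  Of the eligible classes, the two most populated are split
    with a two-component Gaussian mixture on that PC (10 restarts, fixed
    seed); the remainder are split at the Otsu threshold of the PC
    values.
    """
    labels = np.asarray(labels).copy()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    areas = np.asarray(areas, dtype=float)

    classes = [c for c in np.unique(labels) if c != NOISE]
    if not classes:
        return labels
    mean_area = {c: areas[labels == c].mean() for c in classes}
    candidates = sorted(classes, key=lambda c: -mean_area[c])[:refine_top_k]

    eligible = []  # (class, pc_index, bimodality)
    for c in candidates:
        idx = np.nonzero(labels == c)[0]
        if idx.size < MIN_SPLIT_MEMBERS:
            continue
        bs = [bimodality_coefficient(Z[idx, j]) for j in range(Z.shape[1])]
        j_best = int(np.argmax(bs))
        if bs[j_best] > bimod_cutoff:
            eligible.append((c, j_best, bs[j_best]))

    if not eligible:
        return labels
    # the two most populated eligible classes get the GMM split
    by_pop = sorted(eligible, key=lambda t: -(labels == t[0]).sum())
    gmm_classes = {t[0] for t in by_pop[:2]}

    next_label = max(classes) + 1
    for c, j, b in eligible:
        idx = np.nonzero(labels == c)[0]
        x = Z[idx, j][:, None]
        if c in gmm_classes:
            gmm = GaussianMixture(n_components=2, n_init=10,
                                  random_state=seed)
            comp = gmm.fit_predict(x)
        else:
            thr = threshold_otsu(x.ravel(), nbins=256)
            comp = (x.ravel() > thr).astype(int)
        if len(np.unique(comp)) < 2:
            continue
        labels[idx[comp == 1]] = next_label
        logger.info("refined class %d along PC%d (b=%.3f) -> %d/%d",
                    c, j + 1, b, (comp == 0).sum(), (comp == 1).sum())
        next_label += 1
    return labels


# ---------------------------------------------------------------------------
# merging and area fractions
# ---------------------------------------------------------------------------

def fine_fraction_matrix(image_ids: Sequence, labels: np.ndarray,
                         areas: np.ndarray) -> pd.DataFrame:
    """Images x fine-classes matrix of per-image area fractions."""
    df = pd.DataFrame({"image_id": list(image_ids),
                       "label": np.asarray(labels),
                       "area": np.asarray(areas, dtype=float)})
    df = df[df["label"] != NOISE]
    mat = df.pivot_table(index="image_id", columns="label", values="area",
                         aggfunc="sum", fill_value=0.0)
    totals = mat.sum(axis=1)
    return mat.div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)


def merge_classes(fractions: pd.DataFrame, merged_k: int = 3,
                  ) -> Dict[int, int]:
    """Group fine classes by co-alignment of their area-fraction loadings.

    PCA is fit on the images x fine-classes area-fraction matrix; each
    fine class is represented by its loading vector over the leading
    components (two for the default three merged classes; in general
    ``max(2, merged_k - 1)``, the dimensionality needed to resolve
    ``merged_k`` mixture directions), normalized to unit length.  The
    unit vectors are grouped into ``merged_k`` clusters by
    average-linkage hierarchical clustering on cosine distance.
    Returns the fine -> merged mapping (merged ids are 0..merged_k-1).
    """
    fine = list(fractions.columns)
    if len(fractions) < 3:
        raise ValueError("class merging needs at least 3 images")
    if len(fine) <= merged_k:
        logger.warning("only %d fine classes for merged_k=%d: identity "
                       "mapping", len(fine), merged_k)
        return {c: i for i, c in enumerate(fine)}
    n_load = min(max(2, merged_k - 1), len(fractions) - 1, len(fine))
    pca = PCA(n_components=n_load, svd_solver="full")
    pca.fit(fractions.to_numpy())
    load = pca.components_.T                      # (n_fine, n_load)
    norms = np.linalg.norm(load, axis=1)
    unit = load / np.where(norms > 0, norms, 1.0)[:, None]

    # fine classes carrying a trivial area share have unstable loading
    # directions; cluster the substantial classes and attach the minor
    # ones to the nearest group afterwards
    share = fractions.mean(axis=0).to_numpy()
    major = share >= 0.01
    if major.sum() < merged_k:
        major = np.ones(len(fine), dtype=bool)
    d = pdist(unit[major], metric="cosine")
    if major.sum() == merged_k:
        groups_major = np.arange(1, merged_k + 1)
    else:
        groups_major = fcluster(linkage(d, method="average"), t=merged_k,
                                criterion="maxclust")
    mapping: Dict[int, int] = {}
    major_idx = np.nonzero(major)[0]
    for j, g in zip(major_idx, groups_major):
        mapping[fine[j]] = int(g - 1)
    centroids = np.array([
        unit[major_idx[groups_major == g]].mean(axis=0)
        for g in range(1, merged_k + 1)])
    cn = np.linalg.norm(centroids, axis=1)
    centroids = centroids / np.where(cn > 0, cn, 1.0)[:, None]
    for j in np.nonzero(~major)[0]:
        sims = centroids @ unit[j]
        mapping[fine[j]] = int(np.argmax(sims))
    return mapping


def apply_merge(labels: np.ndarray, mapping: Dict[int, int]) -> np.ndarray:
    """Map fine labels to merged labels; noise stays -1."""
    out = np.full(len(labels), NOISE, dtype=int)
    for i, lab in enumerate(labels):
        if lab != NOISE:
            out[i] = mapping[lab]
    return out


def name_merged_classes(merged_labels: np.ndarray, areas: np.ndarray,
                        eccentricities: np.ndarray,
                        channel: str = "septin") -> Dict[int, str]:
    """Advisory names for merged classes, ranked by mean object area.

    Smallest objects are dots/small clusters, intermediate are
    fragments, and the largest are filaments/aggregates (septin) or
    rings (cdc42ep1).  Purely metadata; never used in computation.
    """
    large = "filaments_aggregates" if channel != "cdc42ep1" else "rings"
    order = ["dots_small_clusters", "fragments", large]
    classes = [c for c in np.unique(merged_labels) if c != NOISE]
    ranked = sorted(classes,
                    key=lambda c: areas[merged_labels == c].mean())
    names = {}
    for i, c in enumerate(ranked):
        names[c] = order[i] if i < len(order) else f"class_{c}"
    return names


def area_fractions(merged_labels: np.ndarray, areas: np.ndarray,
                   image_ids: Sequence, ) -> Dict[str, ClassProfile]:
    """Per-image area fraction of every merged class.

    Fractions are computed over classified objects only and sum to 1;
    the area share of noise objects is reported separately.  Images with
    no classified object yield an undefined (flagged) profile.
    """
    merged_labels = np.asarray(merged_labels)
    areas = np.asarray(areas, dtype=float)
    image_ids = np.asarray(list(image_ids))
    all_classes = sorted(c for c in np.unique(merged_labels) if c != NOISE)
    profiles: Dict[str, ClassProfile] = {}
    for img in pd.unique(image_ids):
        sel = image_ids == img
        lab = merged_labels[sel]
        ar = areas[sel]
        classified = lab != NOISE
        total_all = ar.sum()
        total_cls = ar[classified].sum()
        if total_cls == 0:
            logger.warning("image %s has no classified objects", img)
            profiles[str(img)] = ClassProfile(
                image_id=str(img),
                fractions={c: float("nan") for c in all_classes},
                noise_fraction=1.0 if total_all > 0 else float("nan"),
                defined=False)
            continue
        fr = {c: float(ar[(lab == c)].sum() / total_cls)
              for c in all_classes}
        noise_fr = float(ar[~classified].sum() / total_all)
        profiles[str(img)] = ClassProfile(image_id=str(img), fractions=fr,
                                          noise_fraction=noise_fr)
    return profiles
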
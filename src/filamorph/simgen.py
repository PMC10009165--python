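"""Synthetic microscopy with ground truth.

Real inputs to the pipeline are 16-bit live-cell frames of septin or
Cdc42ep1 markers; none are bundled, so this module generates look-alike
scenes with known object labels and classes, plus persistent-random-walk
trajectories, shortening-fiber time series, and image pairs with a
prescribed pixel correlation.  Every generator is a pure function of its
parameters and seed.

A scene is a single cell — a smooth bright ellipse whose interior offset
falls in the 12,000-24,000 count range where cell thresholds are chosen
manually — over a dimmer exterior, with a weak linear intensity gradient.
Five structure classes are drawn inside it: dots (small disks), fragments
(short straight rods), filaments (smoothed random-walk polylines dilated
to 2-3 px), rings (annuli with outer diameters 0.49-1.35 µm, the span
reported for Cdc42ep1 rings under septin inhibition), and aggregates
(blobby unions of disks).  The image model is Poisson shot noise on the
expected counts followed by additive Gaussian read noise, clipped and
quantized to 16 bits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.morphology import disk

from .dynamics import FiberTrace, Trajectory

CLASSES = ("dot", "fragment", "filament", "ring", "aggregate")

#: drawing order: large objects first to ease placement
_PLACE_ORDER = ("aggregate", "filament", "ring", "fragment", "dot")


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed without excessive overlap."""


@dataclass
class SceneParams:
    """Geometry, intensity and noise model of a synthetic scene.

    Lengths are in pixels unless suffixed ``_um``.  ``background_offset``
    of ``None`` draws the cell-interior offset uniformly from
    [12,000, 24,000] per scene.
    """

    image_size: Tuple[int, int] = (512, 512)
    pixel_size: float = 0.1                     # µm / px
    counts: Dict[str, int] = field(default_factory=lambda: {
        "dot": 40, "fragment": 20, "filament": 8, "ring": 6, "aggregate": 4})
    foreground_intensity: float = 8000.0        # counts above background
    intensity_jitter: float = 0.10              # per-object uniform factor
    outside_level: float = 4000.0
    background_offset: Optional[float] = None   # cell interior offset
    background_offset_range: Tuple[float, float] = (12000.0, 24000.0)
    background_gradient: float = 4.0            # counts / px, random direction
    cell_axes_frac: Tuple[float, float] = (0.42, 0.42)
    cell_edge_sigma: float = 6.0                # px, softens the cell edge
    noise_gain: float = 2.0                     # counts per photon
    read_noise_sd: float = 50.0                 # counts
    # class geometry ranges
    dot_radius: Tuple[float, float] = (2.0, 2.6)
    fragment_length: Tuple[float, float] = (6.0, 10.0)
    filament_length: Tuple[float, float] = (14.0, 18.0)
    filament_curvature: float = 0.0            # rad / px heading diffusion
    ring_diameter_um: Tuple[float, float] = (0.49, 1.35)
    ring_thickness: float = 2.0
    aggregate_radius: Tuple[float, float] = (4.0, 7.0)
    # class-dependent brightness: thicker assemblies are brighter
    intensity_factors: Dict[str, float] = field(default_factory=lambda: {
        "dot": 0.8, "fragment": 0.9, "filament": 1.0, "ring": 0.95,
        "aggregate": 1.3})
    # spatial organization: filaments form parallel bundles, fragments and
    # rings sit in regularly spaced arrays, dots and aggregates scatter —
    # mirrors the organization seen in cells and gives the
    # neighbor-distance features class structure
    class_layout: Dict[str, Tuple[str, float]] = field(
        default_factory=lambda: {
            "dot": ("scatter", 0.0),
            "aggregate": ("scatter", 0.0),
            "fragment": ("grid", 11.0),              # lattice spacing px
            "ring": ("grid", 20.0),
            "filament": ("bundle", 8.0)})            # perpendicular spacing
    # radial zones (fractions of the cell radius): filaments and
    # aggregates sit at the cell center, rings and fragments at
    # intermediate radii, dots toward the periphery — the organization
    # described for septin/Cdc42ep1 structures in migrating cells
    class_zone: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "filament": (0.0, 0.40), "aggregate": (0.0, 0.50),
            "ring": (0.35, 0.70), "fragment": (0.50, 0.85),
            "dot": (0.65, 1.0)})
    # shared orientation (radians) of elongated structures and lattices;
    # stress-fiber-aligned septin arrays keep a persistent orientation,
    # and fragments inherit it.  None draws orientations at random.
    structure_orientation: Optional[float] = 0.6
    orientation_jitter: float = 0.0             # rad, per object
    # number of characteristic sizes per class (0 = continuous range);
    # ground-truth classes are built from distinct morphology prototypes,
    # the way assembly intermediates occur at characteristic sizes
    geometry_levels: Dict[str, int] = field(default_factory=lambda: {
        "dot": 3, "fragment": 3, "filament": 1, "ring": 5, "aggregate": 0})
    min_separation: int = 2                     # px kept free around objects
    max_place_tries: int = 100

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for cls, n in self.counts.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.ring_diameter_um[0] > self.ring_diameter_um[1]:
            raise ValueError("ring_diameter_um must be ordered")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class SyntheticScene:
    """Generated image with ground-truth labels, classes and geometry."""

    image: np.ndarray                 # uint16
    truth_labels: np.ndarray          # int32, 0 = background
    truth_classes: Dict[int, str]
    truth_geometry: Dict[int, Dict[str, float]]
    cell_mask: np.ndarray             # bool, the generating cell ellipse
    params: SceneParams
    seed: int

    @property
    def suggested_cell_threshold(self) -> float:
        """Midpoint between exterior level and cell-interior offset."""
        offset = self.truth_geometry.get(0, {}).get("background_offset")
        return 0.5 * (self.params.outside_level + offset)

    def class_area_fractions(self) -> Dict[str, float]:
        """Ground-truth area fraction of each class present."""
        areas: Dict[str, float] = {}
        for oid, cls in self.truth_classes.items():
            areas[cls] = areas.get(cls, 0.0) + (self.truth_labels == oid).sum()
        total = sum(areas.values())
        return {c: a / total for c, a in areas.items()} if total else {}


# ---------------------------------------------------------------------------
# structure scenes
# ---------------------------------------------------------------------------

def _sample_geom(rng: np.random.Generator, lo: float, hi: float,
                 levels: int) -> float:
    """Draw a size: uniform in [lo, hi], or one of `levels` prototypes."""
    if levels and levels > 0:
        if levels == 1:
            return 0.5 * (lo + hi)
        return float(rng.choice(np.linspace(lo, hi, levels)))
    return float(rng.uniform(lo, hi))


def _draw_dot(rng: np.random.Generator, p: SceneParams):
    r = _sample_geom(rng, *p.dot_radius, p.geometry_levels.get("dot", 0))
    n = int(np.ceil(r)) + 1
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return (yy ** 2 + xx ** 2 <= r ** 2), {"radius_px": r}


def _draw_fragment(rng: np.random.Generator, p: SceneParams):
    L = _sample_geom(rng, *p.fragment_length,
                     p.geometry_levels.get("fragment", 0))
    if p.structure_orientation is None:
        theta = rng.uniform(0, np.pi)
    else:
        theta = p.structure_orientation + rng.normal(0, p.orientation_jitter)
    t = np.linspace(-L / 2, L / 2, int(4 * L) + 2)
    rr = t * np.sin(theta)
    cc = t * np.cos(theta)
    return _rasterize(rr, cc, dilate=1), {"length_px": L}


def _draw_filament(rng: np.random.Generator, p: SceneParams,
                   heading: Optional[float] = None):
    L = _sample_geom(rng, *p.filament_length,
                     p.geometry_levels.get("filament", 0))
    n = int(L)
    if heading is None:
        heading = rng.uniform(0, 2 * np.pi)
    steps = rng.normal(0, p.filament_curvature, n)
    angles = heading + np.cumsum(steps)
    rr = np.concatenate([[0.0], np.cumsum(np.sin(angles))])
    cc = np.concatenate([[0.0], np.cumsum(np.cos(angles))])
    # light smoothing so the polyline is gently curved, not jagged
    rr = ndimage.uniform_filter1d(rr, 5, mode="nearest")
    cc = ndimage.uniform_filter1d(cc, 5, mode="nearest")
    fine = np.linspace(0, n, 4 * n)
    rr = np.interp(fine, np.arange(n + 1), rr)
    cc = np.interp(fine, np.arange(n + 1), cc)
    return _rasterize(rr, cc, dilate=1), {"length_px": L}


def _draw_ring(rng: np.random.Generator, p: SceneParams):
    d_um = _sample_geom(rng, *p.ring_diameter_um,
                        p.geometry_levels.get("ring", 0))
    r_out = d_um / 2.0 / p.pixel_size
    r_in = max(r_out - p.ring_thickness, 0.6)
    n = int(np.ceil(r_out)) + 1
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    d2 = yy ** 2 + xx ** 2
    return ((d2 <= r_out ** 2) & (d2 > r_in ** 2)), {"diameter_um": d_um}


def _draw_aggregate(rng: np.random.Generator, p: SceneParams):
    R = rng.uniform(*p.aggregate_radius)
    n = int(np.ceil(2 * R)) + 2
    m = np.zeros((2 * n + 1, 2 * n + 1), dtype=bool)
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    n_lobes = rng.integers(3, 6)
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, R * 0.55)
        cy, cx = rad * np.sin(ang), rad * np.cos(ang)
        rl = rng.uniform(0.45, 0.7) * R
        m |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= rl ** 2
    m = ndimage.binary_fill_holes(m)
    lab, nlab = ndimage.label(m, structure=np.ones((3, 3)))
    if nlab > 1:  # keep the lobe union containing the centre
        keep = lab[n, n] if lab[n, n] else np.argmax(np.bincount(
            lab.ravel())[1:]) + 1
        m = lab == keep
    return m, {"radius_px": R}


def _rasterize(rr: np.ndarray, cc: np.ndarray, dilate: int = 1) -> np.ndarray:
    rr = rr - rr.min()
    cc = cc - cc.min()
    h = int(np.ceil(rr.max())) + 2 * dilate + 1
    w = int(np.ceil(cc.max())) + 2 * dilate + 1
    m = np.zeros((h, w), dtype=bool)
    m[np.round(rr).astype(int) + dilate, np.round(cc).astype(int) + dilate] = True
    if dilate:
        m = ndimage.binary_dilation(m, structure=disk(dilate))
    return m


_DRAWERS = {"dot": _draw_dot, "fragment": _draw_fragment,
            "filament": _draw_filament, "ring": _draw_ring,
            "aggregate": _draw_aggregate}


def _class_positions(rng: np.random.Generator, mode: str, spacing: float,
                     n: int, interior: np.ndarray, int_rows: np.ndarray,
                     int_cols: np.ndarray,
                     orientation: Optional[float] = None):
    """Candidate centers for one class: scatter, hex lattice or bundle."""
    if mode == "scatter" or n == 0:
        return None, None
    # anchor: a random interior point biased toward the interior centroid
    k = rng.integers(int_rows.size)
    anchor = np.array([0.7 * int_rows.mean() + 0.3 * int_rows[k],
                       0.7 * int_cols.mean() + 0.3 * int_cols[k]])
    theta = rng.uniform(0, 2 * np.pi) if orientation is None else orientation
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    if mode == "grid":
        m = int(np.ceil(np.sqrt(3.0 * n))) + 2
        offs = []
        for j in range(-m, m + 1):
            for i in range(-m, m + 1):
                offs.append([spacing * (i + 0.5 * (j % 2)),
                             spacing * 0.866 * j])
        offs = np.asarray(offs)
        offs = offs[np.argsort(np.hypot(offs[:, 0], offs[:, 1]))]
        pts = anchor + offs @ rot.T + rng.normal(0, 0.5, offs.shape)
        heading = None
    elif mode == "bundle":
        heading = theta
        perp = np.array([-np.sin(theta), np.cos(theta)])
        ks = np.arange(-2 * n, 2 * n + 1)
        ks = ks[np.argsort(np.abs(ks))]
        # rigid array: members sit at exact multiples of the spacing
        pts = anchor[None, :] + spacing * ks[:, None] * perp[None, :]
    else:
        raise ValueError(f"unknown layout mode {mode!r}")
    pts = np.round(pts).astype(int)
    ok = ((pts[:, 0] >= 0) & (pts[:, 0] < interior.shape[0])
          & (pts[:, 1] >= 0) & (pts[:, 1] < interior.shape[1]))
    pts = pts[ok]
    pts = pts[interior[pts[:, 0], pts[:, 1]]]
    return [tuple(p) for p in pts], heading


def gen_structure_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Generate one synthetic scene with ground truth.

    Objects are drawn class by class (largest classes first), placed
    uniformly inside the cell ellipse with up to ``max_place_tries``
    retries so that labels stay disjoint with ``min_separation`` px of
    clearance; a class that cannot be placed raises
    :class:`PlacementError`.  Background and noise are applied after
    the geometry, and the image is quantized to 16 bits.
    """
    rng = np.random.default_rng(seed)
    h, w = params.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)

    # cell ellipse
    yy, xx = np.mgrid[0:h, 0:w]
    ay = params.cell_axes_frac[0] * h
    ax = params.cell_axes_frac[1] * w
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rho2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    cell = rho2 <= 1.0
    interior = ndimage.binary_erosion(cell, iterations=10)
    int_rows, int_cols = np.nonzero(interior)

    truth_classes: Dict[int, str] = {}
    truth_geometry: Dict[int, Dict[str, float]] = {}
    oid = 0
    for cls in _PLACE_ORDER:
        n_cls = params.counts.get(cls, 0)
        if not n_cls:
            continue
        mode, spacing = params.class_layout.get(cls, ("scatter", 0.0))
        lo, hi = params.class_zone.get(cls, (0.0, 1.0))
        band = interior & (rho2 >= lo ** 2) & (rho2 <= hi ** 2)
        band_rows, band_cols = np.nonzero(band)
        if band_rows.size == 0:
            band, band_rows, band_cols = interior, int_rows, int_cols
        positions, bundle_heading = _class_positions(
            rng, mode, spacing, n_cls, band, band_rows, band_cols,
            orientation=params.structure_orientation)
        pos_iter = iter(range(len(positions))) if positions is not None \
            else None
        # pre-draw the class's masks; lattice classes are placed in size
        # order (largest nearest the lattice center) so that every size
        # prototype sees a reproducible neighborhood
        draws = []
        for _ in range(n_cls):
            if cls == "filament" and bundle_heading is not None:
                draws.append(_draw_filament(
                    rng, params,
                    heading=bundle_heading
                    + rng.normal(0, params.orientation_jitter)))
            else:
                draws.append(_DRAWERS[cls](rng, params))
        if mode == "grid":
            draws.sort(key=lambda t: -int(t[0].sum()))
        for m, geom in draws:
            oid += 1
            placed = False
            for _try in range(params.max_place_tries):
                mh, mw = m.shape
                if positions is None:
                    k = rng.integers(band_rows.size)
                    ctr = band_rows[k], band_cols[k]
                else:
                    try:
                        ctr = positions[next(pos_iter)]
                    except StopIteration:
                        k = rng.integers(band_rows.size)
                        ctr = band_rows[k], band_cols[k]
                    if not (0 <= ctr[0] < h and 0 <= ctr[1] < w
                            and interior[ctr[0], ctr[1]]):
                        continue
                r0 = int(ctr[0]) - mh // 2
                c0 = int(ctr[1]) - mw // 2
                if r0 < 1 or c0 < 1 or r0 + mh > h - 1 or c0 + mw > w - 1:
                    continue
                pad = params.min_separation
                grown = (ndimage.binary_dilation(m, structure=disk(pad))
                         if pad else m)
                rr, cc = np.nonzero(grown)
                rr = rr + r0 - pad
                cc = cc + c0 - pad
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                if occupied[rr[ok], cc[ok]].any():
                    continue
                mr, mc = np.nonzero(m)
                labels[mr + r0, mc + c0] = oid
                occupied[mr + r0, mc + c0] = True
                truth_classes[oid] = cls
                truth_geometry[oid] = geom
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {cls!r} object after "
                    f"{params.max_place_tries} tries")

    # intensity model
    offset = (params.background_offset if params.background_offset is not None
              else rng.uniform(*params.background_offset_range))
    gdir = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(gdir) * (xx - cx) + np.sin(gdir) * (yy - cy))
    bg = params.outside_level + (offset - params.outside_level) * \
        ndimage.gaussian_filter(cell.astype(float), params.cell_edge_sigma)
    bg = bg + params.background_gradient * ramp * cell
    signal = np.zeros((h, w))
    for o in range(1, oid + 1):
        factor = params.intensity_factors.get(truth_classes[o], 1.0) * (
            1.0 + rng.uniform(-params.intensity_jitter,
                              params.intensity_jitter))
        signal[labels == o] = params.foreground_intensity * factor
    expected = np.clip(bg + signal, 0.0, None)

    gain = params.noise_gain
    img = (gain * rng.poisson(expected / gain) if gain > 0
           else expected.copy())                  # gain 0: noise-free
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, (h, w))
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth_geometry[0] = {"background_offset": float(offset)}
    return SyntheticScene(image=img, truth_labels=labels,
                          truth_classes=truth_classes,
                          truth_geometry=truth_geometry, cell_mask=cell,
                          params=params, seed=seed)


def gen_channel_batch(channel: str, n_scenes: int = 5, seed: int = 0,
                      n_objects: int = 90,
                      image_size: Tuple[int, int] = (440, 440),
                      ) -> List[SyntheticScene]:
    """A batch of scenes emulating one imaging channel.

    Septin-like scenes contain dots, fragments and filaments;
    Cdc42ep1-like scenes contain dots, fragments and rings — the two
    three-class vocabularies the pipeline merges down to.  Mixture
    proportions vary scene to scene (Dirichlet(3) draws), which is what
    makes class merging by area-fraction co-alignment identifiable.
    """
    if channel == "septin":
        classes = ("dot", "fragment", "filament")
    elif channel == "cdc42ep1":
        classes = ("dot", "fragment", "ring")
    else:
        raise ValueError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_scenes):
        mix = rng.dirichlet([3.0] * len(classes))
        counts = {}
        for c, m in zip(classes, mix):
            if c == "filament":           # long objects: fewer per area
                counts[c] = max(int(m * n_objects / 3), 2) + 2
            else:
                counts[c] = int(m * n_objects) + 3
        params = SceneParams(image_size=image_size, counts=counts)
        scenes.append(gen_structure_scene(params, seed + i))
    return scenes


def truth_majority_class(scene: SyntheticScene,
                         pixels: np.ndarray) -> str:
    """Ground-truth class under a segmented pixel set (majority vote)."""
    labs = scene.truth_labels[pixels[:, 0], pixels[:, 1]]
    labs = labs[labs > 0]
    if labs.size == 0:
        return "none"
    return scene.truth_classes.get(int(np.bincount(labs).argmax()), "none")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class WalkParams:
    """Persistent-random-walk ensemble parameters.

    ``persistence`` in [0, 1] scales the heading-noise support:
    1 gives perfectly straight motion, 0 uncorrelated step directions.
    ``group_bias_direction`` (radians) adds a shared pull toward one
    direction, emulating the collective drift of an explant.
    Defaults match nuclear-tracking movies: 5-min frames for 4 h
    (49 frames) at the control speed of 0.90 µm/min.
    """

    n_cells: int = 100
    n_frames: int = 49
    dt: float = 5.0                   # minutes / frame
    mean_speed: float = 0.90          # µm / min
    persistence: float = 0.5
    group_bias_direction: Optional[float] = None
    field_size: float = 400.0         # µm, initial-position spread
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")


def gen_trajectories(params: WalkParams) -> List[Trajectory]:
    """Simulate persistent random walks.

    Step lengths are Gamma-distributed (shape 4) with mean
    ``mean_speed * dt``; heading increments are uniform on
    ``[-pi*(1-persistence), +pi*(1-persistence)]``.
    """
    rng = np.random.default_rng(params.seed)
    mean_step = params.mean_speed * params.dt
    out: List[Trajectory] = []
    for tid in range(params.n_cells):
        x = np.empty(params.n_frames)
        y = np.empty(params.n_frames)
        x[0], y[0] = rng.uniform(0, params.field_size, 2)
        if params.group_bias_direction is not None:
            theta = params.group_bias_direction + \
                (1 - params.persistence) * rng.uniform(-np.pi, np.pi)
        else:
            theta = rng.uniform(-np.pi, np.pi)
        half = np.pi * (1.0 - params.persistence)
        for i in range(1, params.n_frames):
            if i > 1:
                theta += rng.uniform(-half, half)
                if params.group_bias_direction is not None:
                    delta = np.angle(np.exp(
                        1j * (params.group_bias_direction - theta)))
                    theta += 0.5 * delta
            step = (rng.gamma(4.0, mean_step / 4.0)
                    if mean_step > 0 else 0.0)
            x[i] = x[i - 1] + step * np.cos(theta)
            y[i] = y[i - 1] + step * np.sin(theta)
        frames = np.arange(params.n_frames)
        out.append(Trajectory(track_id=tid, frames=frames,
                              t_min=frames * params.dt, x_um=x, y_um=y))
    return out


# ---------------------------------------------------------------------------
# fibers and colocalization pairs
# ---------------------------------------------------------------------------

def gen_fiber_series(l0: float, shortening_rate: float, n_frames: int,
                     dt: float = 5.0, noise_sd: float = 0.0,
                     seed: int = 0, fiber_id: int = 0) -> FiberTrace:
    """Linear fiber shortening with additive measurement noise.

    ``length(t) = max(0, l0 - rate * t) + noise`` with ``t`` in seconds
    (``dt`` seconds per frame; 5-s frames over a 5-min movie by default).
    """
    if l0 <= 0:
        raise ValueError("l0 must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    L = np.clip(l0 - shortening_rate * t, 0.0, None)
    if noise_sd > 0:
        L = L + rng.normal(0.0, noise_sd, n_frames)
    return FiberTrace(fiber_id=fiber_id, t_s=t, length_um=L)


def gen_coloc_pair(size: Tuple[int, int], rho: float, seed: int = 0,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Two images whose population pixel correlation is ``rho``.

    Jointly Gaussian pixels, rescaled to the 16-bit range (mean 32768,
    sd 6000, clipped); ``rho = 1`` makes the second image an exact
    affine transform of the first.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(size)
    b = rho * a + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(size)
    to16 = lambda x: np.clip(32768.0 + 6000.0 * x, 0.0, 65535.0)
    return to16(a), to16(b)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, out_dir) -> None:
    """Write image.tif, labels.tif, truth.csv and params.yaml."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    tifffile.imwrite(os.path.join(out_dir, "image.tif"), scene.image)
    tifffile.imwrite(os.path.join(out_dir, "labels.tif"),
                     scene.truth_labels.astype(np.int32))
    rows = []
    for oid, cls in sorted(scene.truth_classes.items()):
        rr, cc = np.nonzero(scene.truth_labels == oid)
        rows.append({"object_id": oid, "class": cls,
                     "centroid_x": cc.mean(), "centroid_y": rr.mean(),
                     "area_px": rr.size})
    pd.DataFrame(rows, columns=["object_id", "class", "centroid_x",
                                "centroid_y", "area_px"]).to_csv(
        os.path.join(out_dir, "truth.csv"), index=False)
    doc = scene.params.to_dict()
    doc["seed"] = scene.seed
    with open(os.path.join(out_dir, "params.yaml"), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trajectories(tracks: Sequence[Trajectory], path) -> None:
    """Tracks as CSV: track_id, frame, t_min, x_um, y_um."""
    rows = []
    for t in tracks:
        for f, tm, x, y in zip(t.frames, t.t_min, t.x_um, t.y_um):
            rows.append({"track_id": t.track_id, "frame": int(f),
                         "t_min": float(tm), "x_um": float(x),
                         "y_um": float(y)})
    pd.DataFrame(rows, columns=["track_id", "frame", "t_min", "x_um",
                                "y_um"]).to_csv(path, index=False)


def read_trajectories(path) -> List[Trajectory]:
    """Inverse of :func:`write_trajectories`."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"track_id", "frame", "t_min", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns: {sorted(missing)}")
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        out.append(Trajectory(track_id=int(tid),
                              frames=g["frame"].to_numpy(),
                              t_min=g["t_min"].to_numpy(),
                              x_um=g["x_um"].to_numpy(),
                              y_um=g["y_um"].to_numpy()))
    return out
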
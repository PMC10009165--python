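"""End-to-end orchestration and file I/O.

``run_classification`` drives the whole structure pipeline on a batch of
frames: cell mask, background subtraction, structure segmentation, the
74-measure feature block, standardization, PCA to the 90%-variance
basis, DBSCAN, optional bimodality refinement, merging to interpretable
classes, and per-image area fractions.  ``run_dynamics`` applies the
track filter and per-track speed/persistence metrics to a tracks table.
Every run can write its artifacts (CSV tables, TIFF label maps) plus a
YAML manifest echoing the full configuration, input checksums, seed and
per-stage object counts, so identical manifests reproduce identical
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify as _classify
from . import dynamics as _dynamics
from . import features as _features
from . import segmentation as _segmentation
from .config import PipelineConfig
from .segmentation import CellMask, ImageFrame
from .simgen import SyntheticScene

logger = logging.getLogger("filamorph.pipeline")

__version__ = "0.1.0"


class DataError(ValueError):
    """Raised for malformed input data (CLI exit code 3)."""


@dataclass
class RunManifest:
    """Reproducibility record written with every run."""

    config: dict
    inputs: List[dict]
    seed: int
    counts: Dict[str, int]
    version: str = __version__

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class ClassificationResult:
    """Everything `run_classification` computes."""

    profiles: Dict[str, _classify.ClassProfile]
    assignments: pd.DataFrame        # image_id, object_id, fine, refined, merged
    features: _features.FeatureMatrix
    pca: Optional[_classify.PcaBasis]
    merge_mapping: Dict[int, int]
    manifest: RunManifest

    def profiles_frame(self) -> pd.DataFrame:
        classes = sorted({c for p in self.profiles.values()
                          for c in p.fractions})
        rows = []
        for img, p in sorted(self.profiles.items()):
            row = {"image_id": img, "defined": p.defined,
                   "noise_fraction": p.noise_fraction}
            for c in classes:
                row[f"class_{c}_fraction"] = p.fractions.get(c, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _as_frames(inputs, config: PipelineConfig,
               ) -> List[Tuple[str, ImageFrame, Optional[float]]]:
    """Normalize heterogeneous inputs to (image_id, frame, threshold)."""
    out = []
    for i, item in enumerate(inputs):
        thr = None
        if isinstance(item, SyntheticScene):
            frame = ImageFrame(pixels=item.image,
                               pixel_size=item.params.pixel_size)
            thr = item.suggested_cell_threshold
            out.append((f"scene_{i:03d}", frame, thr))
        elif isinstance(item, ImageFrame):
            out.append((f"image_{i:03d}", item, None))
        elif isinstance(item, (str, os.PathLike)):
            data = tifffile.imread(item)
            if data.ndim == 2:
                data = data[None]
            for f_idx in range(data.shape[0]):
                name = os.path.splitext(os.path.basename(item))[0]
                fid = name if data.shape[0] == 1 else f"{name}_f{f_idx:03d}"
                out.append((fid, ImageFrame(pixels=data[f_idx],
                                            pixel_size=config.pixel_size,
                                            frame_index=f_idx), None))
        else:
            raise DataError(f"unsupported input type: {type(item)!r}")
    return out


def run_classification(inputs: Sequence, config: PipelineConfig,
                       out_dir=None) -> ClassificationResult:
    """Run the full structure-classification pipeline on a batch.

    ``inputs`` may mix TIFF paths, :class:`ImageFrame` objects and
    :class:`SyntheticScene` objects (scenes contribute their generated
    cell-threshold suggestion; other inputs use ``config.cell_threshold``).
    Returns per-image area-fraction profiles plus all intermediate
    tables; with ``out_dir`` the artifacts and a manifest are written.
    """
    t0 = time.time()
    if not inputs:
        raise DataError("run_classification needs at least one image")
    frames = _as_frames(inputs, config)

    per_frame = []
    input_records = []
    n_objects = 0
    all_objects: Dict[str, list] = {}
    for image_id, frame, thr in frames:
        cell_thr = thr if thr is not None else config.cell_threshold
        mask = _segmentation.segment_cell(
            frame, cell_thr, open_radius=config.open_radius,
            min_cell_area=config.min_cell_area)
        bgsub = _segmentation.subtract_background(frame, config.bg_sigma)
        objects = _segmentation.segment_structures(
            bgsub, mask, config.structure_threshold,
            config.structure_area_range)
        if config.intensity_on_raw:
            for o in objects:
                o.intensities = frame.pixels[
                    o.pixels[:, 0], o.pixels[:, 1]].astype(float)
        fm = _features.compute_frame_features(
            objects, bgsub, image_id=image_id,
            n_shape_modes=config.n_shape_modes,
            n_dist_modes=config.n_dist_modes,
            n_boundary_points=config.n_boundary_points,
            boundary_err_max=config.boundary_err_max)
        per_frame.append(fm)
        all_objects[image_id] = objects
        n_objects += len(objects)
        input_records.append({"image_id": image_id,
                              "checksum": _checksum(frame.pixels),
                              "cell_threshold": float(cell_thr),
                              "n_objects": len(objects)})
        logger.info("%s: %d structure objects", image_id, len(objects))

    fm_all = _features.concat_feature_matrices(per_frame)
    keep = ~fm_all.meta["excluded"].to_numpy()
    n_excluded = int((~keep).sum())

    counts = {"images": len(frames), "segmented": n_objects,
              "feature_excluded": n_excluded}
    manifest = RunManifest(config=config.to_dict(), inputs=input_records,
                           seed=config.seed, counts=counts)

    if keep.sum() < 2:
        logger.warning("fewer than 2 usable objects: no classification")
        counts.update({"classified": 0, "noise": 0})
        empty = pd.DataFrame(columns=["image_id", "object_id", "fine",
                                      "refined", "merged"])
        profiles = {image_id: _classify.ClassProfile(
            image_id=image_id, fractions={}, noise_fraction=float("nan"),
            defined=False) for image_id, _, _ in frames}
        result = ClassificationResult(profiles=profiles, assignments=empty,
                                      features=fm_all, pca=None,
                                      merge_mapping={}, manifest=manifest)
        if out_dir is not None:
            _write_artifacts(result, all_objects, out_dir)
        return result

    fm_used = _features.FeatureMatrix(
        features=fm_all.features.loc[keep].reset_index(drop=True),
        meta=fm_all.meta.loc[keep].reset_index(drop=True))
    std = _features.standardize(fm_used)
    basis, Z = _classify.fit_pca(std.features.to_numpy(),
                                 config.pca_var_target)
    logger.info("PCA kept %d components (target %.0f%% variance)",
                basis.n_kept, 100 * config.pca_var_target)
    fine = _classify.cluster_dbscan(Z, config.dbscan_eps,
                                    config.dbscan_min_pts)
    areas = std.meta["area"].to_numpy(dtype=float)
    refined = fine
    if config.refine:
        refined = _classify.refine_classes(fine, Z, areas,
                                           refine_top_k=config.refine_top_k,
                                           seed=config.seed)
    image_ids = std.meta["image_id"].to_numpy()
    fractions = _classify.fine_fraction_matrix(image_ids, refined, areas)
    if fractions.shape[1] == 0:
        logger.warning("DBSCAN labeled every object as noise")
        mapping: Dict[int, int] = {}
    elif len(fractions) < 3 or fractions.shape[1] <= config.merged_k:
        logger.warning("too few images or fine classes for merging: "
                       "identity mapping")
        mapping = {c: i for i, c in enumerate(fractions.columns)}
    else:
        mapping = _classify.merge_classes(fractions, config.merged_k)
    merged = _classify.apply_merge(refined, mapping)
    profiles = _classify.area_fractions(merged, areas, image_ids)
    for image_id, _, _ in frames:      # images with zero usable objects
        if image_id not in profiles:
            profiles[image_id] = _classify.ClassProfile(
                image_id=image_id, fractions={}, noise_fraction=float("nan"),
                defined=False)

    counts.update({"classified": int((merged != _classify.NOISE).sum()),
                   "noise": int((merged == _classify.NOISE).sum())})
    assignments = pd.DataFrame({
        "image_id": image_ids,
        "object_id": std.meta["object_id"].to_numpy(),
        "fine": fine, "refined": refined, "merged": merged})
    result = ClassificationResult(profiles=profiles, assignments=assignments,
                                  features=fm_all, pca=basis,
                                  merge_mapping=mapping, manifest=manifest)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    if out_dir is not None:
        _write_artifacts(result, all_objects, out_dir)
    return result


def _write_artifacts(result: ClassificationResult, all_objects: dict,
                     out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    header = ("# coordinates: 0-based (row, col), origin top-left; "
              "areas in px; fractions dimensionless\n")

    feats = pd.concat([result.features.meta.reset_index(drop=True),
                       result.features.features.reset_index(drop=True)],
                      axis=1)
    _write_csv(feats, os.path.join(out_dir, "features.csv"), header)
    _write_csv(result.assignments, os.path.join(out_dir, "classes.csv"),
               header)
    _write_csv(result.profiles_frame(), os.path.join(out_dir, "profiles.csv"),
               header)
    model = {
        "pca": None if result.pca is None else {
            "n_kept": int(result.pca.n_kept),
            "explained_variance_ratio": [
                float(v) for v in result.pca.explained_variance_ratio],
        },
        "merge_mapping": {int(k): int(v)
                          for k, v in result.merge_mapping.items()},
    }
    with open(os.path.join(out_dir, "model.yaml"), "w") as fh:
        yaml.safe_dump(model, fh, sort_keys=False)
    result.manifest.write(os.path.join(out_dir, "manifest.yaml"))
    for image_id, objects in all_objects.items():
        if not objects:
            continue
        shape = None
        rows = []
        for o in objects:
            rows.append({"frame": o.frame_index, "object_id": o.object_id,
                         "area_px": o.area,
                         "centroid_row": o.centroid[0],
                         "centroid_col": o.centroid[1],
                         "bbox_rmin": int(o.pixels[:, 0].min()),
                         "bbox_cmin": int(o.pixels[:, 1].min()),
                         "bbox_rmax": int(o.pixels[:, 0].max()),
                         "bbox_cmax": int(o.pixels[:, 1].max())})
        _write_csv(pd.DataFrame(rows),
                   os.path.join(out_dir, f"objects_{image_id}.csv"), header)


def _write_csv(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_table_csv(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the unit-declaring comment header."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def evaluate_classification(scenes: Sequence[SyntheticScene],
                            result: ClassificationResult,
                            config: PipelineConfig) -> Dict[str, float]:
    """Score a classification run against scene ground truth.

    Re-segments each scene to recover the pixel sets behind every
    assignment row, assigns each object its majority ground-truth class,
    and reports merged-class purity, the per-image area-fraction error
    against the generated fractions (merged classes mapped to truth
    classes by majority), and the noise share.
    """
    from .simgen import truth_majority_class

    truth: Dict[Tuple[str, int], str] = {}
    for i, scene in enumerate(scenes):
        frame = ImageFrame(scene.image, pixel_size=scene.params.pixel_size)
        mask = _segmentation.segment_cell(
            frame, scene.suggested_cell_threshold,
            open_radius=config.open_radius,
            min_cell_area=config.min_cell_area)
        bgsub = _segmentation.subtract_background(frame, config.bg_sigma)
        objects = _segmentation.segment_structures(
            bgsub, mask, config.structure_threshold,
            config.structure_area_range)
        for o in objects:
            truth[(f"scene_{i:03d}", o.object_id)] = \
                truth_majority_class(scene, o.pixels)

    ass = result.assignments.copy()
    ass["truth"] = [truth[(r.image_id, r.object_id)]
                    for r in ass.itertuples()]
    classified = ass[ass.merged >= 0]
    if classified.empty:
        return {"purity": 0.0, "max_fraction_error": 1.0,
                "noise_fraction": 1.0}
    majority = classified.groupby("merged")["truth"]
    purity = majority.agg(
        lambda s: s.value_counts().iloc[0]).sum() / len(classified)
    merged_to_truth = majority.agg(
        lambda s: s.value_counts().index[0]).to_dict()
    errors = []
    for i, scene in enumerate(scenes):
        profile = result.profiles.get(f"scene_{i:03d}")
        generated = scene.class_area_fractions()
        estimated: Dict[str, float] = {}
        if profile is not None and profile.defined:
            for c, frac in profile.fractions.items():
                t = merged_to_truth.get(c, "none")
                estimated[t] = estimated.get(t, 0.0) + frac
        errors += [abs(estimated.get(t, 0.0) - generated[t])
                   for t in generated]
    return {"purity": float(purity),
            "max_fraction_error": float(max(errors)),
            "noise_fraction": float((ass.merged < 0).mean())}


# ---------------------------------------------------------------------------
# dynamics orchestration
# ---------------------------------------------------------------------------

def read_tracks_csv(path) -> List[_dynamics.Trajectory]:
    """Read a tracks CSV, reporting malformed rows with their line number."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["track_id", "frame", "t_min", "x_um", "y_um"]
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"tracks CSV missing columns: {sorted(missing)}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(df.index[bad][0]) + 2    # 1-based, after the header
        raise DataError(f"malformed tracks CSV row at line {line}")
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        try:
            out.append(_dynamics.Trajectory(
                track_id=int(tid), frames=g["frame"].to_numpy(int),
                t_min=g["t_min"].to_numpy(float),
                x_um=g["x_um"].to_numpy(float),
                y_um=g["y_um"].to_numpy(float)))
        except ValueError as e:
            raise DataError(f"track {tid}: {e}") from e
    return out


def run_dynamics(tracks: Union[str, Sequence[_dynamics.Trajectory]],
                 min_frames: int = 5, n_bins: int = 12,
                 out_dir=None) -> Tuple[pd.DataFrame, np.ndarray]:
    """Track filter plus per-track speed/persistence and a rose histogram.

    ``tracks`` is either a CSV path or trajectories in memory.  Returns
    the per-track metrics table and the angular histogram counts; both
    are written as CSV when ``out_dir`` is given.
    """
    if isinstance(tracks, (str, os.PathLike)):
        tracks = read_tracks_csv(tracks)
    kept = _dynamics.filter_tracks(tracks, min_frames=min_frames)
    if not kept:
        logger.warning("no track persisted for more than %d frames",
                       min_frames)
        metrics = pd.DataFrame(columns=["track_id", "n_frames", "speed_um_min",
                                        "directionality_ratio",
                                        "net_angle_rad"])
        counts = np.zeros(n_bins, dtype=int)
    else:
        metrics = pd.DataFrame([{
            "track_id": t.track_id, "n_frames": len(t),
            "speed_um_min": _dynamics.track_speed(t),
            "directionality_ratio": _dynamics.directionality_ratio(t),
            "net_angle_rad": t.net_angle} for t in kept])
        counts, _ = _dynamics.rose_histogram(kept, n_bins=n_bins)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        header = ("# speed in um/min; directionality ratio dimensionless; "
                  "angles in radians, x axis = 0, counter-clockwise\n")
        _write_csv(metrics, os.path.join(out_dir, "track_metrics.csv"),
                   header)
        edges = -np.pi + np.arange(n_bins + 1) * 2 * np.pi / n_bins
        rose = pd.DataFrame({"bin_start_rad": edges[:-1],
                             "bin_end_rad": edges[1:], "count": counts})
        _write_csv(rose, os.path.join(out_dir, "rose_histogram.csv"), header)
    return metrics, counts
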
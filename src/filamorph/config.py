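"""Pipeline configuration.

All tunable parameters of the structure-classification pipeline live in a
single :class:`PipelineConfig`.  The defaults are the operating points used
for septin imaging data: a manually chosen cell threshold in the
12,000-24,000 count range, a structure threshold of 2,000 counts on the
background-subtracted image (1,500 for Cdc42ep1 channels), Gaussian
background smoothing with sigma = 5 px, morphological opening with a
radius-7 disk, a 5,000 px minimum cell area, a 10-400 px structure size
window, and DBSCAN with eps = 2 and min_pts = 3 in PCA space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import yaml

#: Structure thresholds by channel, counts above local background.
CHANNEL_STRUCTURE_THRESHOLDS = {"septin": 2000.0, "cdc42ep1": 1500.0}

#: Manual cell-mask threshold ranges by channel (raw counts).
CHANNEL_CELL_THRESHOLD_RANGES = {
    "septin": (12000.0, 24000.0),
    "cdc42ep1": (2000.0, 5000.0),
}


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid range."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the classification pipeline.

    Parameters
    ----------
    cell_threshold:
        Raw-intensity threshold for the whole-cell mask (chosen per image
        in practice; the default sits in the septin operating range).
    structure_threshold:
        Threshold on the background-subtracted image for structure masks.
    bg_sigma:
        Standard deviation (px) of the Gaussian kernel used to estimate
        the local background.
    open_radius:
        Radius (px) of the disk structuring element for morphological
        opening of the cell mask.
    min_cell_area:
        Connected components of the cell mask smaller than this (px) are
        discarded.
    structure_area_range:
        Inclusive ``(lo, hi)`` size window in px for structure objects.
    boundary_err_max:
        Objects whose truncated-Fourier boundary reconstruction deviates
        from the resampled boundary by more than this mean distance (px)
        are flagged ``excluded``.
    n_shape_modes / n_dist_modes:
        Number of Fourier amplitudes retained for the boundary-shape and
        neighbor-distance-profile descriptors.
    pca_var_target:
        Fraction of total variance the kept principal components must
        explain (smallest such number of components is used).
    dbscan_eps / dbscan_min_pts:
        DBSCAN density parameters in the PCA-reduced feature space.
        ``dbscan_eps`` may be the string ``"auto"`` to use the k-distance
        heuristic (see :func:`filamorph.classify.estimate_eps`).
    refine:
        Whether to run the optional bimodality-driven class refinement
        (used for Cdc42ep1 data; off for septin).
    refine_top_k:
        Number of classes (ranked by mean object area) considered for
        refinement.
    merged_k:
        Number of interpretable merged classes.
    intensity_on_raw:
        If True, per-object intensity statistics are measured on the raw
        image instead of the background-subtracted one.
    seed:
        Global seed for every stochastic stage (GMM restarts, generators).
    """

    cell_threshold: float = 12000.0
    structure_threshold: float = 2000.0
    bg_sigma: float = 5.0
    open_radius: int = 7
    min_cell_area: int = 5000
    structure_area_range: Tuple[int, int] = (10, 400)
    boundary_err_max: float = 0.1
    n_boundary_points: int = 128
    n_shape_modes: int = 30
    n_dist_modes: int = 30
    pca_var_target: float = 0.90
    dbscan_eps: Union[float, str] = 2.0
    dbscan_min_pts: int = 3
    refine: bool = False
    refine_top_k: int = 5
    merged_k: int = 3
    intensity_on_raw: bool = False
    pixel_size: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cell_threshold <= 0 or self.structure_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.bg_sigma <= 0:
            raise ConfigError("bg_sigma must be positive")
        if self.open_radius < 0:
            raise ConfigError("open_radius must be non-negative")
        lo, hi = self.structure_area_range
        if not (0 < lo <= hi):
            raise ConfigError("structure_area_range must be ordered and positive")
        if not (0.0 < self.pca_var_target <= 1.0):
            raise ConfigError("pca_var_target must be in (0, 1]")
        if isinstance(self.dbscan_eps, str):
            if self.dbscan_eps != "auto":
                raise ConfigError("dbscan_eps must be a positive number or 'auto'")
        elif self.dbscan_eps <= 0:
            raise ConfigError("dbscan_eps must be positive")
        if self.dbscan_min_pts < 1:
            raise ConfigError("dbscan_min_pts must be >= 1")
        if self.merged_k < 1:
            raise ConfigError("merged_k must be >= 1")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")

    @classmethod
    def for_channel(cls, channel: str, **overrides) -> "PipelineConfig":
        """Config preset for a named channel ('septin' or 'cdc42ep1').

        Septin uses structure threshold 2,000 and no refinement;
        Cdc42ep1 uses 1,500 with refinement enabled.
        """
        kwargs = {}
        if channel in CHANNEL_STRUCTURE_THRESHOLDS:
            kwargs["structure_threshold"] = CHANNEL_STRUCTURE_THRESHOLDS[channel]
            kwargs["cell_threshold"] = CHANNEL_CELL_THRESHOLD_RANGES[channel][0]
            kwargs["refine"] = channel == "cdc42ep1"
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["structure_area_range"] = list(self.structure_area_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "structure_area_range" in d:
            d["structure_area_range"] = tuple(d["structure_area_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path, channel: Optional[str] = None) -> "PipelineConfig":
        """Load a config from YAML; per-channel sections override the root."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must contain a mapping")
        sections = {
            k: v for k, v in doc.items()
            if isinstance(v, dict) and k in ("septin", "cdc42ep1", "actin",
                                             "adhesion", "nuclear")
        }
        base = {k: v for k, v in doc.items() if k not in sections}
        if channel is not None and channel in sections:
            base.update(sections[channel])
        return cls.from_dict(base)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
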
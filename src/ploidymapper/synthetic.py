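"""Synthetic feature tables and label images with doubling-cluster structure.

Within each class, linear-scale intensity is log2-normal: the log2 values are
Gaussian with mean ``log2(base * fold**c)`` and standard deviation derived
from the configured linear-scale coefficient of variation via the exact
log-normal relation ``sd_log2 = sqrt(ln(1 + cv^2)) / ln 2``.  Consecutive
class means therefore differ by ``log2(fold)`` (one unit for the default
doubling), matching the generative premise the mixture pipeline assumes.
Sizes follow the same law.  An optional haploid-like reference population is
drawn around ``base_intensity / 2``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ploidymapper.feature_io import FeatureTable, LabelImage, NucleusRecord


class SimulationError(RuntimeError):
    pass


def _log2_sd(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


@dataclass
class SpatialConfig:
    """Settings for rendering the simulated nuclei into a label image."""

    shape: tuple[int, ...] = (256, 256)
    voxel_noise_cv: float = 0.05  # per-voxel intensity spread within an object
    max_placement_tries: int = 200
    margin: int = 1


@dataclass
class SimConfig:
    """Generator settings; weights must sum to 1 and folds exceed 1."""

    classes: Sequence[tuple[str, float]] = (("2C", 0.5), ("4C", 0.5))
    base_intensity: float = 1000.0
    intensity_fold: float = 2.0
    intensity_cv: float = 0.1
    base_size: float = 100.0
    size_fold: float = 2.0
    size_cv: float = 0.1
    n: int = 1000
    reference_n: int = 0
    reference_intensity: Optional[float] = None  # default: base_intensity / 2
    reference_cv: float = 0.05
    reference_label: str = "spermatid"
    group: str = "sim"
    spatial: Optional[SpatialConfig] = None
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [w for _, w in self.classes]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise SimulationError(
                f"class weights must sum to 1 (got {sum(weights)})"
            )
        if self.intensity_fold <= 1 or self.size_fold <= 1:
            raise SimulationError("folds must be > 1")
        if self.intensity_cv <= 0 or self.size_cv <= 0:
            raise SimulationError("CVs must be > 0")

    @property
    def class_names(self) -> list[str]:
        return [name for name, _ in self.classes]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.classes], dtype=float)

    def log2_intensity_means(self) -> np.ndarray:
        return np.array(
            [
                math.log2(self.base_intensity * self.intensity_fold**c)
                for c in range(len(self.classes))
            ]
        )

    def log2_size_means(self) -> np.ndarray:
        return np.array(
            [
                math.log2(self.base_size * self.size_fold**c)
                for c in range(len(self.classes))
            ]
        )


@dataclass
class GroundTruth:
    """Generator truth, row-aligned with the emitted feature table."""

    class_index: np.ndarray
    class_name: np.ndarray
    proportions: dict
    log2_intensity_means: np.ndarray
    log2_intensity_sd: float
    log2_size_means: np.ndarray
    log2_size_sd: float
    intensity_fold: float
    size_fold: float
    config: SimConfig
    intensity_image: Optional[np.ndarray] = None  # set by simulate_label_image


def simulate_feature_table(config: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw a feature table from the doubling-cluster generative model.

    Deterministic under a fixed seed.  Reference (haploid-standard) nuclei
    are appended with ``user_label == config.reference_label`` when
    ``reference_n > 0``.
    """
    rng = np.random.default_rng(config.seed)
    n_classes = len(config.classes)
    class_index = rng.choice(n_classes, size=config.n, p=config.weights)
    sd_int = _log2_sd(config.intensity_cv)
    sd_size = _log2_sd(config.size_cv)
    mu_int = config.log2_intensity_means()
    mu_size = config.log2_size_means()

    log2_intensity = rng.normal(mu_int[class_index], sd_int)
    log2_size = rng.normal(mu_size[class_index], sd_size)
    intensity = np.exp2(log2_intensity)
    size = np.exp2(log2_size)

    records = []
    for i in range(config.n):
        records.append(
            NucleusRecord(
                object_id=i + 1,
                total_intensity=float(intensity[i]),
                size=float(size[i]),
                mean_intensity=float(intensity[i] / size[i]),
                user_label="nucleus",
                group=config.group,
            )
        )
    if config.reference_n:
        ref_mean = (
            config.reference_intensity
            if config.reference_intensity is not None
            else config.base_intensity / 2.0
        )
        ref = np.exp2(
            rng.normal(math.log2(ref_mean), _log2_sd(config.reference_cv),
                       size=config.reference_n)
        )
        base_size = config.base_size / 2.0
        for j, value in enumerate(ref):
            records.append(
                NucleusRecord(
                    object_id=config.n + j + 1,
                    total_intensity=float(value),
                    size=float(base_size),
                    mean_intensity=float(value / base_size),
                    user_label=config.reference_label,
                    group=config.group,
                )
            )

    names = np.array(config.class_names, dtype=object)[class_index]
    observed = {
        name: (float(np.mean(names == name)) if config.n else 0.0)
        for name in config.class_names
    }
    truth = GroundTruth(
        class_index=class_index,
        class_name=names,
        proportions=observed,
        log2_intensity_means=mu_int,
        log2_intensity_sd=sd_int,
        log2_size_means=mu_size,
        log2_size_sd=sd_size,
        intensity_fold=config.intensity_fold,
        size_fold=config.size_fold,
        config=config,
    )
    return FeatureTable(records=records), truth


def _radius_for_size(size: float, ndim: int) -> float:
    if ndim == 2:
        return max(math.sqrt(size / math.pi), 1.0)
    return max((3.0 * size / (4.0 * math.pi)) ** (1.0 / 3.0), 1.0)


def _ball_mask(center: tuple, radius: float, shape: tuple) -> tuple:
    """Index arrays of the ball/disk around center, clipped to the image."""
    slices = []
    for c, dim in zip(center, shape):
        lo = max(int(math.floor(c - radius)), 0)
        hi = min(int(math.ceil(c + radius)) + 1, dim)
        slices.append(slice(lo, hi))
    grids = np.meshgrid(
        *[np.arange(s.start, s.stop) for s in slices], indexing="ij"
    )
    dist_sq = sum((g - c) ** 2 for g, c in zip(grids, center))
    inside = dist_sq <= radius * radius
    return tuple(g[inside] for g in grids)


def simulate_label_image(
    config: SimConfig,
) -> tuple[LabelImage, FeatureTable, GroundTruth]:
    """Render the simulated nuclei as non-overlapping spheres/disks.

    Nuclei are placed by rejection sampling (a placement cap per nucleus
    guards against overfull images).  Per-voxel intensities are drawn inside
    each object and the emitted feature table is then *measured* from the
    rendered rasters, so total intensity, size, variance of intensity and
    centroid match the image exactly.  The intensity raster is attached to
    the returned :class:`GroundTruth` (``intensity_image``).
    """
    if config.spatial is None:
        raise SimulationError("spatial settings are required")
    spatial = config.spatial
    shape = tuple(int(v) for v in spatial.shape)
    ndim = len(shape)
    if ndim not in (2, 3):
        raise SimulationError("image shape must be 2D or 3D")

    table, truth = simulate_feature_table(config)
    # only the sample nuclei are placed; the reference population is a
    # separate slide in the real protocol
    sample_records = [r for r in table.records if r.user_label == "nucleus"]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    label = np.zeros(shape, dtype=np.uint16)
    intensity_img = np.zeros(shape, dtype=float)
    placed: list[tuple[tuple, float]] = []

    measured = []
    for rec in sample_records:
        radius = _radius_for_size(rec.size, ndim)
        center = None
        for _ in range(spatial.max_placement_tries):
            candidate = tuple(
                rng.uniform(radius + spatial.margin, dim - radius - spatial.margin)
                for dim in shape
            )
            if all(
                math.dist(candidate, other) > radius + r_other + spatial.margin
                for other, r_other in placed
            ):
                center = candidate
                break
        if center is None:
            raise SimulationError(
                f"could not place object {rec.object_id} after "
                f"{spatial.max_placement_tries} tries; use a larger image"
            )
        placed.append((center, radius))
        idx = _ball_mask(center, radius, shape)
        k = len(idx[0])
        if k == 0:
            raise SimulationError("degenerate object mask")
        mean_voxel = rec.total_intensity / k
        if spatial.voxel_noise_cv > 0:
            voxels = mean_voxel * np.exp2(
                rng.normal(0.0, _log2_sd(spatial.voxel_noise_cv), size=k)
            )
        else:
            voxels = np.full(k, mean_voxel)
        label[idx] = rec.object_id
        intensity_img[idx] = voxels

        total = float(voxels.sum())
        measured.append(
            dataclasses.replace(
                rec,
                total_intensity=total,
                size=float(k),
                mean_intensity=total / k,
                variance_of_intensity=float(np.mean((voxels - total / k) ** 2)),
                centroid=tuple(float(np.mean(axis)) for axis in idx),
            )
        )

    out_table = FeatureTable(records=measured, dimensionality=ndim)
    truth = dataclasses.replace(
        truth,
        class_index=truth.class_index[: len(measured)],
        class_name=truth.class_name[: len(measured)],
        intensity_image=intensity_img,
    )
    return LabelImage(array=label), out_table, truth
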
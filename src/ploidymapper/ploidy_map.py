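"""Render spatial ploidy maps: recolor a label image by assigned class and
project class-coded volumes to 2D."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from ploidymapper.feature_io import LabelImage
from ploidymapper.ploidy_assign import PloidyAssignment

logger = logging.getLogger(__name__)


class PaletteError(ValueError):
    pass


#: Colorblind-safe ordered ramp (dark -> light with hue steps).
DEFAULT_PALETTE: tuple[str, ...] = (
    "#332288",
    "#117733",
    "#44AA99",
    "#88CCEE",
    "#DDCC77",
    "#CC6677",
    "#AA4499",
    "#882255",
)

FILTERED_COLOR = "#808080"  # neutral gray for filtered/unassigned objects
BACKGROUND_COLOR = "#000000"


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))


@dataclass
class PloidyMapImage:
    """Class-coded raster (rank 0 = background) plus its RGB rendering."""

    class_raster: np.ndarray  # uint16 class ranks
    rgb: np.ndarray  # uint8, shape (..., 3)
    ladder: list[str]
    palette: dict = field(default_factory=dict)  # class name -> hex color
    filtered_rank: int = 0

    def legend(self) -> list[dict]:
        entries = [
            {"rank": rank, "class": name, "color": self.palette[name]}
            for rank, name in enumerate(self.ladder, start=1)
        ]
        entries.append(
            {"rank": self.filtered_rank, "class": "filtered", "color": FILTERED_COLOR}
        )
        return entries

    def save(self, directory: str | Path, stem: str = "ploidy_map") -> dict:
        """Write class TIFF, RGB PNG (projected if 3D) and legend JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        class_path = directory / f"{stem}_classes.tif"
        tifffile.imwrite(class_path, self.class_raster.astype(np.uint16))
        rgb = self.rgb
        if self.class_raster.ndim == 3:
            projected = project_classes(self.class_raster)
            rgb = _apply_palette(projected, self.ladder, self.palette,
                                 self.filtered_rank)
        png_path = directory / f"{stem}.png"
        iio.imwrite(png_path, rgb)
        legend_path = directory / f"{stem}_legend.json"
        legend_path.write_text(json.dumps(self.legend(), indent=2))
        return {
            "class_raster": str(class_path),
            "rgb": str(png_path),
            "legend": str(legend_path),
        }


def _apply_palette(
    class_raster: np.ndarray,
    ladder: Sequence[str],
    palette: dict,
    filtered_rank: int,
) -> np.ndarray:
    lut = np.zeros((filtered_rank + 1, 3), dtype=np.uint8)
    for rank, name in enumerate(ladder, start=1):
        lut[rank] = _hex_to_rgb(palette[name])
    lut[filtered_rank] = _hex_to_rgb(FILTERED_COLOR)
    return lut[class_raster]


def render_ploidy_map(
    label_image: LabelImage,
    assignment: PloidyAssignment,
    object_ids: Sequence[int],
    palette: Optional[Sequence[str]] = None,
) -> PloidyMapImage:
    """Recolor every object of the label image by its assigned ploidy class.

    ``object_ids[i]`` is the label-image value of assignment row ``i``.
    Filtered/dropped objects, and objects present in the raster but absent
    from the assignment, take the neutral filtered color (logged).
    Background pixels stay background.
    """
    ladder = list(assignment.class_map.ladder)
    if palette is None:
        palette = DEFAULT_PALETTE
    if len(palette) < len(ladder):
        raise PaletteError(
            f"palette has {len(palette)} colors but {len(ladder)} classes"
        )
    palette_map = {name: palette[i] for i, name in enumerate(ladder)}
    rank_of_class = {name: i + 1 for i, name in enumerate(ladder)}
    filtered_rank = len(ladder) + 1

    object_ids = np.asarray(object_ids, dtype=np.int64)
    if len(object_ids) != len(assignment):
        raise ValueError("object_ids length != assignment length")

    arr = label_image.array
    max_label = int(max(arr.max(initial=0), object_ids.max(initial=0)))
    lut = np.zeros(max_label + 1, dtype=np.uint16)
    raster_labels = set(int(v) for v in label_image.labels)
    lut[list(raster_labels)] = filtered_rank  # default for unassigned objects
    for i, oid in enumerate(object_ids):
        if assignment.filtered[i]:
            lut[oid] = filtered_rank
        else:
            lut[oid] = rank_of_class[assignment.class_name[i]]
    unassigned = raster_labels - set(int(v) for v in object_ids)
    if unassigned:
        logger.info(
            "%d object(s) in the raster without an assignment rendered as "
            "filtered", len(unassigned),
        )

    class_raster = lut[arr]
    rgb = _apply_palette(class_raster, ladder, palette_map, filtered_rank)
    return PloidyMapImage(
        class_raster=class_raster,
        rgb=rgb,
        ladder=ladder,
        palette=palette_map,
        filtered_rank=filtered_rank,
    )


def project_classes(class_volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel maximum class rank along the projection axis.

    A high-ploidy nucleus is never hidden by a low one.  2D input is
    returned unchanged with a warning (idempotent).
    """
    vol = np.asarray(class_volume)
    if vol.ndim == 2:
        logger.warning("project_classes: input is already 2D; returning as is")
        return vol.copy()
    if vol.ndim != 3:
        raise ValueError(f"expected a 2D or 3D class raster, got {vol.ndim}D")
    return vol.max(axis=axis)
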
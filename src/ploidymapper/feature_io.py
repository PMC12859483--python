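"""Readers and writers for segmentation feature tables and label images.

Feature tables are CSV exports of object-level measurements (one row per
segmented object).  The default column dialect follows ilastik object-feature
exports, including the version-dependent ``"Total Intensity"`` /
``"Total Intensity_0"`` spelling; every mapping can be overridden through an
explicit dialect.  Label images are integer rasters (TIFF or HDF5) where all
pixels of an object carry the object's id and background is 0.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)


class FeatureIOError(ValueError):
    """Raised for malformed feature tables or label images."""


#: Candidate physical column names per semantic field, tried in order.
DEFAULT_COLUMN_CANDIDATES: Mapping[str, tuple[str, ...]] = {
    "object_id": ("object_id", "Object ID", "ObjectID", "labelimage_oid", "label"),
    "total_intensity": ("Total Intensity", "Total Intensity_0", "total_intensity"),
    "size": ("Size in pixels", "Size in pixels_0", "size", "Size"),
    "variance_of_intensity": (
        "Variance of Intensity",
        "Variance of Intensity_0",
        "variance_of_intensity",
    ),
    "mean_intensity": ("Mean Intensity", "Mean Intensity_0", "mean_intensity"),
    "user_label": ("User Labels", "user_label", "Predicted Class"),
    "group": ("group", "Group", "condition"),
    "physical_size": ("physical_size", "Physical Size"),
    "normalized_intensity": ("normalized_intensity", "Normalized Hoechst Intensity"),
}

#: Candidate centroid column name templates; ``{axis}`` is the axis index.
CENTROID_TEMPLATES: tuple[str, ...] = ("Center of the object_{axis}", "centroid_{axis}")

_MANDATORY_FIELDS = ("object_id", "total_intensity", "size")


@dataclass
class NucleusRecord:
    """Measured features of one segmented object."""

    object_id: int
    total_intensity: float
    size: float
    user_label: str = ""
    group: str = ""
    mean_intensity: Optional[float] = None
    variance_of_intensity: Optional[float] = None
    physical_size: Optional[float] = None
    normalized_intensity: Optional[float] = None
    centroid: Optional[tuple[float, ...]] = None

    def validate(self) -> None:
        if self.total_intensity < 0:
            raise FeatureIOError(
                f"object {self.object_id}: total_intensity must be >= 0"
            )
        if self.size <= 0:
            raise FeatureIOError(f"object {self.object_id}: size must be > 0")
        if self.variance_of_intensity is not None and self.variance_of_intensity < 0:
            raise FeatureIOError(
                f"object {self.object_id}: variance_of_intensity must be >= 0"
            )
        if self.mean_intensity is not None:
            expected = self.mean_intensity * self.size
            scale = max(abs(self.total_intensity), abs(expected), 1e-300)
            if abs(self.total_intensity - expected) / scale > 1e-3:
                raise FeatureIOError(
                    f"object {self.object_id}: total_intensity "
                    f"({self.total_intensity}) inconsistent with "
                    f"mean_intensity*size ({expected}) beyond 0.1%"
                )


@dataclass
class FeatureTable:
    """A collection of :class:`NucleusRecord` plus acquisition metadata."""

    records: list[NucleusRecord] = field(default_factory=list)
    dimensionality: Optional[int] = None
    intensity_channel: Optional[str] = None
    calibration: Optional[tuple[float, ...]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NucleusRecord]:
        return iter(self.records)

    def validate(self) -> None:
        seen: set[int] = set()
        for rec in self.records:
            rec.validate()
            if rec.object_id in seen:
                raise FeatureIOError(f"duplicate object_id {rec.object_id}")
            seen.add(rec.object_id)
            if (
                self.dimensionality is not None
                and rec.centroid is not None
                and len(rec.centroid) != self.dimensionality
            ):
                raise FeatureIOError(
                    f"object {rec.object_id}: centroid length "
                    f"{len(rec.centroid)} != dimensionality {self.dimensionality}"
                )

    def values(self, field_name: str) -> np.ndarray:
        """Vector of one feature over all records (None becomes NaN)."""
        vals = [getattr(rec, field_name) for rec in self.records]
        return np.array(
            [np.nan if v is None else v for v in vals], dtype=float
        )

    def object_ids(self) -> np.ndarray:
        return np.array([rec.object_id for rec in self.records], dtype=np.int64)

    def with_records(self, records: Iterable[NucleusRecord]) -> "FeatureTable":
        return dataclasses.replace(self, records=list(records))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = dataclasses.asdict(rec)
            centroid = row.pop("centroid")
            if centroid is not None:
                for axis, value in enumerate(centroid):
                    row[f"centroid_{axis}"] = value
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LabelImage:
    """Integer-labeled segmentation raster; 0 is background."""

    array: np.ndarray
    axes: Optional[str] = None
    calibration: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if not np.issubdtype(arr.dtype, np.integer):
            raise FeatureIOError(
                "label image must be an integer raster; got floating-point data "
                "— export object predictions, not probabilities"
            )
        if arr.ndim not in (2, 3):
            raise FeatureIOError(f"label image must be 2D or 3D, got {arr.ndim}D")
        self.array = arr

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero object ids present in the raster."""
        vals = np.unique(self.array)
        return vals[vals != 0]


def _resolve_column(
    columns: Sequence[str], semantic: str, dialect: Optional[Mapping[str, str]]
) -> Optional[str]:
    if dialect and semantic in dialect:
        name = dialect[semantic]
        if name is None:
            return None
        if name not in columns:
            raise FeatureIOError(
                f"dialect maps '{semantic}' to column '{name}', "
                f"which is absent from the file"
            )
        return name
    for candidate in DEFAULT_COLUMN_CANDIDATES.get(semantic, ()):
        if candidate in columns:
            return candidate
    return None


def _resolve_centroid_columns(
    columns: Sequence[str], dialect: Optional[Mapping[str, str]]
) -> list[str]:
    if dialect and "centroid" in dialect:
        cols = list(dialect["centroid"] or [])
        for c in cols:
            if c not in columns:
                raise FeatureIOError(f"dialect centroid column '{c}' absent from file")
        return cols
    for template in CENTROID_TEMPLATES:
        cols = []
        axis = 0
        while template.format(axis=axis) in columns:
            cols.append(template.format(axis=axis))
            axis += 1
        if cols:
            return cols
    return []


def read_feature_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    intensity_channel: Optional[str] = None,
    calibration: Optional[Sequence[float]] = None,
) -> FeatureTable:
    """Read an object feature table from CSV.

    Parameters
    ----------
    path:
        CSV file with a header row, one row per segmented object.
    dialect:
        Optional mapping from semantic field names (``object_id``,
        ``total_intensity``, ``size``, ``variance_of_intensity``,
        ``mean_intensity``, ``user_label``, ``group``, ``centroid``) to the
        physical column names in the file.  Unmapped fields fall back to the
        ilastik-dialect candidates, so both ``"Total Intensity"`` and
        ``"Total Intensity_0"`` resolve automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FeatureIOError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    columns = list(df.columns)

    resolved: dict[str, Optional[str]] = {}
    for semantic in DEFAULT_COLUMN_CANDIDATES:
        resolved[semantic] = _resolve_column(columns, semantic, dialect)
    for semantic in _MANDATORY_FIELDS:
        if resolved[semantic] is None:
            raise FeatureIOError(
                f"mandatory column for '{semantic}' not found in {path.name}; "
                f"tried {DEFAULT_COLUMN_CANDIDATES[semantic]} — "
                f"provide a dialect mapping"
            )
    centroid_cols = _resolve_centroid_columns(columns, dialect)

    records: list[NucleusRecord] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        raw_id = row[resolved["object_id"]]
        if pd.isna(raw_id):
            n_dropped += 1
            continue
        numeric: dict[str, Optional[float]] = {}
        for semantic in (
            "total_intensity",
            "size",
            "variance_of_intensity",
            "mean_intensity",
            "physical_size",
            "normalized_intensity",
        ):
            col = resolved[semantic]
            if col is None:
                numeric[semantic] = None
                continue
            value = row[col]
            if pd.isna(value):
                numeric[semantic] = None
                continue
            try:
                numeric[semantic] = float(value)
            except (TypeError, ValueError) as exc:
                raise FeatureIOError(
                    f"non-numeric value {value!r} for '{semantic}' "
                    f"(column '{col}') in row {idx} of {path.name}"
                ) from exc
        centroid = None
        if centroid_cols:
            centroid = tuple(float(row[c]) for c in centroid_cols)
        records.append(
            NucleusRecord(
                object_id=int(raw_id),
                total_intensity=numeric["total_intensity"],
                size=numeric["size"],
                user_label="" if resolved["user_label"] is None
                or pd.isna(row[resolved["user_label"]])
                else str(row[resolved["user_label"]]),
                group="" if resolved["group"] is None
                or pd.isna(row[resolved["group"]])
                else str(row[resolved["group"]]),
                mean_intensity=numeric["mean_intensity"],
                variance_of_intensity=numeric["variance_of_intensity"],
                physical_size=numeric["physical_size"],
                normalized_intensity=numeric["normalized_intensity"],
                centroid=centroid,
            )
        )
    if n_dropped:
        logger.warning(
            "%s: rejected %d row(s) lacking an object identifier", path.name, n_dropped
        )
    table = FeatureTable(
        records=records,
        dimensionality=len(centroid_cols) or None,
        intensity_channel=intensity_channel,
        calibration=tuple(calibration) if calibration is not None else None,
    )
    table.validate()
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table to CSV using semantic column names.

    The output round-trips through :func:`read_feature_table` with the
    default dialect (15 significant digits for floats).
    """
    path = Path(path)
    df = table.to_dataframe()
    if len(table) == 0:
        df = pd.DataFrame(
            columns=["object_id", "total_intensity", "size", "user_label", "group"]
        )
    df.to_csv(path, index=False, float_format="%.15g")


def read_label_image(
    path: str | Path, dataset: Optional[str] = None
) -> LabelImage:
    """Read a label image from a TIFF file or an HDF5 container.

    For HDF5, the first dataset is used unless ``dataset`` names one.
    Floating-point rasters are rejected: export object predictions, not
    probability maps.
    """
    path = Path(path)
    if not path.exists():
        raise FeatureIOError(f"label image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        return LabelImage(array=np.squeeze(np.asarray(arr)))
    if suffix in (".h5", ".hdf5", ".he5"):
        with h5py.File(path, "r") as fh:
            if dataset is None:
                names: list[str] = []
                fh.visit(
                    lambda n: names.append(n)
                    if isinstance(fh[n], h5py.Dataset)
                    else None
                )
                if not names:
                    raise FeatureIOError(f"no datasets in {path.name}")
                dataset = names[0]
            arr = fh[dataset][()]
        return LabelImage(array=np.squeeze(np.asarray(arr)))
    raise FeatureIOError(
        f"unsupported label image format '{suffix}' (use TIFF or HDF5)"
    )


def write_label_image(
    image: LabelImage, path: str | Path, dataset: str = "exported_data"
) -> None:
    """Write a label image to TIFF or HDF5, preserving integer values."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.array)
    elif suffix in (".h5", ".hdf5", ".he5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=image.array)
    else:
        raise FeatureIOError(f"unsupported label image format '{suffix}'")


def write_assignments(
    table: FeatureTable,
    assignment,  # PloidyAssignment; untyped to avoid a circular import
    path: str | Path,
    index_map: Optional[Sequence[int]] = None,
) -> None:
    """Write one CSV row per input record with its classification.

    ``index_map`` aligns assignment rows to table rows (survivor indices from
    :func:`ploidymapper.preprocess.log2_features` or upstream filters); records
    without an assignment row are written with class ``"filtered"`` and empty
    posteriors.  Without an ``index_map`` the lengths must match exactly.
    """
    path = Path(path)
    n_records = len(table)
    n_assigned = len(assignment.class_name)
    if index_map is None:
        if n_assigned != n_records:
            raise FeatureIOError(
                f"assignment length {n_assigned} != table length {n_records} "
                f"and no index_map given"
            )
        index_map = range(n_records)
    if len(index_map) != n_assigned:
        raise FeatureIOError(
            f"index_map length {len(index_map)} != assignment length {n_assigned}"
        )
    row_of_record: dict[int, int] = {int(t): a for a, t in enumerate(index_map)}

    K = assignment.posteriors.shape[1] if n_assigned else 0
    rows = []
    for i, rec in enumerate(table.records):
        row: dict[str, object] = {
            "object_id": rec.object_id,
            "group": rec.group,
            "user_label": rec.user_label,
            "total_intensity": rec.total_intensity,
            "size": rec.size,
            "mean_intensity": rec.mean_intensity,
            "variance_of_intensity": rec.variance_of_intensity,
            "normalized_intensity": rec.normalized_intensity,
        }
        a = row_of_record.get(i)
        if a is None:
            row.update(
                component="",
                ploidy_class="filtered",
                confident="",
                ambiguous_second="",
            )
            for k in range(K):
                row[f"posterior_{k}"] = ""
        else:
            row.update(
                component=int(assignment.component[a]),
                ploidy_class=str(assignment.class_name[a]),
                confident=bool(assignment.confident[a]),
                ambiguous_second=(
                    str(assignment.second_class[a])
                    if assignment.ambiguous_second[a]
                    else ""
                ),
            )
            for k in range(K):
                row[f"posterior_{k}"] = assignment.posteriors[a, k]
        rows.append(row)
    columns = [
        "object_id",
        "group",
        "user_label",
        "total_intensity",
        "size",
        "mean_intensity",
        "variance_of_intensity",
        "normalized_intensity",
        "component",
        "ploidy_class",
        "confident",
        "ambiguous_second",
    ] + [f"posterior_{k}" for k in range(K)]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, float_format="%.15g"
    )


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read an assignment CSV written by :func:`write_assignments`."""
    return pd.read_csv(path)
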
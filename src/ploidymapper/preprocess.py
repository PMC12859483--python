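"""Record-level filters, reference normalization with QC gates, and the log2
feature transform that feeds the mixture model.

All thresholds and gates default to the published recipe values; every filter
is a pure subset operation (output records are a subset of input records).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ploidymapper.feature_io import FeatureTable

logger = logging.getLogger(__name__)


def variance_of_intensity(intensities: Sequence[float]) -> float:
    """Population variance of per-voxel intensities of one object.

    Uses the 1/n normalization (not 1/(n-1)): the quantity measures the
    inhomogeneity of the signal across the object, and is defined with the
    plain mean of squared deviations.
    """
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("variance_of_intensity requires at least one voxel")
    mu = values.mean()
    return float(np.mean((values - mu) ** 2))


def select_by_label(
    table: FeatureTable,
    exclude: Iterable[str] = (),
    include: Optional[Iterable[str]] = None,
) -> FeatureTable:
    """Keep/drop records by their categorical ``user_label``.

    Records whose label is in ``exclude`` are removed; when ``include`` is
    given, only those labels are kept.  The two sets must not overlap.
    """
    exclude_set = set(exclude)
    include_set = set(include) if include is not None else None
    if include_set is not None and include_set & exclude_set:
        raise ValueError(
            f"include and exclude overlap: {sorted(include_set & exclude_set)}"
        )
    kept = []
    for rec in table.records:
        if rec.user_label in exclude_set:
            continue
        if include_set is not None and rec.user_label not in include_set:
            continue
        kept.append(rec)
    logger.info(
        "select_by_label: kept %d, removed %d of %d records",
        len(kept), len(table) - len(kept), len(table),
    )
    return table.with_records(kept)


def threshold_filter(
    table: FeatureTable, feature: str, cutoff: float, keep: str = "above"
) -> FeatureTable:
    """Keep records on one side of a cutoff on a numeric feature.

    Ties (value == cutoff) are retained on the kept side.  ``keep`` is
    ``"above"`` or ``"below"``.
    """
    if keep not in ("above", "below"):
        raise ValueError(f"keep must be 'above' or 'below', got {keep!r}")
    kept = []
    for rec in table.records:
        value = getattr(rec, feature, None)
        if value is None:
            raise ValueError(
                f"feature '{feature}' absent for object {rec.object_id}"
            )
        if (keep == "above" and value >= cutoff) or (
            keep == "below" and value <= cutoff
        ):
            kept.append(rec)
    logger.info(
        "threshold_filter(%s %s %g): kept %d, removed %d of %d records",
        feature, keep, cutoff, len(kept), len(table) - len(kept), len(table),
    )
    return table.with_records(kept)


@dataclass
class QCReport:
    """Verdict of the reference-population (e.g. spermatid) quality gates."""

    n_reference: int
    median_intensity: float
    fraction_in_band: float
    passed: bool
    reasons: list[str] = field(default_factory=list)
    gates: dict[str, bool] = field(default_factory=dict)


def reference_qc(
    reference_intensities: Sequence[float],
    min_n: int = 10,
    median_range: tuple[float, float] = (2000.0, 6000.0),
    band: tuple[float, float] = (0.5, 1.5),
    min_fraction: float = 0.9,
) -> QCReport:
    """Evaluate the three reference-population gates.

    Passes iff (a) at least ``min_n`` reference nuclei, (b) their median
    intensity lies in ``median_range`` (inclusive), and (c) at least
    ``min_fraction`` of median-normalized intensities lie in ``band``
    (inclusive).  Always returns a report; never raises.
    """
    values = np.asarray(list(reference_intensities), dtype=float)
    n = int(values.size)
    median = float(np.median(values)) if n else float("nan")
    if n and median > 0:
        normalized = values / median
        fraction = float(
            np.mean((normalized >= band[0]) & (normalized <= band[1]))
        )
    else:
        fraction = 0.0
    gates = {
        "count": n >= min_n,
        "median": n > 0
        and median_range[0] <= median <= median_range[1],
        "band": fraction >= min_fraction,
    }
    reasons = [name for name, ok in gates.items() if not ok]
    return QCReport(
        n_reference=n,
        median_intensity=median,
        fraction_in_band=fraction,
        passed=not reasons,
        reasons=reasons,
        gates=gates,
    )


def normalize_by_reference(
    table: FeatureTable, reference_median: float
) -> FeatureTable:
    """Divide each record's total intensity by the reference median.

    The result is stored in ``normalized_intensity`` (the original intensity
    is retained), so that a value of 1.0 sits at the reference ploidy rung
    (e.g. 1C for a haploid spermatid standard).
    """
    if reference_median <= 0:
        raise ValueError(f"reference_median must be > 0, got {reference_median}")
    records = [
        dataclasses.replace(
            rec, normalized_intensity=rec.total_intensity / reference_median
        )
        for rec in table.records
    ]
    return table.with_records(records)


def log2_features(
    table: FeatureTable, features: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Build the log2-scaled feature matrix for mixture fitting.

    Returns ``(X, survivors)`` where ``X`` has shape
    ``(n_kept, len(features))`` with entry ``log2(value)`` and ``survivors``
    is the index map of kept records into ``table.records``.  Records with a
    non-positive or missing selected value are dropped with a warning
    (zero-intensity objects are segmentation artifacts); if every record is
    dropped, raises ``ValueError``.
    """
    if not features:
        raise ValueError("at least one feature is required")
    n = len(table)
    raw = np.empty((n, len(features)), dtype=float)
    for j, name in enumerate(features):
        raw[:, j] = table.values(name)
    valid = np.all(np.isfinite(raw) & (raw > 0), axis=1)
    n_dropped = int(n - valid.sum())
    if n_dropped:
        logger.warning(
            "log2_features: dropped %d record(s) with non-positive or missing "
            "values in %s", n_dropped, list(features),
        )
    if not valid.any():
        raise ValueError(
            f"log2_features: all {n} records dropped (features {list(features)})"
        )
    survivors = np.flatnonzero(valid)
    return np.log2(raw[survivors]), survivors
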
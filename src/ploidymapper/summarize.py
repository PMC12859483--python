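"""Per-group ploidy proportions, per-class feature means with fold increases,
and the two-sample Cramér-von Mises distribution comparison."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ploidymapper.feature_io import FeatureTable
from ploidymapper.ploidy_assign import PloidyAssignment

logger = logging.getLogger(__name__)

_LEVEL_RE = re.compile(r"^[<≥>=]*(\d+)")


def class_numeric_level(class_name: str) -> int:
    """Numeric C-level encoded in a class name: '4C' -> 4, '≥16C' -> 16,
    '2aC' -> 2."""
    match = _LEVEL_RE.match(class_name)
    if not match:
        raise ValueError(f"cannot parse a numeric level from {class_name!r}")
    return int(match.group(1))


@dataclass
class GroupProportions:
    """Per-group class proportions (rows: groups, columns: ladder classes)."""

    proportions: pd.DataFrame
    counts: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "proportions": self.proportions.to_dict(orient="index"),
            "counts": self.counts.to_dict(orient="index"),
        }


def class_proportions(
    assignment: PloidyAssignment, groups: Sequence[str]
) -> GroupProportions:
    """Per-group proportions over non-dropped classes (each row sums to 1).

    ``groups`` maps each assignment row to its sample/condition group.
    Groups left empty after filtering are omitted with a warning.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(assignment):
        raise ValueError(
            f"groups length {len(groups)} != assignment length {len(assignment)}"
        )
    classes = list(assignment.class_map.ladder)
    mask = ~assignment.filtered
    rows = {}
    for group in pd.unique(groups):
        sel = mask & (groups == group)
        total = int(sel.sum())
        if total == 0:
            logger.warning("group %r has no classified nuclei; omitted", group)
            continue
        counts = [
            int(np.sum(assignment.class_name[sel] == name)) for name in classes
        ]
        rows[group] = counts
    counts_df = pd.DataFrame.from_dict(rows, orient="index", columns=classes)
    proportions = counts_df.div(counts_df.sum(axis=1), axis=0)
    return GroupProportions(proportions=proportions, counts=counts_df)


@dataclass
class ClassStats:
    """Per-class linear-scale feature means and consecutive fold increases.

    ``means[feature][class]`` is the arithmetic mean; geometric means are
    also computed (the log2 fit implies them) but arithmetic is the reported
    default.  ``folds[feature]`` lists ``((class_a, class_b), fold)`` for
    consecutive non-dropped ladder classes; a pair involving an empty class
    reports ``None``.
    """

    classes: list[str]
    counts: dict
    means: dict
    geometric_means: dict
    folds: dict

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts,
            "means": self.means,
            "geometric_means": self.geometric_means,
            "folds": {
                feat: [[list(pair), fold] for pair, fold in pairs]
                for feat, pairs in self.folds.items()
            },
        }


def class_means_and_folds(
    table: FeatureTable,
    assignment: PloidyAssignment,
    features: Sequence[str],
    index_map: Optional[Sequence[int]] = None,
) -> ClassStats:
    """Arithmetic per-class means of linear-scale features and their folds.

    ``index_map`` aligns assignment rows to ``table.records`` when upstream
    steps dropped records; without it the lengths must match.
    """
    if index_map is None:
        if len(table) != len(assignment):
            raise ValueError(
                f"table length {len(table)} != assignment length "
                f"{len(assignment)} and no index_map given"
            )
        records = table.records
    else:
        if len(index_map) != len(assignment):
            raise ValueError("index_map length != assignment length")
        records = [table.records[int(i)] for i in index_map]

    classes = list(assignment.class_map.ladder)
    mask = ~assignment.filtered
    counts = {}
    means: dict = {feat: {} for feat in features}
    gmeans: dict = {feat: {} for feat in features}
    for name in classes:
        sel = np.flatnonzero(mask & (assignment.class_name == name))
        counts[name] = int(len(sel))
        for feat in features:
            values = np.array(
                [getattr(records[i], feat) for i in sel], dtype=float
            )
            if len(values) == 0:
                means[feat][name] = None
                gmeans[feat][name] = None
            else:
                means[feat][name] = float(values.mean())
                gmeans[feat][name] = float(np.exp(np.log(values).mean()))

    folds: dict = {}
    for feat in features:
        pairs = []
        for lower, upper in zip(classes[:-1], classes[1:]):
            lo, hi = means[feat][lower], means[feat][upper]
            fold = None if lo is None or hi is None or lo <= 0 else float(hi / lo)
            pairs.append(((lower, upper), fold))
        folds[feat] = pairs
    return ClassStats(
        classes=classes,
        counts=counts,
        means=means,
        geometric_means=gmeans,
        folds=folds,
    )


@dataclass
class CvMResult:
    """Two-sample Cramér-von Mises comparison."""

    T: float
    p: float
    n1: int
    n2: int


def cvm_two_sample(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> CvMResult:
    """Two-sample Cramér-von Mises criterion T with its asymptotic p-value.

    Computed from the pooled empirical distribution functions; ties are
    handled by the midrank convention of the underlying implementation.
    Both samples must have at least two values.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    result = stats.cramervonmises_2samp(a, b, method="asymptotic")
    return CvMResult(
        T=float(result.statistic),
        p=float(result.pvalue),
        n1=int(a.size),
        n2=int(b.size),
    )
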
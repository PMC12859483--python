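"""Name mixture components on a doubling ploidy ladder, classify nuclei, and
derive posterior-based uncertainty intervals.

Components are sorted by ascending mean along an anchor feature (by default
the intensity dimension, the DNA-content proxy).  Ladder names double in
numeric prefix (``2C, 4C, 8C, ...`` or relative ``2aC, 4aC, ...``), with an
optional dropped ``<base/Unclassified`` bottom class and an optional
open-top ``>=`` terminal class.  Uncertainty follows a six-step procedure on
the posterior matrix:

1. posteriors ``p_m^k`` per nucleus, rows summing to 1;
2. hard assignment by argmax; class proportions ``V^k``;
3. an assignment is confident when its max posterior exceeds 0.8;
4. ``C_out^k``: proportion assigned to k with max posterior below 0.8;
5. ``C_in^k``: proportion of nuclei whose second-largest posterior exceeds
   0.2 and points at k;
6. interval ``(V^k - C_out^k, V^k + C_in^k)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ploidymapper.mixture import MixtureModel

logger = logging.getLogger(__name__)


class LadderError(ValueError):
    """Raised for inconsistent component-to-class mappings."""


_BASE_RE = re.compile(r"^(\d+)(.*)$")


def _ladder_names(base_class: str, count: int) -> list[str]:
    match = _BASE_RE.match(base_class)
    if not match:
        raise LadderError(
            f"base class {base_class!r} must start with a numeric prefix "
            f"(e.g. '2C' or '2aC')"
        )
    base_value, suffix = int(match.group(1)), match.group(2)
    return [f"{base_value * 2 ** i}{suffix}" for i in range(count)]


@dataclass
class ComponentClassMap:
    """Mapping from mixture components to ploidy-class names.

    ``order`` lists original component indices by ascending anchor-feature
    mean; ``class_for_component`` names every component (possibly
    many-to-one for merged components); ``ladder`` is the ordered list of
    non-dropped class names; ``drop_classes`` are excluded from summaries.
    """

    order: np.ndarray
    class_for_component: dict[int, str]
    ladder: list[str]
    drop_classes: set[str] = field(default_factory=set)
    anchor_feature_index: int = 0
    component_means: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return len(self.order)

    def to_dict(self) -> dict:
        return {
            "order": self.order.tolist(),
            "class_for_component": {
                str(k): v for k, v in self.class_for_component.items()
            },
            "ladder": list(self.ladder),
            "drop_classes": sorted(self.drop_classes),
            "anchor_feature_index": self.anchor_feature_index,
        }


def map_components_to_classes(
    model: MixtureModel,
    base_class: str = "2C",
    drop_lowest: bool = False,
    open_top: bool = False,
    anchor_feature: Optional[str | int] = None,
    anchors: Optional[tuple[np.ndarray, str]] = None,
) -> ComponentClassMap:
    """Lay a doubling class ladder over the components of a fitted model.

    Components are sorted by ascending mean of the anchor feature.  With
    ``drop_lowest``, the lowest-mean component is named
    ``"<{base_class}/Unclassified"`` and marked dropped.  With ``open_top``,
    the highest class gets a ``">="`` prefix.  ``anchors`` is an optional
    ``(X_anchor, class_name)`` pair of feature rows for nuclei of known
    ploidy: the component holding the majority of anchors is pinned to that
    class, every lower-mean component is merged into it, and the ladder
    doubles upward from there.  Anchors spread over non-adjacent components
    are rejected.
    """
    if anchor_feature is None:
        anchor_index = 0
    elif isinstance(anchor_feature, int):
        anchor_index = anchor_feature
    else:
        if not model.feature_names or anchor_feature not in model.feature_names:
            raise LadderError(
                f"anchor feature {anchor_feature!r} not among model features "
                f"{model.feature_names}"
            )
        anchor_index = model.feature_names.index(anchor_feature)

    anchor_means = model.means[:, anchor_index]
    order = np.argsort(anchor_means, kind="stable")
    K = model.K

    class_for_component: dict[int, str] = {}
    drop_classes: set[str] = set()

    if anchors is not None:
        X_anchor, anchor_class = anchors
        post = model.posteriors(np.asarray(X_anchor, dtype=float))
        anchor_components = post.argmax(axis=1)
        positions = sorted(
            {int(np.where(order == c)[0][0]) for c in anchor_components}
        )
        if positions[-1] - positions[0] + 1 != len(positions):
            raise LadderError(
                f"anchor nuclei span non-adjacent components at sorted "
                f"positions {positions}; cannot pin the ladder"
            )
        counts = np.bincount(anchor_components, minlength=K)
        majority = int(counts.argmax())
        pin_pos = int(np.where(order == majority)[0][0])
        # everything at or below the pinned component is the anchor class
        upper = _ladder_names(anchor_class, K - pin_pos)
        for pos, comp in enumerate(order):
            if pos <= pin_pos:
                class_for_component[int(comp)] = anchor_class
            else:
                class_for_component[int(comp)] = upper[pos - pin_pos]
        ladder = upper
    elif drop_lowest:
        if K < 2:
            raise LadderError("drop_lowest requires at least two components")
        dropped_name = f"<{base_class}/Unclassified"
        names = _ladder_names(base_class, K - 1)
        class_for_component[int(order[0])] = dropped_name
        drop_classes.add(dropped_name)
        for pos, comp in enumerate(order[1:]):
            class_for_component[int(comp)] = names[pos]
        ladder = names
    else:
        names = _ladder_names(base_class, K)
        for pos, comp in enumerate(order):
            class_for_component[int(comp)] = names[pos]
        ladder = names

    if open_top and ladder:
        top = ladder[-1]
        renamed = f"≥{top}"
        ladder = ladder[:-1] + [renamed]
        for comp, name in class_for_component.items():
            if name == top:
                class_for_component[comp] = renamed

    return ComponentClassMap(
        order=order,
        class_for_component=class_for_component,
        ladder=ladder,
        drop_classes=drop_classes,
        anchor_feature_index=anchor_index,
        component_means=anchor_means,
    )


@dataclass
class PloidyAssignment:
    """Per-nucleus classification with the full posterior vector.

    ``component`` holds original component indices; ``class_name`` the class
    after merging; ``filtered`` flags nuclei whose class is dropped from
    summaries.  ``confident`` and ``ambiguous_second`` use the default 0.8 /
    0.2 thresholds (recomputed with custom thresholds in
    :func:`uncertainty_intervals`).
    """

    component: np.ndarray
    class_name: np.ndarray
    posteriors: np.ndarray
    max_posterior: np.ndarray
    second_posterior: np.ndarray
    second_class: np.ndarray
    confident: np.ndarray
    ambiguous_second: np.ndarray
    filtered: np.ndarray
    class_map: ComponentClassMap

    def __len__(self) -> int:
        return len(self.class_name)

    @property
    def n_classified(self) -> int:
        return int((~self.filtered).sum())


def classify(
    posterior_matrix: np.ndarray,
    class_map: ComponentClassMap,
    conf_threshold: float = 0.8,
    second_threshold: float = 0.2,
) -> PloidyAssignment:
    """Hard-assign every nucleus to the component with maximal posterior.

    Exact argmax ties break toward the lower-mean component (conservative
    ploidy call).  Nuclei whose class is in ``class_map.drop_classes`` are
    flagged filtered.
    """
    P = np.asarray(posterior_matrix, dtype=float)
    if P.ndim != 2 or P.size == 0:
        raise ValueError("posterior matrix must be a nonempty 2D array")
    if P.shape[1] != class_map.n_components:
        raise ValueError(
            f"posterior matrix has {P.shape[1]} columns, class map expects "
            f"{class_map.n_components}"
        )
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")

    order = class_map.order
    n = P.shape[0]
    ordered = P[:, order]  # columns ascending by mean: argmax's first-max
    j = ordered.argmax(axis=1)  # tie -> lowest-mean component
    component = order[j]
    max_posterior = ordered[np.arange(n), j]

    masked = ordered.copy()
    masked[np.arange(n), j] = -np.inf
    j2 = masked.argmax(axis=1)
    second_component = order[j2]
    second_posterior = ordered[np.arange(n), j2]

    lookup = np.vectorize(class_map.class_for_component.__getitem__, otypes=[object])
    class_name = lookup(component).astype(object)
    second_class = lookup(second_component).astype(object)

    filtered = np.array(
        [name in class_map.drop_classes for name in class_name], dtype=bool
    )
    return PloidyAssignment(
        component=component.astype(int),
        class_name=class_name,
        posteriors=P,
        max_posterior=max_posterior,
        second_posterior=second_posterior,
        second_class=second_class,
        confident=max_posterior > conf_threshold,
        ambiguous_second=second_posterior > second_threshold,
        filtered=filtered,
        class_map=class_map,
    )


@dataclass
class ClassSummary:
    """Per-class proportions with posterior-based uncertainty terms."""

    classes: list[str]
    counts: np.ndarray
    V: np.ndarray
    C_out: np.ndarray
    C_in: np.ndarray
    intervals: list[tuple[float, float]]
    n: int
    K: int
    conf_threshold: float = 0.8
    second_threshold: float = 0.2

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.tolist(),
            "V": self.V.tolist(),
            "C_out": self.C_out.tolist(),
            "C_in": self.C_in.tolist(),
            "intervals": [list(iv) for iv in self.intervals],
            "n": self.n,
            "K": self.K,
            "conf_threshold": self.conf_threshold,
            "second_threshold": self.second_threshold,
        }


def uncertainty_intervals(
    assignment: PloidyAssignment,
    conf_threshold: float = 0.8,
    second_threshold: float = 0.2,
) -> ClassSummary:
    """Per-class proportions ``V^k`` with ``C_out^k``/``C_in^k`` terms.

    All proportions are over the non-filtered nucleus count ``n``.  The
    inequalities are strict exactly as defined: ``C_out`` counts max
    posteriors ``< conf_threshold``; ``C_in`` counts second-largest
    posteriors ``> second_threshold``.  A nucleus contributes ``C_in`` to
    the class holding its second-largest posterior (when that class differs
    from its own after merging and is not dropped).
    """
    if not (0 < conf_threshold < 1 and 0 < second_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    classes = list(assignment.class_map.ladder)
    mask = ~assignment.filtered
    n = int(mask.sum())
    counts = np.zeros(len(classes), dtype=int)
    c_out = np.zeros(len(classes), dtype=int)
    c_in = np.zeros(len(classes), dtype=int)
    if n:
        for i in np.flatnonzero(mask):
            name = assignment.class_name[i]
            k = classes.index(name)
            counts[k] += 1
            if assignment.max_posterior[i] < conf_threshold:
                c_out[k] += 1
            if (
                assignment.second_posterior[i] > second_threshold
                and assignment.second_class[i] != name
                and assignment.second_class[i] in classes
            ):
                c_in[classes.index(assignment.second_class[i])] += 1
    denom = max(n, 1)
    V = counts / denom
    C_out = c_out / denom
    C_in = c_in / denom
    intervals = [
        (float(v - o), float(v + i)) for v, o, i in zip(V, C_out, C_in)
    ]
    return ClassSummary(
        classes=classes,
        counts=counts,
        V=V,
        C_out=C_out,
        C_in=C_in,
        intervals=intervals,
        n=n,
        K=len(classes),
        conf_threshold=conf_threshold,
        second_threshold=second_threshold,
    )
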
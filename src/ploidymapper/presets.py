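"""Shipped pipeline presets encoding the three published per-organism recipes.

Each preset is a plain config dict; callers override input/output paths and
any field they need.  The Arabidopsis recipe filters sub-epidermal nuclei at
a variance-of-intensity threshold of 2**8.3 and fits volume + total
intensity with the lowest-mean component dropped; the Drosophila recipe
normalizes by a haploid reference population, fits normalized intensity +
projected area with an open-top class; the cardiomyocyte recipe hand-selects
labeled nuclei and uses a relative ladder.
"""

from __future__ import annotations

import copy

PRESETS: dict[str, dict] = {
    "arabidopsis_2d": {
        "filters": [
            {"op": "select_by_label", "exclude": ["incomplete", "merged"]},
            {
                "op": "threshold",
                "feature": "variance_of_intensity",
                "cutoff": 2 ** 8.3,
                "keep": "above",
            },
        ],
        "features": ["total_intensity", "size"],
        "mixture": {
            "k_range": [1, 8],
            "families": ["spherical", "diagonal"],
            "criterion": "bic",
        },
        "ladder": {
            "base_class": "2C",
            "drop_lowest": True,
            "open_top": False,
            "anchor_feature": "total_intensity",
        },
        "uncertainty": {"confident": 0.8, "second": 0.2},
    },
    "drosophila_2d": {
        "filters": [
            {"op": "select_by_label", "exclude": ["incomplete"]},
        ],
        "normalization": {
            "reference_label": "spermatid",
            "min_n": 10,
            "median_range": [2000, 6000],
            "band": [0.5, 1.5],
            "min_fraction": 0.9,
        },
        "features": ["normalized_intensity", "size"],
        "mixture": {
            "k_range": [1, 5],
            "families": ["spherical", "diagonal"],
            "criterion": "bic",
        },
        "ladder": {
            "base_class": "2C",
            "drop_lowest": True,
            "open_top": True,
            "anchor_feature": "normalized_intensity",
        },
        "uncertainty": {"confident": 0.8, "second": 0.2},
    },
    "cardiomyocyte_2d": {
        "filters": [
            {"op": "select_by_label", "include": ["cardiomyocyte"]},
        ],
        "features": ["total_intensity", "size"],
        "mixture": {
            "k_range": [1, 3],
            "families": ["spherical", "diagonal"],
            "criterion": "bic",
        },
        "ladder": {
            "base_class": "2αC",
            "drop_lowest": False,
            "open_top": False,
            "anchor_feature": "total_intensity",
        },
        "uncertainty": {"confident": 0.8, "second": 0.2},
    },
}


def make_config(
    preset: str,
    feature_table: str,
    output_dir: str,
    label_image: str | None = None,
    seed: int = 0,
    **overrides,
) -> dict:
    """Instantiate a preset into a runnable pipeline config."""
    if preset not in PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    config = copy.deepcopy(PRESETS[preset])
    config["input"] = {"feature_table": feature_table}
    if label_image:
        config["input"]["label_image"] = label_image
    config["output_dir"] = output_dir
    config["seed"] = seed
    config.update(overrides)
    return config
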
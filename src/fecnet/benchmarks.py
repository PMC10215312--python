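"""Published benchmark figures used as validation inputs.

These are the printed evaluation numbers of the study this package
re-implements: the four-class image inventory before augmentation, the
per-category accuracies of the twelve compared networks, and the aggregate
precision/recall rows of the per-model evaluation table.  They serve as
inputs for the statistical checks (metric identities, one-way ANOVA) — the
package never uses them to fabricate results.
"""

from __future__ import annotations

CLASS_NAMES = ("diarrhea", "lack_of_water", "normal", "soft_stool")

# Image inventory by class, before augmentation.
INVENTORY_COUNTS: dict[str, int] = {
    "lack_of_water": 482,
    "normal": 491,
    "soft_stool": 335,
    "diarrhea": 315,
}

# Per-category accuracy (%) of each network, order:
# (diarrhea, lack of water, normal, soft stool).
BASIC_NETWORK_ACCURACIES: dict[str, tuple[float, float, float, float]] = {
    "AlexNet": (65.87, 87.83, 58.73, 43.65),
    "VGG-16": (59.52, 75.13, 76.72, 43.65),
    "GoogleNet": (72.22, 71.95, 75.13, 55.56),
    "ResNet-50": (88.10, 85.19, 71.43, 80.95),
    "ResNeSt-50": (88.89, 93.12, 76.19, 77.78),
    "SCMNet": (89.68, 93.65, 78.84, 80.16),
    "MC-SCMNet": (93.65, 92.06, 85.71, 84.13),
}

STATE_OF_ART_ACCURACIES: dict[str, tuple[float, float, float, float]] = {
    "ResNeXt50": (87.30, 83.60, 73.54, 79.36),
    "B-ARNet": (90.48, 84.13, 85.19, 80.16),
    "DMS-Robust Alexnet": (88.89, 88.36, 80.95, 83.33),
    "Swin-transformer": (91.27, 90.48, 83.07, 81.75),
    "CA-MSNet": (89.68, 91.53, 82.54, 82.54),
}


def anova_groups() -> dict[str, tuple[float, float, float, float]]:
    """The twelve unique networks' per-category accuracies (no duplicates)."""
    groups = dict(BASIC_NETWORK_ACCURACIES)
    groups.update(STATE_OF_ART_ACCURACIES)
    return groups


# Aggregate (all-categories) precision and recall (%), per model.
AGGREGATE_PRECISION_RECALL: dict[str, tuple[float, float]] = {
    "ResNet50": (80.79, 81.16),
    "ResNeSt50": (84.13, 84.05),
    "MC-SCMNet": (88.89, 88.93),
}

# Reference trainable-parameter total of the 50-layer residual baseline with
# a 1000-class head, in millions.
BASELINE_PARAMS_M = 25.557
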
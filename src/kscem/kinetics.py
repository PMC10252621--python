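"""Enhancement-kinetics classification for contrast-enhanced mammography.

On CEM, lesion kinetics are quantified by placing a region of interest
(ROI) in the most homogeneous part of the lesion on the recombined images
acquired ~2 min (initial) and ~8 min (delayed) after contrast injection.
The change in mean ROI density classifies the lesion's enhancement
dynamics in analogy to MRI time-intensity curves:

* rise by more than 10 units      -> persistent  (MRI type I)
* change within +/- 10 units      -> plateau     (MRI type II)
* drop by more than 10 units      -> washout     (MRI type III)

ROI densities are dimensionless device units of the recombined image;
the 10-unit threshold is a parameter to allow sensitivity analysis.
A change of exactly 10 units is assigned to plateau (closed middle
interval) so the rule is total and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CURVE_TYPES",
    "MRI_KINETIC_CLASSES",
    "DEFAULT_KINETICS_THRESHOLD",
    "ROIPair",
    "classify_enhancement",
    "curve_type_from_mri_kinetics",
]

CURVE_TYPES: tuple[str, ...] = ("persistent", "plateau", "washout")

#: MRI dynamic curve types and their CEM equivalents.
MRI_KINETIC_CLASSES: dict[str, str] = {
    "typeI": "persistent",
    "typeII": "plateau",
    "typeIII": "washout",
}

DEFAULT_KINETICS_THRESHOLD = 10.0


@dataclass(frozen=True)
class ROIPair:
    """Mean ROI densities on the initial (~2 min) and delayed (~8 min)
    recombined CEM images, in device units."""

    initial_mean: float
    delayed_mean: float

    def __post_init__(self) -> None:
        for name in ("initial_mean", "delayed_mean"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    @property
    def delta(self) -> float:
        return self.delayed_mean - self.initial_mean


def classify_enhancement(
    roi: ROIPair, threshold: float = DEFAULT_KINETICS_THRESHOLD
) -> str:
    """Classify the delayed-phase curve type from an ROI density pair.

    Let ``d = delayed_mean - initial_mean``:
    ``d > threshold`` -> ``"persistent"``; ``d < -threshold`` ->
    ``"washout"``; otherwise (``|d| <= threshold``) -> ``"plateau"``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    d = roi.delta
    if d > threshold:
        return "persistent"
    if d < -threshold:
        return "washout"
    return "plateau"


def curve_type_from_mri_kinetics(kinetic_class: str) -> str:
    """Translate an MRI dynamic curve class (typeI/typeII/typeIII) into
    the persistent/plateau/washout vocabulary."""
    try:
        return MRI_KINETIC_CLASSES[kinetic_class]
    except KeyError:
        raise ValueError(
            f"unknown MRI kinetic class {kinetic_class!r}; "
            f"expected one of {sorted(MRI_KINETIC_CLASSES)}"
        ) from None
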
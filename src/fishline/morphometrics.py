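"""Length and weight estimation from bounding boxes.

Total length is approximated by the diagonal of the detection's bounding
box converted to centimeters through the camera calibration.  Weight
follows the allometric power law W = a L^b (W in grams, L in centimeters);
the packaged default parameters cover anchovy, jack mackerel, mackerel and
sardine.  The power law is defined for standard length (snout to hypural
crease) but is applied here to total length, since a bounding box cannot
localize the hypural crease; this substitution biases weights slightly
upward and is the standard field compromise for box-based measurement.

``fit_length_weight`` estimates (a, b) from paired (length, weight)
samples by ordinary least squares on the log-log scale, the standard
fisheries estimator for the power law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BoundingBox, CameraCalibration, SpeciesCatalog

__all__ = [
    "LengthWeightParams",
    "Morphometry",
    "estimate_length",
    "estimate_weight",
    "fit_length_weight",
    "measure",
]


@dataclass(frozen=True)
class LengthWeightParams:
    """Allometric coefficients: a in g cm^-b, b dimensionless."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("length-weight parameters must be > 0")


@dataclass(frozen=True)
class Morphometry:
    """Per-detection measurement: total length (cm) and optional weight (g)."""

    length_cm: float
    weight_g: float | None = None


def estimate_length(box: BoundingBox, cal: CameraCalibration) -> float:
    """Total length in cm: box diagonal times the cm-per-pixel factor."""
    return math.hypot(box.width, box.height) * cal.cm_per_pixel


def estimate_weight(length_cm: float, params: LengthWeightParams) -> float:
    """Weight in grams from the power law W = a L^b."""
    if length_cm <= 0:
        raise ValueError("length must be > 0")
    return params.a * length_cm ** params.b


def measure(
    box: BoundingBox, species: str, catalog: SpeciesCatalog, cal: CameraCalibration
) -> Morphometry:
    """Length plus, when the species has allometric parameters, weight."""
    length = estimate_length(box, cal)
    lw = catalog[species].lw_params
    if lw is None:
        return Morphometry(length_cm=length)
    return Morphometry(
        length_cm=length, weight_g=estimate_weight(length, LengthWeightParams(*lw))
    )


def fit_length_weight(
    samples: Sequence[tuple[float, float]]
) -> LengthWeightParams:
    """Least-squares fit of log W = log a + b log L.

    Requires at least 3 strictly positive samples and at least two distinct
    lengths (otherwise the slope is unidentifiable).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit the length-weight law")
    arr = np.asarray(samples, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("all lengths and weights must be > 0")
    log_l = np.log(arr[:, 0])
    log_w = np.log(arr[:, 1])
    if np.ptp(log_l) == 0:
        raise ValueError("all lengths equal; slope is unidentifiable")
    b, log_a = np.polyfit(log_l, log_w, 1)
    return LengthWeightParams(a=float(np.exp(log_a)), b=float(b))
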
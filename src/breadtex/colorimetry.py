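"""CIELAB colour analysis: replicate averaging, ΔE, perceptual bands, trend fits.

The primary colour-difference metric is the CIE76 Euclidean distance

    ΔE = sqrt(ΔL*^2 + Δa*^2 + Δb*^2)

classified into five perceptual bands.  CIEDE2000 is available as an
optional variant but is never the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "LabColor",
    "DeltaEResult",
    "TrendFit",
    "BAND_LABELS",
    "BAND_BOUNDARIES",
    "average_readings",
    "delta_e",
    "classify_delta_e",
    "band_lower_bound",
    "fit_color_trend",
]

#: Ordered perceptual band labels, lowest ΔE first.
BAND_LABELS = ("imperceptible", "slight", "noticeable", "substantial", "distinct")

#: Upper boundaries of all bands except the last (which is unbounded).
#: Bands are half-open: a boundary value belongs to the *upper* band.
BAND_BOUNDARIES = (1.0, 2.0, 3.5, 5.0)


@dataclass(frozen=True)
class LabColor:
    """A CIELAB triplet: lightness L* in [0, 100], chroma axes a* and b*."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"L* must lie in [0, 100], got {self.L!r}")
        for name in ("L", "a", "b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class DeltaEResult:
    """A colour difference magnitude and its perceptual band."""

    delta_e: float
    band_label: str

    def __post_init__(self) -> None:
        if self.delta_e < 0:
            raise ValueError("delta_e must be nonnegative")
        if self.band_label != classify_delta_e(self.delta_e):
            raise ValueError("band_label inconsistent with delta_e")


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line of a response against substitution level."""

    slope: float
    intercept: float
    pearson_r: float
    slope_se: float
    levels: tuple
    fitted: tuple

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")


def average_readings(readings: Iterable[LabColor]) -> LabColor:
    """Channel-wise arithmetic mean of one or more colour readings.

    Raises ``ValueError`` on an empty input.
    """
    arr = np.array([r.as_array() for r in readings], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty set of readings")
    mean = arr.mean(axis=0)
    return LabColor(L=float(mean[0]), a=float(mean[1]), b=float(mean[2]))


def classify_delta_e(value: float) -> str:
    """Map a ΔE magnitude to one of the five perceptual bands.

    Bands are half-open ``[0, 1), [1, 2), [2, 3.5), [3.5, 5), [5, inf)``;
    a value sitting exactly on a boundary belongs to the upper band.
    Negative input is rejected.
    """
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"ΔE must be a finite nonnegative number, got {value!r}")
    for label, upper in zip(BAND_LABELS, BAND_BOUNDARIES):
        if value < upper:
            return label
    return BAND_LABELS[-1]


def band_lower_bound(label: str) -> float:
    """Inclusive lower ΔE boundary of a named band (0.0 for the lowest band)."""
    if label not in BAND_LABELS:
        raise ValueError(f"unknown band {label!r}; expected one of {BAND_LABELS}")
    idx = BAND_LABELS.index(label)
    return 0.0 if idx == 0 else BAND_BOUNDARIES[idx - 1]


def delta_e(reference: LabColor, sample: LabColor, *, method: str = "cie76") -> DeltaEResult:
    """Total colour difference between two CIELAB colours.

    ``method="cie76"`` (default) is the Euclidean norm of the channel
    differences; ``method="ciede2000"`` applies the CIEDE2000 correction.
    Both are symmetric in their arguments and the result is always
    classified into a perceptual band.
    """
    if method == "cie76":
        diff = reference.as_array() - sample.as_array()
        value = float(np.sqrt(np.dot(diff, diff)))
    elif method == "ciede2000":
        from skimage.color import deltaE_ciede2000

        value = float(deltaE_ciede2000(reference.as_array(), sample.as_array()))
    else:
        raise ValueError(f"unknown method {method!r}; expected 'cie76' or 'ciede2000'")
    return DeltaEResult(delta_e=value, band_label=classify_delta_e(value))


def fit_color_trend(levels: Sequence[float], responses: Sequence[float]) -> TrendFit:
    """OLS fit of a colour channel (or ΔE) against substitution level.

    Requires at least three distinct levels with nonzero variance.  A
    constant response yields slope 0 with ``pearson_r`` defined as 0 by
    convention.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responses must be 1-D sequences of equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct substitution levels")
    if np.ptp(x) == 0:
        raise ValueError("levels have zero variance")

    if np.ptp(y) == 0:
        # Degenerate: flat response. slope/intercept exact, r set to 0.
        slope, intercept, r, slope_se = 0.0, float(y[0]), 0.0, 0.0
    else:
        res = _scipy_stats.linregress(x, y)
        slope, intercept, r, slope_se = (
            float(res.slope),
            float(res.intercept),
            float(res.rvalue),
            float(res.stderr),
        )
    fitted = tuple(float(slope * xi + intercept) for xi in x)
    return TrendFit(
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        slope_se=slope_se,
        levels=tuple(float(xi) for xi in x),
        fitted=fitted,
    )
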
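"""Torque-curve feature extraction for Chopin+-style mixing protocols.

A recorded run is a ``(time, torque, temperature)`` trace: an isothermal
mixing phase, a heating ramp, a hold at peak temperature, and cooling.
:func:`extract_parameters` recovers the standard landmark vector from such
a trace:

========== =====================================================
T_hydr     first crossing of ``hydration_fraction * C1`` (convention;
           the fraction is configurable and echoed in outputs)
T1, C1     time and value of the mixing-phase consistency maximum
amplitude  peak-to-peak width of the torque oscillation band at C1
stability  duration the smoothed torque stays within
           ``stability_tolerance`` below C1 (contiguous band around T1;
           may extend into early heating, as on real instruments)
slope_a    least-squares torque slope from heating onset to t(C2)
C2         minimum of the smoothed torque during early heating
slope_b    least-squares slope from t(C2) to T3
C3, T3     value and time of the gelatinization maximum on the ramp
gelling    dough temperature at the first crossing of the torque level
           ``(C2 + C3) / 2`` between t(C2) and T3
C4         minimum of the smoothed torque during the peak hold
C5         smoothed torque at the final sample (requires cooling phase)
========== =====================================================

All torque features are read off a *mid envelope* (rolling mean) so the
mixing oscillation and measurement noise do not leak into the landmarks;
the amplitude itself is estimated from the residual band around the mid
envelope near T1.

Water absorption cannot be recovered from a torque trace (it is the
instrument's dosing decision) and is carried through as metadata only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.ndimage import binary_closing, maximum_filter1d, minimum_filter1d, uniform_filter1d

__all__ = [
    "TorqueCurve",
    "MixolabParameters",
    "ExtractionConfig",
    "PhaseBoundaries",
    "DEFAULT_STABILITY_TOLERANCE",
    "smooth_envelope",
    "detect_phases",
    "extract_parameters",
]

#: Fraction of C1 defining the stability band; shared with the curve
#: generator so that stability round-trips by construction.
DEFAULT_STABILITY_TOLERANCE = 0.11

#: Fraction of C1 whose first crossing defines T_hydr (a convention; the
#: instrument literature gives no formula for it).
DEFAULT_HYDRATION_FRACTION = 0.5


@dataclass
class TorqueCurve:
    """Sampled (time, torque, temperature) trace for one run.

    time is in minutes and strictly increasing; torque in Nm (>= 0);
    temperature is the dough temperature in degrees C.  ``metadata`` may
    carry the water absorption percentage and protocol settings.
    """

    time: np.ndarray
    torque: np.ndarray
    temperature: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        n = self.time.size
        if not (self.torque.size == n == self.temperature.size):
            raise ValueError("time, torque and temperature must have equal length")
        if n < 2:
            raise ValueError("a curve needs at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time not increasing")
        if np.min(self.torque) < -1e-9:
            raise ValueError("torque must be nonnegative")
        for name, arr in (("time", self.time), ("torque", self.torque), ("temperature", self.temperature)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def dt(self) -> float:
        """Median sampling step in minutes."""
        return float(np.median(np.diff(self.time)))


@dataclass
class MixolabParameters:
    """The landmark vector of one run.

    Fields that cannot be determined (missing protocol phase, zero-torque
    record) are ``None``.  ``slope_alpha``/``slope_beta`` are reported in
    Nm/min.
    """

    t_hydr: Optional[float] = None
    t1: Optional[float] = None
    c1: Optional[float] = None
    water_absorption: Optional[float] = None
    amplitude: Optional[float] = None
    stability: Optional[float] = None
    slope_alpha: Optional[float] = None
    c2: Optional[float] = None
    slope_beta: Optional[float] = None
    c3: Optional[float] = None
    t3: Optional[float] = None
    gelling_mid: Optional[float] = None
    c4: Optional[float] = None
    c5: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)

    def check_ordering(self) -> None:
        """Validate the internal ordering constraints where defined."""
        if self.c1 is not None and self.c2 is not None and self.c2 > self.c1 + 1e-12:
            raise ValueError(f"C2 ({self.c2}) > C1 ({self.c1}): ordering violated")
        if self.c2 is not None and self.c3 is not None and self.c2 > self.c3 + 1e-12:
            raise ValueError(f"C2 ({self.c2}) > C3 ({self.c3}): ordering violated")
        if self.t1 is not None and self.t3 is not None and self.t1 > self.t3:
            raise ValueError(f"T1 ({self.t1}) > T3 ({self.t3}): ordering violated")


@dataclass
class ExtractionConfig:
    """Tunable conventions for :func:`extract_parameters`.

    The defaults match the synthetic-curve generator: the smoothing window
    equals one oscillation period so the rolling mean cancels the mixing
    oscillation exactly at the default 1 s sampling.
    """

    smoothing_window_min: float = 0.2
    landmark_window_min: float = 0.4
    stability_tolerance: float = DEFAULT_STABILITY_TOLERANCE
    hydration_fraction: float = DEFAULT_HYDRATION_FRACTION
    amplitude_window_min: float = 0.8
    dip_bridge_min: float = 0.2
    temp_tolerance_c: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.stability_tolerance < 1):
            raise ValueError("stability_tolerance must lie in (0, 1)")
        if not (0 < self.hydration_fraction < 1):
            raise ValueError("hydration_fraction must lie in (0, 1)")
        if min(self.smoothing_window_min, self.landmark_window_min, self.amplitude_window_min) <= 0:
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class PhaseBoundaries:
    """Sample indices delimiting the protocol phases found in a trace."""

    heating_onset: Optional[int]  # last isothermal index before the ramp
    ramp_end: Optional[int]  # first index at peak temperature
    hold_end: Optional[int]  # last index at peak temperature
    has_cooling: bool


def _window_samples(curve: TorqueCurve, window_min: float) -> int:
    n = max(1, int(round(window_min / curve.dt)))
    if n >= curve.time.size:
        raise ValueError(
            f"smoothing window ({window_min} min) must be shorter than the record"
        )
    return n


def smooth_envelope(
    curve: TorqueCurve, window_min: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolling (max, mean, min) of the torque over a centred window.

    Returns ``(upper, mid, lower)``; ``upper >= mid >= lower`` pointwise.
    The window must be shorter than the record.
    """
    size = _window_samples(curve, window_min)
    upper = maximum_filter1d(curve.torque, size=size, mode="nearest")
    mid = uniform_filter1d(curve.torque, size=size, mode="nearest")
    lower = minimum_filter1d(curve.torque, size=size, mode="nearest")
    return upper, mid, lower


def detect_phases(curve: TorqueCurve, temp_tolerance_c: float = 0.3) -> PhaseBoundaries:
    """Locate heating onset, ramp end, hold end from the temperature column."""
    temp = curve.temperature
    start = temp[0]
    above = np.flatnonzero(temp > start + temp_tolerance_c)
    if above.size == 0:
        return PhaseBoundaries(None, None, None, False)
    onset = int(max(0, above[0] - 1))
    peak = float(temp.max())
    at_peak = np.flatnonzero(temp >= peak - temp_tolerance_c)
    ramp_end = int(at_peak[0])
    hold_end = int(at_peak[-1])
    has_cooling = hold_end < temp.size - 1 and temp[-1] < peak - temp_tolerance_c
    return PhaseBoundaries(onset, ramp_end, hold_end, has_cooling)


def _ls_slope(t: np.ndarray, y: np.ndarray) -> Optional[float]:
    if t.size < 2 or np.ptp(t) == 0:
        return None
    return float(np.polyfit(t, y, 1)[0])


def _band_duration(time: np.ndarray, inside: np.ndarray, anchor: int) -> float:
    """Length (min) of the contiguous True run of ``inside`` containing ``anchor``."""
    if not inside[anchor]:
        return 0.0
    lo = anchor
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = anchor
    while hi < inside.size - 1 and inside[hi + 1]:
        hi += 1
    return float(time[hi] - time[lo])


def _estimate_amplitude(
    curve: TorqueCurve, mid: np.ndarray, t1_idx: int, window_min: float
) -> float:
    """Peak-to-peak oscillation amplitude near T1.

    Estimated as ``2*sqrt(2) * std`` of the residual ``torque - mid`` over a
    trailing window ending at T1 — exact for a sinusoidal band spanning
    whole periods, and far more noise-robust than a raw max-minus-min.
    """
    t = curve.time
    lo = np.searchsorted(t, t[t1_idx] - window_min)
    resid = curve.torque[lo : t1_idx + 1] - mid[lo : t1_idx + 1]
    if resid.size < 4:
        return 0.0
    return float(2.0 * math.sqrt(2.0) * resid.std())


def extract_parameters(
    curve: TorqueCurve, config: ExtractionConfig | None = None
) -> MixolabParameters:
    """Recover the landmark vector from a torque/temperature trace.

    Missing protocol phases yield a partial result: ramp features need a
    temperature rise, C4 needs a peak hold, C5 needs a cooling phase.  A
    record with zero torque throughout reports ``c1 = 0`` with the other
    torque features zeroed and the times absent.
    """
    config = config or ExtractionConfig()
    phases = detect_phases(curve, config.temp_tolerance_c)
    _, mid, _ = smooth_envelope(curve, config.smoothing_window_min)
    # Torque *values* come from the lightly smoothed mid envelope; time
    # landmarks (argmax/argmin positions, band edges) from a heavier
    # smoothing that keeps noise from shifting flat extrema.
    heavy = uniform_filter1d(
        curve.torque, size=_window_samples(curve, config.landmark_window_min), mode="nearest"
    )
    t = curve.time

    if phases.heating_onset is None:
        warnings.warn("no temperature rise found; only mixing-phase features extracted")

    mix_end = phases.heating_onset if phases.heating_onset is not None else t.size - 1

    out = MixolabParameters(
        water_absorption=curve.metadata.get("water_absorption")
    )

    t1_idx = int(np.argmax(heavy[: mix_end + 1]))
    c1 = float(np.max(mid[: mix_end + 1]))
    out.c1 = c1
    if c1 <= 0.0:
        out.amplitude = 0.0
        out.stability = 0.0
        for name in ("c2", "c3", "c4", "c5", "slope_alpha", "slope_beta"):
            setattr(out, name, 0.0)
        return out

    out.t1 = float(t[t1_idx])
    above_h = np.flatnonzero(mid >= config.hydration_fraction * c1)
    out.t_hydr = float(t[above_h[0]]) if above_h.size else None
    out.amplitude = _estimate_amplitude(curve, mid, t1_idx, config.amplitude_window_min)

    # Stability: contiguous band around T1 where the smoothed torque stays
    # within the tolerance below C1.  Measured over the whole record — on
    # strong doughs the band outlasts the isothermal mixing phase.  Noise
    # dips shorter than dip_bridge_min are bridged before measuring.
    threshold = (1.0 - config.stability_tolerance) * c1
    inside = heavy >= threshold
    bridge = max(1, int(round(config.dip_bridge_min / curve.dt)))
    inside = binary_closing(inside, structure=np.ones(bridge, dtype=bool))
    out.stability = _band_duration(t, inside, t1_idx)

    if phases.heating_onset is None:
        return out

    onset, ramp_end = phases.heating_onset, phases.ramp_end
    ramp = slice(onset, ramp_end + 1)
    c2_idx = onset + int(np.argmin(heavy[ramp]))
    out.c2 = float(np.min(mid[ramp]))
    out.slope_alpha = _ls_slope(t[onset : c2_idx + 1], mid[onset : c2_idx + 1])

    c3_idx = c2_idx + int(np.argmax(heavy[c2_idx : ramp_end + 1]))
    out.c3 = float(np.max(mid[c2_idx : ramp_end + 1]))
    out.t3 = float(t[c3_idx])
    out.slope_beta = _ls_slope(t[c2_idx : c3_idx + 1], mid[c2_idx : c3_idx + 1])

    if out.c3 > out.c2 + 1e-12:
        level = 0.5 * (out.c2 + out.c3)
        seg = mid[c2_idx : c3_idx + 1]
        cross = np.flatnonzero(seg >= level)
        if cross.size:
            j = c2_idx + int(cross[0])
            if j > c2_idx and mid[j] > mid[j - 1]:
                # linear interpolation of the crossing time, then of temperature
                frac = (level - mid[j - 1]) / (mid[j] - mid[j - 1])
                tc = t[j - 1] + frac * (t[j] - t[j - 1])
                out.gelling_mid = float(np.interp(tc, t, curve.temperature))
            else:
                out.gelling_mid = float(curve.temperature[j])

    if phases.hold_end is not None and phases.hold_end > ramp_end:
        hold = slice(ramp_end, phases.hold_end + 1)
        out.c4 = float(np.min(mid[hold]))

    if phases.has_cooling:
        out.c5 = float(mid[-1])

    return out
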
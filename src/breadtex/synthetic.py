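"""Ground-truthed synthetic inputs for every analysis stage.

Three generators, all bit-stable under a fixed seed:

- :func:`generate_crumb_image` -- Boolean pore scenes: darker disks placed
  inside an elliptical "slice" on a pure white background, with known
  per-pore areas and a label mask.
- :func:`generate_torque_curve` -- phenomenological Chopin+-style torque
  traces built by monotone piecewise-cubic interpolation through the
  anchor points implied by a landmark parameter vector, so that
  :func:`breadtex.mixolab.extract_parameters` round-trips the inputs.
- :func:`generate_color_readings` -- Gaussian replicate CIELAB readings
  around per-group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from breadtex.colorimetry import LabColor
from breadtex.mixolab import (
    DEFAULT_HYDRATION_FRACTION,
    DEFAULT_STABILITY_TOLERANCE,
    MixolabParameters,
    TorqueCurve,
)

__all__ = [
    "CrumbSceneSpec",
    "CrumbGroundTruth",
    "ChopinProtocol",
    "generate_crumb_image",
    "generate_torque_curve",
    "generate_color_readings",
    "random_parameters",
]


# ---------------------------------------------------------------------------
# Crumb scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrumbSceneSpec:
    """Recipe for one synthetic crumb scene.

    ``slice_axes`` are the semi-axes (col, row) in pixels of the elliptical
    bread-slice region, centred in the image.  Pores are disks with
    lognormally distributed radii (``pore_radius_median`` px, shape
    ``pore_radius_sigma``), strictly darker than the matrix.
    """

    image_width: int = 600
    image_height: int = 450
    slice_axes: tuple[float, float] = (260.0, 190.0)
    n_pores: int = 40
    pore_radius_median: float = 9.0
    pore_radius_sigma: float = 0.25
    allow_overlap: bool = False
    matrix_intensity: int = 170
    pore_intensity: int = 50
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pores < 0:
            raise ValueError("n_pores must be >= 0")
        if self.pore_intensity >= self.matrix_intensity:
            raise ValueError("pore_intensity must be darker than matrix_intensity")
        if self.pore_radius_median <= 0:
            raise ValueError("pore radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.illumination_gradient < 1):
            raise ValueError("illumination_gradient must lie in [0, 1)")
        if min(self.slice_axes) <= 0:
            raise ValueError("slice axes must be positive")
        if not (0 <= self.pore_intensity and self.matrix_intensity <= 255):
            raise ValueError("intensities must lie in [0, 255]")


@dataclass
class CrumbGroundTruth:
    """Noise-free truth for a generated scene.

    ``label_mask`` assigns every pore pixel its region id (0 = matrix or
    background); ``region_table`` has one row per pore (region_id, area_px,
    centroid_row, centroid_col, radius_px).
    """

    label_mask: np.ndarray
    region_table: pd.DataFrame
    n_pores: int
    slice_mask: np.ndarray


def _ellipse_mask(h: int, w: int, ax_col: float, ax_row: float) -> np.ndarray:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ax_row) ** 2 + ((xx - cx) / ax_col) ** 2 <= 1.0


def _place_pores(spec: CrumbSceneSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample (row, col, radius) triplets inside the slice ellipse."""
    h, w = spec.image_height, spec.image_width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ax_col, ax_row = spec.slice_axes
    placed: list[tuple[float, float, float]] = []
    max_attempts = 2000 * max(1, spec.n_pores)
    attempts = 0
    while len(placed) < spec.n_pores:
        if attempts >= max_attempts:
            raise ValueError(
                f"scene too crowded: placed {len(placed)}/{spec.n_pores} pores "
                f"after {attempts} attempts"
            )
        attempts += 1
        r = float(rng.lognormal(mean=math.log(spec.pore_radius_median), sigma=spec.pore_radius_sigma))
        # shrink the ellipse so the disk stays fully inside the slice
        ar, ac = ax_row - r - 1.0, ax_col - r - 1.0
        if ar <= 0 or ac <= 0:
            continue
        row = cy + (rng.uniform(-1, 1)) * ax_row
        col = cx + (rng.uniform(-1, 1)) * ax_col
        if ((row - cy) / ar) ** 2 + ((col - cx) / ac) ** 2 > 1.0:
            continue
        if not spec.allow_overlap:
            # +2.5 px margin keeps rasterized disks 8-connectivity separated
            if any(
                math.hypot(row - r0, col - c0) < r + rr + 2.5
                for r0, c0, rr in placed
            ):
                continue
        placed.append((row, col, r))
    return placed


def generate_crumb_image(spec: CrumbSceneSpec) -> tuple[np.ndarray, CrumbGroundTruth]:
    """Rasterize a crumb scene; returns ``(image, ground_truth)``.

    The image is 8-bit greyscale: pure white (255) outside the slice
    ellipse (emulating background removal), ``matrix_intensity`` inside,
    pores as darker disks.  An optional linear illumination gradient and
    additive Gaussian noise are applied within the slice only, after
    rasterization; the ground truth reflects the noise-free label mask.
    Identical specs produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    slice_mask = _ellipse_mask(h, w, *spec.slice_axes)
    label_mask = np.zeros((h, w), dtype=np.uint16)

    pores = _place_pores(spec, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for idx, (row, col, r) in enumerate(pores, start=1):
        disk = (yy - row) ** 2 + (xx - col) ** 2 <= r * r
        label_mask[disk] = idx
    # region table from the final mask so overlaps are accounted exactly
    for idx, (row, col, r) in enumerate(pores, start=1):
        sel = label_mask == idx
        area = int(sel.sum())
        if area:
            cy_px = float(yy[sel].mean())
            cx_px = float(xx[sel].mean())
        else:  # fully overwritten by a later overlapping pore
            cy_px, cx_px = float("nan"), float("nan")
        rows.append(
            {
                "region_id": idx,
                "area_px": area,
                "centroid_row": cy_px,
                "centroid_col": cx_px,
                "radius_px": r,
            }
        )
    region_table = pd.DataFrame(
        rows, columns=["region_id", "area_px", "centroid_row", "centroid_col", "radius_px"]
    )

    image = np.full((h, w), 255.0)
    image[slice_mask] = spec.matrix_intensity
    image[label_mask > 0] = spec.pore_intensity
    if spec.illumination_gradient > 0:
        shade = 1.0 - spec.illumination_gradient * (xx / max(1, w - 1))
        image[slice_mask] *= shade[slice_mask]
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(h, w))
        image[slice_mask] += noise[slice_mask]
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    truth = CrumbGroundTruth(
        label_mask=label_mask,
        region_table=region_table,
        n_pores=spec.n_pores,
        slice_mask=slice_mask,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Torque curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChopinProtocol:
    """Piecewise-linear temperature schedule of a Chopin+-style run.

    Defaults: 8 min isothermal mixing at 30 °C, heating at 4 °C/min to
    90 °C, 7 min hold, cooling at 4 °C/min to 50 °C, final hold — 45 min
    total.  All segments are configurable.
    """

    mix_speed_rpm: float = 80.0
    start_temp: float = 30.0
    hold_minutes_at_start: float = 8.0
    heat_rate: float = 4.0
    peak_temp: float = 90.0
    hold_minutes_at_peak: float = 7.0
    cool_rate: float = 4.0
    cool_to: float = 50.0
    total_minutes: float = 45.0
    sampling_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.total_minutes <= 0:
            raise ValueError("total_minutes must be positive")
        if self.heat_rate <= 0:
            raise ValueError("heat_rate must be positive")
        if self.peak_temp <= self.start_temp:
            raise ValueError("peak_temp must exceed start_temp")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.ramp_end_min + self.hold_minutes_at_peak >= self.total_minutes:
            raise ValueError("temperature schedule does not fit in total_minutes")

    @property
    def heating_onset_min(self) -> float:
        return self.hold_minutes_at_start

    @property
    def ramp_end_min(self) -> float:
        return self.hold_minutes_at_start + (self.peak_temp - self.start_temp) / self.heat_rate

    @property
    def hold_end_min(self) -> float:
        return self.ramp_end_min + self.hold_minutes_at_peak

    def temperature_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        temp = np.full_like(t, self.start_temp)
        ramp = (t >= self.heating_onset_min) & (t < self.ramp_end_min)
        temp[ramp] = self.start_temp + self.heat_rate * (t[ramp] - self.heating_onset_min)
        hold = (t >= self.ramp_end_min) & (t <= self.hold_end_min)
        temp[hold] = self.peak_temp
        cool = t > self.hold_end_min
        temp[cool] = np.maximum(
            self.cool_to, self.peak_temp - self.cool_rate * (t[cool] - self.hold_end_min)
        )
        return temp

    def ramp_time_of_temperature(self, temp_c: float) -> float:
        """Time (min) at which the heating ramp reaches ``temp_c``."""
        if not (self.start_temp < temp_c <= self.peak_temp):
            raise ValueError(
                f"temperature {temp_c} °C is not reached on the ramp "
                f"({self.start_temp}..{self.peak_temp} °C)"
            )
        return self.heating_onset_min + (temp_c - self.start_temp) / self.heat_rate


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


# Shape constants for the generated curve.  The stability-band edges get
# "shoulder" anchors (offset min, Nm) so the threshold crossings are steep
# enough to be located under measurement noise; the C1/C3 peaks get
# support anchors that give the maxima a defined curvature instead of a
# noise-ambiguous flat top.
_BAND_SHOULDER = (0.2, 0.04)
_PEAK_SUPPORT_T1 = (0.3, 0.03)
_PEAK_SUPPORT_T3 = (0.5, 0.05)


def _anchor_times(
    params: MixolabParameters,
    protocol: ChopinProtocol,
    stability_tolerance: float,
) -> dict[str, float]:
    """Derive and validate all anchor times for the curve generator."""
    p = params
    for name in ("t_hydr", "t1", "c1", "stability", "c2", "c3", "t3", "gelling_mid", "c4", "c5"):
        _require(getattr(p, name) is not None, f"parameter {name} is required by the generator")

    onset = protocol.heating_onset_min
    _require(p.t_hydr > 0, f"T_hydr ({p.t_hydr}) must be positive")
    _require(p.t_hydr < p.t1, f"T1 ({p.t1}) must exceed T_hydr ({p.t_hydr}): anchor ordering violated")
    _require(p.t1 < onset, f"T1 ({p.t1}) must fall inside the mixing phase (< {onset} min)")
    _require(p.c1 > 0, "C1 must be positive")
    _require(p.c2 <= p.c1, f"C2 ({p.c2}) > C1 ({p.c1}): ordering violated")
    _require(p.c2 <= p.c3, f"C2 ({p.c2}) > C3 ({p.c3}): ordering violated")
    _require(p.c3 > p.c2, f"C3 ({p.c3}) must strictly exceed C2 ({p.c2}) for a gelling mid-point")
    _require(
        p.c2 < (1.0 - stability_tolerance) * p.c1,
        f"C2 ({p.c2}) must lie below the stability band (1-tol)*C1",
    )
    _require(p.c4 <= p.c3, f"C4 ({p.c4}) > C3 ({p.c3}): ordering violated")
    _require(p.c4 <= p.c5, f"C4 ({p.c4}) > C5 ({p.c5}): the cooled torque cannot undercut C4")

    band_d, band_h = _BAND_SHOULDER
    d1, _ = _PEAK_SUPPORT_T1
    d3, h3 = _PEAK_SUPPORT_T3
    thr = (1.0 - stability_tolerance) * p.c1
    _require(0.5 * p.c1 < thr - band_h, "hydration level must lie below the stability band shoulder")
    _require(
        p.c1 - _PEAK_SUPPORT_T1[1] > thr + band_h,
        f"C1 ({p.c1}) too small for the stability tolerance band shape",
    )
    _require(p.c2 < thr - band_h, f"C2 ({p.c2}) must lie below the stability band shoulder")
    _require(p.c3 - p.c2 > 2 * h3, f"C3 - C2 ({p.c3 - p.c2:.3f}) too small for a defined gelling crossing")
    _require(p.c4 <= p.c3 - h3, f"C4 ({p.c4}) too close to C3 ({p.c3}) for a defined T3 peak")

    t_mid = protocol.ramp_time_of_temperature(p.gelling_mid)
    _require(
        t_mid < p.t3 - d3 - 0.05,
        f"T3 ({p.t3}) must follow the gelling mid-point crossing ({t_mid:.2f} min)",
    )
    _require(
        p.t3 < protocol.ramp_end_min - d3,
        f"T3 ({p.t3}) must precede the end of the ramp ({protocol.ramp_end_min:.2f} min)",
    )

    lower = max(p.t_hydr, p.t1 - p.stability)
    upper = min(p.t1, t_mid - p.stability)
    _require(
        lower < upper,
        f"stability ({p.stability} min) cannot be realized between T_hydr, T1 and "
        f"the gelling crossing: empty window [{lower:.2f}, {upper:.2f}]",
    )
    t_s = 0.5 * (lower + upper)
    t_e = t_s + p.stability
    t_c2 = 0.5 * (t_e + t_mid)
    edge = band_d + 0.05
    _require(p.t_hydr < t_s - edge, f"T_hydr ({p.t_hydr}) too close to the stability band start ({t_s:.2f})")
    _require(t_s + edge < p.t1 - d1, f"stability band start ({t_s:.2f}) too close to T1 ({p.t1})")
    _require(p.t1 + d1 < t_e - edge, f"T1 ({p.t1}) too close to the stability band end ({t_e:.2f})")
    _require(t_e + edge < t_c2, f"stability band end ({t_e:.2f}) too close to the C2 trough ({t_c2:.2f})")
    _require(protocol.hold_minutes_at_peak > 0, "protocol needs a peak-temperature hold")
    t_c4 = protocol.ramp_end_min + 0.5 * protocol.hold_minutes_at_peak
    _require(p.t3 + d3 < t_c4, f"T3 ({p.t3}) too close to the hold-phase trough ({t_c4:.2f})")
    return {
        "t_s": t_s,
        "t_e": t_e,
        "t_c2": t_c2,
        "t_mid": t_mid,
        "t_c4": t_c4,
    }


def generate_torque_curve(
    params: MixolabParameters,
    protocol: ChopinProtocol | None = None,
    oscillation_amplitude: Optional[float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    oscillation_period_min: float = 0.2,
    stability_tolerance: float = DEFAULT_STABILITY_TOLERANCE,
    hydration_fraction: float = DEFAULT_HYDRATION_FRACTION,
) -> TorqueCurve:
    """Build a torque/temperature trace that realizes a landmark vector.

    The smoothed curve passes through the anchors implied by ``params``
    (C1 at T1, minimum C2 during early heating, maximum C3 at T3, the
    ``(C2+C3)/2`` torque level crossing exactly where the ramp temperature
    equals ``gelling_mid``, minimum C4 mid-hold, C5 at the end), connected
    by monotone piecewise cubics.  The smoothed plateau stays above
    ``(1 - stability_tolerance) * C1`` for exactly ``stability`` minutes.
    A zero-mean sinusoid of peak-to-peak ``oscillation_amplitude``
    (default: ``params.amplitude``) is superimposed during the mixing
    phase; its period equals the extractor's default smoothing window so a
    rolling mean cancels it exactly at 1 s sampling.

    ``slope_alpha``/``slope_beta`` in ``params`` are ignored: the slopes
    are consequences of the anchor geometry, not free inputs.

    Inconsistent parameters raise ``ValueError`` naming the violated
    ordering.  Same inputs and seed give a bit-identical curve.
    """
    protocol = protocol or ChopinProtocol()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    anchors_t = _anchor_times(params, protocol, stability_tolerance)

    dt = protocol.sampling_interval_s / 60.0
    n = int(round(protocol.total_minutes / dt)) + 1
    time = np.arange(n) * dt

    def snap(t: float) -> float:
        return round(t / dt) * dt

    thr = (1.0 - stability_tolerance) * params.c1
    band_d, band_h = _BAND_SHOULDER
    d1, h1 = _PEAK_SUPPORT_T1
    d3, h3 = _PEAK_SUPPORT_T3
    t_s, t_e = anchors_t["t_s"], anchors_t["t_e"]
    knots = [
        (0.0, 0.0),
        (snap(params.t_hydr), hydration_fraction * params.c1),
        (snap(t_s - band_d), thr - band_h),
        (snap(t_s), thr),
        (snap(t_s + band_d), thr + band_h),
        (snap(params.t1 - d1), params.c1 - h1),
        (snap(params.t1), params.c1),
        (snap(params.t1 + d1), params.c1 - h1),
        (snap(t_e - band_d), thr + band_h),
        (snap(t_e), thr),
        (snap(t_e + band_d), thr - band_h),
        (snap(anchors_t["t_c2"]), params.c2),
        (snap(anchors_t["t_mid"]), 0.5 * (params.c2 + params.c3)),
        (snap(params.t3 - d3), params.c3 - h3),
        (snap(params.t3), params.c3),
        (snap(params.t3 + d3), params.c3 - h3),
        (snap(anchors_t["t_c4"]), params.c4),
        (snap(protocol.total_minutes), params.c5),
    ]
    kt = np.array([k[0] for k in knots])
    kv = np.array([k[1] for k in knots])
    if not np.all(np.diff(kt) > 0):
        raise ValueError("anchor times collide after snapping to the sampling grid")
    torque = PchipInterpolator(kt, kv)(time)

    amp = params.amplitude if oscillation_amplitude is None else oscillation_amplitude
    if amp:
        mixing = time < protocol.heating_onset_min
        torque[mixing] += 0.5 * amp * np.sin(2.0 * np.pi * time[mixing] / oscillation_period_min)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        torque = torque + rng.normal(0.0, noise_sd, size=n)
    torque = np.clip(torque, 0.0, None)

    metadata = {
        "water_absorption": params.water_absorption,
        "protocol": asdict(protocol),
        "stability_tolerance": stability_tolerance,
        "hydration_fraction": hydration_fraction,
        "oscillation_period_min": oscillation_period_min,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return TorqueCurve(
        time=time,
        torque=torque,
        temperature=protocol.temperature_at(time),
        metadata=metadata,
    )


def random_parameters(
    rng: np.random.Generator, protocol: ChopinProtocol | None = None
) -> MixolabParameters:
    """Draw a random landmark vector that the generator accepts.

    Ranges bracket typical wheat/composite-flour runs.  Used by the
    round-trip recovery tests; resamples internally until the stability
    band keeps clear of the heating onset (where the oscillation cutoff
    would blur the band edge).
    """
    protocol = protocol or ChopinProtocol()
    onset = protocol.heating_onset_min
    for _ in range(1000):
        t_hydr = float(rng.uniform(1.0, 4.5))
        t1 = float(rng.uniform(t_hydr + 1.2, onset - 0.5))
        stability = float(rng.uniform(4.5, 7.4))
        gelling = float(rng.uniform(63.0, 70.5))
        t_mid = protocol.ramp_time_of_temperature(gelling)
        t3 = float(rng.uniform(t_mid + 2.0, protocol.ramp_end_min - 0.3))
        c1 = float(rng.uniform(0.9, 1.3))
        c2 = float(rng.uniform(0.35, min(0.65, 0.8 * (1 - DEFAULT_STABILITY_TOLERANCE) * c1)))
        c3 = float(rng.uniform(1.4, 1.9))
        c4 = float(rng.uniform(1.0, min(1.35, c3 - 0.1)))
        c5 = float(rng.uniform(c4 + 0.2, 2.4))
        amplitude = float(rng.uniform(0.05, 0.14))
        params = MixolabParameters(
            t_hydr=t_hydr,
            t1=t1,
            c1=c1,
            water_absorption=float(rng.uniform(58.0, 68.0)),
            amplitude=amplitude,
            stability=stability,
            c2=c2,
            c3=c3,
            t3=t3,
            gelling_mid=gelling,
            c4=c4,
            c5=c5,
        )
        try:
            anchors = _anchor_times(params, protocol, DEFAULT_STABILITY_TOLERANCE)
        except ValueError:
            continue
        if abs(anchors["t_e"] - onset) < 0.6:
            continue
        return params
    raise RuntimeError("failed to draw feasible parameters")  # pragma: no cover


# ---------------------------------------------------------------------------
# Colour replicates
# ---------------------------------------------------------------------------

def generate_color_readings(
    group_means: Mapping[str, LabColor] | Sequence[LabColor],
    sd: float | Sequence[float],
    n_replicates: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian replicate readings around each group's mean colour.

    Returns a table with columns ``group, replicate, L, a, b``; per
    channel, each reading is a draw from N(mean, sd).  L* is clipped into
    [0, 100] to keep readings valid.  Deterministic under ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sds = np.broadcast_to(np.asarray(sd, dtype=float), (3,)).copy()
    if np.any(sds < 0):
        raise ValueError("sd must be >= 0")
    if not isinstance(group_means, Mapping):
        group_means = {f"group{i + 1}": m for i, m in enumerate(group_means)}

    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in group_means.items():
        base = mean.as_array()
        draws = base + rng.normal(0.0, 1.0, size=(n_replicates, 3)) * sds
        draws[:, 0] = np.clip(draws[:, 0], 0.0, 100.0)
        for rep in range(n_replicates):
            rows.append(
                {
                    "group": group,
                    "replicate": rep + 1,
                    "L": float(draws[rep, 0]),
                    "a": float(draws[rep, 1]),
                    "b": float(draws[rep, 2]),
                }
            )
    return pd.DataFrame(rows, columns=["group", "replicate", "L", "a", "b"])
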
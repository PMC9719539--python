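"""Actin flow from kymographs, Fab kinetics, and activated-integrin counting.

Actin retrograde flow is read out as the slope of bright ridges in a
(time x position) kymograph sampled along a line across the cell edge:
ridge points are detected as per-row local maxima, linked into ridges,
and each ridge fit by least squares; slopes convert to nm/s through the
pixel size and frame interval.

Fab exchange kinetics come from injection/washout traces: the bound
signal rises as ``1 - exp(-k_obs t)`` with ``k_obs = k_on C + k_off``
during injection and decays as ``exp(-k_off t)`` after washout, so one
trace at known concentration yields both rate constants.

Counting conformation-reporter Fabs bound under a cell uses the same
single-fluorophore calibration contract as TGT rupture counting:
background-subtracted integrated intensity over the ROI divided by the
single-Fab intensity (bound-Fab densities exceed single-spot
resolvability, so whole-ROI integration is used rather than spot
detection). The derived per-integrin rupture-rate statistic is plain
arithmetic on a rupture total, an activated-integrin count and a
duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .calibration import CalibrationResult
from .synth import ImageStack

__all__ = [
    "KymographFit",
    "FabKinetics",
    "ActivatedIntegrinCount",
    "extract_kymograph",
    "fit_kymograph_speed",
    "fit_fab_kinetics",
    "count_bound_fabs",
    "rupture_rate_per_activated_integrin",
]


@dataclass
class KymographFit:
    """Per-ridge flow speeds from a kymograph linear fit."""

    speeds: np.ndarray        # nm/s per ridge (magnitudes)
    mean: float               # nm/s
    se: float                 # nm/s
    n_ridges: int
    px_per_frame_scale: float  # nm/s per (px/frame)


@dataclass
class FabKinetics:
    """Mono-exponential Fab binding/dissociation fit."""

    k_obs: float              # 1/s, rise rate during injection
    k_off: float              # 1/s, decay rate after washout
    plateau: float            # fitted steady-state intensity
    concentration: float      # M, as supplied
    converged: bool = True
    diagnostics: str = ""

    @property
    def k_on(self) -> float:
        """Association rate constant in 1/(M s), from k_obs = k_on C + k_off."""
        if self.concentration <= 0:
            raise ValueError("k_on requires a positive concentration")
        return (self.k_obs - self.k_off) / self.concentration


@dataclass
class ActivatedIntegrinCount:
    """Bound-Fab count per cell and areal density."""

    n_bound: float            # molecules
    density: float            # molecules / um^2
    area_um2: float
    calibration: CalibrationResult


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------


def extract_kymograph(
    stack: Union[ImageStack, np.ndarray],
    start: Tuple[float, float],
    end: Tuple[float, float],
    width: int = 3,
) -> np.ndarray:
    """Sample a (time x position) kymograph along a line segment.

    Intensity is sampled at unit-pixel spacing along the segment from
    ``start`` to ``end`` (row, col) and averaged across ``width``
    parallel lines perpendicular to it, which reduces noise roughly as
    sqrt(width). Raises when the line (including the width band) leaves
    the frame.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if width < 1:
        raise ValueError("width must be >= 1 px")
    h, w = data.shape[1], data.shape[2]
    r0, c0 = start
    r1, c1 = end
    length = math.hypot(r1 - r0, c1 - c0)
    if length < 2:
        raise ValueError("line segment too short")
    n_samples = int(round(length)) + 1
    t_par = np.linspace(0.0, 1.0, n_samples)
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    # unit normal
    nr, nc = -uc, ur
    offsets = np.arange(width) - (width - 1) / 2.0
    rows = r0 + t_par * (r1 - r0)
    cols = c0 + t_par * (c1 - c0)
    all_r = rows[None, :] + offsets[:, None] * nr
    all_c = cols[None, :] + offsets[:, None] * nc
    if (all_r.min() < 0 or all_r.max() > h - 1 or
            all_c.min() < 0 or all_c.max() > w - 1):
        raise ValueError("kymograph line (with width band) leaves the frame")
    kymo = np.empty((data.shape[0], n_samples))
    coords = np.stack([all_r.ravel(), all_c.ravel()])
    for t in range(data.shape[0]):
        vals = ndimage.map_coordinates(data[t], coords, order=1)
        kymo[t] = vals.reshape(width, n_samples).mean(axis=0)
    return kymo


def _detect_row_maxima(row: np.ndarray, threshold: float) -> List[float]:
    """Sub-pixel local maxima above threshold (3-point parabolic refine)."""
    out: List[float] = []
    for i in range(1, row.size - 1):
        if row[i] >= row[i - 1] and row[i] > row[i + 1] and row[i] > threshold:
            denom = row[i - 1] - 2 * row[i] + row[i + 1]
            delta = 0.5 * (row[i - 1] - row[i + 1]) / denom if denom < 0 else 0.0
            out.append(i + float(np.clip(delta, -0.5, 0.5)))
    return out


def fit_kymograph_speed(
    kymograph: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    gate_px: float = 3.0,
    min_ridge_rows: int = 10,
    threshold_rel: float = 0.3,
) -> KymographFit:
    """Flow speed from linear fits to kymograph ridges.

    Per time row, ridge points are sub-pixel local maxima above
    ``threshold_rel`` of the background-subtracted row amplitude;
    points are linked across rows under a ``gate_px`` jump limit, and
    each ridge with at least ``min_ridge_rows`` points is fit by least
    squares. Slopes (px/frame) convert to nm/s via
    ``pixel_size * 1000 / frame_interval``; speeds are reported as
    magnitudes. Invariant to intensity rescaling of the kymograph.
    Raises when no ridge is found.
    """
    kymo = np.asarray(kymograph, dtype=np.float64)
    bg = float(np.median(kymo))
    amp = kymo.max() - bg
    if amp <= 0:
        raise ValueError("no ridges detectable: kymograph is flat")
    threshold = bg + threshold_rel * amp

    ridges: List[List[Tuple[int, float]]] = []
    open_ridges: List[List[Tuple[int, float]]] = []
    for t in range(kymo.shape[0]):
        positions = _detect_row_maxima(kymo[t], threshold)
        claimed: set[int] = set()
        still_open: List[List[Tuple[int, float]]] = []
        for ridge in open_ridges:
            last_t, last_x = ridge[-1]
            best_j, best_d = -1, gate_px
            for j, x in enumerate(positions):
                if j in claimed:
                    continue
                d = abs(x - last_x)
                if d <= best_d:
                    best_j, best_d = j, d
            if best_j >= 0:
                ridge.append((t, positions[best_j]))
                claimed.add(best_j)
                still_open.append(ridge)
            elif t - last_t <= 2:
                still_open.append(ridge)    # allow a short dropout
            else:
                ridges.append(ridge)
        open_ridges = still_open
        for j, x in enumerate(positions):
            if j not in claimed:
                open_ridges.append([(t, x)])
    ridges.extend(open_ridges)

    scale = pixel_size * 1000.0 / frame_interval   # nm/s per px/frame
    speeds = []
    for ridge in ridges:
        if len(ridge) < min_ridge_rows:
            continue
        tt = np.array([p[0] for p in ridge], dtype=float)
        xx = np.array([p[1] for p in ridge], dtype=float)
        slope = np.polyfit(tt, xx, 1)[0]
        speeds.append(abs(slope) * scale)
    if not speeds:
        raise ValueError("no ridge long enough for a linear fit")
    speeds_arr = np.asarray(speeds)
    se = (speeds_arr.std(ddof=1) / math.sqrt(speeds_arr.size)
          if speeds_arr.size > 1 else 0.0)
    return KymographFit(speeds=speeds_arr, mean=float(speeds_arr.mean()),
                        se=float(se), n_ridges=speeds_arr.size,
                        px_per_frame_scale=scale)


# ---------------------------------------------------------------------------
# Fab kinetics
# ---------------------------------------------------------------------------


def fit_fab_kinetics(
    trace: pd.DataFrame,
    wash_schedule: Tuple[float, float, float],
    concentration: float,
) -> FabKinetics:
    """Fit mono-exponential Fab binding and dissociation to a wash trace.

    ``trace`` has columns ``t_s`` and ``intensity``;
    ``wash_schedule = (t_inject, t_wash, t_end)`` marks the injection
    and washout epochs. The rise over ``[t_inject, t_wash)`` follows
    ``A (1 - exp(-k_obs (t - t_inject)))`` and the decay after washout
    ``A (1 - exp(-k_obs (t_wash - t_inject))) exp(-k_off (t - t_wash))``;
    per-epoch fits seed a joint fit of the whole trace with a shared
    amplitude, which pins each rate with the other epoch's information.
    With ``concentration`` (M) known, ``k_on = (k_obs - k_off) / C``.
    A non-converging fit returns a flagged result with diagnostics
    rather than raising; an effectively zero-signal trace raises.
    """
    t_inject, t_wash, t_end = wash_schedule
    t = trace["t_s"].to_numpy(dtype=float)
    y = trace["intensity"].to_numpy(dtype=float)
    rise_sel = (t >= t_inject) & (t < t_wash)
    decay_sel = (t >= t_wash) & (t <= t_end)
    if rise_sel.sum() < 4 or decay_sel.sum() < 4:
        raise ValueError("wash schedule leaves too few points in an epoch")
    amp = float(np.percentile(y[rise_sel], 95))
    # noise from successive differences so the signal excursion itself
    # does not inflate the estimate
    noise = 1.4826 * float(np.median(np.abs(np.diff(y)))) / math.sqrt(2.0)
    if amp <= 3.0 * max(noise, 1e-12) or amp <= 0:
        raise ValueError("zero-signal trace: no binding signal to fit")

    def rise(tt, a, k):
        return a * (1.0 - np.exp(-k * (tt - t_inject)))

    def decay(tt, b, k):
        return b * np.exp(-k * (tt - t_wash))

    both_sel = rise_sel | decay_sel

    def joint(tt, a, k_obs, k_off):
        out = np.empty_like(tt)
        r = tt < t_wash
        out[r] = a * (1.0 - np.exp(-k_obs * (tt[r] - t_inject)))
        level = a * (1.0 - math.exp(-k_obs * (t_wash - t_inject)))
        out[~r] = level * np.exp(-k_off * (tt[~r] - t_wash))
        return out

    try:
        (a0, k_obs0), _ = optimize.curve_fit(
            rise, t[rise_sel], y[rise_sel], p0=(amp, 1.0 / 100.0),
            bounds=([0, 1e-6], [np.inf, 10.0]), maxfev=10000)
        (_, k_off0), _ = optimize.curve_fit(
            decay, t[decay_sel], y[decay_sel], p0=(amp, 1.0 / 150.0),
            bounds=([0, 1e-6], [np.inf, 10.0]), maxfev=10000)
        (a_fit, k_obs, k_off), _ = optimize.curve_fit(
            joint, t[both_sel], y[both_sel], p0=(a0, k_obs0, k_off0),
            bounds=([0, 1e-6, 1e-6], [np.inf, 10.0, 10.0]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return FabKinetics(k_obs=float("nan"), k_off=float("nan"), plateau=float("nan"),
                           concentration=concentration, converged=False,
                           diagnostics=f"curve_fit failed: {exc}")
    return FabKinetics(k_obs=float(k_obs), k_off=float(k_off), plateau=float(a_fit),
                       concentration=concentration)


# ---------------------------------------------------------------------------
# Activated-integrin (bound Fab) counting
# ---------------------------------------------------------------------------


def count_bound_fabs(
    image: np.ndarray,
    calibration: CalibrationResult,
    roi_mask: np.ndarray,
    pixel_size: float,
    background: Optional[float] = None,
    channel_label: Optional[str] = None,
) -> ActivatedIntegrinCount:
    """Count fluorescent Fabs bound within a cell ROI.

    ``n = (integrated ROI intensity - background * ROI area) / I1``
    with the per-pixel ``background`` estimated from outside the ROI
    when not given. ``channel_label``, when provided, must match the
    calibration channel — Fab and TGT counting share one calibration
    contract and swapping channels is rejected.
    """
    if calibration is None:
        raise ValueError("a CalibrationResult is required")
    if channel_label is not None and calibration.channel_label != channel_label:
        raise ValueError(
            f"channel mismatch: image is {channel_label!r} but the calibration "
            f"is for {calibration.channel_label!r}")
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(roi_mask, dtype=bool)
    if background is None:
        outside = img[~mask]
        background = float(np.median(outside)) if outside.size else 0.0
    integrated = float(img[mask].sum()) - background * int(mask.sum())
    n = integrated / calibration.single_fluor_intensity
    area = float(mask.sum()) * pixel_size ** 2
    if area <= 0:
        raise ValueError("empty ROI")
    return ActivatedIntegrinCount(n_bound=n, density=n / area, area_um2=area,
                                  calibration=calibration)


def rupture_rate_per_activated_integrin(
    total_ruptures: float,
    n_activated: float,
    duration_min: float,
) -> Tuple[float, float]:
    """Average rupture rate per activated integrin and mean waiting time.

    ``rate = total_ruptures / (n_activated * duration_min)`` in
    ruptures/integrin/min; waiting time is its reciprocal in minutes.
    E.g. ~200,000 ruptures across ~70,000 activated integrins over
    60 min gives ~0.05/min, a high-force event about every 20 min.
    """
    if total_ruptures <= 0 or n_activated <= 0 or duration_min <= 0:
        raise ValueError("all inputs must be > 0")
    rate = total_ruptures / (n_activated * duration_min)
    return rate, 1.0 / rate
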
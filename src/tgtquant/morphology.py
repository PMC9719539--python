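"""Cell morphology from RICM images and motility from nucleus tracking.

RICM reports close membrane-substrate contact as dark regions on a
bright background; segmentation of those regions yields per-cell
close-contact ROIs with enclosed area (holes filled), second-moment
aspect ratio and centroid. Locomotion is quantified by detecting
nuclei as Gaussian blobs per frame, linking them with a greedy
nearest-neighbor gate, and fitting a power law to the ensemble mean
squared displacement; an MSD exponent alpha > 1 indicates directed
(superdiffusive) migration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import disk

from .synth import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "CellROI",
    "TrajectorySet",
    "MSDFit",
    "segment_ricm",
    "spread_metrics",
    "classify_spread",
    "percentage_spread",
    "track_nuclei",
    "compute_msd",
    "fit_msd_power_law",
    "DEFAULT_SPREAD_AREA_UM2",
]

#: Default close-contact area above which a cell counts as "spread", um^2.
DEFAULT_SPREAD_AREA_UM2 = 500.0


@dataclass
class CellROI:
    """Close-contact region of one cell.

    ``area`` is the enclosed area in um^2 (mask pixel count times
    pixel_size^2, internal holes filled); ``aspect_ratio`` is the
    major/minor axis ratio of the mask's second-moment ellipse (>= 1).
    """

    mask: np.ndarray                  # (H, W) bool, holes filled
    contour: np.ndarray               # (n_points, 2) row/col polygon
    centroid: Tuple[float, float]     # row, col in px
    area: float                       # um^2
    aspect_ratio: float
    pixel_size: float = 1.0           # um/px
    frame_index: int = 0


@dataclass
class TrajectorySet:
    """Linked trajectories as a long-form table (track_id, t_s, x_um, y_um)."""

    table: pd.DataFrame
    linking_gate_px: float
    min_track_length: int

    def tracks(self) -> List[pd.DataFrame]:
        return [g.sort_values("t_s") for _, g in self.table.groupby("track_id")]

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()


@dataclass
class MSDFit:
    """Ensemble MSD curve and its power-law fit MSD = A * tau^alpha."""

    lag_times: np.ndarray     # s
    msd: np.ndarray           # um^2
    alpha: float
    prefactor: float          # um^2 at tau = 1 s
    fit_range: Tuple[float, float]


# ---------------------------------------------------------------------------
# RICM segmentation and spreading metrics
# ---------------------------------------------------------------------------


def segment_ricm(
    image: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 20.0,
    threshold_offset: float = 0.0,
    closing_radius: int = 2,
    smooth_sigma: float = 1.0,
    frame_index: int = 0,
) -> List[CellROI]:
    """Segment dark close-contact regions of an RICM image into cell ROIs.

    Pipeline: light Gaussian smoothing, automatic two-class (Otsu)
    threshold (dark side, optionally shifted by ``threshold_offset``
    counts), morphological closing, hole filling (enclosed-area
    semantics: bright patches inside a footprint belong to the cell),
    and removal of components below ``min_area_um2``. A blank or
    saturated image returns an empty list rather than raising.
    """
    img = np.asarray(image, dtype=np.float64)
    if smooth_sigma > 0:
        img = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if img.max() - img.min() < 1e-9:
        return []
    try:
        thr = threshold_otsu(img) + threshold_offset
    except ValueError:
        return []
    dark = img < thr
    # Otsu on a nearly unimodal (no-cell) image splits noise; reject
    # when the "dark" class is not actually darker than the background
    if not dark.any() or dark.all():
        return []
    contrast = np.median(img[~dark]) - np.median(img[dark])
    noise = 1.4826 * np.median(np.abs(img - np.median(img)))
    if contrast < 5.0 * max(noise, 1e-9):
        return []

    structure = disk(closing_radius)
    dark = ndimage.binary_closing(dark, structure=structure)
    dark = ndimage.binary_fill_holes(dark)
    min_px = max(int(min_area_um2 / pixel_size ** 2), 1)
    labels = label(dark)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_px)
    dark[np.isin(labels, small[small > 0])] = False
    labels = label(dark)
    rois: List[CellROI] = []
    for prop in regionprops(labels):
        mask = labels == prop.label
        contours = find_contours(mask.astype(float), 0.5)
        contour = max(contours, key=len) if contours else np.empty((0, 2))
        minor = max(prop.axis_minor_length, 0.5)   # guard line-like regions
        rois.append(CellROI(
            mask=mask,
            contour=contour,
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            area=float(prop.area) * pixel_size ** 2,
            aspect_ratio=float(prop.axis_major_length) / minor,
            pixel_size=pixel_size,
            frame_index=frame_index,
        ))
    return rois


def spread_metrics(roi: CellROI) -> Tuple[float, float, Tuple[float, float]]:
    """(area um^2, aspect ratio, centroid) of a cell ROI."""
    return roi.area, roi.aspect_ratio, roi.centroid


def classify_spread(roi: CellROI,
                    area_threshold_um2: float = DEFAULT_SPREAD_AREA_UM2) -> bool:
    """True when the close-contact area exceeds the spreading threshold."""
    return roi.area > area_threshold_um2


def percentage_spread(rois: Sequence[CellROI],
                      area_threshold_um2: float = DEFAULT_SPREAD_AREA_UM2) -> float:
    """Fraction of cells classified as spread (0-1)."""
    rois = list(rois)
    if not rois:
        raise ValueError("percentage_spread requires at least one ROI")
    return sum(classify_spread(r, area_threshold_um2) for r in rois) / len(rois)


# ---------------------------------------------------------------------------
# Nucleus tracking
# ---------------------------------------------------------------------------


def _detect_blobs(frame: np.ndarray, sigma: float, threshold_rel: float
                  ) -> np.ndarray:
    """Sub-pixel Gaussian-blob centers in one frame, (n, 2) row/col."""
    smoothed = gaussian(frame.astype(np.float64), sigma=sigma, preserve_range=True)
    bg = float(np.median(smoothed))
    amp = smoothed.max() - bg
    if amp <= 0:
        return np.empty((0, 2))
    peaks = peak_local_max(smoothed, min_distance=max(int(2 * sigma), 2),
                           threshold_abs=bg + threshold_rel * amp)
    out = []
    rad = max(int(2 * sigma), 2)
    for r, c in peaks:
        win = smoothed[max(r - rad, 0):r + rad + 1, max(c - rad, 0):c + rad + 1]
        w = np.clip(win - bg, 0, None)
        if w.sum() <= 0:
            out.append((float(r), float(c)))
            continue
        rr, cc = np.mgrid[max(r - rad, 0):r + rad + 1, max(c - rad, 0):c + rad + 1]
        out.append((float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())))
    return np.asarray(out) if out else np.empty((0, 2))


def track_nuclei(
    stack: Union[ImageStack, np.ndarray],
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
    blob_sigma: float = 3.0,
    threshold_rel: float = 0.3,
    linking_gate_px: float = 5.0,
    min_track_length: int = 5,
) -> TrajectorySet:
    """Detect nuclei per frame and link them into trajectories.

    Detection: Gaussian smoothing at the nucleus scale, local maxima,
    intensity-centroid refinement. Linking: greedy nearest-neighbor in
    order of increasing distance under a ``linking_gate_px`` maximum
    displacement per frame; unmatched detections start new tracks, and
    tracks shorter than ``min_track_length`` frames are dropped.
    Two detections competing within the gate go to the closer track
    (distance tie-break); track fragmentation is preferred over wrong
    links.
    """
    if isinstance(stack, ImageStack):
        data = stack.data
        pixel_size = pixel_size or stack.pixel_size
        frame_interval = frame_interval or stack.frame_interval
    else:
        data = np.asarray(stack, dtype=np.float64)
        pixel_size = pixel_size or 1.0
        frame_interval = frame_interval or 1.0

    next_id = 0
    active: dict[int, Tuple[float, float]] = {}
    rows: List[dict] = []
    for t in range(data.shape[0]):
        det = _detect_blobs(data[t], blob_sigma, threshold_rel)
        assigned_det: set[int] = set()
        new_active: dict[int, Tuple[float, float]] = {}
        if det.shape[0] and active:
            ids = list(active.keys())
            prev = np.asarray([active[i] for i in ids])
            dist = np.linalg.norm(prev[:, None, :] - det[None, :, :], axis=2)
            pairs = [(dist[a, b], a, b) for a in range(len(ids)) for b in range(det.shape[0])
                     if dist[a, b] <= linking_gate_px]
            pairs.sort()
            contested = np.sum(dist <= linking_gate_px, axis=0)
            for b in np.flatnonzero(contested > 1):
                logger.debug(
                    "frame %d: detection %d within the gate of %d tracks; "
                    "linking to the nearest", t, int(b), int(contested[b]))
            used_tracks: set[int] = set()
            for d, a, b in pairs:
                if a in used_tracks or b in assigned_det:
                    continue
                used_tracks.add(a)
                assigned_det.add(b)
                tid = ids[a]
                new_active[tid] = (det[b, 0], det[b, 1])
                rows.append({"track_id": tid, "t_s": t * frame_interval,
                             "x_um": det[b, 1] * pixel_size,
                             "y_um": det[b, 0] * pixel_size})
        for b in range(det.shape[0]):
            if b in assigned_det:
                continue
            tid = next_id
            next_id += 1
            new_active[tid] = (det[b, 0], det[b, 1])
            rows.append({"track_id": tid, "t_s": t * frame_interval,
                         "x_um": det[b, 1] * pixel_size,
                         "y_um": det[b, 0] * pixel_size})
        active = new_active

    table = pd.DataFrame(rows, columns=["track_id", "t_s", "x_um", "y_um"])
    if len(table):
        lengths = table.groupby("track_id").size()
        keep = lengths[lengths >= min_track_length].index
        table = table[table["track_id"].isin(keep)].reset_index(drop=True)
    return TrajectorySet(table=table, linking_gate_px=linking_gate_px,
                         min_track_length=min_track_length)


# ---------------------------------------------------------------------------
# Mean squared displacement
# ---------------------------------------------------------------------------


def compute_msd(tracks: Union[TrajectorySet, pd.DataFrame],
                max_lag_fraction: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    """Ensemble mean squared displacement, time- then ensemble-averaged.

    Per track, MSD(tau) is averaged over all start times (overlapping
    pairs); tracks are then combined with pair-count weights, so the
    MSD of concatenated track sets equals the weighted average of their
    MSDs exactly. Lags run up to ``max_lag_fraction`` of the longest
    track. Returns (lag_times_s, msd_um2).
    """
    table = tracks.table if isinstance(tracks, TrajectorySet) else tracks
    groups = [g.sort_values("t_s") for _, g in table.groupby("track_id")]
    groups = [g for g in groups if len(g) >= 3]
    if not groups:
        raise ValueError("no track of length >= 3 for MSD computation")
    dt = np.inf
    for g in groups:
        steps = np.diff(g["t_s"].to_numpy())
        if steps.size:
            dt = min(dt, float(np.min(steps)))
    max_len = max(len(g) for g in groups)
    max_lag = max(int(max_lag_fraction * max_len), 1)

    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for g in groups:
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        n = len(g)
        for lag in range(1, min(max_lag, n - 1) + 1):
            dx = x[lag:] - x[:-lag]
            dy = y[lag:] - y[:-lag]
            sums[lag - 1] += float(np.sum(dx * dx + dy * dy))
            counts[lag - 1] += dx.size
    valid = counts > 0
    lags = np.arange(1, max_lag + 1)[valid] * dt
    return lags, sums[valid] / counts[valid]


def fit_msd_power_law(
    lag_times: np.ndarray,
    msd: np.ndarray,
    fit_range: Optional[Tuple[float, float]] = None,
) -> MSDFit:
    """Least-squares power-law fit MSD = A * tau^alpha on log-log axes.

    Non-positive MSD points are excluded; if all are excluded, raises.
    ``fit_range`` restricts the lag times used (seconds); default is
    the whole curve.
    """
    lag_times = np.asarray(lag_times, dtype=np.float64)
    msd = np.asarray(msd, dtype=np.float64)
    sel = msd > 0
    if fit_range is not None:
        sel &= (lag_times >= fit_range[0]) & (lag_times <= fit_range[1])
    if sel.sum() < 4:
        raise ValueError("need at least 4 positive MSD points in the fit range")
    lt = np.log(lag_times[sel])
    lm = np.log(msd[sel])
    alpha, log_a = np.polyfit(lt, lm, 1)
    used = lag_times[sel]
    return MSDFit(lag_times=lag_times, msd=msd, alpha=float(alpha),
                  prefactor=float(math.exp(log_a)),
                  fit_range=(float(used.min()), float(used.max())))
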
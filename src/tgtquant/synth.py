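"""Seeded synthetic-data generators with serialized ground truth.

Every input the analysis pipeline consumes can be generated here with a
known ground truth, so all downstream stages are testable end to end
without any microscopy data:

* turn-on TGT rupture stacks (persistent diffraction-limited spots, one
  fluorophore each, appearing at rupture times under a growing cell
  footprint, with fiducial markers and lateral drift);
* stepwise photobleaching / binding traces for single-fluorophore
  intensity calibration;
* RICM-like images (dark close-contact footprint on a bright
  background);
* kymographs with linearly translating ridges (actin retrograde flow);
* superdiffusive nucleus trajectories (fractional Brownian motion);
* Fab injection / washout fluorescence time courses.

The camera model is Poisson shot noise on (signal + background) at unit
gain plus Gaussian read noise. Spots are rendered as 2-D Gaussians
truncated at 5 sigma and renormalized, so the *integrated* intensity of
one spot equals ``single_fluor_intensity`` exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionParams",
    "SpreadingScenario",
    "GroundTruth",
    "ImageStack",
    "simulate_rupture_stack",
    "simulate_bleaching_traces",
    "simulate_ricm",
    "simulate_kymograph",
    "simulate_tracks",
    "simulate_fab_timecourse",
    "fractional_gaussian_noise",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera / acquisition parameters for synthetic TIRF-like imaging.

    Defaults emulate time-lapse TIRF imaging of Cy3-labelled probes at
    1-min intervals: 0.16 um pixels, a ~1.1 px PSF sigma, an integrated
    single-fluorophore intensity of 800 camera counts (peak pixel ~7x
    the background shot noise, i.e. comfortably detectable), 200
    counts/px background and 5 counts rms read noise at unit gain.
    """

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.16          # um / px
    frame_interval: float = 60.0      # s
    n_frames: int = 60
    psf_sigma: float = 1.1            # px
    single_fluor_intensity: float = 800.0   # integrated counts / fluorophore
    background_level: float = 200.0   # counts / px
    read_noise_sd: float = 5.0        # counts rms
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 16:
            raise ValueError("image_shape must be at least 16x16")
        for name in ("pixel_size", "frame_interval", "psf_sigma",
                     "single_fluor_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")


@dataclass(frozen=True)
class SpreadingScenario:
    """Cell-spreading scenario controlling footprint growth and rupture hazard.

    ``shape_class`` "circular" emulates uniform isotropic spreading
    (alpha4beta1 / LDVP-like); "elongated" emulates irregular polarized
    spreading (RGD-like, 3:1 axes). The footprint is an ellipse growing
    from a small landing patch to ``final_area`` over
    ``spreading_timescale`` frames, starting at ``landing_frame``.

    ``rupture_hazard`` places events either in a peripheral ring that
    translates inward over time ("edge_streaks", emulating centripetally
    moving force streaks at maturing focal adhesions) or uniformly over
    the footprint with a mild edge excess ("interior_puncta").

    ``rate`` is the expected rupture rate in events/min/cell once the
    cell has landed; ``rate_profile`` optionally makes the hazard peak
    early or late in the movie (spreading-phase versus maturing
    adhesions); ``n_events`` optionally fixes the total event count
    exactly (frames then drawn proportionally to the hazard).
    ``tgt_density`` (molecules/um^2, default 1500) caps the cumulative
    event density per pixel.
    """

    shape_class: Literal["circular", "elongated"] = "circular"
    final_area: float = 700.0         # um^2
    spreading_timescale: int = 25     # frames to reach final area
    rupture_hazard: Literal["edge_streaks", "interior_puncta"] = "edge_streaks"
    rate: float = 10.0                # events / min / cell
    rate_profile: Literal["constant", "early_peak", "late_peak"] = "constant"
    n_events: Optional[int] = None
    tgt_density: float = 1500.0       # molecules / um^2
    landing_frame: int = 5

    def __post_init__(self) -> None:
        if self.final_area <= 0:
            raise ValueError("final_area must be > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.spreading_timescale < 1:
            raise ValueError("spreading_timescale must be >= 1")
        if self.landing_frame < 0:
            raise ValueError("landing_frame must be >= 0")


@dataclass
class GroundTruth:
    """Per-simulation ground truth, serializable to JSON.

    ``rupture_events`` are (frame, row, col) in un-drifted sample
    coordinates; ``drift_track`` is the applied per-frame (drow, dcol)
    offset in px; ``footprint_mask_series`` holds the binary
    close-contact mask per frame.
    """

    rupture_events: List[Tuple[int, float, float]] = field(default_factory=list)
    drift_track: Optional[np.ndarray] = None          # (n_frames, 2) px
    footprint_mask_series: Optional[np.ndarray] = None  # (n_frames, H, W) bool
    flow_speed: Optional[float] = None                # nm/s
    msd_exponent: Optional[float] = None
    bleach_lifetime: Optional[float] = None           # s
    fiducial_positions: List[Tuple[float, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        """Write events, drift, fiducials and scalar truth as JSON.

        Masks are not embedded (they are bulky and reconstructable from
        the footprint parameters); the per-frame mask pixel areas are
        stored instead.
        """
        payload = {
            "rupture_events": [[int(f), float(r), float(c)] for f, r, c in self.rupture_events],
            "drift_track": None if self.drift_track is None else self.drift_track.tolist(),
            "footprint_area_px": (
                None if self.footprint_mask_series is None
                else self.footprint_mask_series.sum(axis=(1, 2)).astype(int).tolist()
            ),
            "flow_speed": self.flow_speed,
            "msd_exponent": self.msd_exponent,
            "bleach_lifetime": self.bleach_lifetime,
            "fiducial_positions": [[float(r), float(c)] for r, c in self.fiducial_positions],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class ImageStack:
    """frames x rows x cols intensity array with physical metadata."""

    data: np.ndarray                  # (n_frames, H, W) float
    pixel_size: float                 # um / px
    frame_interval: float             # s

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3-D (frames, rows, cols)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def to_tiff(self, path: str | Path) -> None:
        """Write as multi-page 32-bit TIFF with pixel size and frame interval
        in ImageJ-style metadata (deterministic: no timestamp tag)."""
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            imagej=True,
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "finterval": self.frame_interval, "axes": "TYX"},
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            meta = tif.imagej_metadata or {}
            frame_interval = float(meta.get("finterval", 1.0))
            page = tif.pages[0]
            try:
                xres = page.tags["XResolution"].value
                pixel_size = xres[1] / xres[0]
            except (KeyError, ZeroDivisionError):
                pixel_size = 1.0
        if data.ndim == 2:
            data = data[None]
        return cls(data=data.astype(np.float64), pixel_size=pixel_size,
                   frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

_TRUNC_SIGMAS = 5.0


def _render_spot(image: np.ndarray, row: float, col: float, sigma: float,
                 integrated: float) -> None:
    """Add a 2-D Gaussian spot at a sub-pixel position, in place.

    Truncated at 5 sigma and renormalized so the added flux equals
    ``integrated`` exactly (up to clipping at the image border).
    """
    h, w = image.shape
    rad = int(math.ceil(_TRUNC_SIGMAS * sigma))
    r0, r1 = int(math.floor(row)) - rad, int(math.floor(row)) + rad + 1
    c0, c1 = int(math.floor(col)) - rad, int(math.floor(col)) + rad + 1
    rr = np.arange(r0, r1, dtype=np.float64)
    cc = np.arange(c0, c1, dtype=np.float64)
    gr = np.exp(-0.5 * ((rr - row) / sigma) ** 2)
    gc = np.exp(-0.5 * ((cc - col) / sigma) ** 2)
    kernel = np.outer(gr, gc)
    kernel *= integrated / kernel.sum()
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r1, h), min(c1, w)
    if rs >= re or cs >= ce:
        return
    image[rs:re, cs:ce] += kernel[rs - r0:re - r0, cs - c0:ce - c0]


def _ellipse_mask(shape: Tuple[int, int], center: Tuple[float, float],
                  semi_r: float, semi_c: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    if semi_r <= 0 or semi_c <= 0:
        return np.zeros(shape, dtype=bool)
    return ((rr - center[0]) / semi_r) ** 2 + ((cc - center[1]) / semi_c) ** 2 <= 1.0


def _apply_camera_noise(clean: np.ndarray, params: AcquisitionParams,
                        rng: np.random.Generator) -> np.ndarray:
    noisy = clean
    if params.shot_noise:
        noisy = rng.poisson(np.clip(clean, 0, None)).astype(np.float64)
    if params.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, params.read_noise_sd, size=clean.shape)
    return noisy


def _shift_image(image: np.ndarray, drow: float, dcol: float) -> np.ndarray:
    """Bilinear sub-pixel shift (flux-preserving away from borders)."""
    from scipy import ndimage

    if drow == 0.0 and dcol == 0.0:
        return image.copy()
    return ndimage.shift(image, (drow, dcol), order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# Rupture stack simulation
# ---------------------------------------------------------------------------


def _footprint_axes(scenario: SpreadingScenario, pixel_size: float,
                    frame: int) -> Tuple[float, float]:
    """Ellipse semi-axes (rows, cols) in px for a given frame."""
    if frame < scenario.landing_frame:
        return 0.0, 0.0
    t = frame - scenario.landing_frame
    # smooth saturating growth from ~6% to 100% of final area
    frac = 0.06 + 0.94 * (1.0 - math.exp(-2.5 * t / scenario.spreading_timescale))
    frac = min(frac, 1.0)
    area_px = scenario.final_area * frac / pixel_size ** 2
    aspect = 1.0 if scenario.shape_class == "circular" else 3.0
    # area = pi * a * b with a/b = aspect (long axis along columns)
    b = math.sqrt(area_px / (math.pi * aspect))
    return b, b * aspect


def _sample_event_position(rng: np.random.Generator, scenario: SpreadingScenario,
                           center: Tuple[float, float], semi_r: float, semi_c: float,
                           frame: int, n_frames: int) -> Tuple[float, float]:
    """Draw one event position inside the current footprint ellipse."""
    theta = rng.uniform(0.0, 2.0 * math.pi)
    if scenario.rupture_hazard == "edge_streaks":
        # peripheral ring, translating inward as adhesions mature
        r = rng.uniform(0.8, 1.0) - 0.25 * (frame / max(n_frames - 1, 1))
        r = max(r, 0.35)
    else:
        # uniform over area with a mild edge excess
        if rng.uniform() < 0.25:
            r = rng.uniform(0.8, 1.0)
        else:
            r = math.sqrt(rng.uniform())
    return (center[0] + r * semi_r * math.sin(theta),
            center[1] + r * semi_c * math.cos(theta))


def simulate_rupture_stack(
    params: AcquisitionParams,
    scenario: SpreadingScenario | None = None,
    include_fiducials: bool = True,
    n_fiducials: int = 4,
    drift_velocity: Tuple[float, float] = (0.07, 0.07),
    drift_jitter_sd: float = 0.03,
    fiducial_intensity_factor: float = 40.0,
) -> Tuple[ImageStack, GroundTruth]:
    """Simulate a turn-on TGT rupture image stack with ground truth.

    Each rupture event adds a persistent diffraction-limited spot of
    integrated intensity ``single_fluor_intensity`` from its frame
    onward; spots (and fiducials) are translated by a linear-plus-jitter
    drift track; Poisson shot noise and Gaussian read noise are applied
    last. Event placement is gated by the growing close-contact
    footprint of the spreading cell.

    Parameters
    ----------
    drift_velocity:
        Linear drift (drow, dcol) in px/frame; default magnitude ~0.1
        px/frame, sub-pixel as appropriate for 1-min-interval imaging.
    drift_jitter_sd:
        Per-frame Gaussian jitter added to the linear drift, px.

    Returns the stack and a :class:`GroundTruth` with events, drift,
    per-frame footprint masks and fiducial positions.
    """
    scenario = scenario or SpreadingScenario()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    n = params.n_frames
    center = (h / 2.0, w / 2.0)

    # footprint must fit the field of view
    fr, fc = _footprint_axes(scenario, params.pixel_size, n - 1)
    if fr * 2 > h - 8 or fc * 2 > w - 8:
        raise ValueError(
            f"final footprint ({2*fr:.0f}x{2*fc:.0f} px) does not fit the "
            f"{h}x{w} field of view")

    # drift: linear velocity + per-frame jitter, zero at frame 0
    drift = np.outer(np.arange(n, dtype=np.float64), np.asarray(drift_velocity))
    if drift_jitter_sd > 0:
        jitter = rng.normal(0.0, drift_jitter_sd, size=(n, 2))
        jitter[0] = 0.0
        drift += jitter

    # fiducials: bright persistent spots outside the final footprint
    fiducials: List[Tuple[float, float]] = []
    if include_fiducials:
        margin = 12.0
        corners = [(margin, margin), (margin, w - margin),
                   (h - margin, margin), (h - margin, w - margin)]
        for i in range(n_fiducials):
            base = corners[i % 4]
            fiducials.append((base[0] + rng.uniform(-3, 3), base[1] + rng.uniform(-3, 3)))

    # per-frame footprint masks and expected event counts
    masks = np.zeros((n, h, w), dtype=bool)
    axes = [_footprint_axes(scenario, params.pixel_size, t) for t in range(n)]
    for t, (sr, sc) in enumerate(axes):
        masks[t] = _ellipse_mask((h, w), center, sr, sc)

    hazard = np.array([
        scenario.rate * params.frame_interval / 60.0 if axes[t][0] > 0 else 0.0
        for t in range(n)
    ])
    if scenario.rate_profile != "constant":
        t0 = scenario.landing_frame
        span = max(n - 1 - t0, 1)
        rel = np.clip((np.arange(n) - t0) / span, 0.0, 1.0)
        tau = 0.25
        if scenario.rate_profile == "early_peak":
            hazard *= np.exp(-rel / tau)
        else:
            hazard *= np.exp(-(1.0 - rel) / tau)
    if scenario.n_events is not None:
        n_events = int(scenario.n_events)
        if hazard.sum() <= 0:
            frames = np.full(n_events, scenario.landing_frame, dtype=int)
        else:
            frames = rng.choice(n, size=n_events, p=hazard / hazard.sum())
    else:
        counts = rng.poisson(hazard)
        frames = np.repeat(np.arange(n), counts)
    frames.sort()

    events: List[Tuple[int, float, float]] = []
    for f in frames:
        sr, sc = axes[f]
        if sr <= 0:
            continue
        row, col = _sample_event_position(rng, scenario, center, sr, sc, int(f), n)
        row = float(np.clip(row, 1.0, h - 2.0))
        col = float(np.clip(col, 1.0, w - 2.0))
        events.append((int(f), row, col))

    # clean accumulated signal image in sample coordinates
    accum = np.zeros((h, w), dtype=np.float64)
    for r, c in fiducials:
        _render_spot(accum, r, c, params.psf_sigma,
                     fiducial_intensity_factor * params.single_fluor_intensity)

    stack = np.empty((n, h, w), dtype=np.float64)
    ev_idx = 0
    for t in range(n):
        while ev_idx < len(events) and events[ev_idx][0] <= t:
            _, r, c = events[ev_idx]
            _render_spot(accum, r, c, params.psf_sigma, params.single_fluor_intensity)
            ev_idx += 1
        frame = _shift_image(accum, drift[t, 0], drift[t, 1])
        frame += params.background_level
        stack[t] = _apply_camera_noise(frame, params, rng)

    truth = GroundTruth(
        rupture_events=events,
        drift_track=drift,
        footprint_mask_series=masks,
        fiducial_positions=fiducials,
    )
    return ImageStack(stack, params.pixel_size, params.frame_interval), truth


# ---------------------------------------------------------------------------
# Photobleaching / binding traces
# ---------------------------------------------------------------------------


def simulate_bleaching_traces(
    n_traces: int,
    params: AcquisitionParams,
    trace_length: int = 200,
    bleach_lifetime: float = 3000.0,
    direction: Literal["down", "up"] = "down",
    magnitude_spread: float = 0.0,
    noise_sd: Optional[float] = None,
) -> Tuple[List[np.ndarray], pd.DataFrame]:
    """Simulate stepwise single-fluorophore photobleaching (or binding) traces.

    Each trace carries one step of magnitude ``single_fluor_intensity``
    (optionally spread by ``magnitude_spread`` fractional sd) at an
    exponentially distributed random time with mean ``bleach_lifetime``
    seconds, conditioned to fall inside the observable trace window,
    plus Gaussian noise. ``direction="down"`` emulates
    photobleaching (bright -> dark), ``"up"`` emulates a Fab binding to
    the surface (dark -> bright).

    Returns the traces and a truth table with columns
    ``trace_id, frame, magnitude``.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    rng = np.random.default_rng(params.seed)
    sd = params.read_noise_sd if noise_sd is None else noise_sd
    i1 = params.single_fluor_intensity
    baseline = params.background_level

    traces: List[np.ndarray] = []
    rows = []
    for tid in range(n_traces):
        mag = i1 * (1.0 + magnitude_spread * rng.standard_normal()) if magnitude_spread else i1
        # step frame: exponential conditioned to the observable window
        lo, hi = 3, trace_length - 4
        mean_frames = bleach_lifetime / params.frame_interval
        while True:
            t_step = rng.exponential(mean_frames)
            if lo <= t_step < hi:
                break
        frame = int(t_step)
        trace = np.full(trace_length, baseline, dtype=np.float64)
        if direction == "down":
            trace[:frame] += mag
            signed = -mag
        else:
            trace[frame:] += mag
            signed = mag
        if sd > 0:
            trace += rng.normal(0.0, sd, size=trace_length)
        traces.append(trace)
        rows.append({"trace_id": tid, "frame": frame, "magnitude": signed})
    return traces, pd.DataFrame(rows)


def traces_to_csv(traces: Sequence[np.ndarray], path: str | Path) -> None:
    """Write traces as long-form CSV (trace_id, frame, intensity)."""
    frames = [pd.DataFrame({"trace_id": i, "frame": np.arange(len(t)), "intensity": t})
              for i, t in enumerate(traces)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path: str | Path) -> List[np.ndarray]:
    df = pd.read_csv(path)
    return [g.sort_values("frame")["intensity"].to_numpy()
            for _, g in df.groupby("trace_id")]


# ---------------------------------------------------------------------------
# RICM image
# ---------------------------------------------------------------------------


def simulate_ricm(
    footprint_mask: np.ndarray,
    params: AcquisitionParams,
    background_intensity: float = 1000.0,
    contrast: float = 0.55,
    speckle_cv: float = 0.02,
) -> np.ndarray:
    """Simulate an RICM image: dark close-contact footprint on a bright field.

    The footprint mask multiplies the background by ``1 - contrast``;
    multiplicative speckle (fractional sd ``speckle_cv``) and read noise
    are added. Physically detailed interference fringes are not
    modelled.
    """
    rng = np.random.default_rng(params.seed + 7)
    mask = np.asarray(footprint_mask, dtype=bool)
    image = np.full(mask.shape, background_intensity, dtype=np.float64)
    image[mask] *= (1.0 - contrast)
    if speckle_cv > 0:
        image *= 1.0 + speckle_cv * rng.standard_normal(mask.shape)
    if params.read_noise_sd > 0:
        image += rng.normal(0.0, params.read_noise_sd, size=mask.shape)
    return image


# ---------------------------------------------------------------------------
# Kymograph
# ---------------------------------------------------------------------------


def simulate_kymograph(
    speed: float,
    params: AcquisitionParams,
    n_features: int = 6,
    spacing: float = 14.0,
    n_positions: int = 120,
    ridge_sigma: float = 1.3,
    ridge_intensity: float = 600.0,
) -> np.ndarray:
    """Simulate a (time x position) kymograph with translating ridges.

    Each of ``n_features`` ridges moves at ``speed`` nm/s, i.e. with
    slope ``speed * frame_interval / (pixel_size * 1000)`` px/frame, on
    a noisy background. Ridges are spaced ``spacing`` px apart.
    """
    rng = np.random.default_rng(params.seed + 13)
    n_t = params.n_frames
    slope = speed * params.frame_interval / (params.pixel_size * 1000.0)  # px/frame
    kymo = np.full((n_t, n_positions), params.background_level, dtype=np.float64)
    x0s = 8.0 + spacing * np.arange(n_features) + rng.uniform(-1, 1, n_features)
    tt = np.arange(n_t, dtype=np.float64)
    xx = np.arange(n_positions, dtype=np.float64)
    for x0 in x0s:
        pos = x0 + slope * tt                          # (n_t,)
        prof = np.exp(-0.5 * ((xx[None, :] - pos[:, None]) / ridge_sigma) ** 2)
        kymo += ridge_intensity / (ridge_sigma * math.sqrt(2 * math.pi)) * prof
    return _apply_camera_noise(kymo, params, rng)


# ---------------------------------------------------------------------------
# Fractional Brownian motion trajectories
# ---------------------------------------------------------------------------


def fractional_gaussian_noise(n: int, hurst: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by Davies-Harte circulant embedding.

    Returns ``n`` increments with unit variance and autocovariance
    ``gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H) / 2``. Their cumulative
    sum is fractional Brownian motion with ``E[B(t)^2] = t^(2H)``.
    ``hurst = 1`` is the degenerate ballistic limit (all increments
    equal) and is handled directly.
    """
    if not 0.0 < hurst <= 1.0:
        raise ValueError(f"hurst must lie in (0, 1], got {hurst}")
    if hurst == 1.0:
        return np.full(n, rng.standard_normal())
    k = np.arange(n + 1, dtype=np.float64)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    # first row of the 2n circulant: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    lam = np.clip(lam, 0.0, None)       # guard tiny negative eigenvalues
    m = row.size
    # Hermitian random spectrum -> real Gaussian field
    n_half = lam.size
    re = rng.standard_normal(n_half)
    im = rng.standard_normal(n_half)
    spec = (re + 1j * im) * np.sqrt(lam / 2.0)
    spec[0] = re[0] * np.sqrt(lam[0])
    if m % 2 == 0:
        spec[-1] = re[-1] * np.sqrt(lam[-1])
    field = np.fft.irfft(spec, n=m) * math.sqrt(m)
    return field[:n]


def simulate_tracks(
    n_tracks: int,
    n_steps: int,
    msd_exponent: float = 1.7,
    scale: float = 0.5,
    frame_interval: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate 2-D fractional-Brownian-motion trajectories.

    The MSD exponent ``alpha`` maps to Hurst ``H = alpha/2``; the
    ensemble MSD grows as ``2 * scale^2 * (tau/dt)^alpha`` um^2.
    ``alpha = 1.7`` emulates superdiffusive nucleus motion of migrating
    cells; ``alpha = 1`` is Brownian.

    Returns a long-form table with columns ``track_id, t_s, x_um, y_um``.
    """
    if not 0.0 < msd_exponent <= 2.0:
        raise ValueError(f"msd_exponent must lie in (0, 2], got {msd_exponent}")
    rng = np.random.default_rng(seed)
    hurst = msd_exponent / 2.0
    rows = []
    t = np.arange(n_steps + 1) * frame_interval
    for tid in range(n_tracks):
        dx = fractional_gaussian_noise(n_steps, hurst, rng)
        dy = fractional_gaussian_noise(n_steps, hurst, rng)
        x = np.concatenate([[0.0], np.cumsum(dx)]) * scale
        y = np.concatenate([[0.0], np.cumsum(dy)]) * scale
        rows.append(pd.DataFrame({"track_id": tid, "t_s": t, "x_um": x, "y_um": y}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Fab binding / washout time course
# ---------------------------------------------------------------------------


def simulate_fab_timecourse(
    k_on: float,
    k_off: float,
    concentration: float,
    wash_schedule: Tuple[float, float, float] = (0.0, 600.0, 1500.0),
    dt: float = 2.0,
    plateau: float = 1000.0,
    snr: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Fab injection / washout fluorescence trace.

    During injection (``t_inject <= t < t_wash``) the bound signal rises
    as ``1 - exp(-k_obs * t)`` with ``k_obs = k_on * C + k_off``; after
    washout it decays as ``exp(-k_off * t)``. ``plateau`` is the
    full-occupancy intensity; the rise saturates at
    ``plateau * k_on C / k_obs`` (flat at C = 0). Gaussian noise of sd
    ``amplitude / snr`` is added (``plateau / snr`` for a flat C = 0
    trace, so noise does not vanish with the signal). With k_off ~ 1/150 s^-1 the decay
    emulates a conformation-reporter Fab that exchanges on a 2-3 min
    timescale.

    Returns a table with columns ``t_s, intensity``.
    """
    if k_on < 0 or k_off < 0 or concentration < 0:
        raise ValueError("rates and concentration must be >= 0")
    t_inject, t_wash, t_end = wash_schedule
    if not t_inject < t_wash < t_end:
        raise ValueError("wash_schedule must satisfy t_inject < t_wash < t_end")
    rng = np.random.default_rng(seed)
    t = np.arange(t_inject, t_end, dt)
    k_obs = k_on * concentration + k_off
    # equilibrium bound fraction scales the rise amplitude, so C = 0 is flat
    amp = plateau * (k_on * concentration / k_obs) if k_obs > 0 else 0.0
    signal = np.zeros_like(t)
    rise = t < t_wash
    signal[rise] = amp * (1.0 - np.exp(-k_obs * (t[rise] - t_inject)))
    level_at_wash = amp * (1.0 - math.exp(-k_obs * (t_wash - t_inject)))
    signal[~rise] = level_at_wash * np.exp(-k_off * (t[~rise] - t_wash))
    if snr > 0:
        noise_scale = amp if amp > 0 else plateau
        signal = signal + rng.normal(0.0, noise_scale / snr, size=t.size)
    return pd.DataFrame({"t_s": t, "intensity": signal})
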
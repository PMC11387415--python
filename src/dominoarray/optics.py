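"""Rendering of cascade trajectories into dual-colour TIRF time-lapse movies.

Surface-immobilised structures are diffraction-limited turn-on emitters: a
probe emits Poisson photons at the on-rate while its anti-junction is in the
transformed conformation and the dye has not photobleached, and at a small
residual rate otherwise (dark-quencher leakage).  Emitters are rendered as
pixel-integrated 2-D Gaussians on a Poisson background.  Fiducial structures
emit in both channels from frame 0.  Global stage drift and a chromatic
offset between channels are applied to emitter coordinates.

Timestamps: a frame's time is the start of its exposure; t = 0 is trigger
addition and the first red frame; green frames are offset by the
inter-channel lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import erf

from .imaging import Movie
from .lattice import LatticeTrajectory, Site, junction_state_series, transformation_time_true

logger = logging.getLogger(__name__)

CHANNELS = ("red", "green")


class OpticsConfigError(ValueError):
    pass


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition and noise model of the synthetic microscope.

    Defaults follow the alternating-excitation time-lapse protocol: 100 ms
    exposure, one frame per second and colour, 0.5 s lag between colours,
    25 min total.
    """

    image_size: tuple[int, int] = (96, 96)  # (H, W) px
    pixel_size_nm: float = 117.0
    psf_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"red": 1.15, "green": 1.05}
    )
    photon_rate: float = 180.0        # photons/frame in the on state
    residual_fraction: float = 0.02   # off-state leakage relative to on-rate
    background: float = 20.0          # photons/px/frame
    exposure: float = 0.1             # s
    channel_period: float = 1.0       # s between frames of one colour
    inter_channel_lag: float = 0.5    # s green after red
    total_duration: float = 1500.0    # s
    bleach_rate: Mapping[str, float] = field(
        default_factory=lambda: {"red": 1.0 / 90.0, "green": 1.0 / 90.0}
    )                                 # 1/s of cumulative on-exposure
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # px/s
    drift_jitter: float = 0.0         # px, per-frame white jitter
    chromatic_offset: tuple[float, float] = (0.0, 0.0)  # green = red + offset, px
    n_fiducials: int = 4
    fiducial_brightness: float = 1.5  # relative to photon_rate

    def __post_init__(self):
        if not self.exposure < self.channel_period:
            raise OpticsConfigError("exposure must be shorter than the channel period")
        if not self.inter_channel_lag < self.channel_period:
            raise OpticsConfigError("inter-channel lag must be shorter than the period")
        for name in ("photon_rate", "background", "residual_fraction"):
            if getattr(self, name) < 0:
                raise OpticsConfigError(f"{name} must be >= 0")
        if any(v < 0 for v in dict(self.bleach_rate).values()):
            raise OpticsConfigError("bleach rates must be >= 0")

    def frame_times(self, channel: str) -> np.ndarray:
        offset = 0.0 if channel == "red" else self.inter_channel_lag
        n = int(np.floor(self.total_duration / self.channel_period))
        return offset + self.channel_period * np.arange(n)


@dataclass(frozen=True)
class StructurePlacement:
    """One origami structure in the field of view.

    ``x, y`` are red-channel frame-0 coordinates; ``probes`` maps channel to
    the monitored lattice site.
    """

    x: float
    y: float
    probes: Mapping[str, Site]
    trajectory: LatticeTrajectory


@dataclass
class SyntheticDataset:
    """Rendered movies plus the ground truth that produced them."""

    movies: dict[str, Movie]
    ground_truth: pd.DataFrame
    state_series: dict[int, dict[str, np.ndarray]]
    fiducials_xy: np.ndarray          # red-channel coordinates, (N, 2)
    drift: dict[str, np.ndarray]      # per-channel per-frame (dx, dy)
    optics: OpticsConfig
    scenario: str = ""
    seed: int = 0

    def __post_init__(self):
        n_struct = len(self.state_series)
        if len(self.ground_truth) != n_struct:
            raise OpticsConfigError("every rendered structure needs a ground-truth row")


def true_transformation_time_sampled(
    series: np.ndarray, times: np.ndarray, min_dwell: float = 10.0
) -> float | None:
    """Dwell-rule transformation time of a true state series on the frame grid.

    Applies the same rule as the transient analysis (first dark-to-bright
    transition followed by at least ``min_dwell`` seconds of uninterrupted
    occupancy, record end counting as occupancy) to the noise-free sampled
    conformation series, so recovered times can be compared frame for frame.
    """
    s = np.asarray(series, dtype=int)
    t = np.asarray(times, dtype=float)
    end_time = t[-1] + (t[-1] - t[-2] if len(t) > 1 else 0.0)
    i = 0
    while i < len(s):
        if s[i] == 1 and (i == 0 or s[i - 1] == 0):
            j = i
            while j < len(s) and s[j] == 1:
                j += 1
            dwell = (t[j] if j < len(s) else end_time) - t[i]
            if i > 0 and dwell >= min_dwell:
                return float(t[i])
            i = j
        else:
            i += 1
    return None


def _gauss_pixel_weights(x: float, y: float, sigma: float, shape: tuple[int, int]):
    """Pixel-integrated Gaussian weights in a window around (x, y)."""
    h, w = shape
    r = int(np.ceil(4 * sigma)) + 1
    xi, yi = int(round(x)), int(round(y))
    xs = np.arange(max(0, xi - r), min(w, xi + r + 1))
    ys = np.arange(max(0, yi - r), min(h, yi + r + 1))
    if len(xs) == 0 or len(ys) == 0:
        return ys, xs, np.zeros((0, 0))
    s = sigma * np.sqrt(2.0)
    wx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    wy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    return ys, xs, np.outer(wy, wx)


def render_movie(
    structures: list[StructurePlacement],
    optics: OpticsConfig,
    seed: int,
    scenario: str = "",
) -> SyntheticDataset:
    """Render placed structures into one movie stack per channel.

    Per frame each probe emits Poisson photons at the on-rate if its site is
    transformed and the dye is unbleached, at the residual rate otherwise.
    Deterministic given inputs and *seed*.
    """
    h, w = optics.image_size
    min_sep = 4.0 * max(dict(optics.psf_sigma).values())
    for i, a in enumerate(structures):
        for b in structures[i + 1 :]:
            if (a.x - b.x) ** 2 + (a.y - b.y) ** 2 < min_sep**2:
                logger.warning(
                    "structures at (%.1f, %.1f) and (%.1f, %.1f) closer than %.1f px: "
                    "detection may be ambiguous", a.x, a.y, b.x, b.y, min_sep,
                )
    root = np.random.SeedSequence(seed)
    fid_rng = np.random.default_rng(root.spawn(1)[0])
    margin = 6.0
    occupied = [(s.x, s.y) for s in structures]
    fid_pts: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(fid_pts) == optics.n_fiducials:
            break
        fx = fid_rng.uniform(margin, w - margin)
        fy = fid_rng.uniform(margin, h - margin)
        if all(
            (fx - ox) ** 2 + (fy - oy) ** 2 >= min_sep**2
            for ox, oy in occupied + fid_pts
        ):
            fid_pts.append((fx, fy))
    if len(fid_pts) < optics.n_fiducials:
        raise OpticsConfigError("could not place fiducials clear of structures")
    fiducials_xy = np.asarray(fid_pts, dtype=float).reshape(-1, 2)

    movies: dict[str, Movie] = {}
    drift: dict[str, np.ndarray] = {}
    state_series: dict[int, dict[str, np.ndarray]] = {i: {} for i in range(len(structures))}
    gt_rows = [
        {
            "structure_id": i,
            "site_red": str(tuple(s.probes["red"])),
            "site_green": str(tuple(s.probes["green"])),
            "x_px": s.x,
            "y_px": s.y,
        }
        for i, s in enumerate(structures)
    ]

    chan_seeds = root.spawn(len(CHANNELS) + 1)[1:]
    for channel, chan_seed in zip(CHANNELS, chan_seeds):
        rng = np.random.default_rng(chan_seed)
        times = optics.frame_times(channel)
        n_frames = len(times)
        sigma = dict(optics.psf_sigma)[channel]
        off = np.array(optics.chromatic_offset) if channel == "green" else np.zeros(2)
        vx, vy = optics.drift_velocity
        dxy = np.column_stack([vx * times, vy * times])
        if optics.drift_jitter > 0:
            dxy = dxy + rng.normal(0.0, optics.drift_jitter, size=dxy.shape)
            dxy[0] = (vx * times[0], vy * times[0])
        drift[channel] = dxy

        rate_bleach = dict(optics.bleach_rate).get(channel, 0.0)
        frames = np.empty((n_frames, h, w), dtype=np.uint16)
        # precompute per-structure on/off series and bleach budgets
        onoff = []
        budgets = []
        for i, s in enumerate(structures):
            series = junction_state_series(s.trajectory, s.probes[channel], times)
            state_series[i][channel] = series
            onoff.append(series.astype(bool))
            budgets.append(
                rng.exponential(1.0 / rate_bleach) if rate_bleach > 0 else np.inf
            )
        bleach_t = np.full(len(structures), np.nan)
        remaining = np.array(budgets, dtype=float)

        for t in range(n_frames):
            img = rng.poisson(optics.background, size=(h, w)).astype(np.float64)
            for i, s in enumerate(structures):
                emitting = onoff[i][t] and remaining[i] > 0
                if onoff[i][t] and remaining[i] > 0:
                    remaining[i] -= optics.exposure
                    if remaining[i] <= 0 and np.isnan(bleach_t[i]):
                        bleach_t[i] = times[t] + optics.exposure
                rate = optics.photon_rate if emitting else optics.photon_rate * optics.residual_fraction
                if rate <= 0:
                    continue
                ys, xs, wgt = _gauss_pixel_weights(
                    s.x + off[0] + dxy[t, 0], s.y + off[1] + dxy[t, 1], sigma, (h, w)
                )
                if wgt.size:
                    img[np.ix_(ys, xs)] += rng.poisson(rate * wgt)
            fid_rate = optics.photon_rate * optics.fiducial_brightness
            for fx, fy in fiducials_xy:
                ys, xs, wgt = _gauss_pixel_weights(
                    fx + off[0] + dxy[t, 0], fy + off[1] + dxy[t, 1], sigma, (h, w)
                )
                if wgt.size:
                    img[np.ix_(ys, xs)] += rng.poisson(fid_rate * wgt)
            frames[t] = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)

        movies[channel] = Movie(frames=frames, timestamps=times, channel=channel)
        for i, s in enumerate(structures):
            gt_rows[i][f"t_transform_{channel}_s"] = transformation_time_true(
                s.trajectory, s.probes[channel]
            )
            gt_rows[i][f"t_bleach_{channel}_s"] = bleach_t[i]

    ground_truth = pd.DataFrame(gt_rows)
    return SyntheticDataset(
        movies=movies,
        ground_truth=ground_truth,
        state_series=state_series,
        fiducials_xy=fiducials_xy,
        drift=drift,
        optics=optics,
        scenario=scenario,
        seed=seed,
    )
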
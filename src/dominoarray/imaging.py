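"""From raw two-channel movies to per-structure dual-colour transients.

Processing follows the standard single-molecule time-lapse chain: fiducial
detection, drift estimation, channel registration, detection of spots that
appear during the measurement (turn-on probes), and background-subtracted
intensity extraction.  Drift is never applied by resampling frames; shifts
are applied to extraction coordinates instead.

Coordinates are 0-based with ``x`` the column and ``y`` the row; pixel
centres sit at integer coordinates and subpixel positions are continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

logger = logging.getLogger(__name__)

#: Default aperture geometry (px): integration disk and background annulus.
DISK_RADIUS = 3.0
ANNULUS_INNER = 5.0
ANNULUS_OUTER = 8.0
#: Detection threshold in robust noise units.
DETECTION_NSIGMA = 5.0
#: A fiducial must be bright in at least this fraction of frames.
FIDUCIAL_PERSISTENCE = 0.95


class ImagingError(ValueError):
    pass


@dataclass(frozen=True)
class Movie:
    """A single-channel frame stack with per-frame timestamps (s)."""

    frames: np.ndarray
    timestamps: np.ndarray
    channel: str

    def __post_init__(self):
        frames = np.asarray(self.frames)
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)
        if frames.ndim != 3:
            raise ImagingError("frames must be a (T, H, W) stack")
        if len(ts) != frames.shape[0]:
            raise ImagingError("one timestamp per frame required")
        if np.any(np.diff(ts) <= 0):
            raise ImagingError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class DriftTrace:
    """Per-frame (dx, dy) translation in px relative to frame 0."""

    shifts: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        if shifts.ndim != 2 or shifts.shape[1] != 2:
            raise ImagingError("shifts must be (T, 2)")
        if not np.all(np.isfinite(shifts)):
            raise ImagingError("drift shifts must be finite")
        if not np.allclose(shifts[0], 0.0):
            raise ImagingError("drift at frame 0 must be (0, 0)")

    @classmethod
    def identity(cls, n_frames: int) -> "DriftTrace":
        return cls(shifts=np.zeros((n_frames, 2)))


@dataclass(frozen=True)
class SpotRecord:
    channel: str
    x: float
    y: float
    first_frame: int
    is_fiducial: bool = False
    saturated: bool = False

    def __post_init__(self):
        if self.first_frame < 0:
            raise ImagingError("first-appearance frame must be >= 0")


@dataclass(frozen=True)
class Transient:
    """Background-subtracted intensity-versus-time of one spot."""

    times: np.ndarray
    intensities: np.ndarray
    channel: str
    spot: SpotRecord | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if len(t) != len(i):
            raise ImagingError("times and intensities must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ImagingError("times must be strictly increasing")


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map ``p_red = A @ (x, y, 1)`` from green to red coordinates."""

    matrix: np.ndarray
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "residuals", np.asarray(self.residuals, dtype=float))
        if m.shape != (2, 3):
            raise ImagingError("affine matrix must be 2x3")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ones = np.ones((xy.shape[0], 1))
        return np.hstack([xy, ones]) @ self.matrix.T


# --- low-level helpers -----------------------------------------------------


def robust_sigma(values: np.ndarray) -> float:
    """Noise scale from the median absolute deviation."""
    v = np.asarray(values, dtype=float).ravel()
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


def gaussian_centroid(
    image: np.ndarray,
    x0: float,
    y0: float,
    window: int = 4,
    weight_sigma: float = 2.0,
    n_iter: int = 3,
) -> tuple[float, float]:
    """Subpixel localisation by iterative Gaussian-weighted centroid."""
    h, w = image.shape
    x, y = float(x0), float(y0)
    for _ in range(n_iter):
        xi, yi = int(round(x)), int(round(y))
        sl_y = slice(max(0, yi - window), min(h, yi + window + 1))
        sl_x = slice(max(0, xi - window), min(w, xi + window + 1))
        patch = np.asarray(image[sl_y, sl_x], dtype=float)
        if patch.size == 0:
            break
        yy, xx = np.mgrid[sl_y, sl_x]
        bg = np.median(patch)
        weights = np.clip(patch - bg, 0, None) * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * weight_sigma**2)
        )
        total = weights.sum()
        if total <= 0:
            break
        x = float((weights * xx).sum() / total)
        y = float((weights * yy).sum() / total)
    return x, y


def disk_annulus_masks(shape: tuple[int, int], x: float, y: float):
    """Pixel index arrays of the integration disk and background annulus."""
    h, w = shape
    r_out = int(np.ceil(ANNULUS_OUTER)) + 1
    xi, yi = int(round(x)), int(round(y))
    sl_y = slice(max(0, yi - r_out), min(h, yi + r_out + 1))
    sl_x = slice(max(0, xi - r_out), min(w, xi + r_out + 1))
    yy, xx = np.mgrid[sl_y, sl_x]
    r2 = (xx - x) ** 2 + (yy - y) ** 2
    disk = r2 <= DISK_RADIUS**2
    annulus = (r2 >= ANNULUS_INNER**2) & (r2 <= ANNULUS_OUTER**2)
    return (yy[disk], xx[disk]), (yy[annulus], xx[annulus])


def aperture_intensity(frame: np.ndarray, x: float, y: float) -> float:
    """Disk sum minus (disk area x robust background of the surrounding annulus).

    The background estimate is a sigma-clipped mean: as outlier-resistant as
    an annulus median against bleed-through from neighbouring emitters, but
    without the median's discreteness bias on integer photon counts.
    """
    (dy, dx), (ay, ax) = disk_annulus_masks(frame.shape, x, y)
    if len(dy) == 0:
        return np.nan
    disk_sum = float(np.asarray(frame[dy, dx], dtype=float).sum())
    if len(ay):
        ann = np.asarray(frame[ay, ax], dtype=float)
        centre = np.median(ann)
        scale = 1.4826 * np.median(np.abs(ann - centre)) or ann.std() or 1.0
        clipped = ann[np.abs(ann - centre) <= 3.0 * scale]
        bg = float(clipped.mean()) if len(clipped) else float(centre)
    else:
        bg = 0.0
    return disk_sum - bg * len(dy)


def _detect_peaks(image: np.ndarray, nsigma: float = DETECTION_NSIGMA,
                  low_sigma: float = 1.0, high_sigma: float = 3.0) -> list[tuple[float, float]]:
    """Difference-of-Gaussians band-pass detection with a robust threshold."""
    band = difference_of_gaussians(np.asarray(image, dtype=float), low_sigma, high_sigma)
    noise = robust_sigma(band)
    if noise <= 0:
        noise = band.std() or 1.0
    peaks = peak_local_max(band, min_distance=3, threshold_abs=nsigma * noise, exclude_border=2)
    out = []
    for yi, xi in peaks:
        x, y = gaussian_centroid(image, float(xi), float(yi))
        out.append((x, y))
    return out


# --- operations ------------------------------------------------------------


def detect_fiducials(movie: Movie, nsigma: float = DETECTION_NSIGMA) -> list[SpotRecord]:
    """Spots bright in >= 95% of frames, including frame 0.

    Candidates come from band-pass detection on the temporal median
    projection; persistence is checked with aperture photometry against the
    per-frame detection threshold.
    """
    if movie.n_frames < 10:
        raise ImagingError("need at least 10 frames for fiducial detection")
    median_proj = np.median(np.asarray(movie.frames, dtype=float), axis=0)
    candidates = _detect_peaks(median_proj, nsigma=nsigma)
    out = []
    n_check = min(movie.n_frames, 200)
    check_idx = np.unique(np.linspace(0, movie.n_frames - 1, n_check).astype(int))
    for x, y in candidates:
        vals = np.array([aperture_intensity(movie.frames[i], x, y) for i in check_idx])
        noise = robust_sigma(np.asarray(movie.frames[0], dtype=float)) * np.sqrt(
            np.pi * DISK_RADIUS**2
        )
        bright = vals > nsigma * noise
        if bright[0] and bright.mean() >= FIDUCIAL_PERSISTENCE:
            out.append(SpotRecord(channel=movie.channel, x=x, y=y, first_frame=0, is_fiducial=True))
    return out


def estimate_drift(
    movie: Movie,
    fiducials: list[SpotRecord],
    smooth_frames: int = 9,
) -> DriftTrace:
    """Per-frame translation from fiducial displacements.

    Each fiducial is re-localised every frame around its drift-predicted
    position; the consensus shift is the median across fiducials, smoothed
    with a moving average.  Frames where a fiducial is lost are interpolated.
    """
    if not fiducials:
        logger.warning("no fiducials: drift correction downgraded to identity")
        return DriftTrace.identity(movie.n_frames)
    n = movie.n_frames
    raw = np.zeros((n, 2))
    prev = np.zeros(2)
    for t in range(n):
        frame = np.asarray(movie.frames[t], dtype=float)
        disp = []
        for f in fiducials:
            x, y = gaussian_centroid(frame, f.x + prev[0], f.y + prev[1])
            d = np.array([x - f.x, y - f.y])
            if np.linalg.norm(d - prev) < 5.0:  # reject lost / jumped fits
                disp.append(d)
        if disp:
            raw[t] = np.median(np.asarray(disp), axis=0)
            prev = raw[t]
        else:
            raw[t] = np.nan
            logger.warning("all fiducials lost at frame %d; interpolating", t)
    for k in range(2):
        col = raw[:, k]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), col[~bad])
    smooth = uniform_filter1d(raw, size=max(1, smooth_frames), axis=0, mode="nearest")
    smooth = smooth - smooth[0]
    resid = []
    for t in (0, n // 2, n - 1):
        frame = np.asarray(movie.frames[t], dtype=float)
        for f in fiducials:
            x, y = gaussian_centroid(frame, f.x + smooth[t, 0], f.y + smooth[t, 1])
            resid.append((x - f.x - smooth[t, 0]) ** 2 + (y - f.y - smooth[t, 1]) ** 2)
    rms = float(np.sqrt(np.mean(resid))) if resid else 0.0
    return DriftTrace(shifts=smooth, residual_rms=rms)


def register_channels(
    fiducials_red: list[SpotRecord],
    fiducials_green: list[SpotRecord],
    match_radius: float = 4.0,
) -> AffineTransform2D:
    """Least-squares green-to-red transform from matched fiducial pairs.

    Affine with >= 3 non-collinear pairs, translation-only with fewer;
    identity (with a warning) when no pair matches.
    """
    red = np.array([[f.x, f.y] for f in fiducials_red], dtype=float).reshape(-1, 2)
    green = np.array([[f.x, f.y] for f in fiducials_green], dtype=float).reshape(-1, 2)
    if len(red) == 0 or len(green) == 0:
        logger.warning("no fiducial pairs: channel registration set to identity")
        return AffineTransform2D.identity()
    # coarse alignment by median offset, then nearest-neighbour matching
    offset = np.median(red, axis=0) - np.median(green, axis=0) if len(red) == len(green) else np.zeros(2)
    pairs = []
    for g in green:
        d = np.linalg.norm(red - (g + offset), axis=1)
        j = int(np.argmin(d))
        if d[j] <= match_radius:
            pairs.append((g, red[j]))
    if not pairs:
        logger.warning("no matched fiducial pairs: identity registration")
        return AffineTransform2D.identity()
    g = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    if len(pairs) >= 3 and np.linalg.matrix_rank(g - g.mean(axis=0)) == 2:
        design = np.hstack([g, np.ones((len(g), 1))])
        coef, *_ = np.linalg.lstsq(design, r, rcond=None)
        matrix = coef.T
    else:
        t = (r - g).mean(axis=0)
        matrix = np.array([[1.0, 0.0, t[0]], [0.0, 1.0, t[1]]])
    tr = AffineTransform2D(matrix=matrix)
    resid = np.linalg.norm(tr.apply(g) - r, axis=1)
    return AffineTransform2D(matrix=matrix, residuals=resid)


def detect_appearing_spots(
    movie: Movie,
    drift: DriftTrace,
    nsigma: float = DETECTION_NSIGMA,
    baseline_frames: int = 20,
    n_blocks: int = 10,
) -> list[SpotRecord]:
    """Turn-on spots: bright at some point in the movie but absent early.

    The movie is split into time blocks; band-pass detection runs on the
    pixelwise maximum of the block means minus the early-baseline mean, so
    spots that photobleach mid-movie are still found.  Candidates already
    bright in the baseline (including fiducials) are excluded.  Positions
    are reported in frame-0 coordinates (block drift subtracted); the
    first-appearance frame is the first frame whose aperture intensity
    exceeds half the fitted on-level.
    """
    n = movie.n_frames
    nb = min(baseline_frames, max(1, n // 10))
    base = np.asarray(movie.frames[:nb], dtype=float).mean(axis=0)
    edges = np.linspace(nb, n, min(n_blocks, max(1, (n - nb) // 5)) + 1).astype(int)
    block_means = np.stack(
        [np.asarray(movie.frames[a:b], dtype=float).mean(axis=0) for a, b in zip(edges, edges[1:]) if b > a]
    )
    block_drift = np.stack(
        [drift.shifts[a:b].mean(axis=0) for a, b in zip(edges, edges[1:]) if b > a]
    )
    stack = block_means - base[None]
    diff = stack.max(axis=0)
    out = []
    # robust_sigma(base) already reflects the nb-frame averaging
    noise0 = robust_sigma(base) * np.sqrt(np.pi * DISK_RADIUS**2)
    for x, y in _detect_peaks(diff, nsigma=nsigma):
        # drift of the block in which this candidate is brightest
        vals_b = np.array([aperture_intensity(bm, x, y) for bm in stack])
        late_drift = block_drift[int(np.argmax(vals_b))]
        base_int = aperture_intensity(base, x, y)
        if base_int > nsigma * noise0:
            continue  # present from the start: fiducial or pre-transformed
        x0, y0 = x - late_drift[0], y - late_drift[1]
        vals = np.array(
            [
                aperture_intensity(
                    movie.frames[t], x0 + drift.shifts[t, 0], y0 + drift.shifts[t, 1]
                )
                for t in range(n)
            ]
        )
        on_level = np.median(np.sort(vals)[-max(5, n // 10) :])
        thr = 0.5 * on_level
        sustained = np.array(
            [vals[i] > thr and vals[i : i + 3].mean() > thr for i in range(n)]
        )
        above = np.flatnonzero(sustained)
        first = int(above[0]) if len(above) else 0
        saturated = bool(np.any(movie.frames[n - 1] >= np.iinfo(np.uint16).max)) if movie.frames.dtype == np.uint16 else False
        out.append(
            SpotRecord(channel=movie.channel, x=x0, y=y0, first_frame=first, saturated=saturated)
        )
    return out


def extract_transient(movie: Movie, drift: DriftTrace, spot: SpotRecord) -> Transient:
    """Aperture photometry along the drift-corrected spot position."""
    n = movie.n_frames
    h, w = movie.shape
    vals = np.empty(n)
    last = n
    for t in range(n):
        x = spot.x + drift.shifts[t, 0]
        y = spot.y + drift.shifts[t, 1]
        if not (0 <= x < w and 0 <= y < h):
            last = t
            logger.warning("spot drifted out of frame at t=%d; transient truncated", t)
            break
        vals[t] = aperture_intensity(movie.frames[t], x, y)
    return Transient(
        times=movie.timestamps[:last],
        intensities=vals[:last],
        channel=movie.channel,
        spot=spot,
    )


def pair_colocalized(
    spots_red: list[SpotRecord],
    spots_green: list[SpotRecord],
    transform: AffineTransform2D,
    radius_px: float = 1.5,
) -> tuple[list[tuple[SpotRecord, SpotRecord]], list[SpotRecord], list[SpotRecord]]:
    """Mutual-nearest-neighbour pairing of red and green spots.

    Green positions are mapped into red coordinates first.  Returns
    ``(pairs, unpaired_red, unpaired_green)``; ambiguous matches are resolved
    by distance, ties by earlier first appearance.
    """
    if not spots_red or not spots_green:
        return [], list(spots_red), list(spots_green)
    red_xy = np.array([[s.x, s.y] for s in spots_red])
    green_xy = transform.apply(np.array([[s.x, s.y] for s in spots_green]))
    d = np.linalg.norm(red_xy[:, None, :] - green_xy[None, :, :], axis=2)
    order = sorted(
        ((d[i, j], spots_green[j].first_frame, i, j)
         for i in range(len(spots_red)) for j in range(len(spots_green))
         if d[i, j] <= radius_px),
    )
    used_r: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for dist, _, i, j in order:
        if i in used_r or j in used_g:
            continue
        # mutual nearest neighbour check
        if np.argmin(d[i]) != j and d[i, np.argmin(d[i])] <= radius_px and np.argmin(d[i]) not in used_g:
            continue
        if np.argmin(d[:, j]) != i and d[np.argmin(d[:, j]), j] <= radius_px and np.argmin(d[:, j]) not in used_r:
            continue
        pairs.append((spots_red[i], spots_green[j]))
        used_r.add(i)
        used_g.add(j)
    unpaired_red = [s for i, s in enumerate(spots_red) if i not in used_r]
    unpaired_green = [s for j, s in enumerate(spots_green) if j not in used_g]
    return pairs, unpaired_red, unpaired_green
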